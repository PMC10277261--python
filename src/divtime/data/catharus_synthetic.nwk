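((Catharus_ustulatus:3.4175051180965585,(Catharus_guttatus:2.3849959002340775,Catharus_fuscescens:2.3849959002340775):1.0325092178624806):1.3124948819034425,((Catharus_minimus:1.0839132821322437,Catharus_bicknelli:1.0839132821322437):2.100950030360889,(Catharus_aurantiirostris:1.6612224732454248,((Catharus_fuscater:0.8716566899904065,Catharus_occidentalis:0.8716566899904065):0.6103911116918328,(Catharus_frantzii:1.1993050105303096,((Catharus_mexicanus:0.9909591720363508,Catharus_dryas:0.9909591720363508):0.07695369387821745,Catharus_gracilirostris:1.0679128659145682):0.13139214461574134):0.28274279115192974):0.17917467156318562):1.5236408392477079):1.5451366875068682);
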