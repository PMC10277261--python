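Taxa 1,Taxa 2,Divergence time,CI_low,CI_high,Studies
Passerina amoena,Passerina amoena,0.0,,,
Passerina amoena,Corythornis cristatus,70.0,64.5,80.0,16
Passerina amoena,Chalcomitra amethystine,27.6,25.4,38.1,5
Passerina amoena,Chrysococcyx cupreus,80.0,73.7,97.3,3
Corythornis cristatus,Passerina amoena,70.0,64.5,80.0,16
Corythornis cristatus,Corythornis cristatus,0.0,,,
Corythornis cristatus,Chalcomitra amethystine,70.0,64.5,80.0,16
Corythornis cristatus,Chrysococcyx cupreus,80.0,73.7,97.3,3
Chalcomitra amethystine,Passerina amoena,27.6,25.4,38.1,5
Chalcomitra amethystine,Corythornis cristatus,70.0,64.5,80.0,16
Chalcomitra amethystine,Chalcomitra amethystine,0.0,,,
Chalcomitra amethystine,Chrysococcyx cupreus,80.0,73.7,97.3,3
Chrysococcyx cupreus,Passerina amoena,80.0,73.7,97.3,3
Chrysococcyx cupreus,Corythornis cristatus,80.0,73.7,97.3,3
Chrysococcyx cupreus,Chalcomitra amethystine,80.0,73.7,97.3,3
Chrysococcyx cupreus,Chrysococcyx cupreus,0.0,,,
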