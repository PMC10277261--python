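(((Malurus_cyaneus:1.442090490334003,(Malurus_splendens:0.8374104138697754,((Malurus_lamberti:0.04688824434798045,Malurus_amabilis:0.04688824434798045):0.49234608973581206,(Malurus_pulcherrimus:0.17473525965126366,Malurus_elegans:0.17473525965126366):0.3644990744325288):0.29817607978598293):0.6046800764642276):3.277218836042035,((Malurus_coronatus:0.4965022103311521,Malurus_cyanocephalus:0.4965022103311521):1.7816284312515025,Malurus_alboscapulatus:2.2781306415826545):2.4411786847933836):4.280690673623962,(Malurus_melanocephalus:7.826707736089506,Malurus_leucopterus:7.826707736089506):1.173292263910494);
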