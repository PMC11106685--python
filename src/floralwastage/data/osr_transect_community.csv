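taxon,family,group,count
Apis mellifera,Apidae,honeybee,454
Bombus terrestris agg.,Apidae,bumblebee,92
Bombus lapidarius,Apidae,bumblebee,26
Bombus pascuorum,Apidae,bumblebee,4
Andrena tibialis,Andrenidae,non_apid_bee,4
Andrena fulvago,Andrenidae,non_apid_bee,3
Andrena cineraria,Andrenidae,non_apid_bee,3
Andrena haemorrhoa,Andrenidae,non_apid_bee,1
Andrena scotica,Andrenidae,non_apid_bee,1
Andrena spp.,Andrenidae,non_apid_bee,8
Halictidae,Halictidae,non_apid_bee,2
Dasysyrphus venustas,Syrphidae,non_bee,2
Other Syrphidae,Syrphidae,non_bee,4
Bombylius,Bombyliidae,non_bee,2
Other Diptera,,non_bee,30
Vanessa cardui,Nymphalidae,non_bee,1
Aglais io,Nymphalidae,non_bee,1
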