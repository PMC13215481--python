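genus,n_use_categories
Acrocomia,5
Aiphanes,2
Coccothrinax,3
Gaussia,1
Pseudophoenix,2
Syagrus,4
Thrinax,3
Zombia,1
Chrysobalanus,6
Theophrasta,1
Catesbaea,1
Goetzea,2
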