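species,family,mean_diameter_mm,mean_length_mm,mean_mass_g,total_count,max_floating_day,max_viable_day,p95_viable_day,n_islands
Acrocomia crispa,Arecaceae,23.9,24.3,3.9,111,21,21,21,2
Aiphanes minima,Arecaceae,15.7,16.1,2.7,63,13,13,9,8
Coccothrinax barbadensis,Arecaceae,10.9,12.4,1.1,168,0,0,0,12
Coccothrinax borhidiana,Arecaceae,12.9,15.2,1.8,182,3,3,3,1
Coccothrinax spissa,Arecaceae,10.4,12.0,1.1,77,0,0,0,1
Gaussia attenuata,Arecaceae,11.3,16.1,1.1,340,0,0,0,2
Pseudophoenix vinifera,Arecaceae,19.0,28.6,5.0,152,3,3,3,1
Syagrus amara,Arecaceae,31.0,41.0,25.2,29,0,0,0,4
Thrinax radiata,Arecaceae,8.8,10.3,0.6,168,28,28,11,15
Zombia antillarum,Arecaceae,20.5,21.4,5.2,33,21,21,21,1
Chrysobalanus icaco,Chrysobalanaceae,25.9,28.2,9.5,76,90+,90,87,33
Theophrasta jussieui,Primulaceae,43.4,46.7,49.0,17,28,21,7,1
Catesbaea spinosa,Rubiaceae,27.5,34.1,12.5,60,21,21,21,10
Goetzea elegans,Solanaceae,18.8,22.6,3.9,90,7,7,7,2
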