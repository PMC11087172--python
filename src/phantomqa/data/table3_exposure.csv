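protocol,dose_mgy,contrast_resolution,spatial_resolution,acrylic,air,bone,polyethylene,water,image_scaling,hu_uniformity
Pediatric head,17.6,1.5,6,117.5,-999.9,938.2,-95.7,-0.2,0.4,4.40
Pediatric head,21.2,1.9,6,117.9,-999.9,939.3,-96.2,0.2,0.2,3.64
Pediatric head,26.8,1.8,6,117.4,-999.9,939.5,-96.8,-0.5,0.5,3.85
Pediatric head,31.7,2.6,6,117.4,-999.9,938.4,-96.9,-0.5,0.2,3.53
Pediatric abdomen,2.8,0.7,5,118.8,-999.1,936.2,-95.4,-0.2,0.7,3.04
Pediatric abdomen,3.7,1.3,5,118.5,-999.5,936.5,-95.9,0.7,0.2,2.70
Pediatric abdomen,5.1,1.9,5,118.5,-999.6,937.2,-95.3,0.3,0.2,4.17
Pediatric abdomen,7.0,1.7,5,117.7,-999.7,937.4,-96.0,0.4,0.2,3.51
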