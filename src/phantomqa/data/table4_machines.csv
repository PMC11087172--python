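protocol,machine,phantom,contrast_resolution,spatial_resolution,acrylic,air,bone,polyethylene,water,image_scaling,hu_uniformity
Head,HyperSight,head,1.9,6,115.6,-999.8,932.0,-99.4,-3.4,0.2,4.32
Head,SOMATOM Edge,head,1.3,6,123.1,-980.5,854.0,-86.1,1.6,0.4,0.49
Head,TrueBeam,head,0.6,8,156.1,-998.9,1144.8,-92.0,21.2,0.2,56.52
Head,Halcyon 2.0,head,0.1,6,76.1,-998.6,1012.1,-141.0,-24.8,0.1,56.87
Abdomen,HyperSight,body,0.4,5,102.7,-973.2,834.3,-95.2,-12.5,0.5,6.78
Abdomen,SOMATOM Edge,body,0.5,6,120.8,-961.8,793.7,-79.4,0.2,0.1,0.53
Pelvis,HyperSight,body,0.3,5,102.1,-974.2,838.5,-95.1,-12.5,0.5,5.31
Pelvis,SOMATOM Edge,body,0.6,6,124.4,-963.4,798.2,-78.7,1.3,0.0,0.97
Pelvis,TrueBeam,body,0.2,5,54.3,-958.6,714.7,-126.3,-81.3,0.2,38.30
Pelvis,Halcyon 2.0,body,0.2,5,78.5,-936.6,795.5,-75.6,-27.2,0.1,118.82
Pelvis large,HyperSight,body,0.7,5,92.0,-962.4,765.9,-99.4,-21.5,0.1,7.42
Pelvis large,Halcyon 2.0,body,0.1,5,60.7,-917.0,718.0,-88.2,-36.5,0.0,102.10
Pediatric head,HyperSight,head,1.9,6,117.9,-999.9,939.3,-96.2,0.2,0.2,3.64
Pediatric head,SOMATOM Edge,head,0.6,6,123.6,-980.0,853.7,-85.4,1.9,0.2,0.77
Pediatric abdomen,HyperSight,head,0.6,5,118.4,-998.5,937.9,-96.4,-0.3,0.2,2.73
Pediatric abdomen,SOMATOM Edge,head,1.0,6,123.5,-982.0,853.6,-86.5,1.4,0.1,0.75
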