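phantom,protocol,contrast_resolution,spatial_resolution,acrylic,air,bone,polyethylene,water,image_scaling,hu_uniformity
head,Head,2.5,6,115.8,-999.2,931.3,-100.0,-3.1,0.6,4.05
head,H&N,2.0,6,117.5,-998.1,931.9,-98.2,-0.92,0.2,5.10
head,Thorax,2.2,5,117.2,-998.1,931.8,-98.9,-1.2,0.9,4.02
head,Thorax slow,2.6,5,116.8,-997.5,930.5,-97.6,-0.6,0.6,3.66
head,Breast,1.4,5,116.5,-997.4,928.1,-97.7,-0.7,0.2,4.98
head,Abdomen,2.0,5,116.9,-998.6,931.7,-98.7,-1.4,0.2,3.93
head,Abdomen large,2.6,5,115.2,-999.0,887.2,-98.6,-4.7,0.6,6.05
head,Pelvis,1.7,5,116.5,-998.9,931.3,-99.8,-2.0,0.5,4.02
head,Pelvis large,3.3,5,115.1,-999.3,887.2,-98.7,-5.4,0.2,6.05
head,Pediatric head,1.5,6,117.5,-999.9,938.2,-95.7,-0.2,0.4,4.40
head,Pediatric abdomen,0.7,5,118.8,-999.1,936.2,-95.4,-0.2,0.7,3.04
body,Head,0.7,6,102.4,-971.2,831.0,-93.3,-11.6,0.2,5.66
body,H&N,0.5,6,103.8,-971.4,831.4,-96.8,-11.3,0.2,3.99
body,Thorax,0.4,5,102.0,-970.3,829.5,-95.6,-12.1,0.5,4.51
body,Thorax slow,0.7,5,108.8,-978.2,846.5,-93.5,-6.9,0.5,8.17
body,Breast,0.2,5,101.6,-969.5,830.2,-93.5,-13.5,0.2,5.67
body,Abdomen,0.4,5,102.3,-973.7,833.1,-95.0,-12.0,0.5,5.83
body,Abdomen large,1.2,5,92.6,-961.2,762.2,-99.5,-20.3,0.1,6.62
body,Pelvis,0.4,5,102.7,-975.2,837.0,-94.9,-12.1,0.7,5.66
body,Pelvis large,1.0,5,92.4,-963.0,764.5,-99.6,-21.1,0.8,7.65
body,Pediatric head,0.6,6,99.3,-962.6,805.2,-97.7,-12.2,0.1,8.75
body,Pediatric abdomen,0.3,5,98.8,-965.6,820.0,-95.3,-15.3,0.2,9.79
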