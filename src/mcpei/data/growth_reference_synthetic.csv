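# Synthetic compact growth reference: approximate median weight-for-age and
# height-for-age by sex, month resolution at key ages, smooth-interpolated at
# runtime. These are constructed approximations of published pediatric growth
# medians (infancy chart <12 mo; child chart 12-168 mo), not the official
# tables; adequate for dose standardization, not for clinical growth
# assessment.
sex,age_months,median_weight_kg,median_height_cm
M,0,3.3,49.9
M,1,4.5,54.7
M,2,5.6,58.4
M,3,6.4,61.4
M,4,7.0,63.9
M,5,7.5,65.9
M,6,7.9,67.6
M,7,8.3,69.2
M,8,8.6,70.6
M,9,8.9,72.0
M,10,9.2,73.3
M,11,9.4,74.5
M,12,9.6,75.7
M,24,12.2,87.8
M,36,14.3,96.1
M,48,16.3,103.3
M,60,18.3,110.0
M,72,20.5,116.0
M,84,22.9,121.7
M,96,25.4,127.3
M,108,28.1,132.6
M,120,31.2,137.8
M,132,34.7,143.1
M,144,38.8,149.1
M,156,43.4,156.0
M,168,48.3,163.2
F,0,3.2,49.1
F,1,4.2,53.7
F,2,5.1,57.1
F,3,5.8,59.8
F,4,6.4,62.1
F,5,6.9,64.0
F,6,7.3,65.7
F,7,7.6,67.3
F,8,7.9,68.7
F,9,8.2,70.1
F,10,8.5,71.5
F,11,8.7,72.8
F,12,8.9,74.0
F,24,11.5,86.4
F,36,13.9,95.1
F,48,16.1,102.7
F,60,18.2,109.4
F,72,20.2,115.1
F,84,22.4,120.8
F,96,25.0,126.6
F,108,28.2,132.5
F,120,31.9,138.6
F,132,36.2,145.0
F,144,41.0,151.2
F,156,45.6,155.8
F,168,49.4,158.9
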