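accession,strain,halo_mm,class,act_pH4_T60,act_pH4_T26,act_pH6_T26
AGO02713,a14h,4.6,M,400,280,320
AGO02715,d16d,5.7,H,295,80,300
AGO02724,d19d,5,M,490,360,370
AGO63347,d3d,5,M,60,120,150
AGO63342,h11h,5,M,590,380,205
AGO02730,h13f,4.2,M,170,200,150
AGS78259,h13h,4.1,M,490,370,320
AGO63354,h14d,6.5,H,740,120,170
AGO63351,h14h,5,M,810,130,330
AGO63345,h16h,4.8,M,330,205,150
AGO63356,k2b,7,H,670,230,250
AGO02722,k32l,5,M,280,290,150
AGO02727,k33l,5,M,440,660,330
AGO63344,k36p88,5,M,400,230,180
AGO63350,k40b,6,H,610,320,200
AGO02714,k43l,5,M,220,180,50
AGO02728,k46b,4,M,510,60,210
AGO02725,s6a,5.8,H,710,420,40
AGO02721,s7e,6.5,H,890,420,780
AGO02726,S7h,5,M,370,350,280
AGO97103,t27b,4.3,M,530,280,210
AGO02717,t28d,5,M,525,170,150
AGO63355,t31d,4,M,5,40,50
AGO63353,t34b,4.5,M,210,0,120
AGO02716,t37a,8,H,670,280,590
AGO02718,t41a,5,H,505,310,390
AGO02729,W,4.5,M,410,110,125
AGO63357,Y,4.5,M,690,390,260
AGO02712,b16b,3,L,,,
AGO02719,s2f,2.9,L,,,
AGO02720,s2h,2.5,L,,,
AGO02732,a10d,3.5,M,,,
AGO02723,d3b,2.5,L,,,
AGO02731,b5d,3,L,,,
AGO02733,s3d,2,L,,,
AGO63358,b9h,2.7,L,,,
AGO63360,s5d,3,L,,,
AGO97104,h13d,3,L,,,
AGO02734,S1d,3.8,M,,,
AGO63359,k27k88,3.5,M,,,
AGO63349,b11h,3.5,M,,,
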