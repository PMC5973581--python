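landmark,side,x,y,z
U6C,L,0.0,8.0,24.0
U6C,R,0.0,8.0,-24.0
U6R,L,11.738,5.505,23.0
U6R,R,11.738,5.505,-23.0
U3C,L,0.0,38.0,18.0
U3C,R,0.0,38.0,-18.0
U3R,L,15.524,34.130,17.0
U3R,R,15.524,34.130,-17.0
U2C,L,0.0,44.0,11.0
U2C,R,0.0,44.0,-11.0
U2R,L,12.016,40.555,10.5
U2R,R,12.016,40.555,-10.5
U1C,L,0.0,46.0,4.0
U1C,R,0.0,46.0,-4.0
U1R,L,12.557,42.635,4.0
U1R,R,12.557,42.635,-4.0
ANS,M,6.0,50.0,0.0
PNS,M,10.0,2.0,0.0
IMP_P_HEAD,L,4.0,13.0,27.0
IMP_P_HEAD,R,4.0,13.0,-27.0
IMP_P_TAIL,L,9.0,14.0,22.0
IMP_P_TAIL,R,9.0,14.0,-22.0
IMP_A_HEAD,L,4.0,37.0,16.0
IMP_A_HEAD,R,4.0,37.0,-16.0
IMP_A_TAIL,L,9.0,32.0,19.0
IMP_A_TAIL,R,9.0,32.0,-19.0
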