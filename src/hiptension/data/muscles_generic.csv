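name,segment_origin,ox,oy,oz,via,segment_insertion,ix,iy,iz,f_iso_max,l_opt,l_ts,k_pe,eps0
glut_max1,pelvis,-0.090000000,0.030000000,-0.075000000,femur:-0.035000:0.030000:0.010000,femur,-0.025000000,0.030000000,0.075000000,573.000000000,0.085101831,0.103793039,4.000000000,0.600000000
glut_max2,pelvis,-0.095000000,0.015000000,-0.028000000,femur:-0.036000:0.025000:0.015000,femur,-0.022000000,0.025000000,0.085000000,819.000000000,0.092835001,0.078356559,4.000000000,0.600000000
glut_max3,pelvis,-0.098000000,0.005000000,0.005000000,,femur,-0.018000000,0.020000000,0.110000000,552.000000000,0.080732082,0.103993262,4.000000000,0.600000000
glut_med1,pelvis,0.010000000,0.055000000,-0.055000000,,femur,-0.005000000,0.050000000,0.015000000,819.000000000,0.034692267,0.031916886,4.000000000,0.600000000
glut_med2,pelvis,-0.015000000,0.050000000,-0.055000000,,femur,-0.008000000,0.048000000,0.018000000,573.000000000,0.038329028,0.035262705,4.000000000,0.600000000
glut_med3,pelvis,-0.035000000,0.040000000,-0.050000000,,femur,-0.010000000,0.046000000,0.020000000,653.000000000,0.041464729,0.038147551,4.000000000,0.600000000
glut_min1,pelvis,0.005000000,0.045000000,-0.040000000,,femur,-0.003000000,0.044000000,0.012000000,270.000000000,0.025317427,0.023292033,4.000000000,0.600000000
glut_min2,pelvis,-0.010000000,0.042000000,-0.040000000,,femur,-0.005000000,0.043000000,0.014000000,285.000000000,0.027946742,0.025711003,4.000000000,0.600000000
glut_min3,pelvis,-0.025000000,0.038000000,-0.038000000,,femur,-0.007000000,0.042000000,0.016000000,323.000000000,0.031401516,0.028889394,4.000000000,0.600000000
iliacus,pelvis,0.048000000,0.020000000,-0.055000000,pelvis:0.035000:0.005000:0.010000,femur,-0.028000000,-0.012000000,0.060000000,1073.000000000,0.056048512,0.077307215,4.000000000,0.600000000
psoas,pelvis,0.042000000,-0.010000000,-0.090000000,pelvis:0.033000:0.002000:0.012000,femur,-0.030000000,-0.013000000,0.065000000,1113.000000000,0.066723303,0.100040677,4.000000000,0.600000000
rect_fem,pelvis,0.045000000,0.008000000,-0.020000000,,shank,0.040000000,0.000000000,0.075000000,779.000000000,0.030142936,0.465902294,4.000000000,0.600000000
sartorius,pelvis,0.038000000,0.025000000,-0.030000000,,shank,0.008000000,-0.030000000,0.090000000,156.000000000,0.062435897,0.452523319,4.000000000,0.600000000
tfl,pelvis,0.032000000,0.042000000,-0.030000000,,femur,0.005000000,0.045000000,0.080000000,233.000000000,0.042248993,0.058381207,4.000000000,0.600000000
pectineus,pelvis,0.022000000,-0.040000000,0.000000000,,femur,-0.012000000,-0.010000000,0.095000000,177.000000000,0.036063978,0.058383158,4.000000000,0.600000000
add_longus,pelvis,0.025000000,-0.048000000,0.010000000,,femur,0.005000000,-0.015000000,0.200000000,627.000000000,0.043658937,0.137122211,4.000000000,0.600000000
add_brevis,pelvis,0.012000000,-0.050000000,0.020000000,,femur,-0.004000000,-0.012000000,0.120000000,429.000000000,0.038009025,0.066191036,4.000000000,0.600000000
add_mag_mid,pelvis,-0.060000000,-0.045000000,0.038000000,,femur,0.004000000,-0.018000000,0.230000000,381.000000000,0.104457107,0.158472647,4.000000000,0.600000000
add_mag_isch,pelvis,-0.080000000,-0.030000000,0.050000000,,femur,0.006000000,-0.020000000,0.360000000,343.000000000,0.166485490,0.227230897,4.000000000,0.600000000
gracilis,pelvis,0.008000000,-0.052000000,0.030000000,,shank,0.005000000,-0.032000000,0.095000000,108.000000000,0.029621640,0.436922199,4.000000000,0.600000000
semimem,pelvis,-0.085000000,-0.022000000,0.055000000,,shank,-0.024000000,-0.019000000,0.050000000,1030.000000000,0.076220521,0.371949414,4.000000000,0.600000000
semiten,pelvis,-0.088000000,-0.026000000,0.060000000,,shank,-0.008000000,-0.029000000,0.055000000,328.000000000,0.093080551,0.369029977,4.000000000,0.600000000
bifem_lh,pelvis,-0.086000000,-0.016000000,0.058000000,,shank,-0.022000000,0.030000000,0.048000000,717.000000000,0.075883956,0.377682675,4.000000000,0.600000000
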