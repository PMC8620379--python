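class,Control,ADI/II,ADIII/IV,ADV/VI
cholesterol,27.06,25.24,24.05,22.20
sterol_esters,1.58,2.96,3.81,4.51
dha,13.73,10.66,11.16,8.68
n6_lcpufa,12.19,11.41,11.49,10.69
monoenes,15.71,17.72,16.53,16.29
saturates,27.47,30.10,31.90,35.67
sphingolipids,2.26,1.92,1.06,1.97
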