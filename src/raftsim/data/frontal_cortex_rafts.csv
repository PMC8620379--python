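class,Control,ADI/II,ADIII/IV,ADV/VI
cholesterol,24.57,18.87,19.40,23.78
sterol_esters,1.20,5.57,5.33,3.69
dha,4.28,3.16,2.42,3.66
n6_lcpufa,3.95,4.95,4.90,4.89
monoenes,18.01,18.71,19.81,11.31
saturates,33.54,38.26,38.03,36.18
sphingolipids,14.45,10.49,10.10,16.49
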