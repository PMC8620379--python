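class,width_radius_angstrom,length_angstrom
cholesterol,5.94,19.99
sterol_esters,5.94,19.99
dha,6.74,19.01
n6_lcpufa,5.84,19.70
monoenes,5.30,22.59
saturates,6.14,22.44
sphingolipids,6.18,22.44
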