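term,Composite1,Composite2,Composite3,Composite4,Composite5
intercept,1.08,-0.07,-0.0066,0.479,-0.129
SSHO,,0.0607,2.413,3.137,
arw,0.001,-0.0082,,,
psm,-0.004,-0.0231,-0.919,-1.165,-0.316
nsm,-0.01,-0.0146,,,
dccs,-0.16,-0.0279,-1.381,-1.755,-0.115
mfs,-0.03,0.028,,,
arw_rt,,0.000012,,,
dccs_rt,,0.0000009,,,
psm_rt,,-0.00149,,,
age,,,0.0068,,0.048
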