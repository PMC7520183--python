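predictors,r2_fixed,r2,aic,wi
Sex*Month + (1|SampleSize) + (1|Location) + (1|Year),0.105,0.502,3141.78,0.99
Sex + Month + (1|SampleSize) + (1|Location) + (1|Year),0.076,0.462,3157.91,0.03
Month + (1|SampleSize) + (1|Location) + (1|Year),0.061,0.459,3172.53,2.10E-07
Sex + (1|SampleSize) + (1|Location) + (1|Year),0.017,0.406,3191.43,1.65E-11
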