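year,deaths,deaths_lo,deaths_hi,rate,rate_lo,rate_hi
2000,3549,3103,4248,1.72,1.51,2.05
2010,,,,3.78,3.33,4.31
2020,38253,34839,42181,15.97,14.55,17.61
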