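wavelength_nm,hb,hbo2,icg,irdye800
700,1.000,0.242,0.263,0.125
730,0.614,0.326,0.421,0.292
760,0.863,0.489,0.684,0.750
775,0.783,0.618,0.816,1.000
800,0.425,0.681,1.000,0.500
850,0.385,0.883,0.132,0.0375
900,0.425,1.000,0.026,0.00625
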