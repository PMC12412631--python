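# Molar extinction coefficients of haemoglobin in water, base-10, 1/(cm*M),
# from the standard compiled tabulation used across NIRS processing tools.
wavelength_nm,hbo,hbr
760,586.0,1548.52
850,1058.0,691.32
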