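# Molar extinction coefficients of oxy- and deoxyhemoglobin (cm^-1 M^-1,
# log-10 basis: mu_a = ln(10) * eps * c) from the standard Prahl-style
# NIR compilation, and pure-water absorption coefficients (cm^-1)
# interpolated from the Hale & Querry visible/NIR measurements.
# basis=log10
wavelength_nm,eps_hbo2,eps_hb,mu_a_water
690,276.0,2051.96,0.0047
785,735.4,972.16,0.0236
830,974.0,693.04,0.0343
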