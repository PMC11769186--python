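# Whole-blood absorption coefficients (150 g/L haemoglobin) and pure-water
# absorption at the two pulse-oximetry wavelengths, in mm^-1.
# mu_a = ln(10) * epsilon * C_Hb with C_Hb = 150/64500 mol/L, from the
# standard compiled molar extinction spectra of HbO2 and HHb; water from
# compiled pure-water absorption spectra.
wavelength_nm,mu_a_hbo2_mm,mu_a_hhb_mm,mu_a_water_mm
660,0.1712,1.7278,0.00036
940,0.6501,0.3713,0.0267
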