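# Step change in vapour pressure deficit from 1 to 2 kPa at the reference
# temperate growth environment (25 degC, 400 ppm CO2, PPFD 800, sea level).
scenario: vpd_doubling
output_dir: leafgx_output/vpd_doubling
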