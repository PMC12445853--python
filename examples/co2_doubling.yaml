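# Step change in ambient CO2 from 400 to 800 ppm at the reference
# temperate growth environment (25 degC, VPD 1 kPa, PPFD 800, sea level).
scenario: co2_doubling
output_dir: leafgx_output/co2_doubling
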