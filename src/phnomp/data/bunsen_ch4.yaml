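# Bunsen solubility coefficient polynomial for methane.
#
#   ln(beta) = A1 + A2*(100/T) + A3*ln(T/100)
#              + S * [B1 + B2*(T/100) + B3*(T/100)^2]
#
# with T in kelvin and S in per-mil salinity; beta is litres of CH4 at STP
# dissolved per litre of solution per atmosphere of CH4 partial pressure.
#
# Coefficients: Wiesenburg & Guinasso (1979), J. Chem. Eng. Data 24(4),
# Table I (Bunsen coefficient fit, mL STP / mL / atm units). Fit range
# roughly -2..30 degC and 0..40 permil.
gas: CH4
units: "L gas (STP) per L solution per atm"
A1: -67.1962
A2: 99.1624
A3: 27.9015
B1: -0.072909
B2: 0.041674
B3: -0.0064603
T_min_K: 273.0
T_max_K: 313.0
S_min: 0.0
S_max: 40.0
# Spot value from the source's tabulation for fresh water at 25 degC:
reference_beta_298K_S0: 0.03150
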