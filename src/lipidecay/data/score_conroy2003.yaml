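# SCORE 10-year fatal cardiovascular risk coefficients.
# Transcribed from the published SCORE derivation (Conroy et al., Eur Heart J
# 2003;24:987-1003): Weibull baseline-survival parameters alpha and p per
# cause (coronary heart disease vs non-coronary CVD), sex and calibration
# region, and proportional-hazard coefficients per risk factor with the
# reference value subtracted before multiplication.
# Units: cholesterol mmol/L; ratio dimensionless (TC/HDL); sbp mmHg;
# smoker is a 0/1 indicator.
version: conroy2003-v1
reference_values:
  cholesterol: 6.0
  ratio: 5.0
  sbp: 120.0
  smoker: 0.0
regions:
  low_risk:
    chd:
      alpha: {male: -22.1, female: -29.8}
      p: {male: 4.71, female: 6.36}
      beta: {cholesterol: 0.24, ratio: 0.088, sbp: 0.018, smoker: 0.71}
    non_chd:
      alpha: {male: -26.7, female: -31.0}
      p: {male: 5.64, female: 6.62}
      beta: {cholesterol: 0.02, ratio: 0.098, sbp: 0.022, smoker: 0.63}
  high_risk:
    chd:
      alpha: {male: -21.0, female: -28.7}
      p: {male: 4.62, female: 6.23}
      beta: {cholesterol: 0.24, ratio: 0.088, sbp: 0.018, smoker: 0.71}
    non_chd:
      alpha: {male: -25.7, female: -30.0}
      p: {male: 5.47, female: 6.42}
      beta: {cholesterol: 0.02, ratio: 0.098, sbp: 0.022, smoker: 0.63}
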