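# Published discriminant sexing equations for the great cormorant
# (Phalacrocorax carbo sinensis). Coefficients apply to measurements in mm:
# wing_length (WL), bill_length (BL), min_bill_depth (MBD), tarsus_length (TL).
d1:
  measurements: [wing_length, bill_length, min_bill_depth]
  coefficients: [0.073, 0.082, 0.785]
  constant: -40.623
  provenance: "northern Poland, stepwise WL+BL+MBD equation"
d2:
  measurements: [wing_length, bill_length]
  coefficients: [0.087, 0.161]
  constant: -40.843
  greyzone: [-1.256, 0.916]
  provenance: "northern Poland, WL+BL equation; grey zone holds per-sex error to 1%"
greece:
  measurements: [wing_length, bill_length, tarsus_length]
  coefficients: [0.073, 0.123, 0.310]
  constant: -53.693
  provenance: "Greece population equation (WL+BL+TL)"
netherlands:
  measurements: [wing_length, bill_length]
  coefficients: [0.086, 0.148]
  constant: -39.869
  provenance: "Netherlands population equation (WL+BL)"
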