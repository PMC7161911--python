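# Default distribution of each genotype-specific parameter (GSP),
# assembled from a published literature synthesis for a cassava crop model.
# Bare (p_lo-p_hi) truncations are probability bounds on the untruncated
# distribution; value truncations are given explicitly.  Triangular rows
# carry no extra truncation (the family is bounded already).
B01ND:
  description: Thermal time from planting to first branching
  units: degC-day
  family: triangular
  params: {min: 189.0, max: 1447.0, mode: 764.0}
B12ND:
  description: Mean thermal time between branching levels after the first
  units: degC-day
  family: triangular
  params: {min: 284.0, max: 899.0, mode: 456.0}
LAXS:
  description: Maximum individual leaf area
  units: cm2
  family: lognormal
  params: {mu_log: 5.748, sigma_log: 0.314}
  truncation: {left_kind: probability, left: 0.001, right_kind: probability, right: 0.9}
SLAS:
  description: Specific leaf area
  units: cm2/g
  family: normal
  params: {mu: 242.613, sigma: 59.975}
  truncation: {left_kind: probability, left: 0.1, right_kind: probability, right: 0.9}
LLIFA:
  description: Active leaf area duration in thermal time after full expansion
  units: degC-day
  family: weibull
  params: {shape: 4.183, scale: 1015.34}
  truncation: {left_kind: value, left: 100.0, right_kind: probability, right: 0.9}
LPEFR:
  description: Leaf-petiole weight fraction
  units: "-"
  family: gamma
  params: {shape: 8.984, scale: 0.0237}
  truncation: {left_kind: value, left: 0.1, right_kind: probability, right: 0.9}
LNSLP:
  description: Leaf appearance slope as proportion of the reference curve
  units: "-"
  family: uniform
  params: {min: 0.7, max: 1.3}
NODWT:
  description: Individual node weight
  units: g
  family: weibull
  params: {shape: 3.157, scale: 9.253}
  truncation: {left_kind: value, left: 1.0, right_kind: probability, right: 0.9}
NODL:
  description: Internode length
  units: cm
  family: lognormal
  params: {mu_log: 0.502, sigma_log: 0.398}
  truncation: {left_kind: probability, left: 0.001, right_kind: probability, right: 0.9}
PARUE:
  description: Radiation use efficiency
  units: g/MJ
  family: lognormal
  params: {mu_log: 0.337, sigma_log: 0.310}
  truncation: {left_kind: probability, left: 0.1, right_kind: probability, right: 0.9}
TBLSZ:
  description: Base temperature for leaf development
  units: degC
  family: uniform
  params: {min: 11.0, max: 17.0}
BR1F:
  description: Branch number per fork at fork 1
  units: "#"
  family: uniform
  params: {min: 1.0, max: 4.0}
  integer: true
BR2F:
  description: Branch number per fork at fork 2
  units: "#"
  family: uniform
  params: {min: 1.0, max: 4.0}
  integer: true
BR3F:
  description: Branch number per fork at fork 3
  units: "#"
  family: uniform
  params: {min: 1.0, max: 4.0}
  integer: true
BR4F:
  description: Branch number per fork at fork 4
  units: "#"
  family: uniform
  params: {min: 1.0, max: 4.0}
  integer: true
KCAN:
  description: PAR extinction coefficient
  units: "-"
  family: uniform
  params: {min: 0.58, max: 1.01}
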