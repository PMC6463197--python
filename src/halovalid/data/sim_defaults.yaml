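# Default synthetic-batch parameters for the validation simulator.
#
# Per-analyte "true" values mirror the validated method's performance:
# relative response factors and process recoveries from the validation
# campaign, signed matrix effects from the matrix-effect study, lipid range
# of real fish 0.63-16 %.  noise_cv_pct is the residual CV of the analyte/IS
# response ratio per injection; noise_floor_conc is an additive
# concentration-equivalent noise floor that dominates near the limits of
# the method (it sets the LOD/LOQ scale at the 0.1 ug/kg spike level).

base_scale: 10000.0          # IS counts per (ug/kg) at zero lipid
noise_cv_pct: 2.0
noise_floor_conc: 0.009      # additive noise floor, ug/kg-equivalent SD
lipid_suppression_coeff: 0.04  # per percent lipid, applied to all areas
lipid_ref_pct: 5.2             # lipid anchor: matrix of the ME study
calibration_lipid_pct: 1.9     # chub composite used for calibration/recovery
qc_lipid_pct: 5.2              # chub composite used for QC/precision
addition_conc: 10.0            # single-point standard-addition spike, ug/kg
is_conc:
  Tetrachloro-m-xylene: 10.0
  BDE-77: 20.0

analytes:
  Hexachloro-1,3-butadiene: {rrf_true: 1.7, me_true_pct: -5.1, recovery_true_pct: 95.0}
  Pentachlorobenzene: {rrf_true: 1.0, me_true_pct: -1.9, recovery_true_pct: 95.0}
  alpha-HCH: {rrf_true: 3.3, me_true_pct: -1.2, recovery_true_pct: 89.0}
  Hexachlorobenzene: {rrf_true: 1.4, me_true_pct: 3.8, recovery_true_pct: 107.0}
  beta-HCH: {rrf_true: 2.1, me_true_pct: 9.3, recovery_true_pct: 88.0}
  Lindane: {rrf_true: 2.4, me_true_pct: 2.3, recovery_true_pct: 87.0}
  delta-HCH: {rrf_true: 2.0, me_true_pct: 3.6, recovery_true_pct: 91.0}
  Heptachlor: {rrf_true: 0.46, me_true_pct: 1.0, recovery_true_pct: 94.0}
  BDE-28: {rrf_true: 5.3, me_true_pct: 1.6, recovery_true_pct: 99.0}
  BDE-47: {rrf_true: 3.2, me_true_pct: 5.7, recovery_true_pct: 102.0}
  BDE-100: {rrf_true: 1.6, me_true_pct: 3.9, recovery_true_pct: 100.0}
  BDE-99: {rrf_true: 1.2, me_true_pct: 10.0, recovery_true_pct: 99.0}
  BDE-154: {rrf_true: 0.49, me_true_pct: 7.0, recovery_true_pct: 101.0}
  BDE-153: {rrf_true: 0.26, me_true_pct: 11.0, recovery_true_pct: 105.0}

internal_standards:
  Tetrachloro-m-xylene: {rrf_true: 1.0, me_true_pct: -1.3}
  BDE-77: {rrf_true: 1.0, me_true_pct: 1.3}
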