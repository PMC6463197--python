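# Method definition: analyte panel with MRM metadata, internal-standard
# assignments, standard purities / certificate uncertainties, SRM 1946
# certified values, and the analytical Eco-Scale penalty ledger.
#
# Transitions are precursor>product m/z with collision energy in volts.
# cert_expanded_u_pct is the expanded relative uncertainty (k = 2) of the
# standard purity from the manufacturer's certificate; where absent, the
# purity-based rectangular-distribution estimate is used instead.

panel:
  - name: Hexachloro-1,3-butadiene
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 4.42
    quant_transition: {precursor: 225, product: 190, ce_v: 15}
    qual_transition: {precursor: 260, product: 225, ce_v: 15}
    purity_pct: 96.0
  - name: Pentachlorobenzene
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 6.12
    quant_transition: {precursor: 248, product: 213, ce_v: 25}
    qual_transition: {precursor: 250, product: 180, ce_v: 20}
    purity_pct: 98.5
    cert_expanded_u_pct: 0.50
  - name: Tetrachloro-m-xylene
    role: internal_standard
    rt_min: 6.79
    quant_transition: {precursor: 244, product: 209, ce_v: 15}
    qual_transition: {precursor: 171, product: 136, ce_v: 15}
    purity_pct: 99.0
  - name: alpha-HCH
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 7.36
    quant_transition: {precursor: 219, product: 183, ce_v: 5}
    qual_transition: {precursor: 217, product: 181, ce_v: 15}
    purity_pct: 98.5
    cert_expanded_u_pct: 0.95
  - name: Hexachlorobenzene
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 7.50
    quant_transition: {precursor: 284, product: 214, ce_v: 35}
    qual_transition: {precursor: 284, product: 249, ce_v: 20}
    purity_pct: 98.5
    cert_expanded_u_pct: 2.00
  - name: beta-HCH
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 7.75
    quant_transition: {precursor: 219, product: 183, ce_v: 5}
    qual_transition: {precursor: 217, product: 181, ce_v: 15}
    purity_pct: 98.5
    cert_expanded_u_pct: 0.30
  - name: Lindane
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 7.86
    quant_transition: {precursor: 219, product: 183, ce_v: 5}
    qual_transition: {precursor: 217, product: 181, ce_v: 15}
    purity_pct: 97.0
  - name: delta-HCH
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 8.22
    quant_transition: {precursor: 219, product: 183, ce_v: 5}
    qual_transition: {precursor: 217, product: 181, ce_v: 15}
    purity_pct: 98.5
    cert_expanded_u_pct: 0.66
  - name: Heptachlor
    role: analyte
    is_ref: Tetrachloro-m-xylene
    rt_min: 9.02
    quant_transition: {precursor: 272, product: 237, ce_v: 25}
    qual_transition: {precursor: 272, product: 117, ce_v: 35}
    purity_pct: 98.5
    cert_expanded_u_pct: 0.50
  - name: BDE-28
    role: analyte
    is_ref: BDE-77
    rt_min: 11.94
    quant_transition: {precursor: 246, product: 139, ce_v: 30}
    qual_transition: {precursor: 406, product: 246, ce_v: 20}
    purity_pct: 98.0
    cert_expanded_u_pct: 0.59
  - name: BDE-47
    role: analyte
    is_ref: BDE-77
    rt_min: 14.02
    quant_transition: {precursor: 326, product: 217, ce_v: 30}
    qual_transition: {precursor: 486, product: 326, ce_v: 20}
    purity_pct: 98.0
    cert_expanded_u_pct: 0.60
  - name: BDE-77
    role: internal_standard
    rt_min: 14.74
    quant_transition: {precursor: 326, product: 217, ce_v: 30}
    qual_transition: {precursor: 486, product: 326, ce_v: 20}
    purity_pct: 98.0
  - name: BDE-100
    role: analyte
    is_ref: BDE-77
    rt_min: 15.55
    quant_transition: {precursor: 564, product: 404, ce_v: 20}
    qual_transition: {precursor: 404, product: 297, ce_v: 30}
    purity_pct: 98.0
    cert_expanded_u_pct: 0.60
  - name: BDE-99
    role: analyte
    is_ref: BDE-77
    rt_min: 15.97
    quant_transition: {precursor: 564, product: 404, ce_v: 20}
    qual_transition: {precursor: 404, product: 297, ce_v: 30}
    purity_pct: 98.0
    cert_expanded_u_pct: 0.60
  - name: BDE-154
    role: analyte
    is_ref: BDE-77
    rt_min: 17.19
    quant_transition: {precursor: 644, product: 484, ce_v: 20}
    qual_transition: {precursor: 484, product: 324, ce_v: 40}
    purity_pct: 98.0
    cert_expanded_u_pct: 0.60
  - name: BDE-153
    role: analyte
    is_ref: BDE-77
    rt_min: 17.84
    quant_transition: {precursor: 644, product: 484, ce_v: 20}
    qual_transition: {precursor: 484, product: 324, ce_v: 40}
    purity_pct: 98.0
    cert_expanded_u_pct: 0.60

# NIST SRM 1946 (Lake Superior fish tissue) certified concentrations,
# ug/kg wet weight, with expanded uncertainties.
srm_certified:
  - {analyte: Hexachlorobenzene, certified_conc: 7.25, certified_expanded_u: 0.83}
  - {analyte: alpha-HCH, certified_conc: 5.72, certified_expanded_u: 0.65}
  - {analyte: Lindane, certified_conc: 1.14, certified_expanded_u: 0.18}
  - {analyte: BDE-28, certified_conc: 0.742, certified_expanded_u: 0.027}
  - {analyte: BDE-47, certified_conc: 29.9, certified_expanded_u: 2.3}
  - {analyte: BDE-99, certified_conc: 18.5, certified_expanded_u: 2.1}
  - {analyte: BDE-100, certified_conc: 8.57, certified_expanded_u: 0.52}
  - {analyte: BDE-153, certified_conc: 2.81, certified_expanded_u: 0.41}
  - {analyte: BDE-154, certified_conc: 5.77, certified_expanded_u: 0.80}

# Analytical Eco-Scale penalty ledger for the sample-preparation + GC-MS/MS
# procedure (penalty points per the Eco-Scale criteria; score = 100 - total).
ecoscale:
  - {category: reagent, label: MeCN, amount_note: 5 mL, penalty_points: 4}
  - {category: reagent, label: CHCl3, amount_note: 50 uL, penalty_points: 2}
  - {category: reagent, label: Hexane, amount_note: 80 uL, penalty_points: 8}
  - {category: reagent, label: Analytes standard solution, amount_note: "", penalty_points: 4}
  - {category: reagent, label: H2O, amount_note: 4 mL, penalty_points: 0}
  - {category: reagent, label: H2SO4, amount_note: 1 mL, penalty_points: 2}
  - {category: reagent, label: MgSO4, amount_note: 2 g, penalty_points: 0}
  - {category: reagent, label: NaCl, amount_note: 0.5 g, penalty_points: 0}
  - {category: reagent, label: CH3COONa, amount_note: 0.5 M solution, penalty_points: 0}
  - {category: instrument, label: Vortex, amount_note: "", penalty_points: 1}
  - {category: instrument, label: Centrifuge, amount_note: "", penalty_points: 1}
  - {category: instrument, label: GC-MS/MS, amount_note: "", penalty_points: 3}
  - {category: occupational_hazard, label: Occupational hazard, amount_note: "", penalty_points: 3}
  - {category: waste, label: Waste, amount_note: "", penalty_points: 4}
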