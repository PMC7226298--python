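# Default ground-truth configuration for simulated heavy-water HDL studies.
#
# Group kinetic values (half-lives, FCRs, SDs) and subject covariate
# marginals (median, min, max per group) are the study conditions the
# simulator reproduces.  Peptide sequences are SYNTHETIC tryptic-style
# stand-ins (real identified peptide lists are not bundled); they carry
# realistic residue compositions for their proteins, and PON1 stand-ins
# are hydrophobic low-exchange peptides as expected for that protein.
# Edit or replace this file (GroundTruth.from_yaml) to change conditions.

cholesterol:
  e_as: 0.03
  fcr_per_day:
    control: 0.16
    t2d: 0.29
  fcr_sd_per_day:
    control: 0.01
    t2d: 0.08

proteins:
  P02652:
    name: Apolipoprotein A-II
    half_life_h: {control: 91.9, t2d: 51.9}
    half_life_sd_h: {control: 23.1, t2d: 17.3}
    hba1c_slope_per_h: 0.005
    peptides: [SPELQAEAK, EQLTPLIK, VTDYGQDLK, SYFEQLTPYAK]
  P06727:
    name: Apolipoprotein A-IV
    half_life_h: {control: 36.5, t2d: 26.0}
    half_life_sd_h: {control: 7.2, t2d: 7.2}
    hba1c_slope_per_h: 0.008
    peptides: [SELTQQLNALFQDK, LEPYADQLR, SLAELGGHLDQQVEEFR]
  P01024:
    name: Complement C3
    half_life_h: {control: 54.5, t2d: 33.3}
    half_life_sd_h: {control: 17.8, t2d: 13.0}
    peptides: [TGLQEVEVK, VFLDCCNYITELR, IHWESASLLR]
  P10909:
    name: Apolipoprotein J (Clusterin)
    half_life_h: {control: 26.5, t2d: 19.8}
    half_life_sd_h: {control: 10.6, t2d: 5.4}
    peptides: [ASSIIDELFQDR, ELDESLQVAER, VTTVASHTSDSDVPSGVTEVVVK]
  P27169:
    name: Paraoxonase 1
    half_life_h: {control: 261.6, t2d: 474.8}
    half_life_sd_h: {control: 66.0, t2d: 1001.0}
    slow: true
    peptides: [LTVYDLK, IFFYDWK, VTLVGTK, LWVGTVFK]
  P02656:
    name: Apolipoprotein C-III
    half_life_h: {control: 24.0, t2d: 21.9}
    half_life_sd_h: {control: 5.8, t2d: 6.3}
    peptides: [DALSSVQESQVAQQAR, GWVTDGFSSLK]
  P02766:
    name: Transthyretin
    half_life_h: {control: 37.1, t2d: 28.3}
    half_life_sd_h: {control: 12.9, t2d: 8.3}
    peptides: [GSPAINVAVHVFR, AADDTWEPFASGK, TSESGELHGLTTEEEFVEGIYK]
  P02774:
    name: Vitamin D-binding protein
    half_life_h: {control: 50.8, t2d: 30.8}
    half_life_sd_h: {control: 14.2, t2d: 8.3}
    peptides: [VLEPTLK, ELPEHTVK, HLSLLTTLSNR]

peptide_plateau_range: [0.02, 0.06]
noise_sd_frac: 0.05

subjects:
  control:
    n: 8
    marginals:
      weight_kg: [82.0, 57.1, 102.4]
      bmi_kg_m2: [30.0, 24.0, 32.0]
      glucose_mg_dl: [96.5, 78.0, 108.0]
      insulin_miu_l: [7.0, 4.1, 16.5]
      hba1c_percent: [5.4, 5.1, 5.8]
      adiponectin_ug_ml: [9.5, 2.7, 13.0]
      lcat_activity: [1.10, 1.0, 1.2]
      cetp_activity_pmol_ml_min: [9.7, 5.6, 13.6]
      hdl_cholesterol_mg_dl: [52.0, 34.0, 79.0]
      proinflammatory_index: [19.9, 12.9, 25.4]
  t2d:
    n: 9
    marginals:
      weight_kg: [91.8, 76.0, 121.0]
      bmi_kg_m2: [32.2, 26.0, 36.0]
      glucose_mg_dl: [110.0, 91.0, 143.0]
      insulin_miu_l: [16.21, 12.0, 39.0]
      hba1c_percent: [6.4, 5.8, 6.7]
      adiponectin_ug_ml: [2.9, 1.9, 3.8]
      lcat_activity: [1.14, 1.0, 1.2]
      cetp_activity_pmol_ml_min: [11.4, 5.6, 17.2]
      hdl_cholesterol_mg_dl: [48.0, 33.0, 67.0]
      proinflammatory_index: [19.6, 13.4, 31.0]

# Gaussian-copula couplings (latent correlations); cetp_adiponectin acts
# in the T2D group only, the others in both groups.
correlations:
  hba1c_glucose: 0.70
  insulin_glucose: 0.60
  lcat_glucose: -0.84
  cetp_adiponectin_t2d: -0.80
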