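# PanCan (Brock) lung-cancer probability model -- full model with spiculation.
# Coefficients transcribed from the published full model (model 2b) of
# McWilliams et al., "Probability of Cancer in Pulmonary Nodules Detected on
# First Screening CT", N Engl J Med 2013; 369:910-919.
provenance: >
  McWilliams A, Tammemagi MC, Mayo JR, et al. Probability of cancer in
  pulmonary nodules detected on first screening CT. N Engl J Med
  2013;369:910-919. Full model with spiculation (model 2b), fitted by
  logistic regression to the Pan-Canadian Early Detection of Lung Cancer
  Study cohort.
version: brock-full-2b
horizon: 2y
intercept: -6.7892
age:
  coefficient: 0.0287
  center: 62.0
sex_female: 0.6011
family_history_lung_cancer: 0.2961
emphysema: 0.2953
size:
  # transform: ((mean diameter mm / 10) ** -0.5) - center; center is the
  # transform evaluated at the cohort-mean 4 mm nodule, 1/sqrt(0.4).
  coefficient: -5.3854
  center: 1.58113883
morphology:
  solid: 0.0
  ground_glass: -0.1276
  part_solid: 0.377
upper_lobe: 0.6581
spiculation: 0.7729
nodule_count:
  coefficient: -0.0824
  center: 4.0
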