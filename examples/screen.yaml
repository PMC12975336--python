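# End-to-end simulated drug-target screen: two ancestries, a binary
# (liability) outcome, and two molecular features with their own genetics.
seed: 1
simulate:
  n_variants: 50
  ld_model: [ar1, 0.7]
  n_exposure: 20000
  n_outcome: 20000
  n_mediator: 10000
  n_ref: 500
  causal:
    - [2, 0.12]
    - [7, 0.12]
    - [12, 0.12]
    - [17, 0.12]
    - [22, 0.12]
    - [27, 0.12]
    - [32, 0.12]
    - [37, 0.12]
    - [42, 0.12]
    - [47, 0.12]
  theta_true: 0.3
  outcome_type: binary
  prevalence: 0.1
  binary_engine: linear
  mediators:
    - name: metabolite_a
      alpha_true: 0.5
      beta_true: 0.2
      causal: [[0, 0.15], [24, 0.15]]
      family: metabolite
    - name: protein_b
      alpha_true: 0.4
      beta_true: 0.3
      causal: [[10, 0.2], [35, 0.2]]
      family: protein
  ancestries:
    - name: EAS
    - name: EUR
mediation_features: [metabolite_a]
protein_features: [protein_b]
thresholds:
  instrument_p: 1.0e-8
  r2: 0.3
  window_bp: 1000000
  outcome_p: 5.0e-8
  p1: 1.0e-4
  p2: 1.0e-4
  p12: 1.0e-5
  pp4: 0.7
  heidi_p: 0.05
  fdr: 0.05
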