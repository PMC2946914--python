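# End-to-end synthetic demonstration: 600 patients, 800 markers,
# one QTL explaining 6% of hemoglobin variance planted at snp000042.
seed: 42
sim:
  n_patients: 600
  m_snps: 800
  causal_spec:
    - {snp_index: 42, trait: HGB, r2: 0.06}
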