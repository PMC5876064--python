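# Frequency-rule thresholds (proportions, not percents) and the
# parameters behind their derivation. Thresholds are encoded constants:
# the derivation table is printable for audit (`myh7rules thresholds`)
# but thresholds are not recomputed at run time.
frequency:
  ba1: 1.0e-3     # filtering AF >= 0.1%
  bs1: 2.0e-4     # filtering AF >= 0.02%, deeply characterized populations only
  pm2: 4.0e-5     # filtering AF < 0.004%
  confidence: 0.95
  min_an: 2000
  method: poisson
  bs1_eligible_populations: [NFE, EUR]
derivation:
  BA1: {prevalence: 0.005, contribution: 0.106, penetrance: 0.30}  # 1/200, gene share 10.6%
  BS1: {prevalence: 0.005, contribution: 0.02, penetrance: 0.30}   # max pathogenic variant share 2%
  PM2: {prevalence: 0.002, contribution: 0.02, penetrance: 0.50}   # realistic 1/500, 50%
case_evidence:
  ps4_thresholds: [2, 6, 15]   # probands for supporting / moderate / strong
  pp1_thresholds: [3, 5, 7]    # informative meioses for supporting / moderate / strong
  de_novo_strong_count: 3
domain:
  pm1_start: 181
  pm1_end: 937
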