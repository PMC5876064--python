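# Illustrative quasi case-control cohort model. Controls are the ExAC
# non-Finnish European (NFE) and African (AFR) cohort sizes used as
# healthy-control proxies; case cohort sizes are illustrative pooled
# proband cohorts. Override per run for a specific study design.
assumed_control_carriers: 2
ancestries:
  NFE: {cases: 2500, controls: 33370}
  AFR: {cases: 500, controls: 5203}
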