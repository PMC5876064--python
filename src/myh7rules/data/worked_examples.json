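{
  "schema_version": 1,
  "bundles": [
    {
      "bundle_id": "worked-example-R1420W",
      "variant": {
        "gene": "MYH7",
        "transcript": "NM_000257.3",
        "hgvs_c": "c.4258C>T",
        "hgvs_p": "p.Arg1420Trp",
        "consequence": "missense",
        "aa_position": 1420,
        "in_repeat_region": false
      },
      "disease_context": "HCM",
      "population_frequencies": [
        {"population": "NFE", "ac": 1, "an": 66740, "deeply_characterized": true}
      ],
      "probands": [
        {"proband_id": "R1420W-P01", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P02", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P03", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P04", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P05", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P06", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P07", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P08", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P09", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P10", "cohort_id": "literature", "phenotype": "HCM"},
        {"proband_id": "R1420W-P11", "cohort_id": "literature", "phenotype": "HCM"}
      ],
      "annotations": {"computational_consensus": "pathogenic-supporting"},
      "expert_override": {
        "classification": "likely pathogenic",
        "justification": "Expert panel judgment: additional probands not counted due to the conservative counting approach; evidence considered sufficiently borderline to upgrade."
      }
    },
    {
      "bundle_id": "worked-example-R1909P",
      "variant": {
        "gene": "MYH7",
        "transcript": "NM_000257.3",
        "hgvs_c": "c.5726G>C",
        "hgvs_p": "p.Arg1909Pro",
        "consequence": "missense",
        "aa_position": 1909,
        "in_repeat_region": false
      },
      "disease_context": "DCM",
      "population_frequencies": [
        {"population": "NFE", "ac": 0, "an": 66740, "deeply_characterized": true}
      ],
      "probands": [
        {"proband_id": "R1909P-P01", "cohort_id": "clinic", "phenotype": "DCM"}
      ],
      "de_novo": [
        {
          "paternity_confirmed": false,
          "maternity_confirmed": true,
          "parents_genotype_negative": true,
          "parents_phenotype_negative": true,
          "family_history_negative": true
        }
      ],
      "annotations": {"computational_consensus": "pathogenic-supporting"},
      "expert_override": {
        "classification": "likely pathogenic",
        "justification": "Expert panel judgment: phenotype included DCM and myopathy, with additional segregations; evidence considered sufficiently borderline to upgrade."
      }
    }
  ]
}
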