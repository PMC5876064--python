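# myh7rules

A rules engine for clinical classification of variants in *MYH7* (beta-
myosin heavy chain), the gene behind a large share of inherited
hypertrophic, dilated and restrictive cardiomyopathy (HCM/DCM/RCM). It
implements a gene-adapted ACMG/AMP framework as executable, auditable
code for variant curators, diagnostic laboratories and expert panels:
structured evidence in, five-tier classification out, with a
per-criterion evidence trace.

## What it computes

Evidence for one variant in one disease context is an *evidence bundle*:
population allele counts (AC/AN per cohort), proband observations with
phenotype tags, family segregation records (direct meiosis counts or PED
pedigrees with carrier status), de novo observations, functional-assay
annotations and in-silico/annotation verdicts. The engine evaluates the
adapted criteria:

- **Frequency rules** act on the *filtering allele frequency*, the lower
  bound of a one-sided 95% CI on the allele frequency given the observed
  count (Poisson inversion): BA1 at ≥ 0.1% (standalone benign), BS1 at
  ≥ 0.02% in a deeply characterized population (likely benign on its
  own, absent conflicting evidence), PM2 below 0.004% (absent/extremely
  rare). Thresholds derive from the maximum credible frequency of a
  pathogenic allele, `(prevalence/2) × allelic contribution / penetrance`.
- **Proband enrichment (PS4)**: ≥2 / ≥6 / ≥15 independent probands give
  supporting / moderate / strong, gated on PM2, with duplicate-proband
  collapsing and phenotype filters (isolated LVNC never counts; DCM
  counts for HCM only with prior HCM evidence). A quasi case-control
  Fisher's exact statistic against reference-cohort proxies is reported
  alongside.
- **Segregation (PP1/BS4)**: LOD = n·log10(2) over informative meioses
  between affected carriers; ≥3 / ≥5 / ≥7 meioses (LOD 0.9/1.5/2.1) give
  supporting / moderate / strong, gated on PM2, single family
  sufficient; an affected noncarrier raises BS4.
- **De novo (PS2/PM6)**: paternity-confirmed qualifying occurrences are
  strong; unconfirmed are moderate, upgraded to strong at ≥3.
- **Domain and annotation rules**: PM1 for missense in the myosin head
  (aa 181–937), PVS1_Moderate for loss-of-function variants, PS3/BS3
  restricted to mammalian variant-specific knock-in models, plus PS1,
  PM4, PM5, PP3, BP2, BP4, BP5, BP7 from curated assertions.

Met rules are combined by the parent ACMG/AMP table over strengths as
applied, with the adaptations: BA1 standalone, BS1-alone → likely
benign, mixed-direction evidence → uncertain significance with a
surfaced conflict flag. An expert override can be recorded; it never
alters the rule-based tier and is always reported alongside it. See
`docs/methods.md` for the full model, parameters and limitations.

## Worked example

The package ships the two in-text worked-example variants. Classify
them:

```sh
$ myh7rules classify src/myh7rules/data/worked_examples.json
p.Arg1420Trp	HCM	uncertain significance	PS4_Moderate,PM2,PP3	override=likely pathogenic
p.Arg1909Pro	DCM	uncertain significance	PM2,PM6,PP3	override=likely pathogenic
```

p.Arg1420Trp is absent/rare in controls (PM2), seen in 11 probands
(PS4_Moderate) with supportive computational evidence (PP3): one
moderate short of likely pathogenic, hence rule-based *uncertain
significance*; the recorded expert override to likely pathogenic is
reported without changing the rule-based tier. p.Arg1909Pro is analogous
with an unconfirmed de novo occurrence (PM6) in place of the proband
count.

Print the frequency-threshold derivation and the registry audit:

```sh
$ myh7rules thresholds
rule	prevalence	contribution	penetrance	max_credible_af	encoded_threshold
BA1	0.005	0.106	0.3	0.08833%	0.1%
BS1	0.005	0.02	0.3	0.01667%	0.02%
PM2	0.002	0.02	0.5	0.004%	0.004%

$ myh7rules registry --audit
base_rules=28 removed=9 disease_gene=12 no_change=7 modified_strength=5
```

The derivation columns read: with disease prevalence 1/200 individuals,
gene contribution 10.6% and penetrance 30%, no pathogenic allele is
credibly more frequent than 0.088% — conservatively encoded as the 0.1%
BA1 threshold; the realistic parameters (1/500, 2%, 50%) give the PM2
threshold 0.004% exactly.

Other subcommands: `simulate --seed N --out-dir D` writes the synthetic
scenario set and its expected-outcome manifest; `validate FILE` schema-
checks an evidence file. The Python API mirrors the CLI
(`classify_bundle`, `evaluate_all`, `combine`,
`filtering_allele_frequency`, `max_credible_af`, `quasi_case_control`,
`count_informative_meioses`, `generate_fixtures`, ...).

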