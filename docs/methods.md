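# Methods

`myh7rules` implements a gene-adapted ACMG/AMP classification framework
for variants in *MYH7*, the beta-myosin heavy chain gene, in the context
of the inherited cardiomyopathies (hypertrophic, dilated and restrictive:
HCM, DCM, RCM). The engine consumes curated, declarative evidence — it
never infers a judgment from free text — and produces a five-tier
classification (benign, likely benign, uncertain significance, likely
pathogenic, pathogenic) with a full applied-rule trace.

## The model

The parent ACMG/AMP framework scores weighted pathogenic criteria
(PVS/PS/PM/PP: very strong, strong, moderate, supporting) and benign
criteria (BA/BS/BP: standalone, strong, supporting) and combines them by
a fixed table. The gene adaptation keeps that skeleton and changes three
things:

1. **Which criteria apply.** Of the 28 base criteria, 9 are removed as
   not applicable to dominant *MYH7* cardiomyopathy (PVS1, PM3, PP2,
   PP4, PP5, BS2, BP1, BP3, BP6), 12 receive disease/gene-specific
   definitions, and 5 additional codes apply existing criteria at a
   modified strength (PVS1_Moderate, PS4_Moderate, PS4_Supporting,
   PP1_Moderate, PP1_Strong). The registry is data
   (`data/registry.yaml`), so other gene adaptations can reuse the
   engine by swapping the registry.

2. **Quantitative frequency rules.** Population-frequency criteria act
   on the *filtering allele frequency*: the lower bound of a one-sided
   95% confidence interval on the true allele frequency given the
   observed allele count, computed by inverting the Poisson survival
   function (`P(X >= AC | p·AN) = 0.05`). This penalises counts from
   small cohorts. An exact-binomial inversion is available as a
   numerical cross-check (`method="binomial"`). Thresholds come from the
   maximum credible population allele frequency for a pathogenic allele,

       AF_max = (prevalence / 2) × allelic contribution / penetrance,

   with prevalence per individual (halved to the chromosome level). The
   shipped constants are BA1 ≥ 0.1% (derived from prevalence 1/200, gene
   contribution 10.6%, penetrance 30% → 8.8e-4, rounded by the panel to
   1e-3), BS1 ≥ 0.02% (same parameters with the 2% maximum single-variant
   contribution) and PM2 < 0.004% (realistic parameters 1/500, 2%, 50% —
   exactly 4e-5). The thresholds are encoded constants, not recomputed:
   the panel's rounding is not an algorithm. BA1/BS1 activate inclusively
   (≥), PM2 strictly below. Rules act on the maximum filtering AF across
   populations with AN ≥ 2000 alleles (popmax logic: a variant common in
   any well-sampled ancestry cannot be a dominant pathogenic allele);
   BS1 additionally requires a deeply characterized population (safeguard
   against under-studied ancestries harbouring common pathogenic alleles).

3. **Semiquantitative case-level rules, gated on PM2.**
   - *Proband counts (PS4 tiers).* Independent probands pooled across
     studies reach supporting/moderate/strong at ≥2/≥6/≥15. The tiers
     were calibrated against likelihood-ratio targets of 10/30/100 in a
     quasi case-control design (Fisher's exact test of pooled probands
     against a large reference cohort as control proxy, assuming 2
     control carriers under PM2); with the shipped illustrative NFE
     cohorts (2500 cases vs the 33,370-individual ExAC NFE cohort) the
     thresholds correspond to odds ratios ≈13.4/40.1/100. The statistic
     is reported in the PS4 trace, but tiering is driven by the count
     thresholds for ease of use.
   - *Segregation (PP1 tiers, BS4).* Under dominant inheritance with
     evidence restricted to affected carriers, the LOD score reduces to
     `n·log10(2)` for `n` informative meioses; ≥3/≥5/≥7 meioses (LOD
     0.9/1.5/2.1, likelihood ratios 10/30/100) give
     supporting/moderate/strong. A single family suffices. Any affected
     noncarrier means nonsegregation: the family contributes zero
     meioses and BS4 is raised (one affected noncarrier suffices;
     configurable in principle, since no operational count is defined).
   - *De novo (PS2/PM6).* A qualifying occurrence requires genotype- and
     phenotype-negative parents and a negative three-generation family
     history. Paternity confirmation (maternity proof is waived) gives
     PS2; otherwise PM6, upgraded to PS2 at ≥3 qualifying occurrences.

   Phenotype counting filters: isolated LVNC cases are excluded from HCM
   and DCM evidence; DCM cases are excluded from HCM counts unless
   earlier clinical evidence supported HCM (the `DCM-with-prior-HCM`
   tag). Suspected duplicate probands collapse into one identity cluster
   (union-find over `duplicate_of` links), with an audit trace.

Other adapted criteria: PM1 covers the myosin head domain (amino acids
181–937, inclusive boundaries) and is restricted to missense variants —
the domain evidence comes from clustering of pathogenic *missense*
variants, and truncating variants route to PVS1_Moderate instead,
avoiding double counting. PS3/BS3 accept only mammalian variant-specific
knock-in models; dosage models (transgenic, knockout) and in-vitro
assays never activate either. PS1, PM4, PM5, PP3, BP2, BP4, BP5 and BP7
consume curator-asserted booleans or the computational-consensus
enumeration, with consequence gates where the criterion demands one
(PM4: in-frame indel outside repeat regions, or stop-loss; BP7:
synonymous only).

## Combining evidence

The combiner tallies met rules by *strength as applied* (PP1_Strong
counts as strong, PS4_Supporting as supporting) and applies the parent
combining table, implemented in full — including very-strong rows that
the default registry cannot produce — for reusability. Modifications:
BA1 alone is standalone and absolute; BS1 alone, with no
pathogenic-direction rule met, yields likely benign. Mixed-direction
evidence resolves to uncertain significance with a surfaced conflict
flag (BA1 excepted). Expert override is a recording mechanism, not a
model: reports carry both the rule-based tier and the override, and the
rule-based tier is never altered.

Counting meioses from pedigrees: informative meioses are the
parent→child transmission edges on the minimal subgraph (Steiner tree
over the family graph) connecting all affected carriers. Unaffected or
ungenotyped connectors are traversed — their edges count — but they are
not evidence endpoints; known noncarriers cannot transmit the variant
and are excluded as connectors. Direct counts are authoritative when
supplied and are the escape hatch for consanguineous or multi-founder
families, where edge counting on a general graph is not uniquely
defined.

## Synthetic data

`generate_fixtures(seed)` emits ~64 scenario bundles covering every
non-removed rule's activation and non-activation, the exact count
boundaries (probands 1/2/5/6/14/15, meioses 2–7, de novo 1/2/3,
filtering AF straddling each threshold), the phenotype filters,
duplicate collapsing, combinations reaching every tier, and conflicts.
The manifest of intended rule sets and tiers is ground truth by
construction; the engine must recover 100% of it (this is the end-to-end
acceptance surface, and the acceptance script re-verifies it at run
time). Generation is deterministic: a fixed seed yields byte-identical
files. The generator emulates the *shape* of curated evidence at the
framework's stated operating points; it does not emulate curation noise
(ambiguous phenotypes beyond the encoded tags, inconsistent duplicate
links, partially genotyped pedigrees), so passing recovery demonstrates
the engine's fidelity to the rule definitions, not robustness to messy
real-world curation.

## Numerical choices and tolerances

- Filtering AF: closed-form Poisson inversion via the regularized
  incomplete gamma function; verified against a bisection oracle on the
  Poisson survival function to 1e-6 relative tolerance, and against the
  exact binomial mode. AC = 0 returns 0 (no observation supports a
  credible lower bound); the result never exceeds AC/AN.
- Fisher's exact test: `scipy.stats.fisher_exact`, two-sided by the
  standard "sum of table probabilities ≤ observed" convention (with the
  conventional 1 + 1e-7 relative tie slack); cross-checked in the test
  suite against direct hypergeometric enumeration over all tables with
  total sample size ≤ 50 and random larger tables, to 1e-9 absolute on
  the p-value. The sample odds ratio is +inf when controls carry no
  alleles; the empty table reports OR 1, p 1 by convention.
- Combining table: cross-checked against a literal row-by-row
  transcription on all subsets of a 12-rule core set and 10,000 random
  rule sets.
- Degenerate inputs: an evidence bundle with no population records meets
  no frequency rule (PM2 is *not* assumed); populations below the AN
  gate produce a warning, not an error; validation is total and returns
  violations rather than raising.

## Configuration

All operating points live in shipped YAML and are overridable per run:
frequency thresholds and confidence (`thresholds.yaml`), PS4/PP1 count
ladders and the de novo upgrade count, the PM1 domain interval, the
cohort model (`cohorts.yaml`), and the registry itself
(`registry.yaml`). Evidence is JSON (schema version 1); a flat TSV
dialect carries scalar-only batch input; pedigrees use 7-column PED
(standard 6 columns plus carrier status 0/1/2 = unknown/noncarrier/
carrier). Frequencies are proportions internally; percent appears only
in presentation output.

## Known limitations

- Assumes the dominant single-variant disease paradigm of the adapted
  framework; no recessive or digenic logic beyond the BP2 annotations.
- PS1/PM5 lookups are caller-supplied assertions, not a bundled
  pathogenic-variant database.
- The quasi case-control cohort model ships with illustrative case
  cohort sizes; study-specific odds ratios require the user's actual
  cohort sizes.
- Pedigree meiosis counting targets ordinary tree-like families; loops
  (consanguinity) should use direct counts.
- The expert-override mechanism records judgment; it does not model it.
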