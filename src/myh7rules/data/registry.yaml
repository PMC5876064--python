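# MYH7-adapted ACMG/AMP rule registry.
# specification: no-change | disease-gene | modified-strength | removed
# strength: standalone | very-strong | strong | moderate | supporting
# gating: rule codes that must be met before this rule may activate
rules:
  # ---- pathogenic criteria ----
  - code: PVS1
    direction: pathogenic
    strength: very-strong
    specification: removed
    description: >-
      Null variant in a gene with established loss of function as the disease
      mechanism; not applicable at original strength for MYH7.
  - code: PVS1_Moderate
    base: PVS1
    direction: pathogenic
    strength: moderate
    specification: modified-strength
    description: >-
      Loss-of-function variant (nonsense, frameshift, canonical splice) carries
      moderate weight; alone it yields uncertain significance.
  - code: PS1
    direction: pathogenic
    strength: strong
    specification: no-change
    description: >-
      Different nucleotide change producing the same amino acid change as a
      previously established pathogenic variant.
  - code: PS2
    direction: pathogenic
    strength: strong
    specification: disease-gene
    description: >-
      De novo occurrence with paternity confirmed (maternity proof waived), both
      parents genotype and phenotype negative, three-generation family history
      negative; also reached by three or more qualifying de novo occurrences.
  - code: PS3
    direction: pathogenic
    strength: strong
    specification: disease-gene
    description: >-
      Functional studies in a mammalian variant-specific knock-in model
      supportive of a damaging effect.
  - code: PS4
    direction: pathogenic
    strength: strong
    specification: disease-gene
    gating: [PM2]
    description: Variant identified in >= 15 probands with consistent phenotypes.
  - code: PS4_Moderate
    base: PS4
    direction: pathogenic
    strength: moderate
    specification: modified-strength
    gating: [PM2]
    description: Variant identified in >= 6 probands with consistent phenotypes.
  - code: PS4_Supporting
    base: PS4
    direction: pathogenic
    strength: supporting
    specification: modified-strength
    gating: [PM2]
    description: Variant identified in >= 2 probands with consistent phenotypes.
  - code: PM1
    direction: pathogenic
    strength: moderate
    specification: disease-gene
    description: >-
      Missense variant in the myosin head functional domain (amino acids
      181-937) without benign variation.
  - code: PM2
    direction: pathogenic
    strength: moderate
    specification: disease-gene
    description: >-
      Absent or extremely rare (filtering allele frequency < 0.004%) in large
      population studies.
  - code: PM3
    direction: pathogenic
    strength: moderate
    specification: removed
    description: Detected in trans with a pathogenic variant (recessive); not applicable.
  - code: PM4
    direction: pathogenic
    strength: moderate
    specification: no-change
    description: >-
      Protein length change from an in-frame indel in a non-repeat region or a
      stop-loss variant.
  - code: PM5
    direction: pathogenic
    strength: moderate
    specification: no-change
    description: >-
      Missense change at a residue where a different missense change is
      established as pathogenic.
  - code: PM6
    direction: pathogenic
    strength: moderate
    specification: disease-gene
    description: Assumed de novo without confirmation of paternity.
  - code: PP1
    direction: pathogenic
    strength: supporting
    specification: disease-gene
    gating: [PM2]
    description: >-
      Variant segregates with disease across >= 3 informative meioses (LOD 0.9);
      a single family suffices.
  - code: PP1_Moderate
    base: PP1
    direction: pathogenic
    strength: moderate
    specification: modified-strength
    gating: [PM2]
    description: Variant segregates across >= 5 informative meioses (LOD 1.5).
  - code: PP1_Strong
    base: PP1
    direction: pathogenic
    strength: strong
    specification: modified-strength
    gating: [PM2]
    description: Variant segregates across >= 7 informative meioses (LOD 2.1).
  - code: PP2
    direction: pathogenic
    strength: supporting
    specification: removed
    description: >-
      Missense variant in a missense-constrained gene; removed to avoid double
      counting the head-domain evidence carried by PM1.
  - code: PP3
    direction: pathogenic
    strength: supporting
    specification: no-change
    description: Multiple lines of computational evidence support a deleterious effect.
  - code: PP4
    direction: pathogenic
    strength: supporting
    specification: removed
    description: Phenotype specific for a disease with a single genetic etiology; not applicable.
  - code: PP5
    direction: pathogenic
    strength: supporting
    specification: removed
    description: >-
      Reputable source reports variant as pathogenic without accessible
      evidence; expert curations count only when accompanied by evidence.
  # ---- benign criteria ----
  - code: BA1
    direction: benign
    strength: standalone
    specification: disease-gene
    description: Filtering allele frequency >= 0.1% in a reference population.
  - code: BS1
    direction: benign
    strength: strong
    specification: disease-gene
    description: >-
      Filtering allele frequency >= 0.02% in a deeply characterized population,
      provided there is no conflicting information.
  - code: BS2
    direction: benign
    strength: strong
    specification: removed
    description: >-
      Observed in a healthy adult with full penetrance expected at an early
      age; not applicable given reduced, age-dependent penetrance.
  - code: BS3
    direction: benign
    strength: strong
    specification: no-change
    description: >-
      Functional studies in a mammalian variant-specific knock-in model
      supportive of no damaging effect.
  - code: BS4
    direction: benign
    strength: strong
    specification: disease-gene
    description: Nonsegregation in affected members of a family (affected noncarrier observed).
  - code: BP1
    direction: benign
    strength: supporting
    specification: removed
    description: Missense variant in a gene where only loss of function causes disease; not applicable.
  - code: BP2
    direction: benign
    strength: supporting
    specification: disease-gene
    description: >-
      Observed in trans / double heterozygous without increased disease
      severity, or in cis with a pathogenic variant.
  - code: BP3
    direction: benign
    strength: supporting
    specification: removed
    description: In-frame indel in a repetitive region without known function; not applicable.
  - code: BP4
    direction: benign
    strength: supporting
    specification: no-change
    description: Multiple lines of computational evidence suggest no impact.
  - code: BP5
    direction: benign
    strength: supporting
    specification: disease-gene
    description: Variant found in a case with an alternate molecular basis for disease.
  - code: BP6
    direction: benign
    strength: supporting
    specification: removed
    description: >-
      Reputable source reports variant as benign without accessible evidence;
      removed for the same reason as PP5.
  - code: BP7
    direction: benign
    strength: supporting
    specification: no-change
    description: >-
      Synonymous variant with no predicted splice impact and a nucleotide that
      is not highly conserved.
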