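"""Allele-frequency statistics and the BA1/BS1/PM2 frequency rules.

The benign-spectrum frequency rules compare a *filtering allele
frequency* -- the lower bound of a one-sided 95% confidence interval on
the true allele frequency given the observed allele count -- against
thresholds derived from a maximum credible population allele frequency:

    max credible AF = (prevalence / 2) * allelic contribution / penetrance

where prevalence is per individual (hence the /2 to move to the allele
level), the allelic contribution is the share of disease attributable to
the gene (BA1) or to the single most common pathogenic variant (BS1,
PM2), and incomplete penetrance inflates the tolerable frequency.

Shipped MYH7 defaults: BA1 >= 0.1%, BS1 >= 0.02%, PM2 < 0.004% on the
filtering allele frequency. The thresholds are encoded constants (the
panel's rounding from derived values is not a stated algorithm); the
derivation parameters are also shipped so the derivation table can be
printed and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from scipy import optimize, special, stats

from .evidence import PopulationFrequencyRecord

__all__ = [
    "ThresholdDerivationParams",
    "FrequencyRuleConfig",
    "FrequencyOutcome",
    "filtering_allele_frequency",
    "max_credible_af",
    "evaluate_frequency_rules",
]


@dataclass
class ThresholdDerivationParams:
    """Inputs to the maximum-credible-AF derivation.

    prevalence
        Disease prevalence as a proportion of individuals (e.g. 1/200).
    contribution
        Allelic contribution as a proportion: gene contribution for the
        BA1 derivation, maximum pathogenic variant contribution for
        BS1/PM2.
    penetrance
        Penetrance in (0, 1].
    """

    prevalence: float
    contribution: float
    penetrance: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "contribution", "penetrance"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {value!r}")


@dataclass
class FrequencyRuleConfig:
    """Thresholds and gates for the frequency rules.

    ``min_an`` is the minimum allele number for a population to be
    considered at all (default 2000 alleles): filtering-AF estimates from
    tiny cohorts are too noisy to drive any rule. ``bs1_eligible_populations``
    lists population labels trusted for BS1 in addition to records
    flagged ``deeply_characterized``.
    """

    ba1: float = 1e-3
    bs1: float = 2e-4
    pm2: float = 4e-5
    confidence: float = 0.95
    min_an: int = 2000
    method: str = "poisson"
    bs1_eligible_populations: tuple[str, ...] = ("NFE", "EUR")

    def __post_init__(self) -> None:
        if not (self.pm2 < self.bs1 < self.ba1):
            raise ValueError("thresholds must satisfy PM2 < BS1 < BA1")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")
        if self.method not in ("poisson", "binomial"):
            raise ValueError("method must be 'poisson' or 'binomial'")


def filtering_allele_frequency(
    ac: int, an: int, confidence: float = 0.95, method: str = "poisson"
) -> float:
    """Lower bound of the one-sided CI on the allele frequency.

    Returns the allele frequency ``p`` at which observing at least ``ac``
    alleles among ``an`` has probability exactly ``1 - confidence``
    (default 5%): any true frequency above the returned value would make
    the observed count unsurprising. Returns 0 when ``ac`` is 0 (no
    observations support any credible lower bound).

    ``method='poisson'`` (default) models the allele count as Poisson
    with mean ``p * an`` and inverts its survival function in closed form
    through the regularized incomplete gamma function.
    ``method='binomial'`` inverts the exact binomial survival function by
    root finding; the two agree closely for rare variants and the
    binomial mode serves as a numerical cross-check.
    """
    if an <= 0:
        raise ValueError("AN must be positive")
    if ac < 0 or ac > an:
        raise ValueError("AC must satisfy 0 <= AC <= AN")
    if ac == 0:
        return 0.0
    alpha = 1.0 - confidence
    if method == "poisson":
        # P(Poisson(lam) >= ac) = gammainc(ac, lam); solve for lam.
        lam = float(special.gammaincinv(ac, alpha))
        return min(lam / an, ac / an)
    if method == "binomial":
        point = ac / an

        def excess(p: float) -> float:
            return stats.binom.sf(ac - 1, an, p) - alpha

        if excess(point) <= 0:  # pragma: no cover - ac>=1 makes excess(point)>0
            return point
        return float(optimize.brentq(excess, 0.0, point, xtol=1e-15, rtol=1e-12))
    raise ValueError("method must be 'poisson' or 'binomial'")


def max_credible_af(params: ThresholdDerivationParams) -> float:
    """Maximum credible population allele frequency for a pathogenic allele.

    ``(prevalence / 2) * contribution / penetrance``: individual
    prevalence is halved to the allele (chromosome) level, scaled by the
    allelic contribution, and inflated by incomplete penetrance.
    """
    if params.penetrance == 0:
        raise ValueError("penetrance must be positive")
    return (params.prevalence / 2.0) * params.contribution / params.penetrance


@dataclass
class FrequencyOutcome:
    """Result of the BA1/BS1/PM2 evaluation for one bundle.

    ``rule`` is one of ``"BA1"``, ``"BS1"``, ``"PM2"`` or ``None``; the
    three outcomes are mutually exclusive by construction. ``faf_by_population``
    maps every population label to its filtering AF (eligible or not);
    ``max_faf`` is the popmax filtering AF over eligible populations.
    """

    rule: Optional[str]
    faf_by_population: dict[str, float] = field(default_factory=dict)
    eligible_populations: tuple[str, ...] = ()
    max_faf: Optional[float] = None
    max_faf_population: Optional[str] = None
    low_an_warning: bool = False


def evaluate_frequency_rules(
    records: list[PopulationFrequencyRecord], config: Optional[FrequencyRuleConfig] = None
) -> FrequencyOutcome:
    """Evaluate BA1/BS1/PM2 on per-population AC/AN records.

    Rules act on the maximum filtering AF across populations passing the
    minimum-AN gate (popmax-style): a variant common in any well-sampled
    ancestry cannot be a dominant pathogenic allele. BA1 at
    ``max_faf >= ba1``; else BS1 if some BS1-eligible population reaches
    ``faf >= bs1``; else PM2 if ``max_faf < pm2``; else none. When every
    population fails the AN gate the outcome is none with a warning flag
    (no evidence either way).
    """
    config = config or FrequencyRuleConfig()
    fafs: dict[str, float] = {}
    eligible: list[tuple[str, float, bool]] = []  # label, faf, bs1-eligible
    for rec in records:
        faf = filtering_allele_frequency(
            rec.ac, rec.an, confidence=config.confidence, method=config.method
        )
        fafs[rec.population] = faf
        if rec.an >= config.min_an:
            bs1_ok = rec.deeply_characterized or rec.population in config.bs1_eligible_populations
            eligible.append((rec.population, faf, bs1_ok))

    if not eligible:
        return FrequencyOutcome(
            rule=None, faf_by_population=fafs, low_an_warning=bool(records)
        )

    max_label, max_faf, _ = max(eligible, key=lambda t: t[1])
    outcome = FrequencyOutcome(
        rule=None,
        faf_by_population=fafs,
        eligible_populations=tuple(label for label, _, _ in eligible),
        max_faf=max_faf,
        max_faf_population=max_label,
    )
    if max_faf >= config.ba1:
        outcome.rule = "BA1"
    elif any(bs1_ok and faf >= config.bs1 for _, faf, bs1_ok in eligible):
        outcome.rule = "BS1"
    elif max_faf < config.pm2:
        outcome.rule = "PM2"
    return outcome
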