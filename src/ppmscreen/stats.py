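"""Validation statistics for promoter-model selections.

Covers the 2x2 contingency surface used to validate the promoter model
against positive/negative training sets: fold enrichment of the PPM feature,
a two-sided Fisher exact test (explicit hypergeometric enumeration),
sensitivity/specificity with exact Clopper-Pearson binomial intervals, and
the Yates-corrected chi-square used for pathway over-representation against
a gene universe.

Reported percentages and folds are rounded half-up to one decimal (so
1991/2000 renders as 99.6%); all raw values are kept unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Sequence

from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

from .errors import StatError

_TIE_REL_TOL = 1e-7


def round_half_up(value: float | Fraction | Decimal, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one digit), as used for all
    displayed percentages and folds."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    elif isinstance(value, Decimal):
        dec = value
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def rate_pct(hit: int, n: int, ndigits: int = 1) -> float:
    """Exact percentage ``100*hit/n`` rounded half-up (293/2000 -> 14.7)."""
    if n <= 0:
        raise StatError("rate denominator must be positive")
    return round_half_up(Fraction(100 * hit, n), ndigits)


@dataclass(frozen=True)
class ContingencyTable:
    """Rows = training set (positive, negative); columns = fits yes/no."""

    pos_hit: int
    pos_miss: int
    neg_hit: int
    neg_miss: int

    def __post_init__(self) -> None:
        if min(self.pos_hit, self.pos_miss, self.neg_hit, self.neg_miss) < 0:
            raise StatError("contingency counts must be non-negative")

    @property
    def pos_n(self) -> int:
        return self.pos_hit + self.pos_miss

    @property
    def neg_n(self) -> int:
        return self.neg_hit + self.neg_miss

    def as_rows(self) -> list[list[int]]:
        return [[self.pos_hit, self.pos_miss], [self.neg_hit, self.neg_miss]]


def fold_enrichment(pos_hit: int, pos_n: int, neg_hit: int, neg_n: int) -> float:
    """Ratio of feature rates, (pos_hit/pos_n)/(neg_hit/neg_n).

    Returns ``math.inf`` when the negative set has zero hits (flagged by the
    caller via ``math.isinf``), never raises for that case."""
    if pos_n <= 0 or neg_n <= 0:
        raise StatError("set sizes must be positive")
    if neg_hit == 0:
        return math.inf
    return (pos_hit / pos_n) / (neg_hit / neg_n)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed one (relative tie tolerance 1e-7). A zero margin
    gives p = 1 by convention."""
    a = table.pos_hit
    r1, r2 = table.pos_n, table.neg_n
    c1 = table.pos_hit + table.neg_hit
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    support_lo = max(0, c1 - r2)
    support_hi = min(r1, c1)
    dist = hypergeom(n, r1, c1)
    p_obs = dist.pmf(a)
    total = 0.0
    for x in range(support_lo, support_hi + 1):
        p_x = dist.pmf(x)
        if p_x <= p_obs * (1.0 + _TIE_REL_TOL):
            total += p_x
    return min(total, 1.0)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval for a proportion: the lower bound solves
    P(X >= k | n, p) = alpha/2 (0 when k = 0) and the upper solves
    P(X <= k | n, p) = alpha/2 (1 when k = n), via beta quantiles."""
    if n <= 0 or not 0 <= k <= n:
        raise StatError(f"invalid binomial counts k={k}, n={n}")
    if not 0 < conf < 1:
        raise StatError("confidence level must be in (0, 1)")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass(frozen=True)
class RateWithCI:
    rate: float
    ci_low: float
    ci_high: float

    def as_pct(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.rate * 100, ndigits),
            round_half_up(self.ci_low * 100, ndigits),
            round_half_up(self.ci_high * 100, ndigits),
        )


@dataclass(frozen=True)
class SensSpec:
    sensitivity: RateWithCI
    specificity: RateWithCI


def sensitivity_specificity(table: ContingencyTable, conf: float = 0.95) -> SensSpec:
    """Sensitivity = pos_hit/pos_n, specificity = neg_miss/neg_n, each with
    an exact Clopper-Pearson interval at ``conf``."""
    if table.pos_n == 0 or table.neg_n == 0:
        raise StatError("both training sets must be non-empty")
    sens = table.pos_hit / table.pos_n
    spec = table.neg_miss / table.neg_n
    s_lo, s_hi = clopper_pearson(table.pos_hit, table.pos_n, conf)
    p_lo, p_hi = clopper_pearson(table.neg_miss, table.neg_n, conf)
    return SensSpec(
        sensitivity=RateWithCI(sens, s_lo, s_hi),
        specificity=RateWithCI(spec, p_lo, p_hi),
    )


def chi2_yates(table: ContingencyTable) -> tuple[float, float]:
    """Chi-square with Yates continuity correction on a 2x2 table:
    sum of (|O-E| - 0.5)^2 / E over the four cells, the correction floored
    at zero when |O-E| < 0.5; p from the chi-square distribution, 1 df."""
    rows = table.as_rows()
    n = table.pos_n + table.neg_n
    if n == 0:
        raise StatError("empty table")
    col_sums = [rows[0][j] + rows[1][j] for j in (0, 1)]
    row_sums = [table.pos_n, table.neg_n]
    stat = 0.0
    for i in (0, 1):
        for j in (0, 1):
            expected = row_sums[i] * col_sums[j] / n
            if expected == 0:
                raise StatError(
                    "zero expected cell count; use fisher_exact_two_sided instead"
                )
            corrected = max(abs(rows[i][j] - expected) - 0.5, 0.0)
            stat += corrected * corrected / expected
    p = float(chi2_dist.sf(stat, df=1))
    return stat, p


@dataclass
class TierValidation:
    """One column of the validation table for a single model tier."""

    tier_label: str
    table: ContingencyTable
    conf: float = 0.95
    fold: float = field(init=False)
    fisher_p: float = field(init=False)
    metrics: SensSpec = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        self.fold = fold_enrichment(t.pos_hit, t.pos_n, t.neg_hit, t.neg_n)
        self.fisher_p = fisher_exact_two_sided(t)
        self.metrics = sensitivity_specificity(t, self.conf)

    @property
    def fold_is_infinite(self) -> bool:
        return math.isinf(self.fold)

    def to_dict(self) -> dict:
        t = self.table
        # Headline percentages from exact count ratios (85.35 must render as
        # 85.4, which float arithmetic cannot guarantee); CI bounds are
        # irrational so float rounding is fine there.
        sens_pct = (rate_pct(t.pos_hit, t.pos_n),) + self.metrics.sensitivity.as_pct()[1:]
        spec_pct = (rate_pct(t.neg_miss, t.neg_n),) + self.metrics.specificity.as_pct()[1:]
        return {
            "tier": self.tier_label,
            "pos_hit": t.pos_hit,
            "pos_n": t.pos_n,
            "neg_hit": t.neg_hit,
            "neg_n": t.neg_n,
            "pos_rate_pct": rate_pct(t.pos_hit, t.pos_n),
            "neg_rate_pct": rate_pct(t.neg_hit, t.neg_n),
            "fold_enrichment": None
            if self.fold_is_infinite
            else round_half_up(Fraction(t.pos_hit * t.neg_n, t.pos_n * t.neg_hit)),
            "fold_is_infinite": self.fold_is_infinite,
            "fisher_p": self.fisher_p,
            "sensitivity_pct": sens_pct[0],
            "sensitivity_ci_pct": [sens_pct[1], sens_pct[2]],
            "specificity_pct": spec_pct[0],
            "specificity_ci_pct": [spec_pct[1], spec_pct[2]],
        }


@dataclass
class ValidationReport:
    """Validation of all model tiers on one pair of training sets; renders
    as a tiers-as-columns TSV mirroring the usual sensitivity/specificity
    summary table."""

    tiers: list[TierValidation]

    def to_dict(self) -> dict:
        return {tv.tier_label: tv.to_dict() for tv in self.tiers}

    def to_tsv(self) -> str:
        cols = [tv.to_dict() for tv in self.tiers]
        rows = [
            ("Characteristics", [c["tier"] for c in cols]),
            ("Predicted targets in the (-)-training set (%)",
             [f"{c['neg_rate_pct']}" for c in cols]),
            ("Predicted targets in the (+)-training set (%)",
             [f"{c['pos_rate_pct']}" for c in cols]),
            ("Fold-enrichment",
             ["inf" if c["fold_is_infinite"] else f"{c['fold_enrichment']}" for c in cols]),
            ("Fisher p",
             [f"{c['fisher_p']:.4g}" for c in cols]),
            ("Sensitivity (% [95% CI])",
             [f"{c['sensitivity_pct']} [{c['sensitivity_ci_pct'][0]}-{c['sensitivity_ci_pct'][1]}]"
              for c in cols]),
            ("Specificity (% [95% CI])",
             [f"{c['specificity_pct']} [{c['specificity_ci_pct'][0]}-{c['specificity_ci_pct'][1]}]"
              for c in cols]),
        ]
        return "\n".join("\t".join([name] + vals) for name, vals in rows) + "\n"


def validation_report(tables: Sequence[tuple[str, ContingencyTable]],
                      conf: float = 0.95) -> ValidationReport:
    return ValidationReport([TierValidation(label, table, conf) for label, table in tables])
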