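"""Model-agreement statistics: FAC2, MAPE, Spearman, fractional bias, Wilcoxon.

Two comparison settings share these metrics:

* candidate RHU counts vs census housing-unit counts per census block
  (how well address / building points proxy for dwellings), and
* ABODE vs PPA population estimates per well-area.

FAC2 is the fraction of pairs within a factor of two,
0.5 <= predicted/observed <= 2.0 (closed interval).  The fractional bias is
implemented as

    FB = (1/n) * sum(a - b) / sum((a + b) / 2)

note the leading 1/n, which differs from the conventional normalised mean
bias; the conventional form is available via ``standard=True``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "MetricValue",
    "WilcoxonResult",
    "MetricsReport",
    "fac2",
    "mape",
    "spearman_rho",
    "fractional_bias",
    "wilcoxon_signed_rank",
    "agreement_summary",
    "compute_report",
]


@dataclass(frozen=True)
class PairedSeries:
    """Equal-length paired nonnegative series (predicted vs observed)."""

    predicted: np.ndarray
    observed: np.ndarray
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.predicted, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "observed", o)
        if p.shape != o.shape or p.ndim != 1:
            raise ValueError("predicted and observed must be equal-length 1-D")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
            raise ValueError("values must be finite")
        if np.any(p < 0) or np.any(o < 0):
            raise ValueError("values must be >= 0")
        if self.ids is not None and len(self.ids) != len(p):
            raise ValueError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.predicted)


@dataclass(frozen=True)
class MetricValue:
    """A metric with the number of pairs actually used and exclusion counts."""

    value: float
    n_used: int
    n_excluded: int = 0
    defined: bool = True

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    n_used: int  # nonzero differences
    exact: bool
    degenerate: bool = False


def fac2(s: PairedSeries) -> MetricValue:
    """Fraction of pairs with 0.5 <= predicted/observed <= 2.0.

    Pairs with observed == 0 are excluded (ratio undefined); both interval
    endpoints are included.
    """
    mask = s.observed > 0
    n = int(mask.sum())
    if n == 0:
        return MetricValue(math.nan, 0, len(s), defined=False)
    ratio = s.predicted[mask] / s.observed[mask]
    frac = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))
    return MetricValue(frac, n, len(s) - n)


def mape(s: PairedSeries) -> MetricValue:
    """Mean absolute percentage error with zero predictions removed.

    Pairs with predicted == 0 are excluded by definition; pairs with
    observed == 0 must also be excluded (division guard).  Both exclusion
    counts are folded into ``n_excluded`` so the rule is visible in output.
    """
    mask = (s.predicted > 0) & (s.observed > 0)
    n = int(mask.sum())
    if n == 0:
        return MetricValue(math.nan, 0, len(s), defined=False)
    err = np.abs(s.predicted[mask] - s.observed[mask]) / s.observed[mask]
    return MetricValue(float(np.mean(err)), n, len(s) - n)


def spearman_rho(s: PairedSeries) -> MetricValue:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    if len(s) < 3:
        raise ValueError("spearman_rho requires n >= 3")
    if np.all(s.predicted == s.predicted[0]) or np.all(s.observed == s.observed[0]):
        return MetricValue(math.nan, len(s), defined=False)
    rho = stats.spearmanr(s.predicted, s.observed).statistic
    return MetricValue(float(rho), len(s))


def fractional_bias(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    standard: bool = False,
) -> MetricValue:
    """Fractional bias between two paired series (a vs b).

    Default form carries a leading 1/n:  FB = (1/n) * sum(a-b) / sum((a+b)/2).
    ``standard=True`` drops the 1/n, giving the conventional normalised mean
    bias in [-2, 2].  Antisymmetric under swapping the series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("series must be equal-length, non-empty 1-D")
    denom = float(np.sum((a + b) / 2.0))
    if denom == 0:
        return MetricValue(math.nan, len(a), defined=False)
    fb = float(np.sum(a - b)) / denom
    if not standard:
        fb /= len(a)
    return MetricValue(fb, len(a))


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the mid-ranks of |d|."""
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(np.sum(ranks[d > 0]))
    return w_pos, ranks


def wilcoxon_signed_rank(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    zero_method: str = "wilcox",
    exact_threshold: int = 12,
    continuity: bool = True,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of a vs b (two-sided).

    Differences a - b are ranked by absolute value with mid-ranks for ties.
    ``zero_method="wilcox"`` drops zero differences before ranking (the
    original rule); ``"pratt"`` ranks them but removes their contribution.
    With at most ``exact_threshold`` nonzero differences the p-value is
    computed by exhaustive sign-flip enumeration (exact under the null even
    with ties); otherwise a normal approximation with tie-corrected variance
    Var(W+) = sum(ranks^2)/4 and optional continuity correction is used.

    z is positive when a tends to exceed b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D")
    d = a - b
    if zero_method == "wilcox":
        d = d[d != 0]
        drop_zeros_after = False
    elif zero_method == "pratt":
        drop_zeros_after = True
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n_nonzero = int(np.sum(d != 0))
    if n_nonzero == 0:
        return WilcoxonResult(0.0, 1.0, 0, exact=True, degenerate=True)

    w_pos, ranks = _signed_rank_stat(d)
    if drop_zeros_after:
        ranks = ranks[d != 0]
        d = d[d != 0]
        w_pos = float(np.sum(ranks[d > 0]))
    mu = float(np.sum(ranks)) / 2.0
    sigma = math.sqrt(float(np.sum(ranks**2)) / 4.0)
    if sigma == 0:
        return WilcoxonResult(0.0, 1.0, n_nonzero, exact=True, degenerate=True)
    dev = w_pos - mu
    if continuity:
        z = (dev - 0.5 * np.sign(dev)) / sigma if dev != 0 else 0.0
    else:
        z = dev / sigma

    if n_nonzero <= exact_threshold:
        # exhaustive sign-flip null: W+ symmetric about mu even under ties
        lo, hi = mu - abs(dev), mu + abs(dev)
        count = 0
        total = 2**n_nonzero
        for signs in itertools.product((0.0, 1.0), repeat=n_nonzero):
            w = float(np.dot(signs, ranks))
            if w <= lo + 1e-9 or w >= hi - 1e-9:
                count += 1
        return WilcoxonResult(float(z), count / total, n_nonzero, exact=True)

    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(float(z), min(1.0, float(p)), n_nonzero, exact=False)


def agreement_summary(
    records: Sequence[tuple[str, str]] | Sequence[str],
) -> dict[str, dict[str, int]]:
    """Count agreement categories per stratum.

    ``records`` is either (stratum, category) pairs or bare category labels
    (single stratum ``"all"``).  Category totals are preserved: the counts
    across categories sum to the number of records.
    """
    out: dict[str, dict[str, int]] = {}
    for rec in records:
        if isinstance(rec, str):
            stratum, category = "all", rec
        else:
            stratum, category = rec
        row = out.setdefault(stratum, {})
        row[category] = row.get(category, 0) + 1
    return out


@dataclass
class MetricsReport:
    """Bundle of the evaluation statistics for one paired comparison."""

    fac2: MetricValue
    mape: MetricValue
    spearman: MetricValue
    fractional_bias: MetricValue
    wilcoxon: WilcoxonResult
    agreement_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = [
            {"metric": "fac2", "value": self.fac2.value, "n_used": self.fac2.n_used},
            {"metric": "mape", "value": self.mape.value, "n_used": self.mape.n_used},
            {
                "metric": "spearman_rho",
                "value": self.spearman.value,
                "n_used": self.spearman.n_used,
            },
            {
                "metric": "fractional_bias",
                "value": self.fractional_bias.value,
                "n_used": self.fractional_bias.n_used,
            },
            {"metric": "wilcoxon_z", "value": self.wilcoxon.z, "n_used": self.wilcoxon.n_used},
            {"metric": "wilcoxon_p", "value": self.wilcoxon.p, "n_used": self.wilcoxon.n_used},
        ]
        return rows


def compute_report(
    predicted: Sequence[float],
    observed: Sequence[float],
    fb_standard: bool = False,
    agreement: Sequence[tuple[str, str]] | None = None,
) -> MetricsReport:
    """All metrics for one predicted-vs-observed comparison."""
    s = PairedSeries(np.asarray(predicted, float), np.asarray(observed, float))
    return MetricsReport(
        fac2=fac2(s),
        mape=mape(s),
        spearman=spearman_rho(s),
        fractional_bias=fractional_bias(s.predicted, s.observed, standard=fb_standard),
        wilcoxon=wilcoxon_signed_rank(s.predicted, s.observed),
        agreement_counts=agreement_summary(agreement) if agreement else {},
    )
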