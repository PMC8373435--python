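"""Between-group statistics on similarity features.

Group contrasts (AD vs HC, MCI vs HC, AD vs MCI) are tested per scalp
region with the two-sided Wilcoxon rank-sum test; a Kolmogorov–Smirnov
normality screen documents why a nonparametric test is used (it never
switches the test automatically). Significance within each contrast is
Bonferroni-controlled across the regions tested (α/6 = 0.0083 for the
default six-region montage at α = 0.05).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats

from .brs_features import BRSResult


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


DEFAULT_COMPARISONS = (("AD", "HC"), ("MCI", "HC"), ("AD", "MCI"))


def ks_normality(values: Sequence[float]) -> float:
    """One-sample KS test p-value against a normal with the sample's
    mean and (sample) standard deviation.

    Documentation step only: estimating the parameters from the sample makes
    the p-value conservative (no Lilliefors correction is applied).
    Requires at least 5 values and non-zero variance.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 5:
        raise StatsError(f"KS normality screen needs >= 5 values, got {x.size}")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise StatsError("degenerate sample: zero variance")
    return float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)


def ranksum_test(
    a: Sequence[float], b: Sequence[float], *, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``method="auto"`` uses the exact null distribution when the combined
    sample size is at most 20 and there are no ties, and the normal
    approximation with tie correction (and continuity correction) otherwise.
    Returns ``(U statistic of the first sample, two-sided p)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < pooled.size
        method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise StatsError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test level α/m (0.05/6 → 0.0083...)."""
    if not (0 < alpha < 1):
        raise StatsError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise StatsError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


@dataclasses.dataclass
class GroupComparison:
    """Rank-sum contrast of one region (and band subset) between two groups."""

    comparison: str          # e.g. "MCI-HC"
    region: str
    band_set: tuple[str, ...]
    statistic: float
    p: float
    corrected_alpha: float
    significant: bool
    median_diff: float       # median(group 1) − median(group 2)
    n1: int
    n2: int


def compare_groups(
    results: Sequence[BRSResult],
    groups: Mapping[str, str] | None = None,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    alpha: float = 0.05,
    *,
    value: str = "std",
) -> list[GroupComparison]:
    """Pre-planned pairwise group contrasts per region × band subset.

    For each comparison the per-test level is α/m with m the number of
    regions tested for that band subset (6 with the default montage).
    ``value`` selects the standardized (default) or raw similarity; the
    rank-sum p-value is identical for any monotone transform, so the choice
    only affects the reported median difference.
    """
    if value not in ("std", "raw"):
        raise StatsError("value must be 'std' or 'raw'")
    if groups is None:
        groups = {r.participant: r.group for r in results}
    labels = set(groups.values())
    for g1, g2 in comparisons:
        for g in (g1, g2):
            if g not in labels:
                raise StatsError(f"unknown group label {g!r}; cohort has {sorted(labels)}")

    # organize: (band_set, region) -> group -> values
    cells: dict[tuple[tuple[str, ...], str], dict[str, list[float]]] = {}
    band_regions: dict[tuple[str, ...], list[str]] = {}
    for r in results:
        v = r.std if value == "std" else r.raw
        if v is None:
            raise StatsError("standardized values requested but not computed")
        key = (r.band_set, r.region)
        cells.setdefault(key, {}).setdefault(groups[r.participant], []).append(v)
        regs = band_regions.setdefault(r.band_set, [])
        if r.region not in regs:
            regs.append(r.region)

    out: list[GroupComparison] = []
    for band_set, regions in band_regions.items():
        corrected = bonferroni_alpha(alpha, len(regions))
        for g1, g2 in comparisons:
            for region in regions:
                cell = cells[(band_set, region)]
                a = cell.get(g1, [])
                b = cell.get(g2, [])
                if not a or not b:
                    raise StatsError(
                        f"comparison {g1}-{g2}, region {region!r}: empty group"
                    )
                stat, p = ranksum_test(a, b)
                out.append(
                    GroupComparison(
                        comparison=f"{g1}-{g2}",
                        region=region,
                        band_set=band_set,
                        statistic=stat,
                        p=p,
                        corrected_alpha=corrected,
                        significant=bool(p < corrected),
                        median_diff=float(np.median(a) - np.median(b)),
                        n1=len(a),
                        n2=len(b),
                    )
                )
    return out
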