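"""Strand-aware bisulfite methylation profiling around miRNA start sites.

CpG counts within +/-2000 bp of each miRNA start site are aggregated into
fixed-width bins on a transcription-oriented axis (negative offsets =
upstream of the start site, for either strand).  Per-miRNA upstream and
downstream means feed a Wilcoxon rank-sum comparison between up- and
down-regulated miRNA groups, a per-bin positional difference series (to
localize where the groups diverge), and a Pearson correlation between
upstream methylation and miRNA expression change.

Binning convention: bins are left-open/right-closed intervals
``(edge, edge + bin_bp]`` with edges every ``bin_bp`` from ``-window_bp``;
a CpG exactly on an edge therefore falls in the bin extending upstream of
it.  Bin centers span [-window_bp, +window_bp).  Empty bins are missing
(NaN), never zero-filled — zero would masquerade as unmethylated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, MethylationRecord

__all__ = [
    "MethylationProfile",
    "GroupComparison",
    "profile",
    "region_mean",
    "compare_groups",
    "rank_sum_test",
    "positional_difference",
    "meth_expr_correlation",
]


@dataclass(frozen=True)
class MethylationProfile:
    """Binned methylation fractions around one miRNA start site.

    ``offsets`` are signed bin centers in transcription direction;
    ``fractions`` are pooled meth/(meth+unmeth) per bin (NaN when no CpG);
    ``coverages`` are the pooled read counts per bin.
    """

    mirna_id: str
    offsets: np.ndarray
    fractions: np.ndarray
    coverages: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.fractions) == len(self.coverages)):
            raise ValueError("profile arrays must share one length")


@dataclass(frozen=True)
class GroupComparison:
    """Wilcoxon rank-sum comparison of per-miRNA region means."""

    region: str
    statistic: float
    p_value: float
    n_up: int
    n_down: int
    method: str  # "exact" or "normal"


def _start_site(locus: GenomicInterval) -> int:
    return locus.start if locus.strand == "+" else locus.end - 1


def profile(
    mirna_locus: GenomicInterval,
    records: Sequence[MethylationRecord],
    window_bp: int = 2000,
    bin_bp: int = 100,
) -> MethylationProfile:
    """Bin CpG counts within +/-window_bp of the miRNA start site.

    Offsets are oriented by strand so negative always means upstream in
    transcription direction.  Records on other chromosomes are ignored.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be divisible by bin_bp")
    start = _start_site(mirna_locus)
    n_bins = 2 * window_bp // bin_bp
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for rec in records:
        if rec.chrom != mirna_locus.chrom:
            continue
        genomic_offset = rec.pos - start
        offset = genomic_offset if mirna_locus.strand == "+" else -genomic_offset
        if not (-window_bp < offset <= window_bp):
            continue
        # left-open/right-closed bins: an edge CpG joins the upstream bin
        idx = (offset + window_bp - 1) // bin_bp
        meth[idx] += rec.meth_count
        total[idx] += rec.coverage
    offsets = np.arange(n_bins) * bin_bp - window_bp + bin_bp / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return MethylationProfile(
        mirna_id=mirna_locus.name,
        offsets=offsets,
        fractions=fractions,
        coverages=total.astype(int),
    )


def region_mean(
    prof: MethylationProfile,
    region: Literal["upstream", "downstream", "window"],
) -> float:
    """Coverage-weighted mean methylation fraction over a region.

    Upstream = bin centers < 0, downstream = bin centers >= 0.  Missing
    (empty) bins are excluded; an all-missing region propagates NaN.
    """
    if region == "upstream":
        mask = prof.offsets < 0
    elif region == "downstream":
        mask = prof.offsets >= 0
    elif region == "window":
        mask = np.ones_like(prof.offsets, dtype=bool)
    else:
        raise ValueError(f"unknown region {region!r}")
    fractions = prof.fractions[mask]
    coverages = prof.coverages[mask]
    valid = ~np.isnan(fractions)
    if not valid.any():
        return float("nan")
    weights = coverages[valid]
    return float(np.average(fractions[valid], weights=weights))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 12,
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Exact path (both groups <= ``exact_max_n``): the null distribution of
    the first group's rank sum W is enumerated over all C(n1+n2, n1)
    assignments of the observed midranks, and p = P(|W - E[W]| >= observed
    deviation).  With complete ties every assignment yields the same W, so
    p = 1.  Larger groups use the normal approximation with continuity and
    tie correction (scipy Mann-Whitney U machinery).

    Returns (statistic, p, method); the statistic is W for the exact path
    and the z-score for the normal path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = len(x), len(y)
    if max(n1, n2) <= exact_max_n:
        ranks = stats.rankdata(np.concatenate([x, y]))
        w_obs = ranks[:n1].sum()
        expectation = ranks.sum() * n1 / (n1 + n2)
        dev = abs(w_obs - expectation)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            w = ranks[list(idx)].sum()
            if abs(w - expectation) >= dev - 1e-9:
                count += 1
            total += 1
        return float(w_obs), count / total, "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    # convert the U p-value back to a signed z-score for reporting
    z = stats.norm.isf(res.pvalue / 2.0)
    if res.statistic < n1 * n2 / 2.0:
        z = -z
    return float(z), float(res.pvalue), "normal"


def compare_groups(
    up_profiles: Sequence[MethylationProfile],
    down_profiles: Sequence[MethylationProfile],
    region: Literal["upstream", "downstream", "window"],
    exact_max_n: int = 12,
) -> GroupComparison:
    """Compare per-miRNA region means between up- and down-regulated groups.

    The first sample handed to the test is the down group, so a positive
    shift (higher methylation in down-regulated miRNAs) drives the
    statistic upward.
    """
    up_means = [m for m in (region_mean(p, region) for p in up_profiles)
                if not math.isnan(m)]
    down_means = [m for m in (region_mean(p, region) for p in down_profiles)
                  if not math.isnan(m)]
    if len(up_means) < 2 or len(down_means) < 2:
        raise ValueError(
            "need >= 2 profiles with non-missing region means per group"
        )
    statistic, p_value, method = rank_sum_test(
        down_means, up_means, exact_max_n=exact_max_n
    )
    return GroupComparison(
        region=region,
        statistic=statistic,
        p_value=p_value,
        n_up=len(up_means),
        n_down=len(down_means),
        method=method,
    )


def positional_difference(
    up_profiles: Sequence[MethylationProfile],
    down_profiles: Sequence[MethylationProfile],
) -> pd.DataFrame:
    """Per-bin (down-group mean - up-group mean) methylation difference.

    Requires a common binning across profiles.  Returns a DataFrame with
    columns offset and difference; the row order is ascending offset, and
    ``attrs["argmax_offset"]`` records the offset of the largest positive
    difference.
    """
    if not up_profiles or not down_profiles:
        raise ValueError("both groups need >= 1 profile")
    offsets = up_profiles[0].offsets
    for p in list(up_profiles) + list(down_profiles):
        if not np.array_equal(p.offsets, offsets):
            raise ValueError("profiles do not share a common binning")
    up_mean = np.nanmean(
        np.vstack([p.fractions for p in up_profiles]), axis=0
    )
    down_mean = np.nanmean(
        np.vstack([p.fractions for p in down_profiles]), axis=0
    )
    diff = down_mean - up_mean
    df = pd.DataFrame({"offset": offsets, "difference": diff})
    finite = np.isfinite(diff)
    if finite.any():
        df.attrs["argmax_offset"] = float(offsets[finite][np.argmax(diff[finite])])
    else:
        df.attrs["argmax_offset"] = float("nan")
    return df


def meth_expr_correlation(
    profiles: Sequence[MethylationProfile],
    log2fc: Mapping[str, float],
    region: Literal["upstream", "downstream", "window"] = "upstream",
) -> tuple[float, float]:
    """Pearson correlation between region methylation and expression change.

    Pairs each profile's region mean with that miRNA's log2 fold change;
    p-value comes from the t-distribution transform of r with n-2 df.
    """
    xs, ys = [], []
    for prof in profiles:
        if prof.mirna_id not in log2fc:
            continue
        m = region_mean(prof, region)
        if math.isnan(m):
            continue
        xs.append(m)
        ys.append(log2fc[prof.mirna_id])
    if len(xs) < 3:
        raise ValueError("need >= 3 paired observations")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("constant input vector; correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)
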