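"""Quantifications shared by simulated and synthetic data.

These are the bespoke observables used to read out the timer: virtual 4C
profiles, mean-contact curves against a reference region and their
signal-weighted centroid, the two-micro-TAD split score, cumulative and
hour-interpolated track timecourses, cross-cluster expression
normalization, Welch-test genotype comparison, the colinearity score and
CTCF-site occupancy shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Axis, ContactMap, CurveSeries, Track
from .locus import LocusAnnotation
from .timer import ActivationSchedule

__all__ = [
    "PairList",
    "virtual_4c",
    "mean_contact_curve",
    "contact_centroid",
    "split_score",
    "cumulative_signal",
    "interpolate_timecourse",
    "normalize_cross_cluster",
    "compare_genotypes",
    "colinearity_score",
    "occupancy_share_shift",
]


@dataclass
class PairList:
    """Valid interaction pairs (bin1, bin2) on an axis."""

    axis: Axis
    bin1: np.ndarray
    bin2: np.ndarray

    def __post_init__(self):
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        if self.bin1.shape != self.bin2.shape:
            raise ValueError("bin1 and bin2 must have equal length")
        n = self.axis.n_bins
        for arr in (self.bin1, self.bin2):
            if len(arr) and (arr.min() < 0 or arr.max() >= n):
                raise ValueError("pair bins outside axis")

    def __len__(self) -> int:
        return len(self.bin1)


def _bin_range(region) -> tuple[int, int]:
    lo, hi = int(region[0]), int(region[1])
    if lo > hi:
        raise ValueError(f"empty bin range ({lo}, {hi})")
    return lo, hi


def virtual_4c(source, viewpoint, exclusion: int = 2) -> Track:
    """Interaction profile of a viewpoint, normalized to sum 1.

    ``source`` is a :class:`ContactMap` or :class:`PairList`; ``viewpoint``
    an inclusive bin range.  Bins within ``exclusion`` of the viewpoint are
    masked (set to 0) before normalizing over the unmasked bins.
    """
    lo, hi = _bin_range(viewpoint)
    if isinstance(source, ContactMap):
        axis = source.axis
        if hi >= axis.n_bins:
            raise ValueError("viewpoint outside axis")
        profile = source.matrix[lo : hi + 1, :].mean(axis=0)
    elif isinstance(source, PairList):
        axis = source.axis
        if hi >= axis.n_bins:
            raise ValueError("viewpoint outside axis")
        profile = np.zeros(axis.n_bins)
        in1 = (source.bin1 >= lo) & (source.bin1 <= hi)
        in2 = (source.bin2 >= lo) & (source.bin2 <= hi)
        np.add.at(profile, source.bin2[in1], 1.0)
        np.add.at(profile, source.bin1[in2], 1.0)
    else:
        raise TypeError(f"unsupported source type {type(source).__name__}")

    mask_lo = max(lo - exclusion, 0)
    mask_hi = min(hi + exclusion, axis.n_bins - 1)
    profile = profile.astype(float).copy()
    profile[mask_lo : mask_hi + 1] = 0.0
    total = profile.sum()
    if total <= 0:
        raise ValueError("viewpoint profile empty after masking")
    return Track(axis, profile / total, name="virtual4C")


def mean_contact_curve(cmap: ContactMap, x_region, y_region) -> Track:
    """For each bin in ``x_region``, the mean contact with ``y_region``.

    Returned on the full axis with zeros outside ``x_region`` so it remains
    bedGraph-compatible; the curve values live on the x_region bins.
    """
    xlo, xhi = _bin_range(x_region)
    ylo, yhi = _bin_range(y_region)
    n = cmap.axis.n_bins
    if xhi >= n or yhi >= n:
        raise ValueError("region outside axis")
    curve = cmap.matrix[xlo : xhi + 1, ylo : yhi + 1].mean(axis=1)
    values = np.zeros(n)
    values[xlo : xhi + 1] = curve
    return Track(cmap.axis, values, name="mean_contact")


def contact_centroid(curve: Track) -> float:
    """Signal-weighted mean genomic coordinate (bp) of a non-negative curve."""
    v = curve.values
    if np.any(v < 0):
        raise ValueError("curve must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("zero-sum curve has no centroid")
    return float(np.sum(curve.axis.bin_midpoints() * v) / total)


def split_score(cmap: ContactMap, boundary: int, span=None) -> float:
    """Two-domain segregation strength at ``boundary``.

    ``(mean within-left + mean within-right) / (2 * mean cross)`` over the
    bins of ``span`` (inclusive range; default: whole axis).  The boundary
    bin belongs to the right-hand block.  Uniform matrices score exactly 1;
    higher values mean stronger segregation into two micro-TADs.
    """
    if span is None:
        span = (0, cmap.axis.n_bins - 1)
    lo, hi = _bin_range(span)
    if not (lo < boundary <= hi):
        raise ValueError("boundary must lie strictly inside the span")
    m = cmap.matrix
    left = slice(lo, boundary)
    right = slice(boundary, hi + 1)
    if boundary - lo < 2 or hi + 1 - boundary < 2:
        raise ValueError("degenerate side: need at least 2 bins on each side")
    within_left = _offdiag_mean(m[left, left])
    within_right = _offdiag_mean(m[right, right])
    cross = m[left, right].mean()
    if cross <= 0:
        raise ValueError("zero cross-block contact")
    return float((within_left + within_right) / (2.0 * cross))


def _offdiag_mean(block: np.ndarray) -> float:
    n = block.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(block[mask].mean())


def cumulative_signal(series: CurveSeries) -> CurveSeries:
    """Running per-bin sum over time (cumulative ChIP-signal display)."""
    if len(series) == 0:
        raise ValueError("empty series")
    out = []
    acc = np.zeros(series.axis.n_bins)
    for t, tr in zip(series.times, series.tracks):
        acc = acc + tr.values
        out.append(Track(series.axis, acc.copy(), name=f"cumulative_{t}"))
    return CurveSeries(list(series.times), out)


def interpolate_timecourse(series: CurveSeries, step: float) -> CurveSeries:
    """Per-bin linear interpolation between measured timepoints.

    Returns tracks at ``step``-spaced times from the first to the last
    measured timepoint; measured timepoints reproduce the measured tracks
    exactly (to numerical precision).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if len(series) < 2:
        raise ValueError("need at least two timepoints to interpolate")
    t = np.asarray(series.times, dtype=float)
    data = series.stack()  # (n_times, n_bins)
    n_out = int(np.floor((t[-1] - t[0]) / step + 1e-9)) + 1
    new_times = t[0] + step * np.arange(n_out)
    out = []
    for tq in new_times:
        j = np.searchsorted(t, tq, side="right") - 1
        j = min(max(j, 0), len(t) - 2)
        w = (tq - t[j]) / (t[j + 1] - t[j])
        vals = (1 - w) * data[j] + w * data[j + 1]
        out.append(Track(series.axis, vals, name=f"interp_{tq:g}"))
    return CurveSeries(list(new_times), out)


def normalize_cross_cluster(
    expr: pd.DataFrame, target_genes, normalizer_genes
) -> pd.DataFrame:
    """Correct per-sample depth/staging using genes from other clusters.

    For each sample (column) the scale factor is the sample's mean over
    ``normalizer_genes`` divided by the grand mean of those genes across
    samples; target-gene values are divided by it.  Normalizer rows are
    returned unchanged.
    """
    normalizer_genes = list(normalizer_genes)
    target_genes = list(target_genes)
    missing = [g for g in normalizer_genes + target_genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from table: {missing}")
    norm_means = expr.loc[normalizer_genes].mean(axis=0)
    if (norm_means <= 0).any():
        bad = list(norm_means.index[norm_means <= 0])
        raise ValueError(f"non-positive normalizer mean in sample(s) {bad}")
    grand = norm_means.mean()
    scale = norm_means / grand
    out = expr.copy().astype(float)
    out.loc[target_genes] = out.loc[target_genes].div(scale, axis=1)
    return out


def compare_genotypes(wt: pd.DataFrame, mut: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mutant/control comparison across replicate columns.

    Both tables are genes x replicates (one timepoint).  Returns mean
    log2(mut/wt), Welch's unequal-variances two-sided t statistic and
    p-value, and significance stars at 0.05 / 0.01.  With zero variance in
    both groups and equal means the p-value is reported as 1; zero variance
    with different means gives p = 0.
    """
    if wt.shape[1] < 2 or mut.shape[1] < 2:
        raise ValueError("need at least 2 replicates per genotype")
    common = [g for g in wt.index if g in mut.index]
    rows = []
    eps = 1e-300
    for g in common:
        a = mut.loc[g].to_numpy(dtype=float)
        b = wt.loc[g].to_numpy(dtype=float)
        log2fc = float(np.log2((a.mean() + eps) / (b.mean() + eps)))
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            tstat, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            tstat, p = stats.ttest_ind(a, b, equal_var=False)
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append(
            {"gene": g, "log2_ratio": log2fc, "t": float(tstat), "p": float(p), "sig": stars}
        )
    return pd.DataFrame(rows).set_index("gene")


def colinearity_score(
    schedule: ActivationSchedule, locus: LocusAnnotation, genes=None
) -> float:
    """Spearman correlation between 3'->5' gene position and onset time.

    Defaults to the Hoxd genes (Evx2, not being a Hox gene, is excluded
    from the colinearity statistic).  Never-activated genes are assigned a
    common onset later than every observed one, so they share the last
    ranks with average-tie handling.
    """
    if genes is None:
        genes = [g.name for g in locus.cluster_genes_3to5() if g.name.startswith("Hoxd")]
    onsets = np.array([schedule.onsets.get(g, np.inf) for g in genes], dtype=float)
    finite = onsets[np.isfinite(onsets)]
    if len(finite) < 3:
        raise ValueError("need at least 3 genes with finite onsets")
    filled = np.where(np.isfinite(onsets), onsets, finite.max() + 1.0)
    pos_rank = [locus.gene_rank(g) for g in genes]
    return float(stats.spearmanr(pos_rank, filled).statistic)


def occupancy_share_shift(series: CurveSeries, cbs_bins: dict[str, int]) -> pd.DataFrame:
    """Per-timepoint share of total labeled-CBS occupancy at each site.

    ``cbs_bins`` maps site labels to bin indices.  Rows (timepoints) sum to
    1; a timepoint with zero total occupancy yields NaN shares (flagged by
    the caller via ``DataFrame.isna``).
    """
    if not cbs_bins:
        raise ValueError("no labeled bins")
    n = series.axis.n_bins
    for label, b in cbs_bins.items():
        if not (0 <= b < n):
            raise ValueError(f"bin for {label} outside axis")
    rows = []
    for tr in series.tracks:
        vals = {label: tr.values[b] for label, b in cbs_bins.items()}
        total = sum(vals.values())
        if total > 0:
            rows.append({k: v / total for k, v in vals.items()})
        else:
            rows.append({k: np.nan for k in vals})
    return pd.DataFrame(rows, index=list(series.times))
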