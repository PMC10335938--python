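"""Synthetic inputs with known ground truth for the analysis operations.

The generators emulate the statistical structure of the study's measured
data — an anterior-to-posterior spreading activation wave with posterior
dilution, contact matrices with micro-TAD blocks, a stripe and loops on a
power-law background, replicate expression tables with colinear onsets,
and valid-pair lists sampled from a contact matrix — so every analysis
operation can be tested against a recoverable truth.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Axis, ContactMap, CurveSeries, Track
from .analysis import PairList

__all__ = [
    "WaveParams",
    "SyntheticMapParams",
    "gen_wave_tracks",
    "recover_front_velocity",
    "gen_contact_matrix",
    "gen_expression_table",
    "sample_pairs",
]


@dataclass(frozen=True)
class WaveParams:
    """Sigmoid activation front moving at constant velocity.

    The front starts at ``front_start`` (bp) at the first requested
    timepoint and moves ``velocity`` bp per model-hour in the direction of
    decreasing coordinate (anterior-to-posterior on the HoxD axis); signal
    behind the front decays with onset lateness at ``dilution_rate``
    (two-fold per 1/dilution_rate hours).
    """

    front_start: float
    velocity: float  # bp per model-hour, > 0; front moves toward lower coords
    front_width: float = 4_000.0  # bp
    amplitude: float = 1.0
    dilution_rate: float = 0.0  # per hour of onset lateness
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.front_width <= 0:
            raise ValueError("front_width must be positive")


def _sigmoid(x):
    from scipy.special import expit

    return expit(x)


def gen_wave_tracks(axis: Axis, timepoints, params: WaveParams) -> CurveSeries:
    """Spreading-wave coverage tracks at the requested timepoints.

    At time t the front sits at ``front_start - velocity * (t - t0)``; a
    bin at coordinate x carries
    ``amplitude * sigmoid((front(t) ... ) / front_width)`` scaled by the
    posterior-dilution factor ``2^(-lateness * dilution_rate)``, where
    lateness is the hours since the front passed the bin, plus Gaussian
    noise clipped at zero.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("need at least one timepoint")
    rng = np.random.default_rng(params.seed)
    t0 = timepoints[0]
    x = axis.bin_midpoints()
    tracks = []
    for t in timepoints:
        front = params.front_start - params.velocity * (t - t0)
        clean = params.amplitude * _sigmoid((x - front) / params.front_width)
        if params.dilution_rate > 0:
            # onset lateness of bin x: hours after t0 the front reaches it
            lateness = np.maximum(0.0, (params.front_start - x) / params.velocity)
            clean = clean * 2.0 ** (-lateness * params.dilution_rate)
        noisy = clean + rng.normal(0.0, params.noise_sd, size=len(x))
        tracks.append(Track(axis, np.clip(noisy, 0.0, None), name=f"wave_{t:g}"))
    return CurveSeries(timepoints, tracks)


def _front_position(track: Track, half_max: float) -> float | None:
    """Coordinate of the half-maximum crossing (descending toward low coords)."""
    v = track.values
    x = track.axis.bin_midpoints()
    above = v >= half_max
    if not above.any() or above.all():
        return None
    # front = lowest coordinate from which the signal stays above half-max
    idx = np.flatnonzero(above)
    first = idx[0]
    if first == 0:
        return None
    # linear interpolation between the bin below and the first above
    x0, x1 = x[first - 1], x[first]
    y0, y1 = v[first - 1], v[first]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half_max - y0) / (y1 - y0) * (x1 - x0))


def recover_front_velocity(series: CurveSeries, amplitude: float | None = None) -> float:
    """Least-squares slope of half-maximum front positions versus time.

    Returns the speed (bp per model-hour) at which the front moves toward
    lower coordinates (positive = anterior-to-posterior spreading).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 timepoints")
    amp = amplitude if amplitude is not None else max(tr.values.max() for tr in series.tracks)
    half = amp / 2.0
    ts, fronts = [], []
    for t, tr in zip(series.times, series.tracks):
        f = _front_position(tr, half)
        if f is not None:
            ts.append(t)
            fronts.append(f)
    if len(ts) < 2:
        raise ValueError("front not detectable at >= 2 timepoints")
    slope = np.polyfit(ts, fronts, 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMapParams:
    """Structured contact matrix: power-law background plus enrichments."""

    n_bins: int
    tad_blocks: tuple = ()  # ((lo, hi), enrichment) inclusive bin ranges
    stripe: tuple | None = None  # ((xlo, xhi), (ylo, yhi), enrichment)
    loops: tuple = ()  # (bin1, bin2, enrichment)
    alpha: float = 1.0
    c0: float = 1.0
    noise_sd: float = 0.0  # sd of multiplicative log-normal noise (log scale)
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        for (_, enr) in self.tad_blocks:
            if enr < 0:
                raise ValueError("enrichments must be non-negative")
        for (_, _, enr) in self.loops:
            if enr < 0:
                raise ValueError("enrichments must be non-negative")


def gen_contact_matrix(params: SyntheticMapParams, axis: Axis | None = None) -> ContactMap:
    """Background power law with block/stripe/loop enrichments.

    Enrichments multiply the background as (1 + e) and stack additively
    when features overlap: a bin pair inside a block (e_b) and a loop
    (e_l) carries background * (1 + e_b + e_l).  Multiplicative log-normal
    noise is applied symmetrically; deterministic from the seed.
    """
    n = params.n_bins
    if axis is None:
        axis = Axis("chrS", 0, 1_000, n)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        bg = params.c0 * d ** (-params.alpha)
    np.fill_diagonal(bg, 0.0)

    enrich = np.zeros((n, n))
    for (lo, hi), e in params.tad_blocks:
        enrich[lo : hi + 1, lo : hi + 1] += e
    if params.stripe is not None:
        (xlo, xhi), (ylo, yhi), e = params.stripe
        enrich[xlo : xhi + 1, ylo : yhi + 1] += e
        enrich[ylo : yhi + 1, xlo : xhi + 1] += e
    for b1, b2, e in params.loops:
        enrich[b1, b2] += e
        if b1 != b2:
            enrich[b2, b1] += e
    mat = bg * (1.0 + enrich)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        logn = rng.normal(0.0, params.noise_sd, size=(n, n))
        logn = (logn + logn.T) / np.sqrt(2.0)  # symmetric, same marginal sd
        mat = mat * np.exp(logn)
    cmap = ContactMap(axis, mat)
    cmap.validate()
    return cmap


def gen_expression_table(
    locus,
    onsets: dict[str, float],
    timepoints,
    dilution: float = 0.0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    scale: float = 100.0,
    seed: int = 0,
):
    """Replicate expression tables from known onset times.

    value = scale * 1[t >= onset] * 2^(-rank * dilution) * lognormal noise.
    Returns a list of ``n_replicates`` DataFrames (genes x timepoints).
    """
    import pandas as pd

    genes = [g.name for g in locus.genes]
    missing = [g for g in genes if g not in onsets]
    if missing:
        raise KeyError(f"onsets missing for {missing}")
    timepoints = np.asarray(list(timepoints), dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_replicates):
        data = np.zeros((len(genes), len(timepoints)))
        for i, g in enumerate(genes):
            on = (timepoints >= onsets[g]).astype(float)
            dil = 2.0 ** (-locus.gene_rank(g) * dilution)
            noise = np.exp(rng.normal(0.0, noise_sd, size=len(timepoints))) if noise_sd > 0 else 1.0
            data[i] = scale * on * dil * noise
        frames.append(pd.DataFrame(data, index=genes, columns=timepoints))
    return frames


def sample_pairs(cmap: ContactMap, n: int, seed: int = 0) -> PairList:
    """Draw ``n`` valid pairs with probability proportional to map entries.

    Only the upper triangle (including diagonal) is sampled, matching the
    unordered nature of contact pairs.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    m = cmap.matrix
    nb = cmap.axis.n_bins
    iu = np.triu_indices(nb)
    w = m[iu].astype(float)
    total = w.sum()
    if total <= 0:
        raise ValueError("map has no positive mass")
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(w), size=n, p=w / total)
    return PairList(cmap.axis, iu[0][choice], iu[1][choice])
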