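"""Stochastic discrete-time loop-extrusion engine on a 1D lattice.

Cohesin extruders are represented as anchor pairs (left, right) on lattice
bins.  Each step applies, in order: Poisson loading at bins sampled from a
loading profile, outward anchor movement with orientation-dependent CTCF
stalling, stochastic bypass of stalled anchors, and unloading.  An anchor
entering a bin that holds one or more occupied CTCF sites whose blocking
face opposes its travel direction halts there with probability
``1 - (1 - p_stall)^k`` (k sites in the bin); a stalled anchor re-enters the
mobile pool with per-step probability ``p_bypass`` and then passes the
barrier on the next movement.  Anchors clamp at the lattice edges.  The
partner anchor of a stalled anchor keeps extruding (one-sided extrusion).

Contact observables follow a phenomenological model: a power-law
distance-decay background plus one "bridging" count per snapshot at each
extruder's (left, right) anchor pair, mirroring the loop-anchored contacts
seen in capture Hi-C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Axis, ContactMap, Track
from .locus import LatticeMap, LocusAnnotation, Orientation

__all__ = [
    "SimulationParams",
    "ExtruderState",
    "LatticeState",
    "Trajectory",
    "BarrierField",
    "barrier_counts",
    "barrier_field",
    "init_lattice",
    "simulate_step",
    "run_extrusion",
    "anchor_occupancy",
    "contact_map",
    "background_matrix",
    "region_contact",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the extrusion engine.

    Units: times in model-hours (the stembryo protocol clock), rates per
    model-hour, per-step probabilities dimensionless, speeds in bins/step.
    """

    bin_size: int = 2_000
    dt: float = 0.01  # model-hours per step
    v: int = 1  # bins per anchor per step
    # expected loadings per model-hour per unit loading weight: total
    # loading scales with the summed profile, so spreading transcription
    # recruits more cohesin (the self-entertained feedback)
    load_rate: float = 3.0
    w_active: float = 1.0  # loading weight per active-gene bin
    w_background: float = 1.5e-3  # loading weight per other in-span bin
    unload_prob: float = 0.001  # per extruder per step
    p_stall: float = 1.0  # per blocking-face site encountered
    p_bypass: float = 1.35e-4  # per stalled anchor per step
    # CTCF also hinders extrusion on its non-motif face, with lower capture
    # efficiency and much faster escape than head-on collisions.
    p_stall_reverse: float = 0.2
    p_bypass_reverse: float = 8e-3
    # A discordant site embedded inside the convergent anterior series (a
    # TOWARD_CDOM site flanked by TOWARD_TDOM sites: CBS3 in the wild-type
    # cluster) is treated as a full stage for the posterior-traveling
    # anchor: with probability embedded_full_block it stalls such anchors
    # like a head-on site (escape at p_bypass).  This is the package's
    # resolution of CBS3's otherwise unexplained conservation between Hoxd9
    # and Hoxd10; set to 0 to make discordant sites plain reverse-face
    # obstacles.
    embedded_full_block: float = 1.0
    max_extruders: int = 1500
    alpha: float = 1.0  # background distance-decay exponent
    c0: float = 0.1  # background amplitude (bridging-dominant regime)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "unload_prob",
            "p_stall",
            "p_bypass",
            "p_stall_reverse",
            "p_bypass_reverse",
            "embedded_full_block",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.v < 1:
            raise ValueError("v must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.load_rate < 0 or self.w_active < 0 or self.w_background < 0:
            raise ValueError("rates and weights must be non-negative")


@dataclass(frozen=True)
class ExtruderState:
    """One cohesin ring: anchor pair with stall flags (scalar view)."""

    left_anchor: int
    right_anchor: int
    left_stalled: bool = False
    right_stalled: bool = False
    birth_time: float = 0.0

    def __post_init__(self):
        if self.left_anchor > self.right_anchor:
            raise ValueError("left_anchor must be <= right_anchor")


@dataclass
class LatticeState:
    """Mutable engine state (vectorized over extruders)."""

    time: float
    n_bins: int
    left: np.ndarray
    right: np.ndarray
    left_stalled: np.ndarray
    right_stalled: np.ndarray
    birth: np.ndarray
    rng: np.random.Generator
    max_extruders: int

    @property
    def n_extruders(self) -> int:
        return len(self.left)

    def extruders(self) -> list[ExtruderState]:
        return [
            ExtruderState(
                int(l), int(r), bool(ls), bool(rs), float(b)
            )
            for l, r, ls, rs, b in zip(
                self.left, self.right, self.left_stalled, self.right_stalled, self.birth
            )
        ]


@dataclass
class Trajectory:
    """Snapshots and event log of one simulation replicate."""

    axis: Axis
    snapshot_times: list[float] = field(default_factory=list)
    snapshot_left: list[np.ndarray] = field(default_factory=list)
    snapshot_right: list[np.ndarray] = field(default_factory=list)
    events: list[tuple[float, str, int]] = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshot_times)

    def total_extruder_snapshots(self) -> int:
        return int(sum(len(a) for a in self.snapshot_left))

    def validate(self) -> None:
        t = np.asarray(self.snapshot_times)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("snapshot times must be strictly increasing")

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        """Sub-trajectory with snapshot times in [t_min, t_max]."""
        idx = [i for i, t in enumerate(self.snapshot_times) if t_min <= t <= t_max]
        return Trajectory(
            axis=self.axis,
            snapshot_times=[self.snapshot_times[i] for i in idx],
            snapshot_left=[self.snapshot_left[i] for i in idx],
            snapshot_right=[self.snapshot_right[i] for i in idx],
            events=[e for e in self.events if t_min <= e[0] <= t_max],
        )


# ---------------------------------------------------------------------------
# Barriers
# ---------------------------------------------------------------------------


def barrier_counts(locus: LocusAnnotation, lmap: LatticeMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin counts of occupied blocking sites.

    Returns ``(n_block_left, n_block_right)`` where ``n_block_left[b]``
    counts sites in bin *b* that block left-traveling (toward C-DOM)
    anchors, i.e. TOWARD_TDOM sites, and ``n_block_right`` the converse.
    """
    n = lmap.n_bins
    n_left = np.zeros(n, dtype=np.int64)
    n_right = np.zeros(n, dtype=np.int64)
    for s in locus.ctcf_sites:
        if not s.occupied:
            continue
        b = lmap.cbs_bin[s.id]
        if s.orientation is Orientation.TOWARD_TDOM:
            n_left[b] += 1
        else:
            n_right[b] += 1
    return n_left, n_right


def _stall_probs(counts: np.ndarray, p_stall: float) -> np.ndarray:
    return 1.0 - (1.0 - p_stall) ** counts


@dataclass(frozen=True)
class BarrierField:
    """Per-bin stall and bypass probabilities for each travel direction."""

    stall_left: np.ndarray  # P(halt) for an anchor entering while moving left
    stall_right: np.ndarray
    bypass_left: np.ndarray  # per-step escape probability once stalled there
    bypass_right: np.ndarray

    @classmethod
    def free(cls, n_bins: int) -> "BarrierField":
        z = np.zeros(n_bins)
        return cls(z, z.copy(), z.copy(), z.copy())


def barrier_field(
    locus: LocusAnnotation, lmap: LatticeMap, params: SimulationParams
) -> BarrierField:
    """Stall/bypass probabilities per bin from the annotation.

    A site halts anchors arriving head-on against its motif with
    ``p_stall`` and anchors arriving from its non-motif face with
    ``p_stall_reverse``; escape uses ``p_bypass`` and ``p_bypass_reverse``
    respectively (the stronger, forward-face value wins in mixed bins).
    Multiple sites in one bin stack their capture probabilities.
    """
    n = lmap.n_bins
    # head-on (full) and behind-face (weak) site counts per bin and direction
    full_l = np.zeros(n, dtype=np.int64)  # full blocks for left-movers
    full_r = np.zeros(n, dtype=np.int64)
    weak_l = np.zeros(n, dtype=np.int64)
    weak_r = np.zeros(n, dtype=np.int64)
    embedded = (
        set(s.id for s in _embedded_discordant_sites(locus))
        if params.embedded_full_block > 0
        else set()
    )
    leaky = set(s.id for s in _leaky_tdom_sites(locus))
    for s in locus.ctcf_sites:
        if not s.occupied:
            continue
        b = lmap.cbs_bin[s.id]
        toward_tdom = s.orientation is Orientation.TOWARD_TDOM
        head_on, behind = (full_l, full_r) if toward_tdom else (full_r, full_l)
        weak_head, weak_behind = (weak_l, weak_r) if toward_tdom else (weak_r, weak_l)
        if s.id in leaky:
            # non-boundary T-DOM site: transient pause element on both faces
            weak_head[b] += 1
            weak_behind[b] += 1
        elif s.id in embedded:
            # discordant site inside the convergent series: full stage for
            # the posterior-traveling anchor, head-on block unchanged
            full_l[b] += 1
            full_r[b] += 1
        else:
            head_on[b] += 1
            weak_behind[b] += 1

    p_emb = params.embedded_full_block * params.p_stall
    emb_bins = np.zeros(n, dtype=bool)
    for i in embedded:
        emb_bins[lmap.cbs_bin[i]] = True
    p_full = np.where(emb_bins, p_emb, params.p_stall)
    keep_l = (1 - p_full) ** full_l * (1 - params.p_stall_reverse) ** weak_l
    keep_r = (1 - p_full) ** full_r * (1 - params.p_stall_reverse) ** weak_r
    byp_l = np.where(full_l > 0, params.p_bypass, params.p_bypass_reverse)
    byp_r = np.where(full_r > 0, params.p_bypass, params.p_bypass_reverse)
    return BarrierField(1 - keep_l, 1 - keep_r, byp_l, byp_r)


def _leaky_tdom_sites(locus: LocusAnnotation) -> list:
    """Occupied sites in T-DOM outside the CS38-40 boundary region.

    These engage loops transiently (the sub-TAD1 hotspots) but do not act
    as hard insulators; cohesin accumulates at the CBS-rich CS38-40
    boundary instead.  Annotations without cluster/CS38-40 regions treat
    every site as a full barrier.
    """
    try:
        cluster = locus.region("cluster").interval
        cs = locus.region("CS38_40").interval
    except KeyError:
        return []
    return [
        s
        for s in locus.ctcf_sites
        if s.occupied
        and s.position >= cluster.end
        and not cs.contains(s.position)
    ]


def _embedded_discordant_sites(locus: LocusAnnotation) -> list:
    """Occupied TOWARD_CDOM cluster sites flanked by TOWARD_TDOM sites on
    both sides (CBS3 in the wild-type fixture)."""
    cluster_sites = [s for s in locus.in_cluster_sites() if s.occupied]
    tdom_pos = [
        s.position for s in cluster_sites if s.orientation is Orientation.TOWARD_TDOM
    ]
    if not tdom_pos:
        return []
    lo, hi = min(tdom_pos), max(tdom_pos)
    return [
        s
        for s in cluster_sites
        if s.orientation is Orientation.TOWARD_CDOM and lo < s.position < hi
    ]


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def init_lattice(
    lmap: LatticeMap, params: SimulationParams, t_start: float = 0.0
) -> LatticeState:
    """Empty lattice state with a generator seeded from ``params.seed``."""
    return LatticeState(
        time=t_start,
        n_bins=lmap.n_bins,
        left=np.empty(0, dtype=np.int64),
        right=np.empty(0, dtype=np.int64),
        left_stalled=np.empty(0, dtype=bool),
        right_stalled=np.empty(0, dtype=bool),
        birth=np.empty(0, dtype=float),
        rng=np.random.default_rng(params.seed),
        max_extruders=params.max_extruders,
    )


def simulate_step(
    state: LatticeState,
    loading_profile: Track | np.ndarray,
    params: SimulationParams,
    barriers: BarrierField | None = None,
    events: list | None = None,
) -> LatticeState:
    """Advance the lattice by one step of ``params.dt`` model-hours (in place).

    ``barriers`` carries per-bin stall and bypass probabilities; if omitted,
    the lattice is barrier-free.
    """
    profile = loading_profile.values if isinstance(loading_profile, Track) else loading_profile
    if len(profile) != state.n_bins:
        raise ValueError("loading profile length does not match lattice")
    if np.any(profile < 0):
        raise ValueError("loading profile must be non-negative")
    rng = state.rng
    n_bins = state.n_bins
    if barriers is None:
        barriers = BarrierField.free(n_bins)
    stall_left, stall_right = barriers.stall_left, barriers.stall_right

    # (1) loading: intensity proportional to the total loading weight
    total = profile.sum()
    n_new = 0
    if params.load_rate > 0 and total > 0:
        n_new = rng.poisson(params.load_rate * params.dt * total)
        room = state.max_extruders - state.n_extruders
        n_new = min(n_new, max(room, 0))
    if n_new > 0:
        bins = rng.choice(n_bins, size=n_new, p=profile / profile.sum())
        state.left = np.concatenate([state.left, bins])
        state.right = np.concatenate([state.right, bins])
        state.left_stalled = np.concatenate([state.left_stalled, np.zeros(n_new, bool)])
        state.right_stalled = np.concatenate([state.right_stalled, np.zeros(n_new, bool)])
        state.birth = np.concatenate([state.birth, np.full(n_new, state.time)])
        if events is not None:
            for b in bins:
                events.append((state.time, "load", int(b)))

    # (2) movement: v single-bin substeps with stall checks on entry
    for _ in range(params.v):
        mobile = (~state.left_stalled) & (state.left > 0)
        if mobile.any():
            cand = state.left[mobile] - 1
            p = stall_left[cand]
            hit = rng.random(len(cand)) < p
            state.left[mobile] = cand
            if hit.any():
                idx = np.flatnonzero(mobile)[hit]
                state.left_stalled[idx] = True
                if events is not None:
                    for b in state.left[idx]:
                        events.append((state.time, "stall", int(b)))
        mobile = (~state.right_stalled) & (state.right < n_bins - 1)
        if mobile.any():
            cand = state.right[mobile] + 1
            p = stall_right[cand]
            hit = rng.random(len(cand)) < p
            state.right[mobile] = cand
            if hit.any():
                idx = np.flatnonzero(mobile)[hit]
                state.right_stalled[idx] = True
                if events is not None:
                    for b in state.right[idx]:
                        events.append((state.time, "stall", int(b)))

    # (3) bypass: stalled anchors rejoin the mobile pool (they pass the
    # barrier on the next movement substep, which does not re-test the bin
    # they already occupy)
    for flags, pos, byp in (
        (state.left_stalled, state.left, barriers.bypass_left),
        (state.right_stalled, state.right, barriers.bypass_right),
    ):
        stalled = np.flatnonzero(flags)
        if len(stalled):
            passed = stalled[rng.random(len(stalled)) < byp[pos[stalled]]]
            flags[passed] = False
            if events is not None:
                for i in passed:
                    events.append((state.time, "bypass", int(pos[i])))

    # (4) unloading
    if params.unload_prob > 0 and state.n_extruders:
        gone = rng.random(state.n_extruders) < params.unload_prob
        if gone.any():
            if events is not None:
                for l in state.left[gone]:
                    events.append((state.time, "unload", int(l)))
            keep = ~gone
            state.left = state.left[keep]
            state.right = state.right[keep]
            state.left_stalled = state.left_stalled[keep]
            state.right_stalled = state.right_stalled[keep]
            state.birth = state.birth[keep]

    state.time += params.dt
    return state


def run_extrusion(
    lmap: LatticeMap,
    loading_fn,
    params: SimulationParams,
    t_start: float,
    t_end: float,
    locus: LocusAnnotation | None = None,
    snapshot_every: float = 0.05,
    record_events: bool = False,
) -> Trajectory:
    """Run the engine from ``t_start`` to ``t_end`` model-hours.

    ``loading_fn(t)`` returns the loading profile (Track or array) at time
    *t*.  Barriers are derived from ``locus`` when given.  Fully
    reproducible from ``params.seed``.
    """
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    barriers = barrier_field(locus, lmap, params) if locus is not None else None

    state = init_lattice(lmap, params, t_start)
    traj = Trajectory(axis=lmap.axis)
    events = traj.events if record_events else None
    snap_steps = max(1, round(snapshot_every / params.dt))
    n_steps = round((t_end - t_start) / params.dt)

    traj.snapshot_times.append(state.time)
    traj.snapshot_left.append(state.left.copy())
    traj.snapshot_right.append(state.right.copy())
    for k in range(n_steps):
        profile = loading_fn(state.time)
        simulate_step(state, profile, params, barriers, events)
        if (k + 1) % snap_steps == 0:
            traj.snapshot_times.append(state.time)
            traj.snapshot_left.append(state.left.copy())
            traj.snapshot_right.append(state.right.copy())
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def anchor_occupancy(traj: Trajectory, half_window: int = 0) -> Track:
    """Per-bin anchor density (RAD21 ChIP proxy).

    Counts every anchor snapshot within ``±half_window`` bins and divides by
    the number of snapshots, giving counts per snapshot.  With
    ``half_window=0`` the track sums to twice the mean number of extruders
    per snapshot.
    """
    if traj.n_snapshots == 0:
        raise ValueError("empty trajectory")
    n = traj.axis.n_bins
    counts = np.zeros(n)
    anchors = np.concatenate(traj.snapshot_left + traj.snapshot_right) if (
        traj.snapshot_left or traj.snapshot_right
    ) else np.empty(0, dtype=int)
    if len(anchors):
        base = np.bincount(anchors, minlength=n).astype(float)
        if half_window == 0:
            counts = base
        else:
            kernel = np.ones(2 * half_window + 1)
            counts = np.convolve(base, kernel, mode="same")
    return Track(traj.axis, counts / traj.n_snapshots, name="anchor_occupancy")


def background_matrix(n_bins: int, params: SimulationParams) -> np.ndarray:
    """Power-law distance-decay background, zero diagonal."""
    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        bg = params.c0 * d ** (-params.alpha)
    np.fill_diagonal(bg, 0.0)
    return bg


def contact_map(
    traj: Trajectory,
    params: SimulationParams,
    t_min: float | None = None,
    t_max: float | None = None,
) -> ContactMap:
    """Background power law plus snapshot-averaged anchor bridging."""
    if traj.n_snapshots == 0:
        raise ValueError("empty trajectory")
    sub = traj
    if t_min is not None or t_max is not None:
        sub = traj.window(
            -np.inf if t_min is None else t_min, np.inf if t_max is None else t_max
        )
        if sub.n_snapshots == 0:
            raise ValueError("no snapshots in requested time window")
    n = traj.axis.n_bins
    mat = background_matrix(n, params)
    if sub.total_extruder_snapshots():
        lefts = np.concatenate(sub.snapshot_left)
        rights = np.concatenate(sub.snapshot_right)
        bridge = np.zeros((n, n))
        np.add.at(bridge, (lefts, rights), 1.0)
        bridge = (bridge + bridge.T) / sub.n_snapshots
        # diagonal pairs (fresh extruders) were double-counted by symmetrization
        np.fill_diagonal(bridge, np.diag(bridge) / 2.0)
        mat += bridge
    return ContactMap(traj.axis, mat)


def region_contact(cmap: ContactMap, region_a, region_b) -> float:
    """Mean contact over the rectangle ``region_a x region_b`` (inclusive bin ranges)."""
    a_lo, a_hi = region_a
    b_lo, b_hi = region_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("empty region")
    n = cmap.axis.n_bins
    if a_lo < 0 or b_lo < 0 or a_hi >= n or b_hi >= n:
        raise ValueError("region outside axis")
    return float(cmap.matrix[a_lo : a_hi + 1, b_lo : b_hi + 1].mean())
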