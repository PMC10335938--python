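"""Annotation of the HoxD locus: genes, oriented CTCF sites, regulatory
regions, genotype editing and discretization to a simulation lattice.

The wild-type fixture encodes the published architecture of the mouse HoxD
locus as used throughout the package: a ~1.7-Mb axis (chr2:73,900,037-
75,621,560, mm10-like labels) holding the gene cluster
(chr2:74,667,374-74,767,842), the flanking telomeric regulatory domain
(T-DOM, split into sub-TADs) with its CBS-rich CS38-40 boundary
(chr2:75,105,000-75,190,000), and the centromeric C-DOM, which the model
treats as inert.

Within the cluster, nine occupied CTCF-binding sites (CBS1-9) are placed
between genes. CBS1, CBS2, CBS4 and CBS5 point toward T-DOM and act as the
successive barriers of the timer; CBS3 and CBS6-9 point toward C-DOM.  Five
further sites (TD-CBS1-5) sit in sub-TAD1, pointing back toward the cluster,
convergent with the in-cluster anterior sites.  Exact bp positions of
individual sites are not published at bp precision; the fixture places them
at round coordinates preserving the gene/CBS interleaving that the mutant
phenotypes pin down (CBS1 between Hoxd4 and Hoxd8, CBS2 between Hoxd8 and
Hoxd9, CBS4 between Hoxd10 and Hoxd11, CBS5 between Hoxd11 and Hoxd12).
Everything is overridable through BED input.

Coordinates are 0-based half-open. BED strand "+" maps to TOWARD_TDOM.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

from .core import Axis

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "ClusterDomain",
    "GenomicInterval",
    "Gene",
    "CtcfSite",
    "RegulatoryRegion",
    "LocusAnnotation",
    "GenotypeEdit",
    "LatticeMap",
    "build_default_hoxd_locus",
    "load_annotation",
    "apply_genotype",
    "discretize",
    "GENOTYPE_PRESETS",
    "genotype_edits",
]


class Orientation(enum.Enum):
    """Which way a CTCF motif points along the axis.

    TOWARD_TDOM sites present their blocking face to extruder anchors
    traveling away from T-DOM (toward C-DOM); TOWARD_CDOM sites block
    anchors traveling toward T-DOM.  This is the standard convergent-
    orientation rule: a site halts an anchor arriving head-on against the
    motif's pointing direction, so TOWARD_TDOM cluster sites are convergent
    with the TOWARD_CDOM sites of sub-TAD1.
    """

    TOWARD_TDOM = "TOWARD_TDOM"
    TOWARD_CDOM = "TOWARD_CDOM"


class ClusterDomain(enum.Enum):
    ANTERIOR = "anterior"  # CTCF-free, Wnt-activated
    CENTRAL = "central"
    POSTERIOR = "posterior"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Gene:
    name: str
    interval: GenomicInterval
    cluster_domain: ClusterDomain


@dataclass(frozen=True)
class CtcfSite:
    id: str
    position: int
    orientation: Orientation
    occupied: bool = True


@dataclass(frozen=True)
class RegulatoryRegion:
    name: str
    interval: GenomicInterval
    active_from: float | None = None  # model-hours; enhancer elements only


# The canonical 3'->5' transcriptional order of the modeled genes.  On the
# genomic axis used here (T-DOM at high coordinates) 3' genes have the
# HIGHEST coordinates, so this order corresponds to decreasing position.
CANONICAL_GENE_ORDER = (
    "Hoxd1",
    "Hoxd3",
    "Hoxd4",
    "Hoxd8",
    "Hoxd9",
    "Hoxd10",
    "Hoxd11",
    "Hoxd12",
    "Hoxd13",
    "Evx2",
)


@dataclass(frozen=True)
class LocusAnnotation:
    """Complete annotation of the modeled locus for one genotype."""

    axis_interval: GenomicInterval
    genes: tuple[Gene, ...]
    ctcf_sites: tuple[CtcfSite, ...]
    regions: tuple[RegulatoryRegion, ...]
    genotype_label: str = "wild_type"

    def __post_init__(self):
        self.validate()

    # -- lookups ----------------------------------------------------------
    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"no gene named {name!r}")

    def site(self, site_id: str) -> CtcfSite:
        for s in self.ctcf_sites:
            if s.id == site_id:
                return s
        raise KeyError(f"no CTCF site named {site_id!r}")

    def region(self, name: str) -> RegulatoryRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    @property
    def cluster(self) -> GenomicInterval:
        return self.region("cluster").interval

    def in_cluster_sites(self) -> tuple[CtcfSite, ...]:
        c = self.cluster
        return tuple(s for s in self.ctcf_sites if c.contains(s.position))

    def enhancers(self) -> tuple[RegulatoryRegion, ...]:
        return tuple(r for r in self.regions if r.name.startswith("E"))

    def cluster_genes_3to5(self) -> tuple[Gene, ...]:
        """Genes sorted 3'->5' (decreasing genomic coordinate)."""
        return tuple(sorted(self.genes, key=lambda g: -g.interval.start))

    def gene_rank(self, name: str) -> int:
        """0-based 3'->5' positional rank of a gene."""
        for i, g in enumerate(self.cluster_genes_3to5()):
            if g.name == name:
                return i
        raise KeyError(name)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        if not self.genes:
            raise ValueError("at least one gene required")
        ax = self.axis_interval
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            problems.append("gene names are not unique")
        ids = [s.id for s in self.ctcf_sites]
        if len(set(ids)) != len(ids):
            problems.append("CTCF site ids are not unique")
        for g in self.genes:
            if not ax.contains_interval(g.interval):
                problems.append(f"gene {g.name} outside axis")
        for s in self.ctcf_sites:
            if not ax.contains(s.position):
                problems.append(f"CTCF site {s.id} outside axis")
        for r in self.regions:
            if not ax.contains_interval(r.interval):
                problems.append(f"region {r.name} outside axis")
        # genes pairwise non-overlapping
        by_pos = sorted(self.genes, key=lambda g: g.interval.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.interval.overlaps(b.interval):
                problems.append(f"genes {a.name} and {b.name} overlap")
        # 3'->5' order must match the canonical order for the genes present
        order = [g.name for g in self.cluster_genes_3to5()]
        canon = [n for n in CANONICAL_GENE_ORDER if n in order]
        extra = [n for n in order if n not in CANONICAL_GENE_ORDER]
        if [n for n in order if n in CANONICAL_GENE_ORDER] != canon:
            problems.append(
                f"gene order along the axis {order} violates canonical 3'->5' order"
            )
        del extra
        # anterior domain (3' of the first TOWARD_TDOM barrier) must be CBS-free
        try:
            anterior_problems = self._check_anterior_ctcf_free()
            problems.extend(anterior_problems)
        except KeyError:
            pass
        if problems:
            raise ValueError("invalid annotation: " + "; ".join(problems))

    def _check_anterior_ctcf_free(self) -> list[str]:
        problems = []
        cluster = self.region("cluster").interval
        anterior = [g for g in self.genes if g.cluster_domain is ClusterDomain.ANTERIOR]
        if not anterior:
            return problems
        anterior_lo = min(g.interval.start for g in anterior)
        for s in self.ctcf_sites:
            if s.occupied and cluster.contains(s.position) and s.position >= anterior_lo:
                problems.append(
                    f"occupied site {s.id} lies in the CTCF-free anterior domain"
                )
        return problems


@dataclass(frozen=True)
class GenotypeEdit:
    """One edit of the annotation.

    kind:
      * ``DELETE_CBS`` — inactivate named sites (coordinates unshifted; the
        deleted segments are ~1 kb against a 1.7-Mb axis).
      * ``DELETE_INTERVAL`` — remove a bp interval and shift downstream
        coordinates (used for the larger structural deletions).
      * ``INSERT_CBS_CASSETTE`` — add sites at ``anchor + offset`` for each
        (offset, orientation) pair of ``cassette``.
    """

    kind: str
    targets: tuple[str, ...] = ()
    interval: GenomicInterval | None = None
    cassette: tuple[tuple[int, Orientation], ...] = ()
    anchor: int | None = None
    label: str = ""

    KINDS = ("DELETE_CBS", "DELETE_INTERVAL", "INSERT_CBS_CASSETTE")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "DELETE_CBS" and not self.targets:
            raise ValueError("DELETE_CBS requires target site ids")
        if self.kind == "DELETE_INTERVAL" and self.interval is None:
            raise ValueError("DELETE_INTERVAL requires an interval")
        if self.kind == "INSERT_CBS_CASSETTE":
            if self.anchor is None or not self.cassette:
                raise ValueError("INSERT_CBS_CASSETTE requires anchor and cassette")
            offs = [o for o, _ in self.cassette]
            if any(b <= a for a, b in zip(offs, offs[1:])):
                raise ValueError("cassette offsets must be strictly increasing")


# ---------------------------------------------------------------------------
# Wild-type fixture
# ---------------------------------------------------------------------------

_CHROM = "chr2"
AXIS_START = 73_900_037
AXIS_END = 75_621_560
CLUSTER_START = 74_667_374
CLUSTER_END = 74_767_842
CS38_40 = (75_105_000, 75_190_000)

# gene name -> (start, end, domain)
_GENES = {
    "Hoxd1": (74_760_000, 74_763_000, ClusterDomain.ANTERIOR),
    "Hoxd3": (74_750_000, 74_754_000, ClusterDomain.ANTERIOR),
    "Hoxd4": (74_740_000, 74_743_000, ClusterDomain.ANTERIOR),
    "Hoxd8": (74_728_000, 74_731_000, ClusterDomain.CENTRAL),
    "Hoxd9": (74_716_000, 74_719_000, ClusterDomain.CENTRAL),
    "Hoxd10": (74_706_000, 74_709_000, ClusterDomain.CENTRAL),
    "Hoxd11": (74_694_000, 74_697_000, ClusterDomain.CENTRAL),
    "Hoxd12": (74_682_000, 74_685_000, ClusterDomain.POSTERIOR),
    "Hoxd13": (74_670_500, 74_673_500, ClusterDomain.POSTERIOR),
    "Evx2": (74_667_500, 74_669_000, ClusterDomain.POSTERIOR),
}

# site id -> (position, orientation)
_T = Orientation.TOWARD_TDOM
_C = Orientation.TOWARD_CDOM
_CBS = {
    "CBS1": (74_737_500, _T),  # between Hoxd4 and Hoxd8; first barrier
    "CBS2": (74_725_500, _T),  # between Hoxd8 and Hoxd9
    "CBS3": (74_714_000, _C),  # near Hoxd9; transparent to anterior-loaded cohesin
    "CBS4": (74_702_000, _T),  # between Hoxd10 and Hoxd11
    "CBS5": (74_690_000, _T),  # between Hoxd11 and Hoxd12
    "CBS6": (74_679_000, _C),
    "CBS7": (74_677_000, _C),
    "CBS8": (74_675_500, _C),
    "CBS9": (74_669_300, _C),
    # sub-TAD1 sites, convergent with the anterior cluster sites
    "TD-CBS1": (74_830_000, _C),
    "TD-CBS2": (74_910_000, _C),
    "TD-CBS3": (74_990_000, _C),
    "TD-CBS4": (75_060_000, _C),
    "TD-CBS5": (75_130_000, _C),  # inside CS38-40
}

DEFAULT_ENHANCER_ACTIVE_FROM = 96.0  # model-hours; acetylation of sub-TAD1

_REGIONS = [
    ("cluster", CLUSTER_START, CLUSTER_END, None),
    ("subTAD1", 74_770_000, 75_190_000, None),
    ("subTAD2", 75_190_000, AXIS_END, None),
    ("CS38_40", CS38_40[0], CS38_40[1], None),
    ("CDOM", AXIS_START, 74_660_000, None),
    # ~20-kb pre-looped element containing CBS1
    ("CBS1_element", 74_726_500, 74_746_500, None),
    # enhancer elements inside sub-TAD1, placed at the sub-TAD1 CBS/acetylated
    # hotspots; silent until sub-TAD1 acetylation
    ("E1", 74_826_000, 74_830_000, DEFAULT_ENHANCER_ACTIVE_FROM),
    ("E2", 74_906_000, 74_910_000, DEFAULT_ENHANCER_ACTIVE_FROM),
    ("E3", 75_056_000, 75_060_000, DEFAULT_ENHANCER_ACTIVE_FROM),
]


def build_default_hoxd_locus() -> LocusAnnotation:
    """The wild-type HoxD fixture (see module docstring for provenance)."""
    genes = tuple(
        Gene(n, GenomicInterval(_CHROM, s, e), d) for n, (s, e, d) in _GENES.items()
    )
    sites = tuple(
        CtcfSite(i, p, o) for i, (p, o) in sorted(_CBS.items(), key=lambda kv: kv[1][0])
    )
    regions = tuple(
        RegulatoryRegion(n, GenomicInterval(_CHROM, s, e), af)
        for n, s, e, af in _REGIONS
    )
    return LocusAnnotation(
        axis_interval=GenomicInterval(_CHROM, AXIS_START, AXIS_END),
        genes=genes,
        ctcf_sites=sites,
        regions=regions,
        genotype_label="wild_type",
    )


# ---------------------------------------------------------------------------
# BED loading
# ---------------------------------------------------------------------------

_DOMAIN_BY_NAME = {n: d for n, (_, _, d) in _GENES.items()}


def load_annotation(
    genes_source,
    cbs_source,
    regions_source=(),
    axis: GenomicInterval | None = None,
    genotype_label: str = "custom",
) -> LocusAnnotation:
    """Assemble an annotation from BED6 records.

    Each source is an iterable of BED6 tuples/lists
    ``(chrom, start, end, name, score, strand)`` (as produced by
    :func:`hoxtimer.io.read_bed`).  For CBS records, strand "+" maps to
    TOWARD_TDOM and "-" to TOWARD_CDOM; the site position is the interval
    midpoint.  Gene records carry the cluster domain in the score column
    ("anterior"/"central"/"posterior") or fall back to the default fixture's
    domain for known gene names.  Region records may carry an activation
    hour in the score column.
    """
    genes_source = list(genes_source)
    if not genes_source:
        raise ValueError("at least one gene required")
    if axis is None:
        axis = GenomicInterval(_CHROM, AXIS_START, AXIS_END)

    genes = []
    for rec in genes_source:
        chrom, start, end, name, score, _strand = _bed6(rec)
        domain = _parse_domain(score, name)
        genes.append(Gene(name, GenomicInterval(chrom, start, end), domain))

    sites = []
    for rec in cbs_source:
        chrom, start, end, name, _score, strand = _bed6(rec)
        if strand == "+":
            orient = Orientation.TOWARD_TDOM
        elif strand == "-":
            orient = Orientation.TOWARD_CDOM
        else:
            raise ValueError(f"CBS record {name!r}: strand must be '+' or '-'")
        sites.append(CtcfSite(name, (start + end) // 2, orient))
    sites.sort(key=lambda s: s.position)

    regions = []
    for rec in regions_source:
        chrom, start, end, name, score, _strand = _bed6(rec)
        active_from = None
        try:
            active_from = float(score)
        except (TypeError, ValueError):
            active_from = None
        if not name.startswith("E"):
            active_from = None
        regions.append(
            RegulatoryRegion(name, GenomicInterval(chrom, start, end), active_from)
        )

    return LocusAnnotation(
        axis_interval=axis,
        genes=tuple(genes),
        ctcf_sites=tuple(sites),
        regions=tuple(regions),
        genotype_label=genotype_label,
    )


def _bed6(rec):
    try:
        chrom, start, end, name, score, strand = (
            rec[0],
            int(rec[1]),
            int(rec[2]),
            str(rec[3]),
            rec[4],
            str(rec[5]),
        )
    except (IndexError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed BED6 record: {rec!r}") from exc
    return chrom, start, end, name, score, strand


def _parse_domain(score, name: str) -> ClusterDomain:
    if isinstance(score, str):
        try:
            return ClusterDomain(score.lower())
        except ValueError:
            pass
    if name in _DOMAIN_BY_NAME:
        return _DOMAIN_BY_NAME[name]
    raise ValueError(f"cannot determine cluster domain for gene {name!r}")


# ---------------------------------------------------------------------------
# Genotype editing
# ---------------------------------------------------------------------------


def apply_genotype(locus: LocusAnnotation, edits) -> LocusAnnotation:
    """Return a new annotation with ``edits`` applied in order.

    Pure: the input annotation is never modified.
    """
    current = locus
    for edit in edits:
        current = _apply_one(current, edit)
    return current


def _apply_one(locus: LocusAnnotation, edit: GenotypeEdit) -> LocusAnnotation:
    label = edit.label or edit.kind.lower()
    new_label = (
        label if locus.genotype_label == "wild_type" else f"{locus.genotype_label}+{label}"
    )
    if edit.kind == "DELETE_CBS":
        known = {s.id for s in locus.ctcf_sites}
        missing = [t for t in edit.targets if t not in known]
        if missing:
            raise KeyError(f"unknown CTCF site id(s): {missing}")
        sites = tuple(s for s in locus.ctcf_sites if s.id not in set(edit.targets))
        return replace(locus, ctcf_sites=sites, genotype_label=new_label)

    if edit.kind == "INSERT_CBS_CASSETTE":
        taken = {s.position for s in locus.ctcf_sites}
        new_sites = []
        for k, (off, orient) in enumerate(edit.cassette, start=1):
            pos = edit.anchor + off
            if pos in taken:
                raise ValueError(f"insertion at {pos} collides with an existing site")
            new_sites.append(CtcfSite(f"{label or 'ins'}_{k}", pos, orient))
        sites = tuple(sorted(locus.ctcf_sites + tuple(new_sites), key=lambda s: s.position))
        return replace(locus, ctcf_sites=sites, genotype_label=new_label)

    # DELETE_INTERVAL: drop features inside, shift features downstream
    iv = edit.interval
    shift = iv.length

    def _shift_pos(p: int) -> int | None:
        if p < iv.start:
            return p
        if p >= iv.end:
            return p - shift
        return None  # deleted

    def _shift_iv(g: GenomicInterval) -> GenomicInterval | None:
        s, e = _shift_pos(g.start), _shift_pos(g.end - 1)
        if s is None and e is None:
            return None
        if s is None:
            s = iv.start
        if e is None:
            e = iv.start - 1
        if s > e:
            return None
        return GenomicInterval(g.chrom, s, e + 1)

    genes = tuple(
        Gene(g.name, niv, g.cluster_domain)
        for g in locus.genes
        if (niv := _shift_iv(g.interval)) is not None
    )
    sites = tuple(
        CtcfSite(s.id, np_, s.orientation, s.occupied)
        for s in locus.ctcf_sites
        if (np_ := _shift_pos(s.position)) is not None
    )
    regions = tuple(
        RegulatoryRegion(r.name, niv, r.active_from)
        for r in locus.regions
        if (niv := _shift_iv(r.interval)) is not None
    )
    ax = locus.axis_interval
    new_axis = GenomicInterval(ax.chrom, ax.start, ax.end - shift)
    return replace(
        locus,
        axis_interval=new_axis,
        genes=genes,
        ctcf_sites=sites,
        regions=regions,
        genotype_label=new_label,
    )


def _del_cbs(label: str, *ids: str) -> tuple[GenotypeEdit, ...]:
    return (GenotypeEdit("DELETE_CBS", targets=tuple(ids), label=label),)


# The six engineered genotypes reproduced by the package.  The insertion
# models the published 900-bp two-site cassette placed 2 kb 5' of CBS1 (5' =
# lower coordinate on this axis), giving three TOWARD_TDOM sites between
# Hoxd4 and Hoxd8.
GENOTYPE_PRESETS: dict[str, tuple[GenotypeEdit, ...]] = {
    "wild_type": (),
    "del_cbs1": _del_cbs("del_cbs1", "CBS1"),
    "del_cbs2": _del_cbs("del_cbs2", "CBS2"),
    "del_cbs1_2": _del_cbs("del_cbs1_2", "CBS1", "CBS2"),
    "del_cbs4": _del_cbs("del_cbs4", "CBS4"),
    "del_cbs1_5": _del_cbs("del_cbs1_5", "CBS1", "CBS2", "CBS3", "CBS4", "CBS5"),
    "ins_2xcbs_d4d8": (
        GenotypeEdit(
            "INSERT_CBS_CASSETTE",
            anchor=_CBS["CBS1"][0],
            cassette=((-2_900, Orientation.TOWARD_TDOM), (-2_000, Orientation.TOWARD_TDOM)),
            label="ins_2xcbs_d4d8",
        ),
    ),
}


def genotype_edits(name: str) -> tuple[GenotypeEdit, ...]:
    try:
        return GENOTYPE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown genotype {name!r}; known: {sorted(GENOTYPE_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeMap:
    """Deterministic, invertible mapping of annotation features to lattice bins."""

    axis: Axis
    gene_bins: dict[str, tuple[int, int]] = field(default_factory=dict)  # inclusive
    cbs_bin: dict[str, int] = field(default_factory=dict)
    region_bins: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.axis.n_bins


def discretize(
    locus: LocusAnnotation, bin_size: int, merge_cbs: bool = True
) -> LatticeMap:
    """Map annotation features onto a lattice of ``bin_size``-bp bins.

    Two CTCF sites falling into the same bin raise a "CBS bin collision"
    error unless ``merge_cbs`` is enabled (the default), in which case both
    sites are kept and share the bin (the extrusion engine then stacks their
    blocking probabilities).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    ax_iv = locus.axis_interval
    n_bins = math.ceil(ax_iv.length / bin_size)
    axis = Axis(ax_iv.chrom, ax_iv.start, bin_size, n_bins)

    smallest_gene = min(g.interval.length for g in locus.genes)
    if bin_size > smallest_gene:
        logger.warning(
            "bin_size %d exceeds the smallest gene body (%d bp); per-gene "
            "bin ranges will be single bins",
            bin_size,
            smallest_gene,
        )

    gene_bins = {
        g.name: axis.bp_range_to_bins(g.interval.start, g.interval.end)
        for g in locus.genes
    }
    cbs_bin: dict[str, int] = {}
    seen: dict[int, str] = {}
    for s in locus.ctcf_sites:
        b = axis.bp_to_bin(s.position)
        if b in seen and not merge_cbs:
            raise ValueError(
                f"CBS bin collision: {s.id} and {seen[b]} share bin {b} "
                f"(enable the merge policy to allow this)"
            )
        seen.setdefault(b, s.id)
        cbs_bin[s.id] = b
    region_bins = {
        r.name: axis.bp_range_to_bins(r.interval.start, r.interval.end)
        for r in locus.regions
    }
    return LatticeMap(axis=axis, gene_bins=gene_bins, cbs_bin=cbs_bin, region_bins=region_bins)
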