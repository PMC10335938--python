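"""Plain-text genomic file formats and reproducibility plumbing.

bedGraph for tracks, BED6 for annotation features, dense or upper-triangle
triplet text for contact matrices, CSV for tables and JSON manifests for
run provenance.  All coordinates 0-based half-open; writers emit files the
package's own readers and standard genome browsers accept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Axis, ContactMap, Track

logger = logging.getLogger(__name__)

__all__ = [
    "read_track",
    "write_track",
    "read_map",
    "write_map",
    "read_trajectory",
    "write_trajectory",
    "read_bed",
    "write_bed",
    "write_manifest",
]


def write_track(path, track: Track) -> None:
    """Write a per-bin track as 4-column bedGraph at full float precision."""
    ax = track.axis
    with open(path, "w") as fh:
        for b, v in enumerate(track.values):
            start, end = ax.bin_interval(b)
            fh.write(f"{ax.chrom}\t{start}\t{end}\t{float(v)!r}\n")


def read_track(path, axis: Axis | None = None, name: str = "track") -> Track:
    """Read a bedGraph into a Track.

    Without ``axis``, the axis is inferred from the records (which must be
    contiguous fixed-width bins).  Overlapping intervals are an error;
    unsorted input is sorted with a warning.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start < 0:
                raise ValueError(f"{path}:{ln}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{ln}: empty interval [{start}, {end})")
            rows.append((chrom, start, end, value))
    if not rows:
        raise ValueError(f"{path}: no records")
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValueError(f"{path}: multiple chromosomes {sorted(chroms)}")
    srt = sorted(rows, key=lambda r: r[1])
    if srt != rows:
        logger.warning("%s: intervals were unsorted; sorting", path)
        rows = srt
    for a, b in zip(rows, rows[1:]):
        if b[1] < a[2]:
            raise ValueError(f"{path}: overlapping intervals at {b[1]}")
    widths = {r[2] - r[1] for r in rows}
    if axis is None:
        if len(widths) > 1:
            raise ValueError(f"{path}: variable bin widths {sorted(widths)}")
        bin_size = widths.pop()
        origin = rows[0][1]
        n_bins = (rows[-1][2] - origin) // bin_size
        axis = Axis(rows[0][0], origin, bin_size, n_bins)
    values = np.zeros(axis.n_bins)
    for chrom, start, end, value in rows:
        b = axis.bp_to_bin(start)
        values[b] = value
    return Track(axis, values, name=name)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------


def write_map(path, cmap: ContactMap, fmt: str = "triplet") -> None:
    """Write a contact map as dense text or upper-triangle triplets."""
    ax = cmap.axis
    if fmt == "dense":
        header = f"# chrom={ax.chrom} origin={ax.origin} bin_size={ax.bin_size} n_bins={ax.n_bins}\n"
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, cmap.matrix, fmt="%.17g")
    elif fmt == "triplet":
        with open(path, "w") as fh:
            fh.write(
                f"# chrom={ax.chrom} origin={ax.origin} bin_size={ax.bin_size} n_bins={ax.n_bins}\n"
            )
            n = ax.n_bins
            m = cmap.matrix
            for i in range(n):
                for j in range(i, n):
                    if m[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{float(m[i, j])!r}\n")
    else:
        raise ValueError(f"unknown map format {fmt!r}")


def _parse_map_header(line: str) -> Axis:
    if not line.startswith("#"):
        raise ValueError("missing map header line")
    kv = dict(item.split("=") for item in line[1:].split())
    return Axis(kv["chrom"], int(kv["origin"]), int(kv["bin_size"]), int(kv["n_bins"]))


def read_map(path, fmt: str = "triplet") -> ContactMap:
    """Read a contact map written by :func:`write_map`.

    Triplet input stores the upper triangle only; the reader symmetrizes.
    Asymmetric dense input is an error.
    """
    with open(path) as fh:
        header = fh.readline()
        axis = _parse_map_header(header)
        if fmt == "dense":
            mat = np.loadtxt(fh, ndmin=2)
            if mat.shape != (axis.n_bins, axis.n_bins):
                raise ValueError(f"dense matrix shape {mat.shape} != axis")
            if not np.allclose(mat, mat.T, rtol=1e-9, atol=1e-12):
                raise ValueError("asymmetric dense matrix")
        elif fmt == "triplet":
            mat = np.zeros((axis.n_bins, axis.n_bins))
            for ln, line in enumerate(fh, 2):
                line = line.strip()
                if not line:
                    continue
                i_s, j_s, v_s = line.split("\t")
                i, j, v = int(i_s), int(j_s), float(v_s)
                if j < i:
                    raise ValueError(f"{path}:{ln}: lower-triangle entry ({i},{j})")
                mat[i, j] = v
                mat[j, i] = v
        else:
            raise ValueError(f"unknown map format {fmt!r}")
    return ContactMap(axis, mat)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def write_trajectory(path, traj) -> None:
    """Compact columnar text: one row per extruder-snapshot.

    Columns: snapshot index, time (model-hours), left anchor bin, right
    anchor bin.  A header line carries the axis metadata.
    """
    ax = traj.axis
    with open(path, "w") as fh:
        fh.write(
            f"# chrom={ax.chrom} origin={ax.origin} bin_size={ax.bin_size} n_bins={ax.n_bins}\n"
        )
        for i, (t, lefts, rights) in enumerate(
            zip(traj.snapshot_times, traj.snapshot_left, traj.snapshot_right)
        ):
            if len(lefts) == 0:
                fh.write(f"{i}\t{float(t)!r}\t-\t-\n")  # keep empty snapshots
            for l, r in zip(lefts, rights):
                fh.write(f"{i}\t{float(t)!r}\t{l}\t{r}\n")


def read_trajectory(path):
    """Read a trajectory written by :func:`write_trajectory`."""
    from .extrusion import Trajectory

    with open(path) as fh:
        axis = _parse_map_header(fh.readline())
        times: list[float] = []
        lefts: list[list[int]] = []
        rights: list[list[int]] = []
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed trajectory row {line!r}")
            idx, t = int(parts[0]), float(parts[1])
            if idx == len(times):
                times.append(t)
                lefts.append([])
                rights.append([])
            elif idx != len(times) - 1:
                raise ValueError(f"{path}: snapshot indices out of order")
            if parts[2] != "-":
                lefts[idx].append(int(parts[2]))
                rights[idx].append(int(parts[3]))
    traj = Trajectory(
        axis=axis,
        snapshot_times=times,
        snapshot_left=[np.asarray(a, dtype=np.int64) for a in lefts],
        snapshot_right=[np.asarray(a, dtype=np.int64) for a in rights],
    )
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(path, records) -> None:
    """Write BED6 records: iterables (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for rec in records:
            chrom, start, end, name, score, strand = rec
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path):
    """Read BED6 records as (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns, got {len(parts)}")
            out.append(
                (parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5])
            )
    return out


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def write_manifest(path, config_doc: dict, seeds, outputs=(), extra=None) -> None:
    """Record everything needed to reproduce a run bit-identically."""
    from . import __version__

    blob = json.dumps(config_doc, sort_keys=True, default=str).encode()
    manifest = {
        "package": "hoxtimer",
        "version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config_doc,
        "seeds": list(map(int, seeds)),
        "outputs": [str(p) for p in outputs],
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def config_to_doc(cfg) -> dict:
    """RunConfig -> plain dict (manifest/serialization form)."""
    return {
        "locus": {
            "genotype": cfg.genotype,
            "genes_bed": cfg.genes_bed,
            "cbs_bed": cfg.cbs_bed,
            "regions_bed": cfg.regions_bed,
        },
        "sim": dataclasses.asdict(cfg.sim),
        "timer": dataclasses.asdict(cfg.timer),
        "output": {
            "out_dir": cfg.out_dir,
            "snapshot_every": cfg.snapshot_every,
            "t_start": cfg.t_start,
            "t_end": cfg.t_end,
        },
        "seeds": list(cfg.seeds),
    }
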