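"""Statistics on cytological crossover-focus data.

Works on per-nucleus tables of COSA-1-style focus positions traced along
the chromosome axis (in μm), with each chromosome classified by synapsis
morphology (fully zipped, forked, or unpaired).  Provides the focus-merging
rule for closely spaced signals, normalization onto a standard-length
chromosome divided into equal bins, random focus-pairing nulls for
interval-difference statistics, fork-junction proximity counts, and
per-nucleus/per-chromosome focus-count summaries.

Note on fork proximity: distances are measured in 1-D along the traced
axis, the reproducible desk-scale analogue of the 3-D imaging measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeFoci",
    "FociNucleus",
    "CytologyConfig",
    "merge_close_foci",
    "bin_standard_position",
    "normalize_and_bin",
    "focus_pair_null",
    "fork_proximity",
    "ForkProximity",
    "foci_count_summary",
    "FociSummary",
]

MORPHOLOGIES = ("zipped", "forked", "unpaired")


@dataclass
class ChromosomeFoci:
    """Foci traced along one chromosome of one nucleus."""

    morphology: str
    positions_um: np.ndarray
    traced_length_um: float
    junctions_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.junctions_um = np.asarray(self.junctions_um, dtype=float)
        if self.traced_length_um <= 0:
            raise ValueError("traced_length_um must be positive")
        pos = self.positions_um
        if pos.size and (pos.min() < 0 or pos.max() > self.traced_length_um):
            raise ValueError("focus positions outside [0, traced_length_um]")
        if self.junctions_um.size and self.morphology != "forked":
            raise ValueError("fork junctions only apply to forked chromosomes")

    @property
    def n_foci(self) -> int:
        return int(self.positions_um.size)


@dataclass
class FociNucleus:
    """Per-chromosome focus tracing for a single nucleus."""

    nucleus: str
    chromosomes: dict[str, ChromosomeFoci]

    @property
    def total_foci(self) -> int:
        return sum(cf.n_foci for cf in self.chromosomes.values())


@dataclass(frozen=True)
class CytologyConfig:
    standard_length_um: float = 7.0
    n_bins: int = 6
    merge_threshold_um: float = 0.3
    junction_radius_um: float = 1.0

    def __post_init__(self) -> None:
        if min(self.standard_length_um, self.merge_threshold_um, self.junction_radius_um) <= 0:
            raise ValueError("lengths and radii must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def merge_close_foci(positions: Sequence[float] | np.ndarray, threshold: float) -> np.ndarray:
    """Merge foci chained by gaps below ``threshold`` into single foci.

    Single-linkage and transitive: any sequence of foci in which each
    consecutive gap is < threshold collapses to one focus at the cluster
    mean.  Input must be sorted ascending.  Idempotent whenever cluster
    means remain separated by >= threshold (guaranteed for pairs, and in
    practice for sparse focus data).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return pos.copy()
    if (pos < 0).any():
        raise ValueError("negative focus positions")
    if not np.all(np.diff(pos) >= 0):
        raise ValueError("positions must be sorted ascending")
    breaks = np.flatnonzero(np.diff(pos) >= threshold) + 1
    clusters = np.split(pos, breaks)
    return np.array([c.mean() for c in clusters])


def bin_standard_position(
    positions: Sequence[float] | np.ndarray,
    traced_length_um: float,
    cfg: CytologyConfig | None = None,
) -> np.ndarray:
    """Bin indices on the standard chromosome for traced positions.

    Positions are rescaled to the standard length, bins are half-open, and
    a position exactly at the traced end falls in the last bin.
    """
    cfg = cfg or CytologyConfig()
    if traced_length_um <= 0:
        raise ValueError("traced length must be positive")
    pos = np.asarray(positions, dtype=float)
    if pos.size and (pos.min() < 0 or pos.max() > traced_length_um):
        raise ValueError("position outside traced chromosome")
    bins = np.floor(cfg.n_bins * pos / traced_length_um).astype(int)
    return np.minimum(bins, cfg.n_bins - 1)


def normalize_and_bin(
    nucleus: FociNucleus, cfg: CytologyConfig | None = None
) -> dict[str, np.ndarray]:
    """Per-chromosome bin indices for every focus of a nucleus."""
    cfg = cfg or CytologyConfig()
    return {
        chrom: bin_standard_position(cf.positions_um, cf.traced_length_um, cfg)
        for chrom, cf in nucleus.chromosomes.items()
    }


def focus_pair_null(
    bins: Sequence[int] | np.ndarray,
    n_pairs: int = 24,
    seed: int | None = None,
) -> np.ndarray:
    """Random focus-pairing null for the interval-difference statistic.

    Draws ``n_pairs`` pairs of two distinct foci from the pool (uniformly,
    without replacement within a pair, order randomized) and records
    (bin of 2nd focus) - (bin of 1st focus), sign retained.
    """
    pool = np.asarray(bins, dtype=int)
    if pool.size < 2:
        raise ValueError("focus pool must contain at least 2 foci")
    rng = np.random.default_rng(seed)
    idx = np.array([rng.choice(pool.size, size=2, replace=False) for _ in range(n_pairs)])
    return pool[idx[:, 1]] - pool[idx[:, 0]]


@dataclass(frozen=True)
class ForkProximity:
    n_foci_near: int
    n_foci_total: int
    fraction: float
    n_junctions_with_focus: int
    n_junctions: int


def fork_proximity(
    foci_positions: Sequence[float] | np.ndarray,
    junctions: Sequence[float] | np.ndarray,
    radius: float = 1.0,
) -> ForkProximity:
    """Count foci near fork junctions (and junctions with a nearby focus).

    A focus is "near" a junction when its 1-D distance along the traced
    axis to the closest junction is < ``radius``.
    """
    foci = np.asarray(foci_positions, dtype=float)
    junc = np.asarray(junctions, dtype=float)
    if junc.size == 0 or foci.size == 0:
        return ForkProximity(0, int(foci.size), 0.0, 0, int(junc.size))
    dist = np.abs(foci[:, None] - junc[None, :])
    near_focus = (dist.min(axis=1) < radius)
    junction_hit = (dist.min(axis=0) < radius)
    return ForkProximity(
        n_foci_near=int(near_focus.sum()),
        n_foci_total=int(foci.size),
        fraction=float(near_focus.mean()),
        n_junctions_with_focus=int(junction_hit.sum()),
        n_junctions=int(junc.size),
    )


@dataclass
class FociSummary:
    mean_per_nucleus: float
    sd_per_nucleus: float
    per_nucleus_counts: np.ndarray
    per_chromosome_histogram: pd.DataFrame  # rows: morphology, cols: focus count


def foci_count_summary(
    nuclei: Iterable[FociNucleus], by_morphology: bool = True
) -> FociSummary:
    """Mean +/- SD foci per nucleus and per-chromosome count histograms.

    The histogram stratifies per-chromosome focus counts by synapsis
    morphology when ``by_morphology`` is set (a single ``all`` row
    otherwise).  SD is the population SD over nuclei.
    """
    nuclei = list(nuclei)
    if not nuclei:
        raise ValueError("need at least one nucleus")
    counts = np.array([nuc.total_foci for nuc in nuclei])
    rows: dict[str, dict[int, int]] = {}
    for nuc in nuclei:
        for cf in nuc.chromosomes.values():
            key = cf.morphology if by_morphology else "all"
            rows.setdefault(key, {})
            rows[key][cf.n_foci] = rows[key].get(cf.n_foci, 0) + 1
    max_count = max((k for r in rows.values() for k in r), default=0)
    hist = pd.DataFrame(
        0, index=sorted(rows), columns=range(max_count + 1), dtype=int
    )
    for morph, r in rows.items():
        for k, v in r.items():
            hist.loc[morph, k] = v
    return FociSummary(
        mean_per_nucleus=float(counts.mean()),
        sd_per_nucleus=float(counts.std()),
        per_nucleus_counts=counts,
        per_chromosome_histogram=hist,
    )
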