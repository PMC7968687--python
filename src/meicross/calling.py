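"""Crossover breakpoint calling from backcross genotype vectors.

In a backcross design (F1 hybrid crossed to the recurrent parent), each F2
genotype vector along a chromosome directly reads out one transmitted F1
gamete: heterozygous markers trace the donor (Bristol) haplotype and
homozygous-recurrent markers the Hawaiian haplotype.  A crossover appears as
a switch between maximal runs of consistent genotype.

The caller formalizes the run-based decision rule — a switch must be
backed by enough exchanged SNPs in a row, and stray discordant markers are
absorbed as genotyping background — as an exact dynamic program: among all
segmentations whose segments each contain a support window of at least
``min_run`` concordant informative markers (interruptions of at most
``max_background`` discordant markers tolerated), it returns the one with
the fewest discordant markers, breaking ties by fewest segments and then
by the leftmost switch positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOM_RECURRENT",
    "HET",
    "MISSING",
    "GenotypeMatrix",
    "CallerParams",
    "CrossoverEvent",
    "Segment",
    "segment_genotype_vector",
    "call_crossovers",
    "classify_chromosomes",
]

# Genotype call codes.
HOM_RECURRENT = 0
HET = 1
MISSING = -1


@dataclass
class GenotypeMatrix:
    """F2 individuals x ordered biallelic markers, backcross genotype calls.

    ``calls[chrom]`` is an ``(n_individuals, n_markers)`` int8 array with
    values ``HOM_RECURRENT`` (0), ``HET`` (1) or ``MISSING`` (-1);
    ``positions[chrom]`` holds the matching bp coordinates, strictly
    increasing.
    """

    individuals: list[str]
    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        for chrom in self.positions:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            if pos.ndim != 1 or (len(pos) > 1 and not np.all(np.diff(pos) > 0)):
                raise ValueError(f"{chrom}: marker positions must be strictly increasing")
            self.positions[chrom] = pos
            c = np.asarray(self.calls[chrom], dtype=np.int8)
            if c.shape != (len(self.individuals), len(pos)):
                raise ValueError(
                    f"{chrom}: calls shape {c.shape} does not match "
                    f"({len(self.individuals)}, {len(pos)})"
                )
            bad = ~np.isin(c, (HOM_RECURRENT, HET, MISSING))
            if bad.any():
                raise ValueError(f"{chrom}: invalid call codes {np.unique(c[bad])}")
            self.calls[chrom] = c

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def vector(self, individual: str, chrom: str) -> np.ndarray:
        return self.calls[chrom][self.individuals.index(individual)]

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.individuals != other.individuals or self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self.positions[c], other.positions[c])
            and np.array_equal(self.calls[c], other.calls[c])
            for c in self.positions
        )


@dataclass(frozen=True)
class CallerParams:
    """Decision thresholds for accepting a genotype switch.

    ``min_run`` — informative concordant markers required to support a
    segment; ``max_background`` — longest run of discordant markers absorbed
    into a segment as genotyping noise.
    """

    min_run: int = 5
    max_background: int = 1

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.max_background < 0:
            raise ValueError("max_background must be >= 0")
        if self.min_run <= self.max_background:
            raise ValueError("min_run must exceed max_background")


@dataclass(frozen=True)
class CrossoverEvent:
    """One inferred breakpoint on one chromosome of one individual.

    The breakpoint is localized to the interval between the last marker of
    the preceding segment (``left_bp``) and the first marker of the
    following segment (``right_bp``), 0-based half-open.  When several
    boundary placements tie in discordance, the interval spans all of them
    (earliest left flank to latest right flank).
    """

    individual: str
    chromosome: str
    left_bp: int
    right_bp: int

    def __post_init__(self) -> None:
        if not self.left_bp < self.right_bp:
            raise ValueError("require left_bp < right_bp")

    @property
    def midpoint_bp(self) -> float:
        return (self.left_bp + self.right_bp) / 2


class Segment(NamedTuple):
    """Maximal consistent-genotype segment over original marker indices."""

    genotype: int
    first_index: int
    last_index: int


_INF = (1 << 30, 1 << 30)


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Collapse a 0/1 vector into runs of (value, start, length)."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    return [(int(values[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def segment_genotype_vector(
    vector: Sequence[int] | np.ndarray,
    params: CallerParams,
    tie_break: str = "leftmost",
) -> list[Segment]:
    """Segment one genotype vector into consistent-genotype blocks.

    A segmentation assigns maximal blocks of informative markers to
    alternating genotypes.  A block is *supported* when it contains a
    window with at least ``min_run`` concordant markers in which every
    interruption by discordant markers is at most ``max_background`` long;
    unsupported blocks are not allowed, so a genotype switch must be backed
    by at least ``min_run`` markers "in a row" (up to tolerated background).
    Discordant markers anywhere inside a block are absorbed as genotyping
    background at a cost of one each; among valid segmentations the caller
    returns the one minimizing total discordant markers, breaking ties by
    fewest segments and then by ``tie_break`` ("leftmost" or "rightmost")
    switch positions.  Missing calls are transparent: they neither support
    nor break a block.

    An all-missing vector yields an empty segmentation (with a warning); a
    vector on which no genotype ever achieves a support window falls back
    to a single majority-genotype segment, also with a warning.
    """
    calls = np.asarray(vector, dtype=np.int8)
    if calls.size == 0:
        raise ValueError("empty genotype vector")
    informative = np.flatnonzero(calls != MISSING)
    if informative.size == 0:
        warnings.warn("all-missing genotype vector: empty segmentation")
        return []
    v = calls[informative].astype(np.int64)
    runs = _runs(v)
    R, B = params.min_run, params.max_background

    # Backward DP over runs.  State (g, s, c, t): segment genotype g,
    # s = segment already supported, c = concordant markers in the current
    # support window (capped at R; 0 once supported), t = trailing
    # discordant run length capped at B + 1 (> B breaks the window).
    # Cost = (discordant markers, segments after the first).
    n = len(runs)
    TCAP = B + 1

    def step(state, val, L):
        """Successor state and marker cost for consuming a run in-segment."""
        g, s, c, t = state
        if val == g:
            if s:
                return (g, 1, 0, 0), 0
            c2 = min((c if t <= B else 0) + L, R)
            if c2 >= R:
                return (g, 1, 0, 0), 0
            return (g, 0, c2, 0), 0
        t2 = min(t + L, TCAP)
        return (g, s, (c if t2 <= B else 0), t2), L

    def switch_state(val, L):
        if L >= R:
            return (val, 1, 0, 0)
        return (val, 0, min(L, R), 0)

    J: list[dict, ...] = [dict() for _ in range(n + 1)]
    for g in (0, 1):
        for t in range(TCAP + 1):
            J[n][(g, 1, 0, t)] = (0, 0)  # accept: segment supported, trailing noise absorbed
    for i in range(n - 1, -1, -1):
        val, _start, L = runs[i]
        nxt = J[i + 1]
        cur = J[i]
        states = set(nxt)
        # enumerate all predecessor states exhaustively (small space)
        for g in (0, 1):
            for s in (0, 1):
                for c in range(R + 1) if s == 0 else (0,):
                    for t in range(TCAP + 1):
                        state = (g, s, c, t)
                        best = _INF
                        succ, cost = step(state, val, L)
                        after = nxt.get(succ)
                        if after is not None:
                            best = min(best, (after[0] + cost, after[1]))
                        if s == 1 and t == 0 and val != g:
                            after = nxt.get(switch_state(val, L))
                            if after is not None:
                                best = min(best, (after[0], after[1] + 1))
                        if best != _INF:
                            cur[state] = best

    first_val = runs[0][0]
    starts = {g: J[0].get((g, 0, 0, 0)) for g in (0, 1)}
    feasible = {g: cost for g, cost in starts.items() if cost is not None}
    if not feasible:
        maj = int(np.bincount(v, minlength=2).argmax())
        warnings.warn(
            "no valid segmentation under caller thresholds; "
            "falling back to a single majority-genotype segment"
        )
        return [Segment(maj, int(informative[0]), int(informative[-1]))]
    if tie_break not in ("leftmost", "rightmost"):
        raise ValueError("tie_break must be 'leftmost' or 'rightmost'")
    g0 = min(feasible, key=lambda g: (feasible[g], g != first_val))

    # Forward reconstruction.  "leftmost" switches as early as optimality
    # allows, "rightmost" as late; both traverse the same optimal cost.
    prefer_switch = tie_break == "leftmost"
    boundaries = [0]  # run indices starting a new segment
    genotypes = [g0]
    state = (g0, 0, 0, 0)
    cost_left = feasible[g0]
    for i in range(n):
        val, _start, L = runs[i]
        g, s, c, t = state
        switch_ok = False
        if val != g and s == 1 and t == 0:
            after = J[i + 1].get(switch_state(val, L))
            switch_ok = after is not None and (after[0], after[1] + 1) == cost_left
        continue_ok = False
        if not (switch_ok and prefer_switch):
            succ, cost = step(state, val, L)
            nxt = J[i + 1].get(succ)
            continue_ok = nxt is not None and (nxt[0] + cost, nxt[1]) == cost_left
        if switch_ok and (prefer_switch or not continue_ok):
            boundaries.append(i)
            genotypes.append(val)
            state = switch_state(val, L)
            cost_left = after
        else:
            state, cost = step(state, val, L)
            cost_left = (cost_left[0] - cost, cost_left[1])
    segments: list[Segment] = []
    bounds = boundaries + [n]
    for k in range(len(boundaries)):
        first_run, last_run = bounds[k], bounds[k + 1] - 1
        first_inf = runs[first_run][1]
        last_inf = runs[last_run][1] + runs[last_run][2] - 1
        segments.append(
            Segment(genotypes[k], int(informative[first_inf]), int(informative[last_inf]))
        )
    return segments


def call_crossovers(gm: GenotypeMatrix, params: CallerParams | None = None) -> list[CrossoverEvent]:
    """Call crossover breakpoints for every individual and chromosome.

    One event per accepted segment boundary, carrying flanking-marker
    coordinates.  Chromosomes with fewer than ``min_run`` informative
    markers for an individual yield no calls (warning).
    """
    params = params or CallerParams()
    events: list[CrossoverEvent] = []
    for chrom in gm.chromosomes:
        pos = gm.positions[chrom]
        mat = gm.calls[chrom]
        for i, ind in enumerate(gm.individuals):
            vector = mat[i]
            n_inf = int(np.count_nonzero(vector != MISSING))
            if n_inf < params.min_run:
                warnings.warn(
                    f"{ind}/{chrom}: only {n_inf} informative markers "
                    f"(< min_run={params.min_run}); no calls"
                )
                continue
            left_segs = segment_genotype_vector(vector, params, tie_break="leftmost")
            if len(left_segs) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                right_segs = segment_genotype_vector(vector, params, tie_break="rightmost")
            # breakpoint interval spans every minimum-cost boundary
            # placement: earliest left flank to latest right flank
            for a, b in zip(left_segs, right_segs[1:]):
                events.append(
                    CrossoverEvent(
                        individual=ind,
                        chromosome=chrom,
                        left_bp=int(pos[a.last_index]),
                        right_bp=int(pos[b.first_index]),
                    )
                )
    return events


def classify_chromosomes(
    events: Iterable[CrossoverEvent],
    n_individuals: int,
    chromosomes: Sequence[str],
) -> pd.DataFrame:
    """Per-chromosome census of 0-CO, 1-CO and 2+-CO chromosomes.

    Rows are chromosomes, columns ``zero``/``one``/``two_plus``; each row
    sums to ``n_individuals``.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        if ev.chromosome not in chromosomes:
            raise ValueError(f"event on unknown chromosome {ev.chromosome!r}")
        counts[(ev.individual, ev.chromosome)] = counts.get((ev.individual, ev.chromosome), 0) + 1
    census = pd.DataFrame(
        0, index=list(chromosomes), columns=["zero", "one", "two_plus"], dtype=int
    )
    for (_, chrom), k in counts.items():
        census.loc[chrom, "one" if k == 1 else "two_plus"] += 1
    census["zero"] = n_individuals - census["one"] - census["two_plus"]
    if (census["zero"] < 0).any():
        raise ValueError("more individuals with events than n_individuals")
    return census
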