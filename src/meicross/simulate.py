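"""Forward simulation of meiotic crossover formation and its readouts.

The generative model, per meiosis and per chromosome (bivalent):

1. A synapsis morphology is drawn — fully ``zipped``, ``forked`` (partially
   zipped, anchored at the pairing-center end where synapsis initiates), or
   ``unpaired``.  Unpaired chromosomes form no crossovers; forked
   chromosomes restrict crossovers to the zipped segment.
2. Crossover (CO) number and positions on the bivalent come from one of
   three models: ``obligate_one`` (exactly one CO, the wild-type regime),
   ``poisson`` (no interference), or ``gamma_renewal`` (a stationary
   gamma-renewal point process on the genetic scale whose shape ``nu`` > 1
   widens inter-CO spacing, i.e. encodes interference; ``nu`` = 1 recovers
   Poisson).  An arm/center placement-weight density reshapes positions via
   an inverse-CDF transform.
3. Each bivalent CO involves two of the four chromatids; with no chromatid
   interference, each CO lands on the single transmitted chromatid
   independently with probability 1/2.  A bivalent with two COs therefore
   transmits both on one chromatid only a quarter of the time.

Downstream readouts are simulated from the same truth: backcross genotype
matrices with genotyping error and missing data, per-nucleus cytological
focus tables (one focus per bivalent CO), diakinesis DAPI-body counts, and
X-ray dose-response focus counts under a Poisson break-induction model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calling import HET, HOM_RECURRENT, MISSING, GenotypeMatrix
from .chromosomes import ChromosomeSpec, default_chromosomes
from .cytology import ChromosomeFoci, FociNucleus

__all__ = [
    "MeiosisModelParams",
    "BivalentOutcome",
    "GameteHaplotype",
    "DoseResponse",
    "wildtype_params",
    "mutant_params",
    "simulate_meiosis",
    "transmit_bivalent",
    "simulate_backcross_genotypes",
    "random_marker_map",
    "simulate_foci",
    "simulate_dose_response",
    "dapi_body_count",
]

CO_MODELS = ("obligate_one", "gamma_renewal", "poisson")
MORPH_NAMES = ("zipped", "forked", "unpaired")


@dataclass(frozen=True)
class MeiosisModelParams:
    """Free parameters of the meiosis simulator.

    Parameters
    ----------
    zipping_probs
        Per-chromosome ``(P(zipped), P(forked), P(unpaired))``; either one
        triple applied to every chromosome or a mapping by chromosome name.
    forked_zipped_fraction
        Fraction of chromosome length that is zipped on forked chromosomes
        (anchored at the pairing-center end).
    co_model
        ``obligate_one`` | ``gamma_renewal`` | ``poisson``.
    co_rate
        Expected bivalent COs per fully zipped chromosome.
    interference_nu
        Gamma-renewal shape; 1 = no interference, larger = stronger.
    placement_weights
        Relative CO density for the ``arm`` and ``center`` domains.
    genotyping_error_rate, missing_rate
        Per-marker probabilities applied when genotyping gametes.
    unpaired_focus_rate
        Mean SC-associated foci per unpaired chromosome (models regimes in
        which unpaired chromosomes recruit crossover-factor foci).
    """

    zipping_probs: tuple[float, float, float] | Mapping[str, tuple[float, float, float]] = (
        1.0,
        0.0,
        0.0,
    )
    forked_zipped_fraction: float = 0.5
    co_model: str = "obligate_one"
    co_rate: float = 1.0
    interference_nu: float = 1.0
    placement_weights: Mapping[str, float] = field(
        default_factory=lambda: {"arm": 1.0, "center": 1.0}
    )
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    unpaired_focus_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.co_model not in CO_MODELS:
            raise ValueError(f"co_model must be one of {CO_MODELS}")
        if self.interference_nu < 1:
            raise ValueError("interference_nu must be >= 1 (1 = no interference)")
        if not 0 < self.forked_zipped_fraction <= 1:
            raise ValueError("forked_zipped_fraction must be in (0, 1]")
        if self.co_rate < 0:
            raise ValueError("co_rate must be >= 0")
        for name in ("genotyping_error_rate", "missing_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.unpaired_focus_rate < 0:
            raise ValueError("unpaired_focus_rate must be >= 0")
        if any(w < 0 for w in self.placement_weights.values()):
            raise ValueError("placement_weights must be >= 0")
        if sum(self.placement_weights.values()) <= 0:
            raise ValueError("placement_weights must not all be zero")
        probs = self.zipping_probs
        triples = probs.values() if isinstance(probs, Mapping) else [probs]
        for p in triples:
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,) or (arr < 0).any() or (arr > 1).any():
                raise ValueError("zipping probabilities must be three values in [0, 1]")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError("zipping probabilities must sum to 1")

    def zipping_for(self, chrom: str) -> np.ndarray:
        if isinstance(self.zipping_probs, Mapping):
            return np.asarray(self.zipping_probs[chrom], dtype=float)
        return np.asarray(self.zipping_probs, dtype=float)


def wildtype_params(seed: int = 0) -> MeiosisModelParams:
    """Wild-type regime: every chromosome fully synapsed, one obligate CO."""
    return MeiosisModelParams(
        zipping_probs=(1.0, 0.0, 0.0), co_model="obligate_one", seed=seed
    )


def mutant_params(seed: int = 0) -> MeiosisModelParams:
    """Synapsis-compromised regime with residual interference.

    Emulates a partially synapsed mutant: variable per-chromosome zipping
    success (transmitted recombinant fractions span roughly 0.3-0.5),
    forked and unpaired chromosomes, multiple COs per zipped bivalent with
    weakened interference (gamma shape 4, ~6% of transmitted chromatids
    carrying double crossovers), a crossover landscape skewed toward the
    chromosome center, and realistic genotyping noise.
    """
    zip_success = {"I": 0.35, "II": 1.0, "III": 0.60, "IV": 0.70, "V": 0.80, "X": 0.90}
    probs = {
        chrom: (z, round(0.75 * (1 - z), 10), round(0.25 * (1 - z), 10))
        for chrom, z in zip_success.items()
    }
    return MeiosisModelParams(
        zipping_probs=probs,
        forked_zipped_fraction=0.5,
        co_model="gamma_renewal",
        co_rate=1.2,
        interference_nu=4.0,
        placement_weights={"arm": 1.0, "center": 2.5},
        genotyping_error_rate=0.002,
        missing_rate=0.02,
        seed=seed,
    )


@dataclass(frozen=True)
class BivalentOutcome:
    """Morphology and bivalent-level CO positions for one chromosome."""

    chromosome: str
    morphology: str
    bivalent_co_positions_bp: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.morphology not in MORPH_NAMES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        pos = self.bivalent_co_positions_bp
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("CO positions must be strictly increasing")
        if self.morphology == "unpaired" and pos:
            raise ValueError("unpaired chromosomes cannot carry COs")


@dataclass(frozen=True)
class GameteHaplotype:
    """COs inherited by the transmitted chromatid of one chromosome."""

    chromosome: str
    transmitted_co_positions_bp: tuple[float, ...]
    start_parent: str  # 'bristol' | 'hawaiian' at position 0

    def __post_init__(self) -> None:
        if self.start_parent not in ("bristol", "hawaiian"):
            raise ValueError("start_parent must be 'bristol' or 'hawaiian'")


@dataclass
class DoseResponse:
    """Per-dose lists of per-nucleus focus counts."""

    doses_rads: list[float]
    foci_counts: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.doses_rads) != len(self.foci_counts):
            raise ValueError("doses and count lists must align")
        if any(d < 0 for d in self.doses_rads):
            raise ValueError("negative dose")
        self.foci_counts = [np.asarray(c, dtype=int) for c in self.foci_counts]
        if any(c.size and c.min() < 0 for c in self.foci_counts):
            raise ValueError("negative focus counts")

    def means(self) -> np.ndarray:
        return np.array([c.mean() if c.size else np.nan for c in self.foci_counts])


# ---------------------------------------------------------------------------
# placement density and renewal process


def _placement_cdf(
    spec: ChromosomeSpec, weights: Mapping[str, float], lo: float, hi: float
):
    """Piecewise-linear CDF of the placement density restricted to [lo, hi).

    Returns (breaks, cum) where cum[i] is the cumulative weight-mass at
    breaks[i], normalized to 1 at hi, plus the unnormalized mass.
    """
    wa, wc = weights.get("arm", 1.0), weights.get("center", 1.0)
    edges = [0.0, float(spec.center_start_bp), float(spec.center_end_bp), float(spec.length_bp)]
    dens = [wa, wc, wa]
    breaks = [lo]
    cum = [0.0]
    for (a, b), w in zip(zip(edges, edges[1:]), dens):
        s, e = max(a, lo), min(b, hi)
        if e > s:
            breaks.append(e)
            cum.append(cum[-1] + w * (e - s))
    mass = cum[-1]
    if mass <= 0:
        raise ValueError(f"{spec.name}: placement density has zero mass on eligible region")
    return np.asarray(breaks), np.asarray(cum) / mass, mass


def _inv_cdf(u: np.ndarray, breaks: np.ndarray, cum: np.ndarray) -> np.ndarray:
    """Map uniform/genetic-scale values in [0,1) to physical positions."""
    return np.interp(u, cum, breaks)


def _stationary_gamma_renewal(rng: np.random.Generator, rate: float, nu: float) -> np.ndarray:
    """Event locations in [0, 1) of a stationary gamma-renewal process.

    Intensity ``rate`` events per unit length; inter-event gaps are
    Gamma(nu, scale=1/(nu*rate)).  The first event uses the equilibrium
    (forward-recurrence) delay, sampled as U * L with L drawn from the
    length-biased gap distribution Gamma(nu + 1, same scale).
    """
    if rate <= 0:
        return np.empty(0)
    scale = 1.0 / (nu * rate)
    points = []
    x = rng.uniform() * rng.gamma(nu + 1.0, scale)
    while x < 1.0:
        points.append(x)
        x += rng.gamma(nu, scale)
    return np.asarray(points)


def _eligible_interval(spec: ChromosomeSpec, morphology: str, frac: float) -> tuple[float, float]:
    if morphology == "zipped":
        return 0.0, float(spec.length_bp)
    if morphology == "forked":
        z = frac * spec.length_bp
        return (0.0, z) if spec.pc_end == "left" else (spec.length_bp - z, float(spec.length_bp))
    raise ValueError(morphology)


def _draw_bivalent_cos(
    rng: np.random.Generator,
    params: MeiosisModelParams,
    spec: ChromosomeSpec,
    morphology: str,
) -> np.ndarray:
    """Bivalent CO positions (bp, sorted) for one chromosome."""
    if morphology == "unpaired":
        return np.empty(0)
    lo, hi = _eligible_interval(spec, morphology, params.forked_zipped_fraction)
    breaks, cum, mass = _placement_cdf(spec, params.placement_weights, lo, hi)
    _, _, total_mass = _placement_cdf(spec, params.placement_weights, 0.0, float(spec.length_bp))
    rate = params.co_rate * mass / total_mass
    if params.co_model == "obligate_one":
        u = rng.uniform(size=1)
    elif params.co_model == "poisson":
        n = rng.poisson(rate)
        u = np.sort(rng.uniform(size=n))
    else:  # gamma_renewal on the genetic scale of the eligible region
        u = _stationary_gamma_renewal(rng, rate, params.interference_nu)
    return np.sort(_inv_cdf(u, breaks, cum))


def transmit_bivalent(
    positions_bp: Sequence[float] | np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """Thin bivalent COs onto the transmitted chromatid.

    Each CO involves two of the four chromatids; with no chromatid
    interference the transmitted chromatid carries each CO independently
    with probability 1/2.  Also draws the parental identity of the
    chromatid start (Bristol or Hawaiian, equally likely).
    """
    pos = np.asarray(positions_bp, dtype=float)
    keep = rng.random(pos.size) < 0.5
    start = "bristol" if rng.random() < 0.5 else "hawaiian"
    return pos[keep], start


def simulate_meiosis(
    params: MeiosisModelParams,
    specs: Sequence[ChromosomeSpec] | None = None,
    n_individuals: int = 1,
    seed: int | None = None,
) -> list[list[tuple[BivalentOutcome, GameteHaplotype]]]:
    """Simulate meioses: per individual, one (bivalent, gamete) per chromosome."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    specs = list(specs) if specs is not None else default_chromosomes()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out: list[list[tuple[BivalentOutcome, GameteHaplotype]]] = []
    morph_draws = {
        spec.name: rng.choice(3, size=n_individuals, p=params.zipping_for(spec.name))
        for spec in specs
    }
    for i in range(n_individuals):
        row = []
        for spec in specs:
            morphology = MORPH_NAMES[morph_draws[spec.name][i]]
            biv_pos = _draw_bivalent_cos(rng, params, spec, morphology)
            trans_pos, start = transmit_bivalent(biv_pos, rng)
            row.append(
                (
                    BivalentOutcome(spec.name, morphology, tuple(biv_pos)),
                    GameteHaplotype(spec.name, tuple(trans_pos), start),
                )
            )
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# genotyping


def random_marker_map(
    specs: Sequence[ChromosomeSpec],
    markers_per_chromosome: int,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Random sorted SNP marker positions per chromosome."""
    rng = np.random.default_rng(seed)
    out = {}
    for spec in specs:
        pos = np.sort(
            rng.choice(spec.length_bp, size=markers_per_chromosome, replace=False)
        ).astype(np.int64)
        out[spec.name] = pos
    return out


def simulate_backcross_genotypes(
    gametes: Sequence[Sequence[GameteHaplotype]],
    marker_map: Mapping[str, np.ndarray],
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
    specs: Sequence[ChromosomeSpec] | None = None,
) -> GenotypeMatrix:
    """Genotype transmitted haplotypes at a marker map (backcross design).

    A marker is heterozygous where the transmitted haplotype carries the
    Bristol (donor) parent, homozygous-recurrent where it carries Hawaiian;
    the parent switches exactly at transmitted CO positions.  Each call is
    then independently flipped with ``error_rate`` and set missing with
    ``missing_rate``.
    """
    if specs is not None:
        by_name = {s.name: s for s in specs}
        for chrom, pos in marker_map.items():
            if chrom in by_name and (pos.min() < 0 or pos.max() >= by_name[chrom].length_bp):
                raise ValueError(f"{chrom}: marker outside chromosome bounds")
    rng = np.random.default_rng(seed)
    individuals = [f"F2_{i + 1:04d}" for i in range(len(gametes))]
    positions = {c: np.asarray(p, dtype=np.int64) for c, p in marker_map.items()}
    calls: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError(f"{chrom}: markers must be strictly increasing")
        mat = np.empty((len(gametes), len(pos)), dtype=np.int8)
        for i, row in enumerate(gametes):
            gam = next(g for g in row if g.chromosome == chrom)
            n_before = np.searchsorted(
                np.asarray(gam.transmitted_co_positions_bp), pos, side="right"
            )
            bristol = (n_before % 2 == 0) == (gam.start_parent == "bristol")
            mat[i] = np.where(bristol, HET, HOM_RECURRENT)
        if error_rate > 0:
            flip = rng.random(mat.shape) < error_rate
            mat[flip] = 1 - mat[flip]
        if missing_rate > 0:
            mat[rng.random(mat.shape) < missing_rate] = MISSING
        calls[chrom] = mat
    return GenotypeMatrix(individuals=individuals, positions=positions, calls=calls)


# ---------------------------------------------------------------------------
# cytology and dose response


def simulate_foci(
    params: MeiosisModelParams,
    n_nuclei: int,
    seed: int | None = None,
    specs: Sequence[ChromosomeSpec] | None = None,
    standard_length_um: float = 7.0,
) -> list[FociNucleus]:
    """Simulate per-nucleus cytological focus tables.

    Zipped and forked chromosomes show one focus per bivalent CO; unpaired
    chromosomes receive Poisson(``unpaired_focus_rate``) SC-associated foci
    at uniform positions.  Positions are reported on the standardized
    chromosome coordinate (0..``standard_length_um``).
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    specs = list(specs) if specs is not None else default_chromosomes()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    meioses = simulate_meiosis(params, specs, n_nuclei, seed=rng.integers(2**31))
    nuclei = []
    for i, row in enumerate(meioses):
        chroms: dict[str, ChromosomeFoci] = {}
        for (biv, _gam), spec in zip(row, specs):
            if biv.morphology == "unpaired":
                n = rng.poisson(params.unpaired_focus_rate)
                pos = np.sort(rng.uniform(0, standard_length_um, size=n))
            else:
                pos = np.asarray(biv.bivalent_co_positions_bp) / spec.length_bp
                pos = pos * standard_length_um
            chroms[spec.name] = ChromosomeFoci(
                morphology=biv.morphology,
                positions_um=pos,
                traced_length_um=standard_length_um,
            )
        nuclei.append(FociNucleus(nucleus=f"nucleus_{i + 1:05d}", chromosomes=chroms))
    return nuclei


def simulate_dose_response(
    c: float,
    doses_rads: Sequence[float],
    n_per_dose: int,
    f_max: int = 5,
    seed: int | None = None,
) -> DoseResponse:
    """Simulate X-ray dose-response focus counts.

    Per nucleus, each of ``f_max`` homolog pairs receives
    Poisson(``c`` * dose) breaks independently; the focus count is the
    number of pairs with at least one break (each broken pair forms one
    crossover focus).
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    if f_max < 1:
        raise ValueError("f_max must be >= 1")
    if any(d < 0 for d in doses_rads):
        raise ValueError("negative dose")
    rng = np.random.default_rng(seed)
    counts = []
    for d in doses_rads:
        breaks = rng.poisson(c * d, size=(n_per_dose, f_max))
        counts.append((breaks > 0).sum(axis=1))
    return DoseResponse(doses_rads=list(doses_rads), foci_counts=counts)


def dapi_body_count(linked_pairs: int) -> int:
    """DAPI-staining bodies at diakinesis given k of 6 pairs with >= 1 CO.

    Each crossover-linked pair condenses into one bivalent body and each
    unlinked pair into two univalents: k + 2*(6 - k) = 12 - k.
    """
    if not 0 <= linked_pairs <= 6:
        raise ValueError("linked_pairs must be in 0..6")
    return 12 - linked_pairs
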