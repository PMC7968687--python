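"""Saturating model of X-ray break induction read out as crossover foci.

X-rays induce double-strand breaks at a rate proportional to dose: breaks
per homolog pair ~ Poisson(c * dose), with c in breaks/rad/pair.  In a
background where endogenous breaks are absent, a homolog pair forms one
crossover focus iff it receives at least one break, so the expected focus
count per nucleus saturates at the number of focus-competent pairs:

    E[foci](d) = f_max * (1 - exp(-c * d))

f_max = 5 in a him-8 background (the unsynapsed X cannot form a focus).
The conversion constant c is fitted by minimizing the root-mean-square
deviation between per-dose observed mean counts and the model curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .simulate import DoseResponse

__all__ = [
    "BreakModelFit",
    "expected_foci",
    "fit_break_constant",
    "fit_break_constant_from_means",
    "breaks_for_dose",
]


@dataclass(frozen=True)
class BreakModelFit:
    """Fitted break-induction constant and fit quality."""

    c: float  # breaks / rad / homolog pair
    f_max: int
    rmsd: float
    dose_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.c < 0 or self.rmsd < 0 or self.f_max < 1:
            raise ValueError("invalid fit fields")


def expected_foci(dose, c: float, f_max: int = 5):
    """Expected focus count at a dose: f_max * (1 - exp(-c * dose))."""
    dose = np.asarray(dose, dtype=float)
    if c < 0 or (dose < 0).any() or f_max < 1:
        raise ValueError("dose, c and f_max must be non-negative (f_max >= 1)")
    out = f_max * (1.0 - np.exp(-c * dose))
    return float(out) if out.ndim == 0 else out


def _rmsd(c: float, doses: np.ndarray, means: np.ndarray, f_max: int) -> float:
    return float(np.sqrt(np.mean((means - expected_foci(doses, c, f_max)) ** 2)))


def fit_break_constant_from_means(
    doses, means, f_max: int = 5
) -> BreakModelFit:
    """Fit c to per-dose mean focus counts by RMSD minimization.

    Bounded scalar minimization on c in [0, c_hi], with c_hi large enough
    that the model is saturated (exp(-c_hi * d_min_pos) < 1e-6) at the
    smallest positive dose, so the optimum is interior.
    """
    doses = np.asarray(doses, dtype=float)
    means = np.asarray(means, dtype=float)
    if len(np.unique(doses)) < 2 or not (doses > 0).any():
        raise ValueError("need >= 2 distinct doses, at least one positive")
    positive = doses > 0
    if np.all(means[positive] == 0):
        warnings.warn("all counts zero at positive doses; c = 0")
        return BreakModelFit(c=0.0, f_max=f_max, rmsd=_rmsd(0.0, doses, means, f_max),
                             dose_grid=tuple(doses))
    d_min_pos = doses[positive].min()
    c_hi = np.log(1e6) / d_min_pos
    res = optimize.minimize_scalar(
        _rmsd,
        bounds=(0.0, c_hi),
        args=(doses, means, f_max),
        method="bounded",
        options={"xatol": 1e-12},
    )
    c = float(res.x)
    return BreakModelFit(c=c, f_max=f_max, rmsd=_rmsd(c, doses, means, f_max),
                         dose_grid=tuple(doses))


def fit_break_constant(data: DoseResponse, f_max: int = 5) -> BreakModelFit:
    """Fit c to a dose-response experiment (RMSD over per-dose mean counts)."""
    return fit_break_constant_from_means(data.doses_rads, data.means(), f_max)


def breaks_for_dose(c: float, dose: float) -> tuple[float, float]:
    """Mean breaks at a dose: (per homolog pair, per chromosome).

    Per pair = c * dose; per chromosome = half of that, since a pair
    comprises two chromosomes.
    """
    if dose < 0 or c < 0:
        raise ValueError("c and dose must be >= 0")
    per_pair = c * dose
    return per_pair, per_pair / 2.0
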