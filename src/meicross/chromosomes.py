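"""Chromosome geometry: physical length, arm/center recombination domains,
and the pairing-center end used to anchor partial synapsis.

C. elegans chromosomes have crossover-rich arms and a crossover-poor
center domain; the default domain boundaries here are a generic central-half
convention and are meant to be overridden from config with empirically
defined domains when comparing against reference recombination maps.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ChromosomeSpec", "default_chromosomes", "ELEGANS_LENGTHS_BP"]

#: Reference assembly (ce11/WBcel235) chromosome sizes in bp.
ELEGANS_LENGTHS_BP = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical geometry of one chromosome.

    Parameters
    ----------
    name
        Chromosome label (e.g. ``"I"``).
    length_bp
        Physical length in base pairs.
    center_start_bp, center_end_bp
        Boundaries of the central (crossover-suppressed) domain; the two
        arms are ``[0, center_start_bp)`` and ``[center_end_bp, length_bp)``.
    pc_end
        Which end carries the pairing center, where synapsis initiates:
        ``"left"`` or ``"right"``.
    """

    name: str
    length_bp: int
    center_start_bp: int
    center_end_bp: int
    pc_end: str = "left"

    def __post_init__(self) -> None:
        if not (0 < self.center_start_bp < self.center_end_bp < self.length_bp):
            raise ValueError(
                f"{self.name}: require 0 < center_start_bp < center_end_bp "
                f"< length_bp, got {self.center_start_bp}, {self.center_end_bp}, "
                f"{self.length_bp}"
            )
        if self.pc_end not in ("left", "right"):
            raise ValueError(f"pc_end must be 'left' or 'right', got {self.pc_end!r}")

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def domain_of(self, pos_bp: float) -> str:
        """Return ``"center"`` or ``"arm"`` for a physical position."""
        if not 0 <= pos_bp < self.length_bp:
            raise ValueError(f"position {pos_bp} outside [0, {self.length_bp})")
        return "center" if self.center_start_bp <= pos_bp < self.center_end_bp else "arm"


def default_chromosomes() -> list[ChromosomeSpec]:
    """The six C. elegans chromosomes with central-half center domains.

    Domain boundaries are placeholders for the generic case; analyses that
    compare arm/center rates to a reference map should supply the map's own
    domain boundaries via configuration.
    """
    return [
        ChromosomeSpec(
            name=name,
            length_bp=length,
            center_start_bp=length // 4,
            center_end_bp=3 * length // 4,
            pc_end="left",
        )
        for name, length in ELEGANS_LENGTHS_BP.items()
    ]
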