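"""End-to-end seeded demonstration run and caller evaluation utilities."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .breakmodel import fit_break_constant
from .calling import CrossoverEvent, call_crossovers, classify_chromosomes
from .cytology import foci_count_summary
from .interference import (
    compare_observed_to_null,
    double_crossover_prevalence,
    inter_crossover_distances,
    random_pairing_null,
)
from .io import (
    PipelineConfig,
    save_config,
    write_crossovers,
    write_dose_response,
    write_foci_table,
    write_genotypes_tsv,
)
from .simulate import (
    random_marker_map,
    simulate_backcross_genotypes,
    simulate_dose_response,
    simulate_foci,
    simulate_meiosis,
)

__all__ = ["run_demo", "evaluate_calls", "CallerEvaluation", "truth_events"]


@dataclass(frozen=True)
class CallerEvaluation:
    """Caller fidelity against simulated truth.

    A truth crossover counts as recovered when it lies inside a called
    breakpoint interval extended by one marker interval on each side
    (greedy one-to-one matching); unmatched calls are false calls.  Truth
    crossovers outside the marker span are unobservable and excluded.
    """

    n_truth: int
    n_called: int
    n_matched: int
    n_chromosome_samples: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def false_call_rate(self) -> float:
        """False calls per (individual, chromosome)."""
        return (self.n_called - self.n_matched) / self.n_chromosome_samples


def truth_events(
    meioses: Sequence[Sequence[tuple]], individuals: Sequence[str] | None = None
) -> dict[tuple[str, str], np.ndarray]:
    """Transmitted crossover positions keyed by (individual, chromosome)."""
    if individuals is None:
        individuals = [f"F2_{i + 1:04d}" for i in range(len(meioses))]
    truth = {}
    for ind, row in zip(individuals, meioses):
        for _biv, gam in row:
            truth[(ind, gam.chromosome)] = np.asarray(gam.transmitted_co_positions_bp)
    return truth


def _match_intervals(truth_gaps: list[int], intervals: list[tuple[int, int]]) -> int:
    """Greedy one-to-one matching of truth gaps to called gap intervals."""
    matched = 0
    j = 0
    for t in sorted(truth_gaps):
        while j < len(intervals) and intervals[j][1] < t:
            j += 1
        if j < len(intervals) and intervals[j][0] <= t <= intervals[j][1]:
            matched += 1
            j += 1
    return matched


def evaluate_calls(
    truth: Mapping[tuple[str, str], np.ndarray],
    events: Sequence[CrossoverEvent],
    marker_map: Mapping[str, np.ndarray],
) -> CallerEvaluation:
    """Breakpoint recall and false-call rate of a call set against truth."""
    called: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for ev in events:
        markers = marker_map[ev.chromosome]
        lo = int(np.searchsorted(markers, ev.left_bp, side="right") - 1)
        hi = int(np.searchsorted(markers, ev.right_bp, side="left"))
        # truth gaps g span markers[g]..markers[g+1]; the called interval
        # covers gaps lo..hi-1, widened by one marker interval per side
        called.setdefault((ev.individual, ev.chromosome), []).append((lo - 1, hi))
    n_truth = n_matched = 0
    for key, positions in truth.items():
        markers = marker_map[key[1]]
        inside = positions[(positions >= markers[0]) & (positions < markers[-1])]
        gaps = (np.searchsorted(markers, inside, side="right") - 1).tolist()
        n_truth += len(gaps)
        n_matched += _match_intervals(gaps, sorted(called.get(key, [])))
    n_called = sum(len(v) for v in called.values())
    return CallerEvaluation(
        n_truth=n_truth,
        n_called=n_called,
        n_matched=n_matched,
        n_chromosome_samples=len(truth),
    )


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"demo stage {name!r} failed: {exc}") from exc

    return _Ctx()


def run_demo(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline on synthetic data and write all artifacts.

    Simulates meioses and backcross genotypes, calls crossovers, computes
    the interference summary with its random-pairing null, simulates and
    summarizes cytological foci, simulates a dose-response experiment and
    fits the break-induction constant.  A single seed in the config makes
    the whole bundle reproducible; a JSON log records versions, seeds and
    parameters.  Returns the summary dict that is also written to
    ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = config.chromosomes
    chrom_names = [s.name for s in specs]
    root = np.random.default_rng(config.seed)
    seeds = {
        name: int(root.integers(2**31))
        for name in ("markers", "meiosis", "genotyping", "null", "foci", "dose")
    }
    summary: dict = {"seeds": seeds}

    with _stage("simulate"):
        marker_map = random_marker_map(specs, config.markers_per_chromosome, seeds["markers"])
        meioses = simulate_meiosis(
            config.simulator, specs, config.n_individuals, seed=seeds["meiosis"]
        )
        gm = simulate_backcross_genotypes(
            [[gam for _, gam in row] for row in meioses],
            marker_map,
            error_rate=config.simulator.genotyping_error_rate,
            missing_rate=config.simulator.missing_rate,
            seed=seeds["genotyping"],
            specs=specs,
        )
        write_genotypes_tsv(gm, out / "genotypes.tsv")
        truth = truth_events(meioses, gm.individuals)
        truth_bed = [
            CrossoverEvent(ind, chrom, int(p), int(p) + 1)
            for (ind, chrom), pos in truth.items()
            for p in pos
        ]
        write_crossovers(truth_bed, out / "truth_crossovers.bed")

    with _stage("call"):
        events = call_crossovers(gm, config.caller)
        write_crossovers(events, out / "calls.bed")
        census = classify_chromosomes(events, config.n_individuals, chrom_names)
        census.to_csv(out / "census.tsv", sep="\t")
        fidelity = evaluate_calls(truth, events, marker_map)
        summary["caller"] = {
            "recall": fidelity.recall,
            "false_call_rate": fidelity.false_call_rate,
            "n_truth": fidelity.n_truth,
            "n_called": fidelity.n_called,
        }

    with _stage("interference"):
        overall, per_chrom = double_crossover_prevalence(census)
        distances = inter_crossover_distances(events)
        interference: dict = {
            "double_co_prevalence_pct": overall,
            "per_chromosome_prevalence_pct": per_chrom.to_dict(),
            "n_double_co_chromosomes": int(census["two_plus"].sum()),
        }
        if distances.size and census["two_plus"].sum() > 0:
            null = random_pairing_null(
                events, n_resamples=config.n_resamples, seed=seeds["null"]
            )
            cmp = compare_observed_to_null(distances, null)
            interference.update(
                observed_median_mb=cmp.observed_median_mb,
                null_median_mb=cmp.null_median_mb,
                p_value=cmp.p_value,
                observed_hist=cmp.observed_hist.tolist(),
                null_hist=cmp.null_hist.tolist(),
            )
        summary["interference"] = interference

    with _stage("cytology"):
        nuclei = simulate_foci(
            config.simulator, config.n_nuclei, seed=seeds["foci"], specs=specs,
            standard_length_um=config.cytology.standard_length_um,
        )
        write_foci_table(nuclei, out / "foci.tsv")
        foci_sum = foci_count_summary(nuclei)
        summary["cytology"] = {
            "mean_foci_per_nucleus": foci_sum.mean_per_nucleus,
            "sd_foci_per_nucleus": foci_sum.sd_per_nucleus,
            "per_chromosome_histogram": {
                str(m): row.to_dict()
                for m, row in foci_sum.per_chromosome_histogram.iterrows()
            },
        }

    with _stage("breakfit"):
        dose = simulate_dose_response(
            config.break_c,
            config.break_doses,
            config.break_n_per_dose,
            f_max=config.break_f_max,
            seed=seeds["dose"],
        )
        write_dose_response(dose, out / "dose_response.tsv")
        fit = fit_break_constant(dose, f_max=config.break_f_max)
        summary["break_model"] = {
            "c_true": config.break_c,
            "c_fitted": fit.c,
            "rmsd": fit.rmsd,
            "f_max": fit.f_max,
        }

    with _stage("log"):
        save_config(config, out / "config.yaml")
        log = {
            "meicross_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "stage_seeds": seeds,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
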