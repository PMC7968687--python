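"""File formats and configuration.

Genotype matrices travel as TSV (rows = individuals, columns = chrom:pos,
values 0 = homozygous-recurrent, 1 = heterozygous, . = missing) or as
minimal VCF (GT field only; 0/0 = homozygous for the recurrent-parent
allele, 0/1 = heterozygous, ./. = missing).  Crossover calls travel as BED
(0-based half-open breakpoint intervals, name = individual).  Cytological
focus tables and dose-response counts are plain TSV.  Pipeline settings
load from a schema-validated YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .calling import HET, HOM_RECURRENT, MISSING, CallerParams, CrossoverEvent, GenotypeMatrix
from .chromosomes import ChromosomeSpec, default_chromosomes
from .cytology import ChromosomeFoci, CytologyConfig, FociNucleus
from .simulate import DoseResponse, MeiosisModelParams

__all__ = [
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_crossovers",
    "read_crossovers",
    "write_foci_table",
    "read_foci_table",
    "write_dose_response",
    "read_dose_response",
    "PipelineConfig",
    "default_config",
    "load_config",
    "save_config",
]

_TSV_CODE = {HOM_RECURRENT: "0", HET: "1", MISSING: "."}
_TSV_DECODE = {"0": HOM_RECURRENT, "1": HET, ".": MISSING}


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the fixed TSV dialect: header ``individual`` then chrom:pos."""
    cols = ["individual"]
    blocks = []
    for chrom in gm.chromosomes:
        cols.extend(f"{chrom}:{p}" for p in gm.positions[chrom])
        blocks.append(gm.calls[chrom])
    mat = np.concatenate(blocks, axis=1)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ind, row in zip(gm.individuals, mat):
            fh.write(ind + "\t" + "\t".join(_TSV_CODE[v] for v in row) + "\n")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "individual":
            raise ValueError(f"{path}:1: malformed header (expected 'individual' first)")
        markers = []
        for col in header[1:]:
            try:
                chrom, pos = col.rsplit(":", 1)
                markers.append((chrom, int(pos)))
            except ValueError:
                raise ValueError(f"{path}:1: malformed marker column {col!r}") from None
        individuals = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            individuals.append(fields[0])
            try:
                rows.append([_TSV_DECODE[v] for v in fields[1:]])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: invalid genotype code {exc}") from None
    mat = np.asarray(rows, dtype=np.int8).reshape(len(individuals), len(markers))
    positions: dict[str, list[int]] = {}
    col_of: dict[str, list[int]] = {}
    for j, (chrom, pos) in enumerate(markers):
        positions.setdefault(chrom, []).append(pos)
        col_of.setdefault(chrom, []).append(j)
    for chrom, pos in positions.items():
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{path}: {chrom} markers not strictly increasing")
    return GenotypeMatrix(
        individuals=individuals,
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        calls={c: mat[:, col_of[c]] for c in positions},
    )


def write_genotypes_vcf(
    gm: GenotypeMatrix, path: str | Path, specs: Sequence[ChromosomeSpec] | None = None
) -> None:
    """Write a minimal GT-only VCF (placeholder ref/alt alleles)."""
    lengths = {s.name: s.length_bp for s in (specs or [])}
    gt = {HOM_RECURRENT: "0/0", HET: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chromosomes:
            if chrom in lengths:
                fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for chrom in gm.chromosomes:
            calls = gm.calls[chrom]
            for j, pos in enumerate(gm.positions[chrom]):
                fields = [chrom, str(pos + 1), ".", "A", "T", ".", "PASS", ".", "GT"]
                fields.extend(gt[v] for v in calls[:, j])
                fh.write("\t".join(fields) + "\n")


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    with pysam.VariantFile(str(path)) as vcf:
        individuals = list(vcf.header.samples)
        positions: dict[str, list[int]] = {}
        columns: dict[str, list[np.ndarray]] = {}
        for rec in vcf:
            col = np.empty(len(individuals), dtype=np.int8)
            for i, sample in enumerate(individuals):
                alleles = rec.samples[sample].get("GT", (None, None))
                if alleles is None or None in alleles:
                    col[i] = MISSING
                elif sum(alleles) == 0:
                    col[i] = HOM_RECURRENT
                elif set(alleles) == {0, 1}:
                    col[i] = HET
                else:
                    raise ValueError(
                        f"{path}: unexpected genotype {alleles} at {rec.chrom}:{rec.pos} "
                        "(backcross designs have no homozygous-donor calls)"
                    )
            positions.setdefault(rec.chrom, []).append(rec.pos - 1)
            columns.setdefault(rec.chrom, []).append(col)
    for chrom, pos in positions.items():
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{path}: {chrom} markers not strictly increasing")
    return GenotypeMatrix(
        individuals=individuals,
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        calls={c: np.stack(cols, axis=1) for c, cols in columns.items()},
    )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or minimal VCF.

    ``format`` is inferred from the extension when omitted.
    """
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# crossover BED

_BED_HEADER = "#chrom\tleft_bp\tright_bp\tindividual\tn_co_on_chrom"


def write_crossovers(events: Iterable[CrossoverEvent], path: str | Path) -> None:
    """Write crossover calls as BED (0-based half-open), sorted, deterministic."""
    events = list(events)
    n_on_chrom: dict[tuple[str, str], int] = {}
    for ev in events:
        key = (ev.individual, ev.chromosome)
        n_on_chrom[key] = n_on_chrom.get(key, 0) + 1
    ordered = sorted(events, key=lambda e: (e.chromosome, e.left_bp, e.right_bp, e.individual))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for ev in ordered:
            fh.write(
                f"{ev.chromosome}\t{ev.left_bp}\t{ev.right_bp}\t{ev.individual}\t"
                f"{n_on_chrom[(ev.individual, ev.chromosome)]}\n"
            )


def read_crossovers(path: str | Path) -> list[CrossoverEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED fields")
            events.append(
                CrossoverEvent(
                    individual=fields[3],
                    chromosome=fields[0],
                    left_bp=int(fields[1]),
                    right_bp=int(fields[2]),
                )
            )
    return events


# ---------------------------------------------------------------------------
# foci and dose-response tables


def _join(values: Iterable[float]) -> str:
    return ",".join(f"{v:.6g}" for v in values)


def _split(text: str) -> np.ndarray:
    text = text.strip()
    if not text:
        return np.empty(0)
    return np.array([float(v) for v in text.split(",")])


def write_foci_table(nuclei: Iterable[FociNucleus], path: str | Path) -> None:
    """One row per (nucleus, chromosome); positions comma-joined in μm."""
    rows = []
    for nuc in nuclei:
        for chrom, cf in nuc.chromosomes.items():
            rows.append(
                {
                    "nucleus": nuc.nucleus,
                    "chromosome": chrom,
                    "morphology": cf.morphology,
                    "traced_length_um": cf.traced_length_um,
                    "positions_um": _join(cf.positions_um),
                    "junctions_um": _join(cf.junctions_um),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_foci_table(path: str | Path) -> list[FociNucleus]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    nuclei: dict[str, dict[str, ChromosomeFoci]] = {}
    for _, row in df.iterrows():
        nuclei.setdefault(row["nucleus"], {})[row["chromosome"]] = ChromosomeFoci(
            morphology=row["morphology"],
            positions_um=_split(row["positions_um"]),
            traced_length_um=float(row["traced_length_um"]),
            junctions_um=_split(row["junctions_um"]),
        )
    return [FociNucleus(nucleus=n, chromosomes=c) for n, c in nuclei.items()]


def write_dose_response(data: DoseResponse, path: str | Path) -> None:
    rows = []
    for dose, counts in zip(data.doses_rads, data.foci_counts):
        for k, n in enumerate(counts):
            rows.append({"dose_rads": dose, "nucleus_id": k, "foci": int(n)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dose_response(path: str | Path) -> DoseResponse:
    df = pd.read_csv(path, sep="\t")
    doses = sorted(df["dose_rads"].unique())
    counts = [df.loc[df["dose_rads"] == d, "foci"].to_numpy() for d in doses]
    return DoseResponse(doses_rads=[float(d) for d in doses], foci_counts=counts)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything a seeded end-to-end run needs."""

    chromosomes: list[ChromosomeSpec]
    simulator: MeiosisModelParams
    caller: CallerParams
    cytology: CytologyConfig
    n_individuals: int = 84
    markers_per_chromosome: int = 1000
    n_nuclei: int = 60
    n_resamples: int = 2100
    break_c: float = 0.0028
    break_f_max: int = 5
    break_doses: list[float] = field(
        default_factory=lambda: [0, 250, 500, 1000, 2000, 5000, 10000]
    )
    break_n_per_dose: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s.name for s in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome definitions")
        if self.n_individuals < 1 or self.markers_per_chromosome < 1 or self.n_nuclei < 1:
            raise ValueError("sample sizes must be >= 1")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


def default_config(seed: int = 0) -> PipelineConfig:
    from .simulate import mutant_params

    return PipelineConfig(
        chromosomes=default_chromosomes(),
        simulator=mutant_params(seed=seed),
        caller=CallerParams(),
        cytology=CytologyConfig(),
        seed=seed,
    )


_SCHEMA_KEYS = {
    "chromosomes",
    "simulator",
    "caller",
    "cytology",
    "n_individuals",
    "markers_per_chromosome",
    "n_nuclei",
    "n_resamples",
    "break_c",
    "break_f_max",
    "break_doses",
    "break_n_per_dose",
    "seed",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _SCHEMA_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = default_config(seed=int(raw.get("seed", 0)))
    chroms = [
        ChromosomeSpec(**spec) for spec in raw.get("chromosomes", [])
    ] or cfg.chromosomes
    sim_raw = dict(raw.get("simulator", {}))
    if "zipping_probs" in sim_raw and isinstance(sim_raw["zipping_probs"], dict):
        sim_raw["zipping_probs"] = {
            k: tuple(v) for k, v in sim_raw["zipping_probs"].items()
        }
    elif "zipping_probs" in sim_raw:
        sim_raw["zipping_probs"] = tuple(sim_raw["zipping_probs"])
    simulator = MeiosisModelParams(**{**_params_dict(cfg.simulator), **sim_raw})
    caller = CallerParams(**raw.get("caller", {}))
    cytology = CytologyConfig(**raw.get("cytology", {}))
    scalars = {
        k: raw[k]
        for k in (
            "n_individuals",
            "markers_per_chromosome",
            "n_nuclei",
            "n_resamples",
            "break_c",
            "break_f_max",
            "break_doses",
            "break_n_per_dose",
            "seed",
        )
        if k in raw
    }
    return PipelineConfig(
        chromosomes=chroms,
        simulator=simulator,
        caller=caller,
        cytology=cytology,
        **scalars,
    )


def _params_dict(params: MeiosisModelParams) -> dict:
    return {
        "zipping_probs": params.zipping_probs,
        "forked_zipped_fraction": params.forked_zipped_fraction,
        "co_model": params.co_model,
        "co_rate": params.co_rate,
        "interference_nu": params.interference_nu,
        "placement_weights": dict(params.placement_weights),
        "genotyping_error_rate": params.genotyping_error_rate,
        "missing_rate": params.missing_rate,
        "unpaired_focus_rate": params.unpaired_focus_rate,
        "seed": params.seed,
    }


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    raw = {
        "chromosomes": [
            {
                "name": s.name,
                "length_bp": s.length_bp,
                "center_start_bp": s.center_start_bp,
                "center_end_bp": s.center_end_bp,
                "pc_end": s.pc_end,
            }
            for s in cfg.chromosomes
        ],
        "simulator": _yamlify(_params_dict(cfg.simulator)),
        "caller": {"min_run": cfg.caller.min_run, "max_background": cfg.caller.max_background},
        "cytology": {
            "standard_length_um": cfg.cytology.standard_length_um,
            "n_bins": cfg.cytology.n_bins,
            "merge_threshold_um": cfg.cytology.merge_threshold_um,
            "junction_radius_um": cfg.cytology.junction_radius_um,
        },
        "n_individuals": cfg.n_individuals,
        "markers_per_chromosome": cfg.markers_per_chromosome,
        "n_nuclei": cfg.n_nuclei,
        "n_resamples": cfg.n_resamples,
        "break_c": cfg.break_c,
        "break_f_max": cfg.break_f_max,
        "break_doses": list(cfg.break_doses),
        "break_n_per_dose": cfg.break_n_per_dose,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def _yamlify(obj):
    if isinstance(obj, dict):
        return {k: _yamlify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_yamlify(v) for v in obj]
    return obj
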