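"""Configuration objects shared across the pipeline.

Holds the simulation parameters, the per-fraction metadata (cell counts and
flow-cytometry phase compositions), and the pipeline-wide threshold bundle.
All proportion vectors are validated to sum to one.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

SAMPLES = ("F1", "F2", "F3", "F4", "F5", "F6", "ASYNC")
FRACTIONS = SAMPLES[:6]
PHASES = ("G1", "S", "G2M")
PEAK_CLASSES = ("G1", "S", "G2M", "G2M+G1")

#: broad-class mapping of the six elutriated fractions
FRACTION_BROAD_CLASS = {
    "F1": "G1", "F2": "G1", "F3": "S", "F4": "S", "F5": "G2M", "F6": "G2M",
}

_PROP_TOL = 1e-9


def _check_proportions(name: str, values: Sequence[float]) -> tuple[float, ...]:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name}: proportions must be non-negative, got {values}")
    if abs(arr.sum() - 1.0) > _PROP_TOL:
        raise ValueError(
            f"{name}: proportions must sum to 1 (got {arr.sum():.12f}); "
            "normalize before constructing the config"
        )
    return tuple(arr)


@dataclass(frozen=True)
class FractionMeta:
    """One elutriated fraction (or the asynchronous sample).

    ``cell_count`` is the population yield of the fraction;
    ``phase_composition`` is the (G1, S, G2M) proportion from flow cytometry.
    ``loaded_cells`` is the number of cells represented in the MS injection
    (equal loads by default, so load normalization is a no-op up to a
    constant).
    """

    fraction: str
    cell_count: float
    phase_composition: tuple[float, float, float]
    loaded_cells: float = 1.0

    def __post_init__(self):
        if self.cell_count <= 0:
            raise ValueError(f"{self.fraction}: cell count must be positive")
        if self.loaded_cells <= 0:
            raise ValueError(f"{self.fraction}: loaded cell count must be positive")
        object.__setattr__(
            self,
            "phase_composition",
            _check_proportions(f"{self.fraction} phase_composition", self.phase_composition),
        )


#: default fraction metadata: cell yields decrease from F1 to F6 and the
#: compositions shift from G1- to G2&M-enriched.
DEFAULT_FRACTIONS = (
    FractionMeta("F1", 8.0e7, (0.90, 0.08, 0.02)),
    FractionMeta("F2", 5.0e7, (0.80, 0.17, 0.03)),
    FractionMeta("F3", 3.0e7, (0.35, 0.55, 0.10)),
    FractionMeta("F4", 1.5e7, (0.20, 0.60, 0.20)),
    FractionMeta("F5", 6.0e6, (0.10, 0.30, 0.60)),
    FractionMeta("F6", 2.0e6, (0.05, 0.15, 0.80)),
)


def composition_matrix(fractions: Sequence[FractionMeta]) -> np.ndarray:
    """6x3 matrix of phase proportions, rows ordered F1..F6."""
    return np.array([f.phase_composition for f in fractions], dtype=float)


def cell_count_weights(fractions: Sequence[FractionMeta]) -> np.ndarray:
    counts = np.array([f.cell_count for f in fractions], dtype=float)
    return counts / counts.sum()


def async_phase_composition(fractions: Sequence[FractionMeta]) -> np.ndarray:
    """Phase composition of the cell-count-weighted fraction mixture."""
    w = cell_count_weights(fractions)
    return w @ composition_matrix(fractions)


def fractions_to_frame(fractions: Sequence[FractionMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fraction": [f.fraction for f in fractions],
            "cell_count": [f.cell_count for f in fractions],
            "pi_G1": [f.phase_composition[0] for f in fractions],
            "pi_S": [f.phase_composition[1] for f in fractions],
            "pi_G2M": [f.phase_composition[2] for f in fractions],
            "loaded_cells": [f.loaded_cells for f in fractions],
        }
    )


def fractions_from_frame(df: pd.DataFrame) -> tuple[FractionMeta, ...]:
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            FractionMeta(
                fraction=row.fraction,
                cell_count=float(row.cell_count),
                phase_composition=(float(row.pi_G1), float(row.pi_S), float(row.pi_G2M)),
                loaded_cells=float(getattr(row, "loaded_cells", 1.0)),
            )
        )
    return tuple(metas)


# the printed S/T/Y percentages (64/17/16) sum to 0.97 because of rounding;
# the default mix keeps their ratios and normalizes exactly.
_STY_DEFAULT = tuple(np.array([0.64, 0.17, 0.16]) / 0.97)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic expression universe."""

    n_genes: int = 2000
    frac_regulated: float = 0.055
    peak_phase_mix: tuple[float, float, float, float] = (0.17, 0.27, 0.49, 0.07)
    fold_range: tuple[float, float] = (2.0, 8.0)
    rna_protein_rho: float = 0.63
    rna_regulated_fold: float = 1.5
    noise_cv: float = 0.10
    isoform_rate: tuple[float, ...] = (0.70, 0.15, 0.08, 0.04, 0.03)
    phospho_rate: float = 0.03
    sty_mix: tuple[float, float, float] = _STY_DEFAULT
    seed: int = 0

    # abundance model: log10 copy number per cell
    log_copy_mean: float = 4.5
    log_copy_sd: float = 1.3

    # secondary structure of the universe
    coordinated_rate: float = 0.09      # of regulated genes, protein+RNA coordinated
    discordant_rate: float = 0.30       # of multi-isoform unregulated genes
    histone_rate: float = 0.01
    phospho_regulated_rate: float = 0.03
    multisite_rate: float = 0.28
    unregulated_wiggle: float = 0.15    # max phase-level deviation for flat genes

    # sequence model
    seq_length_median: int = 220
    seq_length_sigma: float = 0.35
    seq_length_bounds: tuple[int, int] = (60, 700)

    # measurement model (evidence table)
    response_sigma: float = 0.8         # ln-scale sd of per-peptide response factor
    detect_midpoint: float = 1.5        # log10 intensity of 50% detection; -inf => always
    detect_slope: float = 3.0
    msms_ref_intensity: float = 3.0e4  # intensity yielding msms_ref_rate
    msms_ref_rate: float = 10.0
    msms_max_rate: float = 60.0        # duty-cycle saturation
    contaminant_rate: float = 0.01
    decoy_rate: float = 0.005
    oxidation_rate: float = 0.02
    deamidation_rate: float = 0.02
    evidence_missed_cleavages: int = 1
    peptide_length_bounds: tuple[int, int] = (7, 35)

    # RNA measurement model
    rna_noise_cv: float = 0.15
    rna_log_mean: float = 1.0
    rna_log_sd: float = 0.8

    fractions: tuple[FractionMeta, ...] = DEFAULT_FRACTIONS

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ValueError("frac_regulated must be in [0, 1]")
        if self.fold_range[0] < 1.0 or self.fold_range[1] < self.fold_range[0]:
            raise ValueError("fold_range must satisfy 1 <= lo <= hi")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        object.__setattr__(
            self, "peak_phase_mix", _check_proportions("peak_phase_mix", self.peak_phase_mix)
        )
        object.__setattr__(
            self, "isoform_rate", _check_proportions("isoform_rate", self.isoform_rate)
        )
        object.__setattr__(self, "sty_mix", _check_proportions("sty_mix", self.sty_mix))
        if len(self.fractions) != 6:
            raise ValueError("exactly six elutriated fractions are required")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Thresholds and paths for the end-to-end run.

    Every threshold defaults to the module default; the object round-trips
    losslessly through YAML.
    """

    seed: int = 0
    tau: float = 1.0                 # checksum log2 tolerance
    rho_max: float = 0.5             # deconvolution relative residual cap
    fold_cutoff: float = 2.0         # protein regulation, inclusive
    phospho_cutoff: float = 2.0      # phospho regulation, strict
    rna_fold_cutoff: float = 1.5     # coordinated-subset RNA fold, strict
    concordance_r0: float = 0.5      # isoform discordance threshold
    profile_r0: float = 0.5          # protein/RNA profile concordance threshold
    min_peptides: int = 2
    n_clusters: int = 16
    log_level: str = "INFO"
    evidence: str = "evidence.tsv"
    fasta: str = "isoforms.fasta"
    fpkm: str = "fpkm.tsv"
    fractions: str = "fractions.tsv"
    annotations: str = "annotations.tsv"
    out_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
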