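"""Data-cleaning rules and the quantitation self-consistency ("checksum")
filter.

A protein is retained only when its asynchronous-sample intensity is
explainable as the cell-count-weighted combination of the six fraction
intensities, and when its fraction profile is explainable as a non-negative
mixture of phase-level expression given the flow-cytometry phase
compositions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .config import FRACTIONS, FractionMeta, cell_count_weights, composition_matrix
from .quantification import ProteinGroup


def clean_evidence(
    groups: Sequence[ProteinGroup],
    intensities: pd.DataFrame,
    contaminant_flags: pd.Series | None = None,
    decoy_flags: pd.Series | None = None,
    min_peptides: int = 2,
) -> tuple[list[ProteinGroup], pd.DataFrame]:
    """Initial cleaning: drop groups with fewer than ``min_peptides``
    peptides, contaminant or reverse-decoy groups, and groups missing
    intensity in any of F1..F6 or the asynchronous sample."""
    keep_ids = []
    for g in groups:
        if g.peptide_count < min_peptides:
            continue
        if contaminant_flags is not None and bool(contaminant_flags.get(g.group_id, False)):
            continue
        if decoy_flags is not None and bool(decoy_flags.get(g.group_id, False)):
            continue
        row = intensities.loc[g.group_id] if g.group_id in intensities.index else None
        if row is None or (row <= 0).any() or row.isna().any():
            continue
        keep_ids.append(g.group_id)
    keep_set = set(keep_ids)
    kept_groups = [g for g in groups if g.group_id in keep_set]
    return kept_groups, intensities.loc[keep_ids]


@dataclass
class ConsistencyResult:
    """Per-protein checksum deviation and phase-deconvolution residual."""

    table: pd.DataFrame  # predicted, measured, deviation, residual, flags
    tau: float
    rho_max: float

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["pass"]]


def load_normalized(intensities: pd.DataFrame,
                    meta: Sequence[FractionMeta]) -> pd.DataFrame:
    """Per-cell intensities: divide each fraction column by the loaded cell
    count of that sample (equal loads by default, so this is a no-op up to
    a constant)."""
    loads = {m.fraction: m.loaded_cells for m in meta}
    loads.setdefault("ASYNC", 1.0)
    return intensities.div(pd.Series(loads).reindex(intensities.columns), axis=1)


def checksum_filter(
    intensities: pd.DataFrame,
    meta: Sequence[FractionMeta],
    tau: float = 1.0,
) -> pd.DataFrame:
    """Compare each protein's measured asynchronous intensity with the
    cell-count-weighted mixture of its per-cell fraction intensities.

    pass iff |log2(predicted / measured)| <= tau (boundary inclusive).
    Proteins with zero measured asynchronous intensity fail with a reason
    code instead of raising.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    tilde = load_normalized(intensities, meta)
    w = cell_count_weights(meta)
    predicted = tilde[list(FRACTIONS)].to_numpy() @ w
    measured = tilde["ASYNC"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        deviation = np.abs(np.log2(predicted / measured))
    ok = measured > 0
    out = pd.DataFrame(
        {
            "predicted_async": predicted,
            "measured_async": measured,
            "deviation": np.where(ok, deviation, np.inf),
            "checksum_pass": ok & (np.where(ok, deviation, np.inf) <= tau),
            "reason": np.where(ok, "", "zero_async"),
        },
        index=intensities.index,
    )
    out.loc[ok & (out["deviation"] > tau), "reason"] = "checksum_deviation"
    return out


def phase_deconvolution(
    intensities: pd.DataFrame,
    meta: Sequence[FractionMeta],
    rho_max: float = 0.5,
) -> pd.DataFrame:
    """Non-negative least squares deconvolution of each per-cell fraction
    profile into phase-level expression x = (x_G1, x_S, x_G2M).

    residual = RMS error / mean per-cell intensity; pass iff
    residual <= rho_max. This formalizes the adjacent-fraction consistency
    factors (cell number + phase proportions) as one linear model.
    """
    M = composition_matrix(meta)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        degenerate = [m.fraction for m in meta]
        raise ValueError(
            "phase-composition matrix is rank deficient; fractions "
            f"{degenerate} do not span the three phases"
        )
    tilde = load_normalized(intensities, meta)[list(FRACTIONS)].to_numpy()
    n = tilde.shape[0]
    x = np.zeros((n, 3))
    residual = np.zeros(n)
    for i in range(n):
        sol, rnorm = nnls(M, tilde[i])
        x[i] = sol
        mean_i = tilde[i].mean()
        residual[i] = (rnorm / np.sqrt(M.shape[0])) / mean_i if mean_i > 0 else np.inf
    out = pd.DataFrame(
        {
            "x_G1": x[:, 0], "x_S": x[:, 1], "x_G2M": x[:, 2],
            "residual": residual,
            "deconv_pass": residual <= rho_max,
        },
        index=intensities.index,
    )
    return out


def consistency_filter(
    intensities: pd.DataFrame,
    meta: Sequence[FractionMeta],
    tau: float = 1.0,
    rho_max: float = 0.5,
) -> ConsistencyResult:
    """Both criteria combined: checksum deviation <= tau AND deconvolution
    residual <= rho_max."""
    chk = checksum_filter(intensities, meta, tau)
    dec = phase_deconvolution(intensities, meta, rho_max)
    table = chk.join(dec)
    table["pass"] = table["checksum_pass"] & table["deconv_pass"]
    table.loc[~table["deconv_pass"] & (table["reason"] == ""), "reason"] = \
        "deconvolution_residual"
    return ConsistencyResult(table, tau, rho_max)
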