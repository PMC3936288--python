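"""Isoform-resolved re-analysis of the peptide evidence.

Uses MS/MS spectral counts of peptides unique to one isoform (within the
gene's isoform set) to build per-isoform 6-fraction profiles, scores
inter-isoform concordance by pairwise Pearson correlation, and flags genes
where gene-level aggregation masks isoform-level regulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FRACTIONS


def _unique_peptide_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Evidence rows whose peptide maps to exactly one isoform of its gene;
    contaminant/decoy rows and fraction-external samples excluded."""
    ev = evidence.loc[
        ~evidence["is_contaminant"]
        & ~evidence["is_reverse"]
        & evidence["sample"].isin(FRACTIONS)
    ]
    unique = ~ev["proteins"].str.contains(";")
    return ev.loc[unique].rename(columns={"proteins": "isoform_id"})


def isoform_profiles(evidence: pd.DataFrame, min_unique_peptides: int = 2
                     ) -> pd.DataFrame:
    """Per-fraction mean unique-peptide MS/MS counts for each eligible
    isoform.

    Eligibility: at least ``min_unique_peptides`` peptides with unique
    sequences, each quantified (intensity > 0) in all six fractions.
    Peptides matching more than one isoform of the gene count for none.
    Returns a frame indexed by isoform with F1..F6 profile columns,
    ``gene_id`` and ``n_unique_peptides``.
    """
    ev = _unique_peptide_evidence(evidence)
    if len(ev) == 0:
        return pd.DataFrame(columns=["gene_id", "n_unique_peptides", *FRACTIONS])
    # peptide x fraction completeness within isoform
    counts = ev.pivot_table(index=["isoform_id", "sequence"], columns="sample",
                            values="msms_count", aggfunc="mean")
    inten = ev.pivot_table(index=["isoform_id", "sequence"], columns="sample",
                           values="intensity", aggfunc="sum")
    complete = (inten.reindex(columns=list(FRACTIONS)) > 0).all(axis=1)
    counts = counts.loc[complete, list(FRACTIONS)]

    prof = counts.groupby(level="isoform_id").mean()
    npep = counts.groupby(level="isoform_id").size()
    prof = prof.loc[npep >= min_unique_peptides]
    gene = ev.drop_duplicates("isoform_id").set_index("isoform_id")["gene_id"]
    out = prof.copy()
    out.insert(0, "gene_id", gene.reindex(prof.index))
    out.insert(1, "n_unique_peptides", npep.reindex(prof.index))
    return out


@dataclass
class ConcordanceScore:
    gene_id: str
    isoforms: tuple[str, ...]
    matrix: pd.DataFrame          # pairwise Pearson r, unit diagonal
    min_r: float                  # NaN when no valid pair
    discordant: bool
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def concordance(profiles: pd.DataFrame, gene_id: str, r0: float = 0.5
                ) -> ConcordanceScore:
    """Pairwise Pearson correlation over the 6-point MS/MS profiles of one
    gene's isoforms; discordant iff the minimum pairwise r falls below
    ``r0``. Constant profiles make r undefined for that pair; such pairs
    are skipped and reported."""
    sub = profiles.loc[profiles["gene_id"] == gene_id, list(FRACTIONS)]
    if len(sub) < 2:
        raise ValueError(f"gene {gene_id}: need >= 2 eligible isoforms")
    isos = tuple(sub.index)
    mat = pd.DataFrame(np.eye(len(isos)), index=isos, columns=isos)
    skipped = []
    min_r = np.inf
    any_pair = False
    vals = sub.to_numpy()
    sd = vals.std(axis=1)
    for i in range(len(isos)):
        for j in range(i + 1, len(isos)):
            if sd[i] == 0 or sd[j] == 0:
                mat.iloc[i, j] = mat.iloc[j, i] = np.nan
                skipped.append((isos[i], isos[j]))
                continue
            r = float(np.corrcoef(vals[i], vals[j])[0, 1])
            mat.iloc[i, j] = mat.iloc[j, i] = r
            min_r = min(min_r, r)
            any_pair = True
    min_r = min_r if any_pair else float("nan")
    discordant = bool(any_pair and min_r < r0)
    return ConcordanceScore(gene_id, isos, mat, min_r, discordant, skipped)


def concordance_table(profiles: pd.DataFrame, r0: float = 0.5) -> pd.DataFrame:
    """Concordance scores for every gene with >= 2 eligible isoforms."""
    rows = []
    for gid, sub in profiles.groupby("gene_id"):
        if len(sub) < 2:
            continue
        score = concordance(profiles, str(gid), r0)
        rows.append((gid, len(sub), score.min_r, score.discordant,
                     len(score.skipped_pairs)))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_isoforms", "min_r", "discordant",
                       "skipped_pairs"]
    ).set_index("gene_id")


def aggregation_masking(
    evidence: pd.DataFrame,
    gene_id: str,
    cutoff: float = 2.0,
) -> dict:
    """Gene-level pooled fold vs per-isoform folds (intensity currency).

    The gene-level profile pools every quantifiable fraction-sample peptide
    intensity of the gene; per-isoform profiles use only isoform-unique
    peptides. ``masking`` is True when the pooled fold stays below the
    cutoff while some isoform reaches it — the situation where summing
    isoforms hides a regulated one.
    """
    ev = evidence.loc[
        (evidence["gene_id"] == gene_id)
        & ~evidence["is_contaminant"]
        & ~evidence["is_reverse"]
        & evidence["sample"].isin(FRACTIONS)
        & (evidence["modifications"] != "Phospho (STY)")
    ]
    pooled = ev.groupby("sample")["intensity"].sum().reindex(list(FRACTIONS))
    if pooled.isna().any() or (pooled <= 0).any():
        return {"gene_id": gene_id, "pooled_fold": float("nan"),
                "isoform_folds": {}, "masking": False}
    pooled_fold = float(pooled.max() / pooled.min())

    uniq = ev.loc[~ev["proteins"].str.contains(";")]
    iso_folds = {}
    for iso, sub in uniq.groupby("proteins"):
        prof = sub.groupby("sample")["intensity"].sum().reindex(list(FRACTIONS))
        if prof.isna().any() or (prof <= 0).any():
            continue
        iso_folds[str(iso)] = float(prof.max() / prof.min())
    masking = pooled_fold < cutoff and any(f >= cutoff for f in iso_folds.values())
    return {
        "gene_id": gene_id,
        "pooled_fold": pooled_fold,
        "isoform_folds": iso_folds,
        "masking": masking,
    }
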