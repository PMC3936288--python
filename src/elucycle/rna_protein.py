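"""Gene-level merging of protein (iBAQ) and mRNA (FPKM) quantitation and
their correlation analyses.

Protein isoform/variant abundances are summed per gene; histone genes are
removed before any correlation (their transcripts lack poly(A) tails and
are not captured by the RNA workflow). Abundance correlations are Spearman
on log-scale values; profile concordance is Pearson over three paired
points after pooling the six protein fractions into G1 (F1+F2), S (F3+F4)
and G2&M (F5+F6) with cell-count weights, mirroring the physical pooling of
the RNA samples.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import FractionMeta

logger = logging.getLogger(__name__)

RNA_SAMPLES = ("G1", "S", "G2M", "ASYNC")
POOLS = {"G1": ("F1", "F2"), "S": ("F3", "F4"), "G2M": ("F5", "F6")}


def pool_protein_phases(
    intensities: pd.DataFrame, meta: Sequence[FractionMeta]
) -> pd.DataFrame:
    """Reduce 6-fraction protein intensities to (G1, S, G2M) by cell-count-
    weighted pooling of the member fractions."""
    counts = {m.fraction: m.cell_count for m in meta}
    out = {}
    for phase, members in POOLS.items():
        w = np.array([counts[f] for f in members])
        w = w / w.sum()
        out[phase] = intensities[list(members)].to_numpy() @ w
    return pd.DataFrame(out, index=intensities.index)


def summarize_fpkm(rna: pd.DataFrame) -> pd.DataFrame:
    """Mean FPKM per gene per pooled sample across replicates; carries the
    histone flag through."""
    mean = rna.pivot_table(index="gene_id", columns="sample", values="fpkm",
                           aggfunc="mean")
    mean = mean.reindex(columns=list(RNA_SAMPLES))
    histone = rna.groupby("gene_id")["is_histone"].any()
    mean["is_histone"] = histone.reindex(mean.index).fillna(False)
    return mean


def merge_gene_level(
    protein_gene: pd.DataFrame,
    fpkm: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One record per gene with both protein and RNA quantitation.

    ``protein_gene``: per-gene summed protein quantitation (columns F1..F6,
    ASYNC); ``fpkm``: output of :func:`summarize_fpkm`. ``id_map``
    translates protein-side gene ids to the RNA-side namespace when they
    differ. Histone genes are dropped (count logged); genes missing any
    required sample are excluded from the complete-case set."""
    prot = protein_gene.copy()
    if id_map is not None:
        unmapped = [g for g in prot.index if g not in id_map]
        if unmapped:
            logger.warning("%d protein gene ids not in id map", len(unmapped))
        prot = prot.loc[[g for g in prot.index if g in id_map]]
        prot.index = [id_map[g] for g in prot.index]
    if prot.index.has_duplicates:
        logger.warning("duplicate gene ids after mapping; aggregating by sum")
        prot = prot.groupby(level=0).sum()
    merged = prot.join(fpkm, how="inner", rsuffix="_rna")
    n_hist = int(merged["is_histone"].sum())
    if n_hist:
        logger.info("removed %d histone genes", n_hist)
    merged = merged.loc[~merged["is_histone"]].drop(columns="is_histone")
    complete = merged.notna().all(axis=1) & (merged > 0).all(axis=1)
    return merged.loc[complete]


def correlate_abundances(
    records: pd.DataFrame,
    protein_col: str,
    rna_col: str,
    min_records: int = 10,
) -> tuple[float, int]:
    """Spearman rank correlation of log protein vs log RNA abundance over
    the complete-case records of a scope (a sample pair or a cluster
    subset). Returns (rho, n)."""
    sub = records[[protein_col, rna_col]].dropna()
    sub = sub[(sub > 0).all(axis=1)]
    if len(sub) < min_records:
        raise ValueError(f"need >= {min_records} complete records, got {len(sub)}")
    rho = spearmanr(np.log10(sub[protein_col]), np.log10(sub[rna_col])).statistic
    return float(rho), len(sub)


def classify_profile_correlation(
    protein_pooled: pd.DataFrame,
    rna_phases: pd.DataFrame,
    r0: float = 0.5,
) -> pd.DataFrame:
    """Pearson correlation over the three paired (G1, S, G2M) points per
    gene; concordant iff r >= r0 (boundary inclusive). Genes with a
    constant profile on either side have undefined r and are flagged
    ``undefined``."""
    common = protein_pooled.index.intersection(rna_phases.index)
    prot = protein_pooled.loc[common, ["G1", "S", "G2M"]].to_numpy(dtype=float)
    rna = rna_phases.loc[common, ["G1", "S", "G2M"]].to_numpy(dtype=float)
    r = np.full(len(common), np.nan)
    defined = (prot.std(axis=1) > 0) & (rna.std(axis=1) > 0)
    for i in np.flatnonzero(defined):
        r[i] = np.corrcoef(prot[i], rna[i])[0, 1]
    # tiny tolerance keeps the inclusive boundary robust to rounding
    status = np.where(~defined, "undefined",
                      np.where(r >= r0 - 1e-12, "concordant", "discordant"))
    return pd.DataFrame({"r": r, "status": status}, index=common)


def coordinated_subset(
    regulated_genes: Sequence[str],
    rna_phases: pd.DataFrame,
    protein_pooled: pd.DataFrame | None = None,
    rna_cutoff: float = 1.5,
) -> pd.DataFrame:
    """Genes whose protein abundance is cell-cycle regulated AND whose
    cognate mRNA varies by more than ``rna_cutoff`` across the pooled
    phases (strict).

    Returns the subset with RNA fold and, when protein profiles are given,
    the Pearson r between the mean scaled protein and RNA profiles as a
    frame attribute ``mean_profile_r``."""
    idx = [g for g in regulated_genes if g in rna_phases.index]
    rna = rna_phases.loc[idx, ["G1", "S", "G2M"]]
    rna = rna[(rna > 0).all(axis=1)]
    fold = rna.max(axis=1) / rna.min(axis=1)
    out = pd.DataFrame({"rna_fold": fold})
    out["coordinated"] = fold > rna_cutoff
    subset = out.loc[out["coordinated"]].copy()
    if protein_pooled is not None and len(subset):
        common = subset.index.intersection(protein_pooled.index)
        prot_scaled = protein_pooled.loc[common, ["G1", "S", "G2M"]]
        prot_scaled = prot_scaled.div(prot_scaled.max(axis=1), axis=0)
        rna_scaled = rna.loc[common].div(rna.loc[common].max(axis=1), axis=0)
        mp, mr = prot_scaled.mean(), rna_scaled.mean()
        subset.attrs["mean_protein_profile"] = mp.to_numpy()
        subset.attrs["mean_rna_profile"] = mr.to_numpy()
        subset.attrs["mean_profile_r"] = float(np.corrcoef(mp, mr)[0, 1])
    return subset
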