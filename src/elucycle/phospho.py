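"""Cell-cycle analysis of phosphopeptides detected without enrichment.

Phosphopeptides are keyed by (isoform set, phospho site set); peptides with
multiple phosphorylated residues are treated as one analyzable unit.
Regulation uses a strict greater-than twofold criterion (note the asymmetry
with the inclusive protein cutoff) and requires identification in all six
fractions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FRACTIONS

PHOSPHO_MOD = "Phospho (STY)"


def extract_phospho_sites(evidence: pd.DataFrame) -> pd.DataFrame:
    """Aggregate phospho evidence rows into site units.

    One row per (proteins, phospho_sites) key with per-fraction summed
    intensity, identification flags, the residue(s), and an ambiguity flag
    for peptides shared by several proteins (e.g. paralogs producing the
    same phosphopeptide)."""
    ev = evidence.loc[
        (evidence["modifications"] == PHOSPHO_MOD)
        & ~evidence["is_contaminant"]
        & ~evidence["is_reverse"]
    ]
    if len(ev) == 0:
        return pd.DataFrame(
            columns=["proteins", "phospho_sites", "residues", "ambiguous",
                     "n_fractions", *FRACTIONS, "ASYNC"])
    piv = ev.pivot_table(index=["proteins", "phospho_sites"], columns="sample",
                         values="intensity", aggfunc="sum", fill_value=0.0)
    piv = piv.reindex(columns=[*FRACTIONS, "ASYNC"], fill_value=0.0)
    out = piv.reset_index()
    out["residues"] = out["phospho_sites"].map(
        lambda s: "".join(sorted({tok[0] for tok in s.split(";")})))
    out["ambiguous"] = out["proteins"].str.contains(";")
    out["n_fractions"] = (out[list(FRACTIONS)] > 0).sum(axis=1)
    return out


def detect_regulated_phospho(sites: pd.DataFrame, cutoff: float = 2.0
                             ) -> tuple[pd.DataFrame, dict]:
    """Flag regulated phosphosites among those identified in all six
    fractions: regulated iff max/min > cutoff (strict).

    Returns the testable-site table with fold and flag, plus a summary with
    the regulated share as a rounded integer percent.
    """
    testable = sites.loc[sites["n_fractions"] == len(FRACTIONS)].copy()
    mat = testable[list(FRACTIONS)]
    if (mat.to_numpy() <= 0).any():
        raise ValueError("phosphopeptide intensities must be positive")
    folds = mat.max(axis=1) / mat.min(axis=1)
    testable["fold"] = folds
    testable["regulated"] = folds > cutoff
    n_total = len(testable)
    n_reg = int(testable["regulated"].sum())
    summary = {
        "n_testable": n_total,
        "n_regulated": n_reg,
        "regulated_percent": phospho_regulated_percent(n_reg, n_total),
    }
    return testable, summary


def phospho_regulated_percent(n_regulated: int, n_total: int) -> int:
    """Regulated share as an integer percent, rounded to nearest."""
    if n_total == 0:
        return 0
    return int(round(100.0 * n_regulated / n_total))


def residue_breakdown(sites: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of pS/pT/pY (multi-residue units contribute
    each residue once)."""
    counts = {"S": 0, "T": 0, "Y": 0}
    for res in sites["residues"]:
        for aa in res:
            if aa in counts:
                counts[aa] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": counts,
            "percent": {k: (100.0 * v / total if total else 0.0)
                        for k, v in counts.items()},
        }
    )


def residue_breakdown_and_overlap(
    sites: pd.DataFrame,
    regulated_sites: pd.DataFrame,
    regulated_proteins: set[str],
) -> dict:
    """Residue breakdown for all and regulated sites, plus the overlap
    between proteins with regulated phosphosites and proteins whose
    abundance is regulated. Protein sets are compared at the gene level of
    the leading isoform id."""
    def _genes(frame: pd.DataFrame) -> set[str]:
        out: set[str] = set()
        for prot in frame["proteins"]:
            for iso in prot.split(";"):
                out.add(iso.rsplit("-", 1)[0])
        return out

    phospho_genes = _genes(regulated_sites.loc[regulated_sites.get(
        "regulated", pd.Series(True, index=regulated_sites.index))])
    overlap = phospho_genes & regulated_proteins
    return {
        "breakdown_all": residue_breakdown(sites),
        "breakdown_regulated": residue_breakdown(
            regulated_sites.loc[regulated_sites["regulated"]]
            if "regulated" in regulated_sites else regulated_sites),
        "n_phospho_regulated_proteins": len(phospho_genes),
        "n_abundance_regulated_proteins": len(regulated_proteins),
        "overlap": len(overlap),
        "overlap_genes": sorted(overlap),
    }


@dataclass
class PairedProfileResult:
    phospho_scaled: np.ndarray
    protein_scaled: np.ndarray
    pearson_r: float
    flag: str  # "stoichiometry-constant" | "site-regulated" | "other"


def phospho_vs_protein_profiles(
    site_profile: pd.Series | np.ndarray,
    protein_profile: pd.Series | np.ndarray,
    r_constant: float = 0.8,
    cutoff: float = 2.0,
) -> PairedProfileResult:
    """Max-scaled phosphopeptide vs protein profiles with an interpretation
    flag: ``stoichiometry-constant`` when the profiles track (r >= 0.8),
    ``site-regulated`` when the protein is flat (< cutoff) but the
    phosphopeptide varies (>= cutoff)."""
    ph = np.asarray(site_profile, dtype=float)
    pr = np.asarray(protein_profile, dtype=float)
    if ph.shape != pr.shape:
        raise ValueError("profiles must have the same length")
    ph_s = ph / ph.max()
    pr_s = pr / pr.max()
    r = float(np.corrcoef(ph, pr)[0, 1]) if ph.std() > 0 and pr.std() > 0 \
        else float("nan")
    ph_fold = ph.max() / ph.min()
    pr_fold = pr.max() / pr.min()
    if pr_fold < cutoff and ph_fold >= cutoff:
        flag = "site-regulated"
    elif np.isfinite(r) and r >= r_constant:
        flag = "stoichiometry-constant"
    else:
        flag = "other"
    return PairedProfileResult(ph_s, pr_s, r, flag)
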