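"""Degron motif scanning and annotation-term enrichment.

Motifs: the KEN box (literal tripeptide) and the D-box (R-x-x-L, any two
residues between R and L). All match start positions are reported,
including overlapping ones. Enrichment uses the standard hypergeometric
upper tail with Benjamini-Hochberg adjustment; promoter-frequency tests use
the exact binomial upper tail at a stated background rate.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binomtest, hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: configurable degron regex table; lookahead so overlapping matches count
DEGRON_PATTERNS = {
    "KEN": re.compile(r"(?=(KEN))"),
    "DBOX": re.compile(r"(?=(R..L))"),
}


@dataclass(frozen=True)
class MotifHit:
    isoform_id: str
    motif: str
    position: int  # 1-based start
    match: str


def scan_sequence(sequence: str, patterns: Mapping[str, re.Pattern] | None = None
                  ) -> list[MotifHit]:
    patterns = patterns or DEGRON_PATTERNS
    hits = []
    for motif, pat in patterns.items():
        for m in pat.finditer(sequence):
            hits.append(MotifHit("", motif, m.start() + 1, m.group(1)))
    return hits


def scan_degrons(
    fasta: Mapping[str, str],
    gene_set: Iterable[str] | None = None,
    background: Iterable[str] | None = None,
) -> tuple[list[MotifHit], pd.DataFrame]:
    """Scan isoform sequences for degron motifs.

    Returns all hits plus a per-gene summary (has_KEN / has_DBOX /
    has_either / has_both; a gene carries a motif when any of its isoforms
    does). When ``gene_set`` is given, the summary also reports the fold
    enrichment of the motif frequency in the set versus the background
    gene-set frequency (``summary.attrs``)."""
    hits: list[MotifHit] = []
    per_gene: dict[str, dict[str, bool]] = {}
    for iso_id, seq in fasta.items():
        gene = iso_id.rsplit("-", 1)[0]
        flags = per_gene.setdefault(gene, {"has_KEN": False, "has_DBOX": False})
        for h in scan_sequence(seq):
            hits.append(MotifHit(iso_id, h.motif, h.position, h.match))
            flags[f"has_{h.motif}"] = True
    summary = pd.DataFrame.from_dict(per_gene, orient="index")
    summary["has_either"] = summary["has_KEN"] | summary["has_DBOX"]
    summary["has_both"] = summary["has_KEN"] & summary["has_DBOX"]
    summary.index.name = "gene_id"
    if gene_set is not None:
        genes = [g for g in gene_set if g in summary.index]
        bg = [g for g in (background or summary.index) if g in summary.index]
        for col in ("has_KEN", "has_DBOX", "has_either"):
            set_rate = summary.loc[genes, col].mean() if genes else float("nan")
            bg_rate = summary.loc[bg, col].mean()
            summary.attrs[f"{col}_set_rate"] = float(set_rate)
            summary.attrs[f"{col}_background_rate"] = float(bg_rate)
            summary.attrs[f"{col}_fold_enrichment"] = (
                float(set_rate / bg_rate) if bg_rate > 0 else float("inf"))
    return hits, summary


# ---------------------------------------------------------------------------
# enrichment


def percent_round_half_up(k: int, n: int) -> int:
    """k/n as an integer percent with round-half-up semantics."""
    if n == 0:
        return 0
    return int(math.floor(100.0 * k / n + 0.5))


def enrich_terms(
    gene_set: Iterable[str],
    annotations: pd.DataFrame,
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of annotation terms in a gene
    set against a background universe, BH-adjusted across terms.

    ``annotations`` maps gene_id -> term_id (long frame with ``gene_id`` and
    ``term_id`` columns). Terms with no annotated gene in the background are
    skipped with a warning. The per-term percentage of set genes annotated
    is reported with round-half-up semantics."""
    bg = set(background)
    genes = set(gene_set)
    if not genes <= bg:
        raise ValueError("gene set must be a subset of the background")
    ann = annotations.loc[annotations["gene_id"].isin(bg)]
    N, n = len(bg), len(genes)
    rows = []
    for term, sub in ann.groupby("term_id"):
        term_genes = set(sub["gene_id"])
        K = len(term_genes)
        if K == 0:
            logger.warning("term %s absent from background; skipped", term)
            continue
        k = len(term_genes & genes)
        # upper tail: P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p, percent_round_half_up(k, n)))
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p_value", "percent_in_set"]
    )
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def hypergeom_enumeration(N: int, K: int, n: int, k: int) -> float:
    """Brute-force upper-tail hypergeometric by subset enumeration;
    independent oracle for small universes (N <= ~20)."""
    from itertools import combinations

    universe = list(range(N))
    annotated = set(universe[:K])
    hits = total = 0
    for subset in combinations(universe, n):
        total += 1
        if len(annotated.intersection(subset)) >= k:
            hits += 1
    return hits / total


def tfbs_frequency_test(k: int, n: int, background_rate: float) -> dict:
    """Observed promoter-motif frequency in a gene set versus a stated
    genome-wide background rate: exact binomial upper-tail p."""
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background rate must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = float(binomtest(k, n, background_rate, alternative="greater").pvalue)
    return {
        "k": k,
        "n": n,
        "observed_percent": percent_round_half_up(k, n),
        "background_rate": background_rate,
        "p_value": p,
    }
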