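"""Peptide-to-protein-group aggregation, normalization, iBAQ and cumulative
abundance accounting.

Protein grouping follows the indistinguishability convention: isoforms with
identical detected peptide sets are merged, and an isoform whose peptide set
is a subset of another's is subsumed into that group. Shared peptides are
assigned razor-style to the group with the most peptides (ties broken
lexicographically by group id).

Cross-sample equalization uses median-log-ratio normalization against a
geometric-mean pseudo-reference; the full delayed-normalization LFQ scheme
is intentionally not reimplemented, since downstream analysis depends only
on relative per-sample protein intensities.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SAMPLES
from .digestion import theoretical_peptide_count

#: modifications retained for quantitation (sample-processing artifacts)
QUANT_SAFE_MODIFICATIONS = frozenset({
    "Unmodified", "Deamidation (NQ)", "Gln->pyro-Glu",
})


@dataclass
class ProteinGroup:
    group_id: str
    members: tuple[str, ...]
    gene_id: str
    peptides: frozenset[str]

    @property
    def peptide_count(self) -> int:
        return len(self.peptides)


def quantifiable_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Evidence rows eligible for protein quantitation: unmodified peptides
    plus modifications known to occur during sample processing; phospho and
    other variable modifications are excluded."""
    keep = evidence["modifications"].isin(QUANT_SAFE_MODIFICATIONS)
    return evidence.loc[keep]


def group_proteins(evidence: pd.DataFrame) -> list[ProteinGroup]:
    """Merge isoforms indistinguishable by their detected peptide sets.

    Identical sets merge into one group; a proper-subset peptide set is
    subsumed into the group with the largest superset (ties: lexicographic
    smallest group). Grouping is computed on quantifiable, non-decoy,
    non-contaminant evidence.
    """
    ev = quantifiable_evidence(evidence)

    iso_peps: dict[str, set[str]] = {}
    for proteins, seq in zip(ev["proteins"], ev["sequence"]):
        for iso in proteins.split(";"):
            iso_peps.setdefault(iso, set()).add(seq)

    # merge identical peptide sets
    by_set: dict[frozenset, list[str]] = {}
    for iso, peps in iso_peps.items():
        by_set.setdefault(frozenset(peps), []).append(iso)

    entries = [(peps, tuple(sorted(isos))) for peps, isos in by_set.items()]
    entries.sort(key=lambda e: (-len(e[0]), e[1]))

    # inverted index peptide -> entry indices, for fast superset lookup
    pep_index: dict[str, set[int]] = {}
    for i, (peps, _) in enumerate(entries):
        for p in peps:
            pep_index.setdefault(p, set()).add(i)

    absorbed_into: dict[int, int] = {}
    for i, (peps, _) in enumerate(entries):
        candidates: set[int] | None = None
        for p in peps:
            hits = pep_index[p]
            candidates = set(hits) if candidates is None else candidates & hits
            if len(candidates) == 1:
                break
        supersets = [j for j in candidates or () if j != i and len(entries[j][0]) > len(peps)]
        if supersets:
            # largest superset, ties by lexicographic member order
            j = min(supersets, key=lambda j: (-len(entries[j][0]), entries[j][1]))
            absorbed_into[i] = j

    groups: list[ProteinGroup] = []
    members_of: dict[int, list[str]] = {}
    for i, (_, isos) in enumerate(entries):
        root = i
        while root in absorbed_into:
            root = absorbed_into[root]
        members_of.setdefault(root, []).extend(isos)
    for root in sorted(members_of):
        peps, _ = entries[root]
        members = tuple(sorted(members_of[root]))
        gene = members[0].rsplit("-", 1)[0]
        groups.append(ProteinGroup(members[0], members, gene, peps))
    groups.sort(key=lambda g: g.group_id)
    return groups


def group_flags(evidence: pd.DataFrame, groups: Sequence[ProteinGroup]
                ) -> pd.DataFrame:
    """Contaminant / reverse-decoy flags per group: a group is flagged when
    any member isoform appears in a flagged evidence row."""
    con: set[str] = set()
    rev: set[str] = set()
    flagged = evidence.loc[evidence["is_contaminant"] | evidence["is_reverse"]]
    for proteins, is_c, is_r in zip(flagged["proteins"],
                                    flagged["is_contaminant"],
                                    flagged["is_reverse"]):
        for iso in proteins.split(";"):
            if is_c:
                con.add(iso)
            if is_r:
                rev.add(iso)
    rows = {
        g.group_id: (any(m in con for m in g.members),
                     any(m in rev for m in g.members))
        for g in groups
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["is_contaminant", "is_reverse"])


def _razor_assignment(groups: Sequence[ProteinGroup]) -> dict[str, str]:
    """Peptide -> owning group id; shared peptides go to the group with the
    most peptides (ties broken lexicographically by group id)."""
    owner: dict[str, tuple[int, str]] = {}
    for g in sorted(groups, key=lambda g: g.group_id):
        key = (-g.peptide_count, g.group_id)
        for p in g.peptides:
            if p not in owner or key < owner[p]:
                owner[p] = key
    return {p: gid for p, (_, gid) in owner.items()}


def aggregate_intensities(
    evidence: pd.DataFrame,
    groups: Sequence[ProteinGroup],
    samples: Sequence[str] = SAMPLES,
) -> pd.DataFrame:
    """Protein intensity per sample = sum of razor-assigned quantifiable
    peptide intensities. Returns a groups x samples frame (absent
    observations are 0)."""
    ev = quantifiable_evidence(evidence)
    owner = _razor_assignment(groups)
    ev = ev.loc[ev["sequence"].isin(owner.keys())].copy()
    ev["group_id"] = ev["sequence"].map(owner)
    mat = (
        ev.pivot_table(index="group_id", columns="sample", values="intensity",
                       aggfunc="sum", fill_value=0.0)
        .reindex(index=[g.group_id for g in groups], columns=list(samples))
        .fillna(0.0)
    )
    mat.index.name = "group_id"
    return mat


def median_ratio_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Equalize samples by the median log-ratio to a geometric-mean
    pseudo-reference (computed on proteins observed in every sample).

    Idempotent: normalized data has unit size factors.
    """
    mat = intensities.to_numpy(dtype=float)
    complete = (mat > 0).all(axis=1)
    if not complete.any():
        raise ValueError("no protein observed in every sample; cannot normalize")
    logm = np.log(mat[complete])
    ref = logm.mean(axis=1, keepdims=True)  # geometric-mean pseudo-reference
    log_factors = np.median(logm - ref, axis=0)
    # anchor the geometric mean of the size factors at 1 so the
    # normalization is idempotent
    factors = np.exp(log_factors - log_factors.mean())
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate size factors; check for empty samples")
    out = intensities / factors
    return out


def aggregate_and_normalize(
    evidence: pd.DataFrame,
    groups: Sequence[ProteinGroup],
    samples: Sequence[str] = SAMPLES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw and median-ratio-normalized protein intensity matrices."""
    raw = aggregate_intensities(evidence, groups, samples)
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total intensity: {empty}")
    return raw, median_ratio_normalize(raw)


# ---------------------------------------------------------------------------
# iBAQ


def compute_ibaq(
    intensities: pd.DataFrame,
    groups: Sequence[ProteinGroup],
    fasta: Mapping[str, str],
    min_length: int = 7,
    max_length: int = 30,
) -> pd.DataFrame:
    """iBAQ per group per sample: summed intensity divided by the count of
    theoretically observable tryptic peptides (length window 7-30, fully
    cleaved) of the group's representative (longest) member sequence.

    Groups with zero theoretical peptides get NaN iBAQ and a flag.
    """
    counts, flags = {}, {}
    for g in groups:
        seqs = [fasta[m] for m in g.members if m in fasta]
        if not seqs:
            counts[g.group_id], flags[g.group_id] = 0, True
            continue
        rep = max(seqs, key=len)
        c = theoretical_peptide_count(rep, min_length, max_length)
        counts[g.group_id] = c
        flags[g.group_id] = c == 0
    count_s = pd.Series(counts).reindex(intensities.index)
    ibaq = intensities.div(count_s.replace(0, np.nan), axis=0)
    ibaq["theoretical_peptides"] = count_s
    ibaq["ibaq_undefined"] = pd.Series(flags).reindex(intensities.index)
    return ibaq


# ---------------------------------------------------------------------------
# cumulative abundance


@dataclass
class AbundanceSummary:
    """Ranked-abundance accounting: how few proteins carry most of the
    summed protein mass, plus quartile bins of log abundance."""

    n_proteins: int
    k50: int
    k90: int
    ranked: pd.Series
    quartile_bins: pd.Series

    def k(self, q: float) -> int:
        share = self.ranked.cumsum() / self.ranked.sum()
        return int(np.searchsorted(share.to_numpy(), q) + 1)


def cumulative_abundance(abundances: pd.Series) -> AbundanceSummary:
    """Sort descending; k(q) is the smallest k whose cumulative share of the
    summed abundance reaches q. Also bins log10 abundance into quartiles
    (labels Q1..Q4, Q4 = most abundant) for enrichment reporting."""
    ab = abundances.dropna()
    ab = ab[ab > 0]
    if len(ab) == 0:
        raise ValueError("no positive abundances")
    ranked = ab.sort_values(ascending=False)
    share = ranked.cumsum() / ranked.sum()
    k50 = int(np.searchsorted(share.to_numpy(), 0.50) + 1)
    k90 = int(np.searchsorted(share.to_numpy(), 0.90) + 1)
    # rank-based so ties cannot collapse bin edges
    quartiles = pd.qcut(np.log10(ab).rank(method="first"), 4,
                        labels=["Q1", "Q2", "Q3", "Q4"])
    return AbundanceSummary(len(ab), k50, k90, ranked,
                            pd.Series(quartiles, index=ab.index))


def abundance_group_percentages(k50: int, k90: int, total: int) -> dict[str, float]:
    """Percentage breakdown of the three cumulative-mass groups
    (top 50% of mass / next 40% / remainder) given their counts."""
    return {
        "top50_count": k50,
        "next40_count": k90 - k50,
        "rest_count": total - k90,
        "top50_pct": round(100.0 * k50 / total, 1),
        "next40_pct": round(100.0 * (k90 - k50) / total, 1),
        "rest_pct": round(100.0 * (total - k90) / total, 1),
    }
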