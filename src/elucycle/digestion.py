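"""In-silico proteolysis, peptide-to-sequence mapping and coverage accounting.

Two proteases are modeled: Lys-C (cleaves C-terminal to K) and a double
digest referred to as Trypsin-DD (cleaves C-terminal to K or R). The tryptic
rule follows the trypsin/P convention by default, i.e. cleavage before
proline is allowed; classic trypsin (no cleavage before P) is available as
an option.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

LYSC = "LysC"
TRYPSIN_DD = "TrypsinDD"


@dataclass(frozen=True)
class DigestSpec:
    """Protease and enumeration bounds for an in-silico digest."""

    protease: str = TRYPSIN_DD
    missed_cleavages: int = 2
    min_length: int = 1
    max_length: int = 10**9
    before_proline: bool = True  # trypsin/P convention

    def __post_init__(self):
        if self.protease not in (LYSC, TRYPSIN_DD):
            raise ValueError(f"unknown protease {self.protease!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid length bounds")


@dataclass(frozen=True)
class Peptide:
    """A digest product with 0-based half-open coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed: int


def cleavage_sites(sequence: str, spec: DigestSpec) -> list[int]:
    """Positions after which the protease cuts (0-based index of the residue
    preceding the scissile bond)."""
    targets = "K" if spec.protease == LYSC else "KR"
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in targets:
            if not spec.before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest_sequence(sequence: str, spec: DigestSpec) -> list[Peptide]:
    """Enumerate digest peptides with up to ``spec.missed_cleavages`` internal
    sites, within the spec's length bounds.

    Raises ``ValueError`` on sequences containing non-standard residues; the
    caller is expected to drop the record and log it.
    """
    if not sequence:
        return []
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in sequence")
    cuts = cleavage_sites(sequence, spec)
    # boundaries of 0-missed-cleavage fragments
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(sequence)]
    peptides = []
    n = len(starts)
    for i in range(n):
        for m in range(spec.missed_cleavages + 1):
            j = i + m
            if j >= n:
                break
            s, e = starts[i], ends[j]
            if spec.min_length <= e - s <= spec.max_length:
                peptides.append(Peptide(sequence[s:e], s, e, m))
    return peptides


def theoretical_peptide_count(
    sequence: str, min_length: int = 7, max_length: int = 30
) -> int:
    """Count of fully cleaved tryptic peptides in the iBAQ length window."""
    spec = DigestSpec(TRYPSIN_DD, missed_cleavages=0,
                      min_length=min_length, max_length=max_length)
    return len(digest_sequence(sequence, spec))


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageMap:
    """Merged covered intervals per isoform, 0-based half-open coordinates."""

    intervals: dict[str, list[tuple[int, int]]]
    lengths: dict[str, int]

    def covered_residues(self, isoform: str) -> int:
        return sum(e - s for s, e in self.intervals.get(isoform, []))

    def coverage_fraction(self, isoform: str) -> float:
        return self.covered_residues(isoform) / self.lengths[isoform]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def build_peptide_index(
    fasta: Mapping[str, str], missed_cleavages: int = 3,
    min_length: int = 5, max_length: int = 60,
) -> dict[str, list[str]]:
    """Digest-based inverted index: peptide sequence -> isoform ids.

    Used to avoid quadratic substring search when mapping observed peptides
    back to an assembled proteome; peptides outside the index fall back to a
    brute-force scan in :func:`compute_coverage`.
    """
    index: dict[str, list[str]] = {}
    for iso, seq in fasta.items():
        seen: set[str] = set()
        for spec in (
            DigestSpec(TRYPSIN_DD, missed_cleavages, min_length, max_length),
            DigestSpec(LYSC, missed_cleavages, min_length, max_length),
        ):
            for pep in digest_sequence(seq, spec):
                if pep.sequence not in seen:
                    seen.add(pep.sequence)
                    index.setdefault(pep.sequence, []).append(iso)
    return index


@dataclass
class CoverageSummary:
    coverage: CoverageMap
    per_isoform: pd.DataFrame
    mean_coverage: float
    unmapped_peptides: list[str] = field(default_factory=list)


def compute_coverage(
    peptides: Iterable[str],
    fasta: Mapping[str, str],
    index: dict[str, list[str]] | None = None,
) -> CoverageSummary:
    """Map observed peptides onto isoform sequences and merge the covered
    intervals.

    Peptides shared across isoforms contribute coverage to every isoform
    they match; all occurrences within a sequence are counted. Unmappable
    peptides are excluded and reported in the summary diagnostics.
    """
    if index is None:
        index = build_peptide_index(fasta)
    raw: dict[str, list[tuple[int, int]]] = {iso: [] for iso in fasta}
    unmapped = []
    for pep in set(peptides):
        isoforms = index.get(pep)
        if isoforms is None:
            isoforms = [iso for iso, seq in fasta.items() if pep in seq]
        hit = False
        for iso in isoforms:
            for s in _find_all(fasta[iso], pep):
                raw[iso].append((s, s + len(pep)))
                hit = True
        if not hit:
            unmapped.append(pep)
    intervals = {iso: merge_intervals(ivs) for iso, ivs in raw.items() if ivs}
    lengths = {iso: len(seq) for iso, seq in fasta.items()}
    cov = CoverageMap(intervals, lengths)
    rows = []
    for iso in intervals:
        covered = cov.covered_residues(iso)
        rows.append((iso, lengths[iso], covered, covered / lengths[iso]))
    per_iso = pd.DataFrame(rows, columns=["isoform", "length", "covered", "coverage"])
    mean_cov = float(per_iso["coverage"].mean()) if len(per_iso) else float("nan")
    return CoverageSummary(cov, per_iso, mean_cov, sorted(unmapped))


# ---------------------------------------------------------------------------
# protease complementarity


@dataclass(frozen=True)
class ProteaseVenn:
    lysc_only: int
    trypsin_only: int
    shared: int

    @property
    def total(self) -> int:
        return self.lysc_only + self.trypsin_only + self.shared

    def percentages(self) -> dict[str, float]:
        t = self.total
        return {
            "lysc_only": 100.0 * self.lysc_only / t,
            "trypsin_only": 100.0 * self.trypsin_only / t,
            "shared": 100.0 * self.shared / t,
        }

    def relative_increase_percent(self) -> int:
        """Lys-C-only gain over the Trypsin-DD total, truncated to an
        integer percent."""
        denom = self.trypsin_only + self.shared
        if denom == 0:
            return 0
        return int(100.0 * self.lysc_only / denom)


def partition_by_protease(peptide_proteases: Mapping[str, set[str]]) -> ProteaseVenn:
    """Venn partition of unique peptides by the protease(s) that produced
    them."""
    lysc_only = trypsin_only = shared = 0
    for labels in peptide_proteases.values():
        has_l = LYSC in labels
        has_t = TRYPSIN_DD in labels
        if has_l and has_t:
            shared += 1
        elif has_l:
            lysc_only += 1
        elif has_t:
            trypsin_only += 1
    return ProteaseVenn(lysc_only, trypsin_only, shared)


def venn_from_percentages(total: int, lysc_only_pct: float, trypsin_only_pct: float) -> ProteaseVenn:
    """Reconstruct a Venn partition from a printed total and two printed
    percentages (remainder = shared)."""
    lysc = round(total * lysc_only_pct / 100.0)
    tryp = round(total * trypsin_only_pct / 100.0)
    return ProteaseVenn(lysc, tryp, total - lysc - tryp)


# ---------------------------------------------------------------------------
# composition bias

RESIDUE_ORDER = tuple(sorted(STANDARD_RESIDUES))


def residue_frequencies(sequences: Iterable[str]) -> np.ndarray:
    """Length-20 residue frequency vector (order: alphabetical)."""
    counts = np.zeros(len(RESIDUE_ORDER))
    lut = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}
    total = 0
    for seq in sequences:
        for aa in seq:
            i = lut.get(aa)
            if i is not None:
                counts[i] += 1
                total += 1
    if total == 0:
        raise ValueError("no standard residues in the sequence set")
    return counts / total


def composition_bias(
    observed: Mapping[str, str] | Iterable[str],
    reference: Mapping[str, str] | Iterable[str],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Residue frequency vectors of an identified set vs. the search
    database, plus their Pearson correlation."""
    obs_seqs = observed.values() if isinstance(observed, Mapping) else list(observed)
    ref_seqs = reference.values() if isinstance(reference, Mapping) else list(reference)
    if not obs_seqs or not ref_seqs:
        raise ValueError("both sequence sets must be non-empty")
    f_obs = residue_frequencies(obs_seqs)
    f_ref = residue_frequencies(ref_seqs)
    r = float(np.corrcoef(f_obs, f_ref)[0, 1])
    return f_obs, f_ref, r
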