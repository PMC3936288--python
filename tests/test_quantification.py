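import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from elucycle.config import SAMPLES
from elucycle.quantification import (
    ProteinGroup,
    abundance_group_percentages,
    aggregate_and_normalize,
    aggregate_intensities,
    compute_ibaq,
    cumulative_abundance,
    group_proteins,
    group_flags,
    median_ratio_normalize,
)


def _evidence_from_map(iso_peps: dict[str, list[str]], intensity=1.0):
    """Build a minimal evidence frame from isoform -> peptide lists."""
    pep_isos: dict[str, set[str]] = {}
    for iso, peps in iso_peps.items():
        for p in peps:
            pep_isos.setdefault(p, set()).add(iso)
    rows = []
    for pep, isos in sorted(pep_isos.items()):
        for sample in SAMPLES:
            rows.append({
                "peptide_id": pep, "sequence": pep, "protease": "TrypsinDD",
                "gene_id": sorted(isos)[0].rsplit("-", 1)[0],
                "proteins": ";".join(sorted(isos)),
                "modifications": "Unmodified", "phospho_sites": "",
                "is_contaminant": False, "is_reverse": False,
                "sample": sample, "intensity": intensity, "msms_count": 1,
            })
    return pd.DataFrame(rows)


def _oracle_groups(iso_peps: dict[str, set[str]]):
    """Exhaustive-comparison grouping oracle: merge identical sets, then
    repeatedly absorb any set that is a subset of another (largest superset,
    lexicographic ties)."""
    sets: dict[frozenset, list[str]] = {}
    for iso, peps in iso_peps.items():
        sets.setdefault(frozenset(peps), []).append(iso)
    entries = [[peps, sorted(isos)] for peps, isos in sets.items()]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.permutations(range(len(entries)), 2):
            if entries[a][0] < entries[b][0]:  # proper subset
                supers = [j for j in range(len(entries))
                          if j != a and entries[a][0] < entries[j][0]]
                best = min(supers, key=lambda j: (-len(entries[j][0]),
                                                  entries[j][1]))
                entries[best][1] = sorted(entries[best][1] + entries[a][1])
                del entries[a]
                changed = True
                break
    return sorted(frozenset(e[1]) for e in entries)


class TestGrouping:
    def test_indistinguishable_isoforms_merge(self):
        ev = _evidence_from_map({"A-1": ["PEPTIDEK", "SEQK", "THIRDK"],
                                 "A-2": ["PEPTIDEK", "SEQK", "THIRDK"]})
        groups = group_proteins(ev)
        assert len(groups) == 1
        assert groups[0].members == ("A-1", "A-2")

    def test_subset_subsumption(self):
        ev = _evidence_from_map({"A-1": ["P1", "P2"], "A-2": ["P1", "P2", "P3"]})
        groups = group_proteins(ev)
        assert len(groups) == 1
        assert set(groups[0].members) == {"A-1", "A-2"}
        assert groups[0].peptides == frozenset({"P1", "P2", "P3"})

    def test_unique_peptides_keep_groups_separate(self):
        ev = _evidence_from_map({"A-1": ["SHARED", "P4"], "A-2": ["SHARED", "P5"]})
        groups = group_proteins(ev)
        assert len(groups) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"PEP{i}" for i in range(12)]
        iso_peps = {
            f"G-{i}": set(rng.choice(universe, size=rng.integers(1, 6),
                                     replace=False))
            for i in range(1, 9)
        }
        ev = _evidence_from_map({k: sorted(v) for k, v in iso_peps.items()})
        got = sorted(tuple(sorted(g.members)) for g in group_proteins(ev))
        oracle = sorted(tuple(sorted(s)) for s in _oracle_groups(iso_peps))
        assert got == oracle

    def test_contaminant_groups_flagged(self, small_evidence):
        groups = group_proteins(small_evidence)
        flags = group_flags(small_evidence, groups)
        con_groups = flags.index[flags["is_contaminant"]]
        assert len(con_groups) > 0
        assert all(g.startswith("CON_") for g in con_groups)


class TestAggregation:
    def test_summation(self):
        ev = _evidence_from_map({"A-1": ["P1", "P2"]})
        ev.loc[ev["sequence"] == "P1", "intensity"] = 2.0
        ev.loc[ev["sequence"] == "P2", "intensity"] = 3.0
        groups = group_proteins(ev)
        mat = aggregate_intensities(ev, groups)
        assert mat.loc["A-1", "F1"] == pytest.approx(5.0)

    def test_phospho_rows_excluded(self):
        ev = _evidence_from_map({"A-1": ["P1", "P2"]})
        extra = ev.loc[ev["sequence"] == "P1"].copy()
        extra["modifications"] = "Phospho (STY)"
        extra["intensity"] = 100.0
        ev2 = pd.concat([ev, extra], ignore_index=True)
        groups = group_proteins(ev2)
        mat = aggregate_intensities(ev2, groups)
        assert mat.loc["A-1", "F1"] == pytest.approx(2.0)

    def test_deamidation_retained_oxidation_excluded(self):
        ev = _evidence_from_map({"A-1": ["P1"]})
        for mod, inten in (("Deamidation (NQ)", 10.0), ("Oxidation (M)", 100.0)):
            extra = ev.loc[ev["sequence"] == "P1"].copy()
            extra["modifications"] = mod
            extra["intensity"] = inten
            ev = pd.concat([ev, extra], ignore_index=True)
        groups = group_proteins(ev)
        mat = aggregate_intensities(ev, groups)
        assert mat.loc["A-1", "F1"] == pytest.approx(1.0 + 10.0)

    def test_razor_assignment_to_largest_group(self):
        # SHARED belongs to A-1 (3 peptides) not B-1 (2 peptides)
        ev = _evidence_from_map({"A-1": ["SHARED", "P1", "P2"],
                                 "B-1": ["SHARED", "P3"]})
        groups = group_proteins(ev)
        mat = aggregate_intensities(ev, groups)
        assert mat.loc["A-1", "F1"] == pytest.approx(3.0)
        assert mat.loc["B-1", "F1"] == pytest.approx(1.0)

    def test_no_peptide_counted_twice(self):
        ev = _evidence_from_map({"A-1": ["SHARED", "P1"], "B-1": ["SHARED", "P2"]})
        groups = group_proteins(ev)
        mat = aggregate_intensities(ev, groups)
        total_rows = ev.loc[ev["sample"] == "F1", "intensity"].sum()
        assert mat["F1"].sum() == pytest.approx(total_rows)

    def test_global_scaling_removed_by_normalization(self):
        # every peptide in F2 is exactly twice its F1 value: after
        # normalization the two samples' protein intensities are equal
        ev = _evidence_from_map({f"G{i:02d}-1": [f"P{i}A", f"P{i}B"]
                                 for i in range(20)})
        rng = np.random.default_rng(0)
        per_pep = {p: rng.uniform(1, 10) for p in ev["sequence"].unique()}
        ev["intensity"] = ev["sequence"].map(per_pep)
        ev.loc[ev["sample"] == "F2", "intensity"] *= 2.0
        groups = group_proteins(ev)
        _, norm = aggregate_and_normalize(ev, groups)
        np.testing.assert_allclose(norm["F2"], norm["F1"], rtol=1e-12)

    def test_normalization_idempotent(self, small_evidence):
        groups = group_proteins(small_evidence)
        _, norm = aggregate_and_normalize(small_evidence, groups)
        again = median_ratio_normalize(norm)
        pd.testing.assert_frame_equal(norm, again)

    def test_zero_sample_errors(self):
        ev = _evidence_from_map({"A-1": ["P1", "P2"]})
        ev.loc[ev["sample"] == "F3", "intensity"] = 0.0
        groups = group_proteins(ev)
        with pytest.raises(ValueError, match="zero total intensity"):
            aggregate_and_normalize(ev, groups)


class TestIbaq:
    FASTA = {"A-1": "ACDEFGHIK" + "LMNPQSTVWYK" + "AK"}  # 2 peptides in window

    def _mat(self, value=1000.0):
        return pd.DataFrame({s: [value] for s in SAMPLES}, index=["A-1"])

    def _groups(self):
        return [ProteinGroup("A-1", ("A-1",), "A", frozenset({"X"}))]

    def test_definition(self):
        ibaq = compute_ibaq(self._mat(1000.0), self._groups(), self.FASTA)
        assert ibaq.loc["A-1", "F1"] == pytest.approx(500.0)

    def test_linearity(self):
        one = compute_ibaq(self._mat(1000.0), self._groups(), self.FASTA)
        two = compute_ibaq(self._mat(2000.0), self._groups(), self.FASTA)
        assert two.loc["A-1", "F1"] == pytest.approx(2 * one.loc["A-1", "F1"])

    def test_zero_theoretical_flagged(self):
        fasta = {"A-1": "MKAK"}  # no peptide in the 7-30 window
        ibaq = compute_ibaq(self._mat(), self._groups(), fasta)
        assert bool(ibaq.loc["A-1", "ibaq_undefined"])
        assert np.isnan(ibaq.loc["A-1", "F1"])

    def test_ibaq_tracks_copy_number_noiseless(self, noiseless_truth, noiseless_evidence):
        groups = group_proteins(noiseless_evidence)
        _, norm = aggregate_and_normalize(noiseless_evidence, groups)
        ibaq = compute_ibaq(norm, groups, noiseless_truth.fasta)
        iso = noiseless_truth.isoforms
        single = iso.groupby("gene_id").filter(lambda s: len(s) == 1)
        common = ibaq.index.intersection(single.index)
        truth_copy = noiseless_truth.genes.loc[
            single.loc[common, "gene_id"], "copy_number"]
        rho = spearmanr(ibaq.loc[common, "ASYNC"], truth_copy).statistic
        assert rho >= 0.99


class TestCumulativeAbundance:
    def test_small_example(self):
        summary = cumulative_abundance(pd.Series([50, 30, 10, 5, 5]))
        assert summary.k50 == 1
        assert summary.k90 == 3

    def test_uniform(self):
        n = 7
        summary = cumulative_abundance(pd.Series([1.0] * n))
        assert summary.k50 == int(np.ceil(n / 2))

    def test_k_monotone_in_q(self, small_evidence):
        groups = group_proteins(small_evidence)
        mat = aggregate_intensities(small_evidence, groups)
        summary = cumulative_abundance(mat["ASYNC"])
        ks = [summary.k(q) for q in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert ks == sorted(ks)
        assert summary.k50 <= summary.k90 <= summary.n_proteins

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            cumulative_abundance(pd.Series([0.0, 0.0]))

    def test_printed_group_counts_partition(self):
        # 90 + 1028 + 9075 proteins partition the 10,193-protein set
        pct = abundance_group_percentages(k50=90, k90=90 + 1028, total=10_193)
        assert pct["top50_count"] + pct["next40_count"] + pct["rest_count"] == 10_193
        assert pct["top50_pct"] == 0.9
        assert pct["next40_pct"] == 10.1

    def test_quartile_bins(self):
        summary = cumulative_abundance(pd.Series(np.logspace(0, 3, 40)))
        assert set(summary.quartile_bins.cat.categories) == {"Q1", "Q2", "Q3", "Q4"}
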