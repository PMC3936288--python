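import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from elucycle.config import (
    DEFAULT_FRACTIONS,
    FRACTIONS,
    FractionMeta,
    SimulationConfig,
    cell_count_weights,
    composition_matrix,
)
from elucycle.synthetic import (
    generate_evidence_table,
    generate_ground_truth,
    generate_rna_table,
    max_fraction_fold,
    solve_phase_shape,
    write_outputs,
)


class TestConfigValidation:
    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimulationConfig(n_genes=5)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(peak_phase_mix=(0.5, 0.2, 0.2, 0.2))

    def test_sty_default_sums_to_one(self):
        cfg = SimulationConfig()
        assert sum(cfg.sty_mix) == pytest.approx(1.0, abs=1e-12)

    def test_fold_range_lower_bound(self):
        with pytest.raises(ValueError, match="fold_range"):
            SimulationConfig(fold_range=(0.5, 4.0))

    def test_fraction_meta_validates(self):
        with pytest.raises(ValueError, match="cell count"):
            FractionMeta("F1", -1, (0.9, 0.08, 0.02))
        with pytest.raises(ValueError, match="sum to 1"):
            FractionMeta("F1", 1e6, (0.9, 0.2, 0.02))


class TestPhaseShapes:
    @pytest.mark.parametrize("cls", ["G1", "S", "G2M", "G2M+G1"])
    def test_solved_shape_hits_target_fold(self, cls):
        M = composition_matrix(DEFAULT_FRACTIONS)
        target = min(2.2, 0.9 * max_fraction_fold(cls, M))
        shape = solve_phase_shape(cls, target, M)
        mixed = M @ shape
        assert mixed.max() / mixed.min() == pytest.approx(target, rel=1e-9)

    def test_unreachable_fold_raises(self):
        M = composition_matrix(DEFAULT_FRACTIONS)
        with pytest.raises(ValueError, match="unreachable"):
            solve_phase_shape("G2M+G1", 5.0, M)

    def test_dual_peak_shape_depresses_s(self):
        M = composition_matrix(DEFAULT_FRACTIONS)
        shape = solve_phase_shape("G2M+G1", 2.0, M)
        assert shape[1] < shape[0] and shape[1] < shape[2]


class TestGroundTruth:
    def test_async_is_exact_weighted_mixture(self, small_truth):
        ge = small_truth.gene_expected()
        w = cell_count_weights(small_truth.fractions)
        pred = ge[list(FRACTIONS)].to_numpy() @ w
        np.testing.assert_allclose(pred, ge["ASYNC"].to_numpy(), rtol=1e-12)

    def test_no_regulation_when_frac_zero(self):
        cfg = SimulationConfig(n_genes=150, seed=3, frac_regulated=0.0)
        truth = generate_ground_truth(cfg)
        assert (truth.genes["fraction_fold"] < 2).all()
        assert (truth.isoforms["iso_fold"] < 2).all()

    def test_regulated_genes_reach_cutoff(self, small_truth):
        reg = small_truth.genes.loc[small_truth.genes["regulated"]]
        assert (reg["fraction_fold"] >= 2.0).all()

    def test_unregulated_genes_below_cutoff(self):
        cfg = SimulationConfig(n_genes=150, seed=5, discordant_rate=0.0)
        truth = generate_ground_truth(cfg)
        flat = truth.genes.loc[~truth.genes["regulated"]]
        assert (flat["fraction_fold"] < 2).all()

    def test_seed_determinism(self, small_cfg, small_truth):
        again = generate_ground_truth(small_cfg)
        pd.testing.assert_frame_equal(small_truth.genes, again.genes)
        pd.testing.assert_frame_equal(small_truth.isoforms, again.isoforms)

    def test_copula_spearman_near_target(self):
        cfg = SimulationConfig(n_genes=5000, seed=13)
        truth = generate_ground_truth(cfg)
        rho = spearmanr(np.log10(truth.genes["copy_number"]),
                        np.log10(truth.genes["rna_ASYNC"])).statistic
        assert rho == pytest.approx(0.63, abs=0.03)

    def test_peak_class_mix_recovered(self):
        cfg = SimulationConfig(n_genes=4000, seed=17, frac_regulated=0.5)
        truth = generate_ground_truth(cfg)
        reg = truth.genes.loc[truth.genes["regulated"], "peak_class"]
        props = reg.value_counts(normalize=True)
        for cls, target in zip(("G1", "S", "G2M", "G2M+G1"),
                               (0.17, 0.27, 0.49, 0.07)):
            # binomial 99% CI at n ~ 2000
            tol = 3 * np.sqrt(target * (1 - target) / len(reg))
            assert props[cls] == pytest.approx(target, abs=tol)

    def test_motifs_in_coordinated_genes(self, small_truth):
        coord = small_truth.genes.index[small_truth.genes["coordinated"]]
        for gid in coord:
            seqs = small_truth.isoforms.loc[
                small_truth.isoforms["gene_id"] == gid, "sequence"]
            for seq in seqs:
                assert "KEN" in seq
                assert any(seq[i] == "R" and seq[i + 3] == "L"
                           for i in range(len(seq) - 3))

    def test_coordinated_rna_fold(self, small_truth):
        genes = small_truth.genes
        coord = genes.loc[genes["coordinated"]]
        if len(coord):
            rna = coord[["rna_G1", "rna_S", "rna_G2M"]]
            fold = rna.max(axis=1) / rna.min(axis=1)
            assert (fold >= 1.5).all()


class TestEvidence:
    def test_determinism_byte_identical(self, tmp_path, noiseless_truth, noiseless_cfg):
        ev1 = generate_evidence_table(noiseless_truth, noiseless_cfg)
        ev2 = generate_evidence_table(noiseless_truth, noiseless_cfg)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        ev1.to_csv(p1, sep="\t", index=False, float_format="%.8g")
        ev2.to_csv(p2, sep="\t", index=False, float_format="%.8g")
        assert p1.read_bytes() == p2.read_bytes()

    def test_noiseless_aggregation_proportional_to_expected(
            self, noiseless_truth, noiseless_evidence):
        # summed protein intensities reproduce expected intensities exactly
        # (up to the per-protein sum of response factors)
        ev = noiseless_evidence
        iso_single = noiseless_truth.isoforms.groupby("gene_id").size()
        single_genes = set(iso_single.index[iso_single == 1])
        expected = noiseless_truth.gene_expected()
        got = ev.loc[ev["gene_id"].isin(single_genes)].pivot_table(
            index="gene_id", columns="sample", values="intensity", aggfunc="sum")
        for gid in list(single_genes)[:30]:
            ratio = got.loc[gid] / expected.loc[gid]
            assert ratio.max() / ratio.min() == pytest.approx(1.0, rel=1e-9)

    def test_sty_mix_recovered(self):
        cfg = SimulationConfig(n_genes=400, seed=23, phospho_rate=0.4,
                               multisite_rate=0.0, seq_length_median=150)
        truth = generate_ground_truth(cfg)
        ev = generate_evidence_table(truth, cfg)
        ph = ev.loc[ev["modifications"] == "Phospho (STY)",
                    ["sequence", "phospho_sites"]].drop_duplicates()
        assert len(ph) >= 2000
        residues = ph["phospho_sites"].str[0]
        props = residues.value_counts(normalize=True)
        for aa, target in zip("STY", cfg.sty_mix):
            assert props[aa] == pytest.approx(target, abs=0.03)

    def test_contaminants_and_decoys_present(self, small_evidence):
        assert small_evidence["is_contaminant"].any()
        assert small_evidence["is_reverse"].any()

    def test_phospho_positions_consistent_with_sequence(self, small_truth,
                                                        small_evidence):
        fasta = small_truth.fasta
        ph = small_evidence.loc[
            small_evidence["modifications"] == "Phospho (STY)"].head(200)
        for proteins, sites in zip(ph["proteins"], ph["phospho_sites"]):
            lead = fasta[proteins.split(";")[0]]
            for tok in sites.split(";"):
                res, pos = tok[0], int(tok[1:])
                assert lead[pos - 1] == res


class TestRna:
    def test_replicate_correlation_above_090(self, small_truth, small_rna):
        piv = small_rna.pivot_table(index="gene_id", columns=["sample", "bio_rep", "tech_rep"],
                                    values="fpkm")
        a = np.log10(piv[("ASYNC", 1, 1)])
        b = np.log10(piv[("ASYNC", 2, 1)])
        assert pearsonr(a, b).statistic > 0.90

    def test_zero_noise_gives_perfect_replicates(self, small_truth):
        cfg = small_truth.config.replace(rna_noise_cv=0.0)
        rna = generate_rna_table(small_truth, cfg)
        piv = rna.pivot_table(index="gene_id", columns=["sample", "bio_rep", "tech_rep"],
                              values="fpkm")
        r = pearsonr(piv[("G1", 1, 1)], piv[("G1", 2, 2)]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_histone_flag_present(self, small_rna):
        assert small_rna["is_histone"].any()


class TestOutputs:
    def test_write_outputs_round_trip(self, tmp_path, small_truth, small_evidence, small_rna):
        from elucycle import io

        paths = write_outputs(small_truth, small_evidence, small_rna, tmp_path)
        ev = io.read_evidence(paths["evidence"])
        assert len(ev) == len(small_evidence)
        fasta = io.read_fasta(paths["fasta"])
        assert fasta == small_truth.fasta
        metas = io.read_fractions(paths["fractions"])
        assert [m.fraction for m in metas] == list(FRACTIONS)
        ann = io.read_annotations(paths["annotations"])
        assert {"GO", "TFBS"} <= set(ann["term_type"])
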