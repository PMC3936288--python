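import numpy as np
import pandas as pd
import pytest

from elucycle.config import DEFAULT_FRACTIONS, FRACTIONS, FractionMeta, composition_matrix
from elucycle.consistency import (
    checksum_filter,
    clean_evidence,
    consistency_filter,
    phase_deconvolution,
)
from elucycle.quantification import ProteinGroup


def _group(gid, n_pep=3):
    return ProteinGroup(gid, (gid,), gid.rsplit("-", 1)[0],
                        frozenset(f"P{gid}{i}" for i in range(n_pep)))


def _mat(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[*FRACTIONS, "ASYNC"])


def _mixture_async(fracs=DEFAULT_FRACTIONS):
    w = np.array([f.cell_count for f in fracs])
    return w / w.sum()


class TestCleanEvidence:
    def test_single_peptide_removed(self):
        groups = [_group("A-1", n_pep=1), _group("B-1", n_pep=2)]
        mat = _mat({"A-1": [1] * 7, "B-1": [1] * 7})
        kept, _ = clean_evidence(groups, mat)
        assert [g.group_id for g in kept] == ["B-1"]

    def test_contaminant_removed_despite_many_peptides(self):
        groups = [_group("CON_001", n_pep=20), _group("B-1", n_pep=2)]
        mat = _mat({"CON_001": [1] * 7, "B-1": [1] * 7})
        flags = pd.Series({"CON_001": True, "B-1": False})
        kept, _ = clean_evidence(groups, mat, contaminant_flags=flags)
        assert [g.group_id for g in kept] == ["B-1"]

    def test_missing_fraction_removed(self):
        groups = [_group("A-1"), _group("B-1")]
        mat = _mat({"A-1": [1, 1, 0, 1, 1, 1, 1], "B-1": [1] * 7})
        kept, kept_mat = clean_evidence(groups, mat)
        assert [g.group_id for g in kept] == ["B-1"]
        assert list(kept_mat.index) == ["B-1"]


class TestChecksum:
    def test_exact_mixture_passes_with_zero_deviation(self):
        w = _mixture_async()
        profile = np.array([3.0, 2.5, 2.0, 1.5, 1.0, 0.5])
        mat = _mat({"A-1": [*profile, float(profile @ w)]})
        res = checksum_filter(mat, DEFAULT_FRACTIONS, tau=1.0)
        assert res.loc["A-1", "deviation"] == pytest.approx(0.0, abs=1e-12)
        assert bool(res.loc["A-1", "checksum_pass"])

    def test_twofold_boundary_inclusive(self):
        w = _mixture_async()
        profile = np.ones(6)
        mat = _mat({"A-1": [*profile, 2.0 * float(profile @ w)]})
        res = checksum_filter(mat, DEFAULT_FRACTIONS, tau=1.0)
        assert res.loc["A-1", "deviation"] == pytest.approx(1.0)
        assert bool(res.loc["A-1", "checksum_pass"])

    def test_2p5_fold_fails(self):
        w = _mixture_async()
        profile = np.ones(6)
        mat = _mat({"A-1": [*profile, 2.5 * float(profile @ w)]})
        res = checksum_filter(mat, DEFAULT_FRACTIONS, tau=1.0)
        # log2(2.5) = 1.3219...
        assert res.loc["A-1", "deviation"] == pytest.approx(1.3219, abs=1e-3)
        assert not bool(res.loc["A-1", "checksum_pass"])
        assert res.loc["A-1", "reason"] == "checksum_deviation"

    def test_zero_async_fails_with_reason(self):
        mat = _mat({"A-1": [1, 1, 1, 1, 1, 1, 0.0]})
        res = checksum_filter(mat, DEFAULT_FRACTIONS, tau=1.0)
        assert not bool(res.loc["A-1", "checksum_pass"])
        assert res.loc["A-1", "reason"] == "zero_async"

    def test_invariant_to_joint_global_rescaling(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 10, (5, 7))
        mat = pd.DataFrame(vals, columns=[*FRACTIONS, "ASYNC"],
                           index=[f"G{i}-1" for i in range(5)])
        r1 = checksum_filter(mat, DEFAULT_FRACTIONS)
        r2 = checksum_filter(mat * 1234.5, DEFAULT_FRACTIONS)
        np.testing.assert_allclose(r1["deviation"], r2["deviation"])


class TestPhaseDeconvolution:
    def test_identity_compositions_recover_exactly(self):
        metas = tuple(
            FractionMeta(f"F{i+1}", 1e6, tuple(np.eye(3)[i % 3]))
            for i in range(6)
        )
        x_true = np.array([3.0, 5.0, 7.0])
        M = composition_matrix(metas)
        profile = M @ x_true
        mat = _mat({"A-1": [*profile, 1.0]})
        res = phase_deconvolution(mat, metas)
        np.testing.assert_allclose(
            res.loc["A-1", ["x_G1", "x_S", "x_G2M"]].astype(float), x_true,
            rtol=1e-10)
        assert res.loc["A-1", "residual"] == pytest.approx(0.0, abs=1e-10)

    def test_forward_model_recovered_with_default_compositions(self):
        rng = np.random.default_rng(2)
        M = composition_matrix(DEFAULT_FRACTIONS)
        rows = {}
        x_true = {}
        for i in range(10):
            x = rng.uniform(0.5, 5.0, 3)
            x_true[f"G{i}-1"] = x
            rows[f"G{i}-1"] = [*(M @ x), 1.0]
        res = phase_deconvolution(_mat(rows), DEFAULT_FRACTIONS)
        for gid, x in x_true.items():
            np.testing.assert_allclose(
                res.loc[gid, ["x_G1", "x_S", "x_G2M"]].astype(float), x,
                atol=1e-8)
            assert res.loc[gid, "residual"] < 1e-8

    def test_adversarial_profile_fails(self):
        # alternating profile orthogonal to any achievable non-negative mix
        profile = np.array([3.0, 0.01, 3.0, 0.01, 3.0, 0.01])
        mat = _mat({"A-1": [*profile, 1.0]})
        res = phase_deconvolution(mat, DEFAULT_FRACTIONS, rho_max=0.5)
        assert res.loc["A-1", "residual"] > 0.5
        assert not bool(res.loc["A-1", "deconv_pass"])

    def test_rank_deficient_compositions_error(self):
        metas = tuple(
            FractionMeta(f"F{i+1}", 1e6, (0.5, 0.3, 0.2)) for i in range(6)
        )
        mat = _mat({"A-1": [1] * 7})
        with pytest.raises(ValueError, match="rank deficient"):
            phase_deconvolution(mat, metas)

    @pytest.mark.parametrize("seed", range(6))
    def test_nnls_matches_grid_search_oracle(self, seed):
        # multi-resolution grid search as an independent minimizer
        rng = np.random.default_rng(seed)
        M = rng.dirichlet(np.ones(3), size=6)
        metas = tuple(
            FractionMeta(f"F{i+1}", 1e6, tuple(M[i])) for i in range(6)
        )
        profile = rng.uniform(0.1, 5.0, 6)
        mat = _mat({"A-1": [*profile, 1.0]})
        res = phase_deconvolution(mat, metas, rho_max=np.inf)

        lo, hi = np.zeros(3), np.full(3, 2.0 * profile.max())
        best = None
        for _ in range(4):
            axes = [np.linspace(lo[d], hi[d], 25) for d in range(3)]
            G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            errs = np.square(G @ M.T - profile).sum(axis=1)
            k = int(np.argmin(errs))
            best = G[k]
            span = (hi - lo) / 6
            lo, hi = np.maximum(best - span, 0.0), best + span
        oracle_resid = np.sqrt(np.square(M @ best - profile).mean()) / profile.mean()
        assert res.loc["A-1", "residual"] <= oracle_resid + 1e-3


class TestCombinedFilter:
    def test_noise_free_synthetic_all_pass(self, noiseless_truth, noiseless_evidence):
        from elucycle.quantification import (
            aggregate_and_normalize,
            group_flags,
            group_proteins,
        )

        groups = group_proteins(noiseless_evidence)
        flags = group_flags(noiseless_evidence, groups)
        _, norm = aggregate_and_normalize(noiseless_evidence, groups)
        kept, cleaned = clean_evidence(groups, norm, flags["is_contaminant"],
                                       flags["is_reverse"])
        res = consistency_filter(cleaned, noiseless_truth.fractions)
        assert res.table["pass"].all()

    def test_combined_reason_codes(self):
        w = _mixture_async()
        good = np.ones(6)
        bad_profile = np.array([3.0, 0.01, 3.0, 0.01, 3.0, 0.01])
        mat = _mat({
            "A-1": [*good, float(good @ w)],
            "B-1": [*good, 10.0 * float(good @ w)],
            "C-1": [*bad_profile, float(bad_profile @ w)],
        })
        res = consistency_filter(mat, DEFAULT_FRACTIONS)
        assert bool(res.table.loc["A-1", "pass"])
        assert res.table.loc["B-1", "reason"] == "checksum_deviation"
        assert res.table.loc["C-1", "reason"] == "deconvolution_residual"
        assert list(res.passed) == ["A-1"]
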