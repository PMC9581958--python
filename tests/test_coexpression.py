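import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ciceratlas import coexpression as cx
from ciceratlas.models import ValidationError


def tom_oracle(adjacency):
    """Loop evaluation of the topological overlap formula."""
    a = np.array(adjacency, float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def adjacency_from_cor(cor, beta):
    a = np.abs(np.array(cor, float)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


class TestPrefilter:
    def test_boundaries(self):
        # row 1: max mean below 0.1 -> dropped before the transform
        # row 2: high-variance row -> kept
        # row 3: constant -> variance 0 -> dropped
        prof = pd.DataFrame(
            [
                [0.05, 0.05, 0.05, 0.05],
                [0.5, 3.0, 15.0, 63.0],
                [2.0, 2.0, 2.0, 2.0],
            ],
            index=["low", "kept", "flat"],
            columns=list("ABCD"),
        )
        out = cx.prefilter(prof, cx.CoexpressionConfig(min_cluster_size=1))
        assert list(out.index) == ["kept"]
        assert np.allclose(out.loc["kept"], np.log2(prof.loc["kept"] + 1))

    def test_variance_boundary_inclusive(self):
        prof = pd.DataFrame([[0.5, 3.0, 15.0, 63.0]], index=["t"], columns=list("ABCD"))
        var = np.log2(prof.to_numpy() + 1).var(ddof=1)
        cfg = cx.CoexpressionConfig(variance_threshold=float(var), min_cluster_size=1)
        assert list(cx.prefilter(prof, cfg).index) == ["t"]  # >= keeps the boundary
        cfg2 = cx.CoexpressionConfig(
            variance_threshold=float(var) + 1e-9, min_cluster_size=1
        )
        assert list(cx.prefilter(prof, cfg2).index) == []


class TestSoftThreshold:
    def test_selection_rule_and_fallback(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 12))
        cor = np.corrcoef(x)
        cfg = cx.CoexpressionConfig(beta_grid=(2, 4, 6))
        with pytest.warns(UserWarning, match="argmax"):
            beta, table = cx.pick_soft_threshold(cor, cfg)
        assert beta in cfg.beta_grid
        assert list(table["beta"]) == [2, 4, 6]
        # the selection rule: smallest beta reaching the target, else argmax
        reached = table[table["scale_free_r2"] >= cfg.scale_free_r2_target]
        if len(reached):
            assert beta == reached["beta"].iloc[0]
        else:
            assert beta == int(table.loc[table["scale_free_r2"].idxmax(), "beta"])

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        cor = np.corrcoef(rng.normal(size=(60, 10)))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1, t1 = cx.pick_soft_threshold(cor)
            b2, t2 = cx.pick_soft_threshold(cor)
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)

    def test_adjacency_monotone_in_beta(self):
        rng = np.random.default_rng(5)
        cor = np.clip(rng.uniform(-0.99, 0.99, size=(8, 8)), -0.99, 0.99)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        a2 = adjacency_from_cor(cor, 2)
        a3 = adjacency_from_cor(cor, 3)
        off = ~np.eye(8, dtype=bool)
        assert (a3[off] < a2[off]).all()


class TestTOM:
    def test_uniform_triangle_closed_form(self):
        # all off-diagonal a = 0.5: TOM = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        cor = np.full((3, 3), 0.5)
        np.fill_diagonal(cor, 1.0)
        tom = cx.compute_tom(cor, beta=1)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(tom[off], 0.5, atol=1e-12)
        assert np.allclose(np.diag(tom), 1.0)

    def test_zero_and_clique_limits(self):
        zero = np.eye(4)
        assert np.allclose(cx.compute_tom(zero, 1), np.eye(4))
        ones = np.ones((4, 4))
        assert np.allclose(cx.compute_tom(ones, 1), 1.0)

    def test_matches_loop_oracle_on_random_3_and_4_node_fixtures(self):
        rng = np.random.default_rng(6)
        for n in (3, 4):
            for _ in range(50):
                cor = rng.uniform(-1, 1, size=(n, n))
                cor = (cor + cor.T) / 2
                np.fill_diagonal(cor, 1.0)
                for beta in (1, 2, 6):
                    got = cx.compute_tom(cor, beta)
                    want = tom_oracle(adjacency_from_cor(cor, beta))
                    assert np.allclose(got, want, atol=1e-12)
                    assert np.allclose(got, got.T)
                    assert got.min() >= 0.0 and got.max() <= 1.0 + 1e-12

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValidationError):
            cx.compute_tom(bad, 2)


def planted_blocks(rng, sizes=(40, 40, 40), n_tissues=20, noise=0.3):
    rows, labels = [], []
    for m, size in enumerate(sizes, 1):
        profile = rng.normal(0, 2, size=n_tissues)
        for _ in range(size):
            rows.append(profile + rng.normal(0, noise, size=n_tissues))
            labels.append(m)
    log_expr = pd.DataFrame(
        rows, index=[f"t{i}" for i in range(len(rows))]
    )
    return log_expr, np.array(labels)


class TestModuleDetection:
    def test_three_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(7)
        log_expr, truth = planted_blocks(rng)
        cor = np.corrcoef(log_expr.to_numpy())
        tom = cx.compute_tom(cor, beta=6)
        labels = cx.detect_modules(1.0 - tom)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_too_few_transcripts_all_unassigned(self):
        rng = np.random.default_rng(8)
        diss = 1.0 - cx.compute_tom(np.corrcoef(rng.normal(size=(20, 10))), 6)
        assert (cx.detect_modules(diss) == 0).all()

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        log_expr, _ = planted_blocks(rng)
        diss = 1.0 - cx.compute_tom(np.corrcoef(log_expr.to_numpy()), 6)
        assert (cx.detect_modules(diss) == cx.detect_modules(diss)).all()


class TestEigengenes:
    def test_identical_rows_give_common_profile(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(size=8)
        log_expr = pd.DataFrame([profile] * 5, columns=list("ABCDEFGH"))
        eig, ve = cx.module_eigengenes(log_expr, np.ones(5, dtype=int))
        assert ve[1] == pytest.approx(1.0)
        v = eig.loc[1].to_numpy()
        assert np.linalg.norm(v) == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(v, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(v, profile)[0, 1] > 0  # sign orientation

    def test_two_opposite_rows_variance_explained_one(self):
        rng = np.random.default_rng(11)
        profile = rng.normal(size=6)
        log_expr = pd.DataFrame([profile, -profile])
        eig, ve = cx.module_eigengenes(log_expr, np.ones(2, dtype=int))
        assert ve[1] == pytest.approx(1.0)
        assert np.linalg.norm(eig.loc[1]) == pytest.approx(1.0)


class TestMerging:
    def test_identical_eigengenes_merge_and_distant_do_not(self):
        rng = np.random.default_rng(12)
        shared = rng.normal(0, 2, size=10)
        other = rng.normal(0, 2, size=10)
        rows = (
            [shared + rng.normal(0, 0.05, 10) for _ in range(5)]
            + [shared + rng.normal(0, 0.05, 10) for _ in range(5)]
            + [other + rng.normal(0, 0.05, 10) for _ in range(5)]
        )
        log_expr = pd.DataFrame(rows)
        labels = np.repeat([1, 2, 3], 5)
        merged = cx.merge_modules(log_expr, labels, cut_height=0.2)
        assert len(set(merged[:10])) == 1  # near-identical eigengenes merged
        assert merged[10] != merged[0]  # independent module survives

    def test_threshold_behavior_on_constructed_eigengene_correlation(self):
        # two modules whose eigengene correlation is ~0.85 (diss 0.15 < 0.2)
        rng = np.random.default_rng(13)
        base = rng.normal(0, 1, size=40)
        tilt = rng.normal(0, 1, size=40)
        e1 = base
        r_target = 0.85
        e2 = r_target * base + np.sqrt(1 - r_target**2) * (
            tilt - np.dot(tilt, base) / np.dot(base, base) * base
        ) / np.linalg.norm(
            tilt - np.dot(tilt, base) / np.dot(base, base) * base
        ) * np.linalg.norm(base)
        rows = [e1] * 4 + [e2.tolist()] * 4
        log_expr = pd.DataFrame(rows)
        labels = np.repeat([1, 2], 4)
        merged = cx.merge_modules(log_expr, labels, cut_height=0.2)
        assert len(set(merged)) == 1
        kept = cx.merge_modules(log_expr, labels, cut_height=0.1)
        assert len(set(kept)) == 2


class TestModuleTissueCorrelation:
    def test_indicator_and_orthogonal_cases(self):
        tissues = list("ABCDEFGH")
        ind = np.zeros(8)
        ind[2] = 1.0
        eig = pd.DataFrame([ind], index=["M1"], columns=tissues)
        tbl = cx.module_trait_correlation(eig).set_index("tissue")
        assert tbl.loc["C", "r"] == pytest.approx(1.0)
        assert tbl.loc["C", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_printed_correlation_value_reproduced(self):
        # r = 0.71 over the 32-tissue design reproduces P = 5e-06
        p = cx.correlation_pvalue(0.71, 32)
        assert p == pytest.approx(5e-06, rel=0.5)
        assert float(f"{p:.0e}") == 5e-06  # 1 significant figure


class TestPipelineOnSyntheticAtlas:
    def test_planted_modules_recovered(self, bundle, profiles):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cx.run_coexpression(profiles)
        truth = bundle.truth.transcripts.loc[res.labels.index, "module"]
        assert adjusted_rand_score(truth, res.labels) >= 0.8
        # recovered eigengenes match the planted eigen-profiles
        for m in range(1, 6):
            members = [
                t for t in truth.index[truth == m] if t in res.labels.index
            ]
            label = res.labels.loc[members].mode()[0]
            assert label != "M0"
            r = np.corrcoef(
                res.eigengenes.loc[label], bundle.truth.module_profiles.loc[m]
            )[0, 1]
            assert abs(r) >= 0.9

    def test_labels_stable_under_row_permutation(self, profiles):
        import warnings

        rng = np.random.default_rng(14)
        perm = rng.permutation(len(profiles))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cx.run_coexpression(profiles, beta=9)
            b = cx.run_coexpression(profiles.iloc[perm], beta=9)
        common = a.labels.index
        assert (a.labels.loc[common] == b.labels.loc[common]).all()
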