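"""PCA models, knee selection and projectable score models."""

import numpy as np
import pandas as pd
import pytest

from methlineage import lineage
from methlineage.matrix import MethlineageError, MethylationMatrix


def _matrix(arr, probe_prefix="cg", sample_prefix="s", groups=None):
    arr = np.asarray(arr, dtype=float)
    probes = [f"{probe_prefix}{i}" for i in range(arr.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(arr.shape[1])]
    return MethylationMatrix(pd.DataFrame(arr, index=probes, columns=samples), "beta", groups or {})


class TestFitPca:
    def test_rank_one_data_explains_everything(self):
        # three collinear samples in 2-D probe space
        m = _matrix(np.array([[0.0, 0.1, 0.2], [0.0, 0.1, 0.2]]))
        model = lineage.fit_pca(m, scale=False)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_conservation(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(0.1, 0.9, (40, 8)))
        model = lineage.fit_pca(m, scale=False)
        total = m.values.T.var(axis=0, ddof=1).sum()
        assert model.explained_variance.sum() == pytest.approx(total, abs=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.uniform(0.1, 0.9, (30, 6)))
        model = lineage.fit_pca(m, scale=True)
        L = model.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_explained_variance_non_increasing(self, tiny_beta_matrix):
        model = lineage.fit_pca(tiny_beta_matrix, scale=True)
        assert (np.diff(model.explained_variance) <= 1e-12).all()

    def test_projection_reproduces_training_scores(self, tiny_beta_matrix):
        model = lineage.fit_pca(tiny_beta_matrix, scale=True)
        proj = lineage.transform_pca(model, tiny_beta_matrix)
        pd.testing.assert_frame_equal(proj, model.sample_scores, atol=1e-8, check_exact=False)

    def test_single_sample_rejected(self):
        m = _matrix(np.array([[0.5], [0.4]]))
        with pytest.raises(MethlineageError):
            lineage.fit_pca(m)


class TestRankLoadings:
    def _model_with_loadings(self, loadings: dict[str, float]):
        s = pd.Series(loadings)
        return lineage.PcaModel(
            center=pd.Series(0.0, index=s.index),
            scale_=pd.Series(1.0, index=s.index),
            loadings=s.to_frame("PC1"),
            explained_variance=np.array([1.0]),
            explained_variance_ratio=np.array([1.0]),
            sample_scores=pd.DataFrame({"PC1": [0.0, 1.0]}, index=["s0", "s1"]),
        )

    def test_sorted_ascending(self):
        model = self._model_with_loadings({"p1": 0.2, "p2": -0.5, "p3": 0.0})
        assert list(lineage.rank_loadings(model, 1).index) == ["p2", "p3", "p1"]

    def test_ties_break_on_probe_id(self):
        model = self._model_with_loadings({"b": 0.1, "a": 0.1, "c": 0.1})
        assert list(lineage.rank_loadings(model, 1).index) == ["a", "b", "c"]

    def test_length_preserved(self, tiny_beta_matrix):
        model = lineage.fit_pca(tiny_beta_matrix, scale=True)
        assert len(lineage.rank_loadings(model, 2)) == tiny_beta_matrix.n_probes

    def test_bad_component_raises(self):
        model = self._model_with_loadings({"a": 0.3})
        with pytest.raises(MethlineageError):
            lineage.rank_loadings(model, 9)


class TestSelectInformativeCpgs:
    def test_knee_on_five_point_curve(self):
        # max-chord-distance oracle: elbow sits after the two large loadings
        ranked = pd.Series([0.9, 0.8, 0.01, 0.005, 0.002], index=list("abcde")).sort_values()
        sel = lineage.select_informative_cpgs(ranked, method="knee")
        assert sorted(sel.index) == ["a", "b"]

    def test_knee_picks_planted_tail_on_large_curve(self):
        # 50 strong loadings (both signs) against 5000 weak background ones
        rng = np.random.default_rng(0)
        strong = np.concatenate([rng.uniform(0.4, 0.6, 25), -rng.uniform(0.4, 0.6, 25)])
        weak = rng.normal(0, 0.02, 5000)
        s = pd.Series(np.concatenate([strong, weak]))
        s.index = [f"p{i}" for i in range(len(s))]
        sel = lineage.select_informative_cpgs(s.sort_values(), method="knee")
        strong_ids = {f"p{i}" for i in range(50)}
        tp = len(strong_ids & set(sel.index))
        assert tp / len(sel) >= 0.9 and tp / 50 >= 0.9

    def test_top_k(self):
        ranked = pd.Series({"a": -0.9, "b": 0.5, "c": 0.1, "d": -0.2}).sort_values()
        sel = lineage.select_informative_cpgs(ranked, method="top_k", k=3)
        assert set(sel.index) == {"a", "b", "d"}

    def test_abs_threshold_excluding_all_raises(self):
        ranked = pd.Series({"a": 0.1, "b": 0.2}).sort_values()
        with pytest.raises(MethlineageError, match="smaller tau"):
            lineage.select_informative_cpgs(ranked, method="abs_threshold", tau=0.5)

    def test_flat_curve_has_no_knee(self):
        ranked = pd.Series(0.3, index=[f"p{i}" for i in range(10)])
        with pytest.raises(MethlineageError, match="no curvature"):
            lineage.select_informative_cpgs(ranked, method="knee")


def _score_fixture():
    rng = np.random.default_rng(2)
    m = _matrix(rng.uniform(0.1, 0.9, (20, 6)))
    model = lineage.fit_pca(m, scale=False)
    selected = lineage.rank_loadings(model, 1).iloc[:5]
    return m, model, selected


class TestScoreModel:
    def test_single_cpg_score_is_its_beta(self):
        m = _matrix(np.array([[0.2, 0.5, 0.8], [0.3, 0.3, 0.3], [0.6, 0.1, 0.9]]))
        model = lineage.fit_pca(m, scale=False)
        sel = pd.Series({"cg0": 1.0})
        sm = lineage.build_score_model(model, 1, sel, 1, m)
        raw = sm.sign * (sel.to_numpy()[:, None] * m.values.loc[sel.index].to_numpy()).sum(axis=0)
        np.testing.assert_allclose(raw, m.values.loc["cg0"].to_numpy())

    def test_negating_sign_and_loadings_cancels(self):
        m, model, selected = _score_fixture()
        sm1 = lineage.build_score_model(model, 1, selected, 1, m)
        sm2 = lineage.build_score_model(model, 1, -selected, -1, m)
        pd.testing.assert_series_equal(lineage.score_samples(sm1, m), lineage.score_samples(sm2, m))

    def test_normalisation_parameters(self):
        # reference raw scores [1, 2, 3] -> mean 2, sample SD 1
        m = MethylationMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["cg0"], columns=["s0", "s1", "s2"]), "mvalue"
        )
        model = lineage.fit_pca(_matrix(np.random.default_rng(0).uniform(0, 1, (2, 3))), scale=False)
        sel = pd.Series({"cg0": 1.0})
        sm = lineage.build_score_model(model, 1, sel, 1, m)
        assert sm.norm_mean == pytest.approx(2.0)
        assert sm.norm_sd == pytest.approx(1.0)
        np.testing.assert_allclose(lineage.score_samples(sm, m).to_numpy(), [-1.0, 0.0, 1.0])

    def test_reference_scores_standardised(self):
        m, model, selected = _score_fixture()
        sm = lineage.build_score_model(model, 1, selected, 1, m)
        z = lineage.score_samples(sm, m)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_probe_order_irrelevant(self):
        m, model, selected = _score_fixture()
        sm = lineage.build_score_model(model, 1, selected, 1, m)
        shuffled = MethylationMatrix(m.values.iloc[::-1], "beta", dict(m.group_labels))
        pd.testing.assert_series_equal(lineage.score_samples(sm, m), lineage.score_samples(sm, shuffled))

    def test_score_linear_in_betas(self):
        m, model, selected = _score_fixture()
        sm = lineage.build_score_model(model, 1, selected, 1, m)
        scaled = MethylationMatrix(m.values * 0.5, "beta", dict(m.group_labels))
        raw = lambda mat: lineage.score_samples(sm, mat) * sm.norm_sd + sm.norm_mean
        np.testing.assert_allclose(raw(scaled).to_numpy(), 0.5 * raw(m).to_numpy(), atol=1e-9)

    def test_missing_probes_policy(self):
        m, model, selected = _score_fixture()
        sm = lineage.build_score_model(model, 1, selected, 1, m)
        # one of five missing (20%) exceeds the default 10% tolerance
        reduced = m.subset_probes([p for p in m.probe_ids if p != selected.index[0]])
        with pytest.raises(MethlineageError):
            lineage.score_samples(sm, reduced)
        with pytest.warns(UserWarning, match="imputing"):
            z = lineage.score_samples(sm, reduced, max_missing_fraction=0.25)
        assert np.isfinite(z).all()

    def test_save_load_round_trip(self, tmp_path):
        m, model, selected = _score_fixture()
        sm = lineage.build_score_model(model, 1, selected, -1, m, name="neuroendocrine")
        path = tmp_path / "model.tsv"
        lineage.save_score_model(sm, path)
        back = lineage.load_score_model(path)
        assert back.sign == sm.sign and back.name == sm.name
        assert back.norm_mean == pytest.approx(sm.norm_mean)
        pd.testing.assert_series_equal(back.selected, sm.selected, check_names=False)
        pd.testing.assert_series_equal(lineage.score_samples(back, m), lineage.score_samples(sm, m))


class TestAxisLoadings:
    def test_recovers_axis_under_component_mixing(self):
        # two equally strong planted axes: plain PCs may rotate inside the
        # signal plane, the discriminant direction must not
        rng = np.random.default_rng(5)
        n_per = 6
        groups = {}
        cols = []
        for gi, (lin, prog) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            for j in range(n_per):
                cols.append((f"g{gi}_{j}", lin, prog))
        arr = rng.normal(0.5, 0.03, (400, len(cols)))
        for k, (_, lin, prog) in enumerate(cols):
            arr[:40, k] += 0.25 * lin
            arr[40:80, k] += 0.25 * prog
        arr = np.clip(arr, 0, 1)
        m = MethylationMatrix(
            pd.DataFrame(arr, index=[f"cg{i}" for i in range(400)], columns=[c for c, _, _ in cols]),
            "beta",
            {c: f"g{lin}{prog}" for c, lin, prog in cols},
        )
        model = lineage.fit_pca(m, scale=True)
        lin_labels = {c: str(lin) for c, lin, _ in cols}
        ld = lineage.axis_loadings(model, lin_labels, "1")
        mass_lin = (ld.iloc[:40] ** 2).sum()
        mass_prog = (ld.iloc[40:80] ** 2).sum()
        assert mass_lin > 10 * mass_prog

    def test_one_sided_labels_rejected(self, tiny_beta_matrix):
        model = lineage.fit_pca(tiny_beta_matrix, scale=True)
        with pytest.raises(MethlineageError):
            lineage.axis_loadings(model, {s: "same" for s in tiny_beta_matrix.sample_ids}, "same")

    def test_separation_f_statistic_flags_structured_component(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(0.5, 0.02, (200, 12))
        arr[:30, :6] += 0.3  # first 6 samples shifted on 30 probes
        m = MethylationMatrix(
            pd.DataFrame(np.clip(arr, 0, 1), index=[f"cg{i}" for i in range(200)],
                         columns=[f"s{j}" for j in range(12)]),
            "beta",
            {f"s{j}": ("X" if j < 6 else "Y") for j in range(12)},
        )
        model = lineage.fit_pca(m, scale=False)
        f = lineage.component_group_separation(model, m.group_labels)
        assert f.idxmax() == "PC1"
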