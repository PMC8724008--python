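"""Moderated t, DMP thresholds, Venn overlaps and DMR aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methlineage import differential as diff
from methlineage.matrix import MethlineageError, MethylationMatrix
from methlineage.synthetic import CohortDesign, GroupSpec, generate_cohort, generate_manifest


def _matrix(rows: dict[str, list[float]], scale="mvalue") -> MethylationMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return MethylationMatrix(df.astype(float), scale)


A3 = ["s0", "s1", "s2"]
B3 = ["s3", "s4", "s5"]


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        # textbook pooled two-sample t on A=[1,2,3], B=[3,4,5]
        m = _matrix({"p1": [1, 2, 3, 3, 4, 5], "p2": [0, 1, 0, 1, 0, 1]})
        st_table, _ = diff.fit_moderated_t(m, A3, B3, prior=diff.EbPrior(0.0, 1.0))
        t = st_table.loc["p1", "moderated_t"]
        assert t == pytest.approx(-2.449489742783178, abs=1e-9)
        ref = stats.ttest_ind([1, 2, 3], [3, 4, 5])
        assert st_table.loc["p1", "p_value"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_d0_infinite_is_fixed_variance_limit(self):
        m = _matrix({"p1": [1, 2, 3, 3, 4, 5], "p2": [5, 5, 6, 7, 8, 8]})
        s0_sq = 0.7
        st_table, _ = diff.fit_moderated_t(m, A3, B3, prior=diff.EbPrior(math.inf, s0_sq))
        expected = st_table["delta_m"] / np.sqrt(s0_sq * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(st_table["moderated_t"], expected, atol=1e-12)

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            rng.normal(0, 1, (200, 8)),
            index=[f"p{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(8)],
        )
        m = MethylationMatrix(vals, "mvalue")
        st_table, prior = diff.fit_moderated_t(m, [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)])
        lo = np.minimum(st_table["s_sq"], prior.s0_sq)
        hi = np.maximum(st_table["s_sq"], prior.s0_sq)
        assert ((st_table["post_var"] >= lo - 1e-12) & (st_table["post_var"] <= hi + 1e-12)).all()

    def test_prior_recovery_from_scaled_inverse_chi2(self):
        # variances drawn from the hierarchical model are moment-matched back
        rng = np.random.default_rng(3)
        d0, s0_sq, d = 4.0, 0.04, 10
        sigma2 = s0_sq * d0 / rng.chisquare(d0, 10_000)
        s2 = sigma2 * rng.chisquare(d, 10_000) / d
        prior = diff.estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.2)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.2)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (0.1, 1.0, 7.3, 150.0):
            y = float(polygamma(1, x))
            assert diff.trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_zero_variance_probe_handled_by_shrinkage(self):
        m = _matrix({"p1": [1, 1, 1, 2, 2, 2], "p2": [0, 1, 2, 1, 2, 3]})
        st_table, _ = diff.fit_moderated_t(m, A3, B3)
        assert np.isfinite(st_table.loc["p1", "moderated_t"])

    def test_small_group_rejected(self):
        m = _matrix({"p1": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(MethlineageError):
            diff.fit_moderated_t(m, ["s0"], B3)


class TestCallDmps:
    def test_threshold_logic(self):
        table = pd.DataFrame(
            {"p_value": [0.005, 0.5, 0.001], "delta_m": [3.0, 3.0, 1.9]},
            index=["a", "b", "c"],
        )
        out = diff.call_dmps(table)
        assert list(out.index) == ["a"]

    def test_empty_input_gives_empty_output(self):
        table = pd.DataFrame({"p_value": [], "delta_m": []})
        assert diff.call_dmps(table).empty


class TestVennOverlap:
    def test_hand_counts(self):
        counts = diff.overlap_dmp_sets({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert counts == {"A": 1, "B": 1, "A&B": 2}

    def test_disjoint_sets(self):
        counts = diff.overlap_dmp_sets({"A": {1}, "B": {2}})
        assert counts["A&B"] == 0

    def test_nested_chain(self):
        counts = diff.overlap_dmp_sets({"A": {1}, "B": {1, 2}, "C": {1, 2, 3}})
        assert counts == {"A": 0, "B": 0, "C": 1, "A&B": 0, "A&C": 0, "B&C": 1, "A&B&C": 1}

    def test_counts_sum_to_union(self):
        sets = {"A": set(range(10)), "B": set(range(5, 20)), "C": set(range(0, 30, 3))}
        counts = diff.overlap_dmp_sets(sets)
        assert sum(counts.values()) == len(set.union(*sets.values()))


def _dmr_inputs(positions, p_values, delta_ms, beta_a=0.2, beta_b=0.6):
    n = len(positions)
    probe_ids = [f"p{i}" for i in range(n)]
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": "chr1",
            "pos": positions,
            "island_relation": "Island",
            "gene_feature": "Body",
            "gene_symbol": "G",
            "sex_chrom": False,
            "snp_flagged": False,
            "cross_reactive": False,
        }
    )
    stats_table = pd.DataFrame({"p_value": p_values, "delta_m": delta_ms}, index=probe_ids)
    vals = pd.DataFrame(
        {"a1": beta_a, "a2": beta_a, "b1": beta_b, "b2": beta_b}, index=probe_ids
    )
    betas = MethylationMatrix(vals, "beta")
    return stats_table, betas, manifest


class TestCallDmrs:
    def test_gap_and_size_rules(self):
        # [100, 500, 900] chain (gaps 400); 5000 is isolated and dropped
        st_table, betas, man = _dmr_inputs([100, 500, 900, 5000], [1e-5] * 4, [-3.0] * 4)
        dmrs = diff.call_dmrs(st_table, betas, man, ["a1", "a2"], ["b1", "b2"])
        assert len(dmrs) == 1
        assert (dmrs.loc[0, "start"], dmrs.loc[0, "end"], dmrs.loc[0, "n_cpgs"]) == (100, 900, 3)

    def test_stouffer_statistic_matches_normal_oracle(self):
        # three probes at two-sided p = 0.0455 (z = 2), same sign
        p = 2 * stats.norm.sf(2.0)
        st_table, betas, man = _dmr_inputs([100, 200, 300], [p] * 3, [1.0] * 3)
        dmrs = diff.call_dmrs(
            st_table, betas, man, ["a1", "a2"], ["b1", "b2"], probe_p_cut=0.05
        )
        assert dmrs.loc[0, "combined_z"] == pytest.approx(2 * 3 / math.sqrt(3), abs=1e-6)
        assert dmrs.loc[0, "combined_z"] == pytest.approx(3.464, abs=1e-3)
        assert dmrs.loc[0, "p_value"] == pytest.approx(5.3e-4, rel=0.01)

    def test_mean_delta_beta_is_region_mean_difference(self):
        st_table, betas, man = _dmr_inputs([100, 200, 300], [1e-6] * 3, [-2.0] * 3)
        betas.values.loc[:, ["a1", "a2"]] = np.array([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3]])
        betas.values.loc[:, ["b1", "b2"]] = np.array([[0.5, 0.5], [0.6, 0.6], [0.7, 0.7]])
        dmrs = diff.call_dmrs(st_table, betas, man, ["a1", "a2"], ["b1", "b2"])
        assert dmrs.loc[0, "mean_delta_beta"] == pytest.approx(-0.4, abs=1e-12)

    def test_emitted_regions_satisfy_their_invariants(self, two_group_cohort, small_manifest):
        from methlineage import preprocessing as pp

        betas, det, _ = two_group_cohort
        m = pp.matrix_to_m(betas)
        st_table, _ = diff.fit_moderated_t(
            m, betas.samples_in_group("A"), betas.samples_in_group("B"), beta_matrix=betas
        )
        dmrs = diff.call_dmrs(
            st_table, betas, small_manifest, betas.samples_in_group("A"), betas.samples_in_group("B")
        )
        ann = small_manifest.set_index("probe_id")
        for _, row in dmrs.iterrows():
            members = row["probe_ids"].split(",")
            assert row["n_cpgs"] >= 3
            assert row["p_value"] <= 0.01
            pos = ann.loc[members, "pos"].sort_values()
            assert (pos.diff().dropna() <= 1000).all()
            assert row["start"] <= row["end"]

    def test_tss_flag_reflects_member_annotation(self):
        st_table, betas, man = _dmr_inputs([100, 200, 300], [1e-6] * 3, [2.0] * 3)
        man.loc[1, "gene_feature"] = "TSS200"
        dmrs = diff.call_dmrs(st_table, betas, man, ["a1", "a2"], ["b1", "b2"])
        assert bool(dmrs.loc[0, "tss_within_2000bp"])


class TestFilterDmrsByEffect:
    def test_threshold_example(self):
        dmrs = pd.DataFrame(
            {"mean_delta_beta": [-0.15, -0.35, 0.25], "tss_within_2000bp": [True, False, True]}
        )
        counts = diff.filter_dmrs_by_effect(dmrs, [0.2])
        assert counts.loc[0, "n_total"] == 2
        assert counts.loc[0, "n_hypo"] == 1
        assert counts.loc[0, "n_hyper"] == 1

    def test_counts_monotone_in_cut(self):
        rng = np.random.default_rng(0)
        dmrs = pd.DataFrame(
            {"mean_delta_beta": rng.uniform(-1, 1, 50), "tss_within_2000bp": rng.random(50) < 0.5}
        )
        counts = diff.filter_dmrs_by_effect(dmrs, [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.01])
        assert counts["n_total"].is_monotonic_decreasing
        assert counts.loc[0, "n_total"] == 50  # cut 0 keeps all
        assert counts.iloc[-1]["n_total"] == 0  # |delta beta| <= 1 always
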