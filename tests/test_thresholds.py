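"""Cluster-specific threshold equations and the four core-set schemes."""

import numpy as np
import pandas as pd
import pytest

import clustercore as cc
from clustercore.errors import DegenerateDataWarning

import oracles


def _enz(values, ids=None, cols=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"e{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return cc.EnzymeExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols))


def _clustering(stats, M, Delta):
    """Build a ClusteringResult directly from chosen statistics."""
    table = pd.DataFrame.from_dict(
        {
            c: {"mu": mu, "sigma": sigma, "n_members": 1, "n_values": 10}
            for c, (mu, sigma) in stats.items()
        },
        orient="index",
    ).sort_index()
    assignment = {f"e{c}": c for c in stats}
    return cc.ClusteringResult(
        n_clusters=len(stats),
        assignment=assignment,
        cluster_stats=table,
        M=M,
        Delta=Delta,
    )


class TestRawThresholds:
    def test_max_sd_cluster_at_dataset_mean_scores_one(self):
        # f = 1 for the argmax(sigma - Delta) cluster, g = 0 at mu = M
        cl = _clustering({1: (1.2, 1.4), 2: (0.5, 0.3)}, M=1.2, Delta=0.9)
        theta = cc.raw_cluster_thresholds(cl)
        assert theta[1] == pytest.approx(1.0)

    def test_higher_mean_lowers_theta(self):
        lo = _clustering({1: (1.2, 1.0), 2: (0.2, 0.5)}, M=1.2, Delta=0.9)
        hi = _clustering({1: (2.0, 1.0), 2: (0.2, 0.5)}, M=1.2, Delta=0.9)
        assert (
            cc.raw_cluster_thresholds(hi)[1] < cc.raw_cluster_thresholds(lo)[1]
        )

    def test_two_cluster_hand_oracle(self):
        # f_A = (1.0-0.9)/0.1 = 1, g_A = -(2.0-1.2) = -0.8 -> 0.2
        # f_B = (0.5-0.9)/0.1 = -4, g_B = 1.2 -> -2.8
        cl = _clustering({1: (2.0, 1.0), 2: (0.0, 0.5)}, M=1.2, Delta=0.9)
        theta = cc.raw_cluster_thresholds(cl)
        assert theta[1] == pytest.approx(0.2, abs=1e-12)
        assert theta[2] == pytest.approx(-2.8, abs=1e-12)

    def test_zero_denominator_sets_f_to_zero_with_warning(self):
        cl = _clustering({1: (1.0, 0.9), 2: (2.0, 0.9)}, M=1.5, Delta=0.9)
        with pytest.warns(DegenerateDataWarning):
            theta = cc.raw_cluster_thresholds(cl)
        assert theta[1] == pytest.approx(0.5)  # pure mean term
        assert theta[2] == pytest.approx(-0.5)

    def test_all_tighter_than_dataset_warns(self):
        cl = _clustering({1: (1.0, 0.2), 2: (2.0, 0.4)}, M=1.5, Delta=0.9)
        with pytest.warns(DegenerateDataWarning, match="tighter"):
            cc.raw_cluster_thresholds(cl)

    def test_lowering_cluster_mean_never_lowers_theta(self):
        """Monotonicity of the mean term, other statistics fixed."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            mus = rng.normal(1, 1, size=4)
            sigmas = rng.uniform(0.1, 1.5, size=4)
            base = _clustering(
                {i + 1: (mus[i], sigmas[i]) for i in range(4)}, M=1.0, Delta=0.8
            )
            lowered = _clustering(
                {i + 1: (mus[i] - (0.5 if i == 2 else 0.0), sigmas[i]) for i in range(4)},
                M=1.0,
                Delta=0.8,
            )
            t0 = cc.raw_cluster_thresholds(base)
            t1 = cc.raw_cluster_thresholds(lowered)
            assert t1[3] >= t0[3] - 1e-12


class TestNormalize:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            ([1.0, 3.0], [0.0, 100.0]),
            ([1.0, 2.0, 3.0], [0.0, 50.0, 100.0]),
            ([-5.0, 0.0, 5.0], [0.0, 50.0, 100.0]),
        ],
    )
    def test_affine_map(self, theta, expected):
        out = cc.normalize_thresholds(pd.Series(theta, index=range(len(theta))))
        assert np.allclose(out.to_numpy(), expected)

    def test_permutation_equivariance(self):
        theta = pd.Series([2.0, -1.0, 5.0, 0.5], index=[1, 2, 3, 4])
        out = cc.normalize_thresholds(theta)
        perm = [3, 1, 4, 2]
        out_p = cc.normalize_thresholds(theta.loc[perm])
        assert np.allclose(out.loc[perm].to_numpy(), out_p.to_numpy())

    def test_constant_theta_degenerates_to_100(self):
        with pytest.warns(DegenerateDataWarning):
            out = cc.normalize_thresholds(pd.Series([2.0, 2.0, 2.0]))
        assert (out == 100.0).all()

    def test_single_cluster_is_an_error(self):
        with pytest.raises(cc.InputError):
            cc.normalize_thresholds(pd.Series([1.0]))


class TestResolveCutoffs:
    def _setup(self):
        rng = np.random.default_rng(1)
        enz = _enz(10.0 ** rng.normal(1, 1, size=(8, 10)))
        assignment = {f"e{i}": 1 + i % 2 for i in range(8)}
        cl = cc.clustering_from_assignment(enz, assignment)
        return enz, cl

    def test_theta_100_takes_dataset_mean(self):
        enz, cl = self._setup()
        ts = cc.resolve_cutoffs(pd.Series({1: 100.0, 2: 40.0}), cl, enz)
        assert ts.table.loc[1, "cutoff"] == pytest.approx(cl.M)
        assert bool(ts.table.loc[1, "special_mean"])
        assert not bool(ts.table.loc[2, "special_mean"])

    def test_theta_0_is_cluster_maximum(self):
        enz, cl = self._setup()
        ts = cc.resolve_cutoffs(pd.Series({1: 0.0, 2: 50.0}), cl, enz)
        members = [e for e, c in cl.assignment.items() if c == 1]
        logs = np.log10(
            enz.data.loc[members].to_numpy()[enz.data.loc[members].to_numpy() > 0]
        )
        assert ts.table.loc[1, "cutoff"] == pytest.approx(logs.max())

    def test_percentile_matches_sort_interpolate_oracle(self):
        values = np.arange(1.0, 101.0)  # log10 units directly
        enz = _enz(10.0 ** values.reshape(10, 10))
        cl = cc.clustering_from_assignment(
            enz, {f"e{i}": 1 if i < 10 else 2 for i in range(10)} | {"e9": 2}
        )
        ts = cc.resolve_cutoffs(pd.Series({1: 25.0, 2: 10.0}), cl, enz)
        members1 = [e for e, c in cl.assignment.items() if c == 1]
        logs1 = [
            v
            for e in members1
            for v in np.log10(enz.data.loc[e][enz.data.loc[e] > 0])
        ]
        assert ts.table.loc[1, "cutoff"] == pytest.approx(
            oracles.top_percentile(logs1, 25.0), abs=1e-9
        )


class TestStanDepCore:
    def test_activation_and_provenance(self, toy_expression, toy_catalog):
        enz, _ = cc.compute_enzyme_expression(toy_expression, toy_catalog)
        cl = cc.clustering_from_assignment(
            enz, {e: 1 + i % 2 for i, e in enumerate(enz.data.index)}
        )
        ts = cc.standep_thresholds(enz, cl)
        core = cc.standep_core(enz, cl, ts, toy_catalog, protect=["R5"])
        # protected reaction present everywhere with the marker
        for ctx in core.sets:
            assert "R5" in core.sets[ctx]
            assert core.provenance[ctx].get("R5") == ("protected",)
        # every non-protected core reaction names >= 1 activating enzyme
        for ctx, prov in core.provenance.items():
            for rid, enzymes in prov.items():
                if enzymes != ("protected",):
                    assert len(enzymes) >= 1

    def test_isoenzyme_any_active_rule(self):
        # two isoenzymes, only one above its cutoff -> reaction is core
        cat = cc.catalog_from_rules([("R1", "", "a or b")])
        enz = _enz([[100.0, 100.0], [1.0, 1.0]], ids=["a", "b"])
        cl = cc.clustering_from_assignment(enz, {"a": 1, "b": 2})
        ts = cc.ThresholdSet(
            pd.DataFrame(
                {
                    "theta_raw": [0.0, 0.0],
                    "theta_norm": [50.0, 50.0],
                    "cutoff": [1.0, 1.0],  # a (log 2) above, b (log 0) below
                    "special_mean": [False, False],
                },
                index=[1, 2],
            )
        )
        core = cc.standep_core(enz, cl, ts, cat)
        assert all("R1" in s for s in core.sets.values())
        for prov in core.provenance.values():
            assert prov["R1"] == ("a",)

    def test_zero_expression_never_activates(self):
        cat = cc.catalog_from_rules([("R1", "", "a")])
        enz = _enz([[0.0, 10.0], [5.0, 5.0]], ids=["a", "b"])
        cl = cc.clustering_from_assignment(enz, {"a": 1, "b": 2})
        # cutoff far below everything
        ts = cc.ThresholdSet(
            pd.DataFrame(
                {
                    "theta_raw": [0.0, 0.0],
                    "theta_norm": [99.0, 99.0],
                    "cutoff": [-10.0, -10.0],
                    "special_mean": [False, False],
                },
                index=[1, 2],
            )
        )
        core = cc.standep_core(enz, cl, ts, cat)
        assert "R1" not in core.sets["c0"]
        assert "R1" in core.sets["c1"]

    def test_unassigned_enzyme_is_an_error(self):
        cat = cc.catalog_from_rules([("R1", "", "a")])
        enz = _enz([[1.0, 2.0], [3.0, 4.0]], ids=["a", "b"])
        cl = cc.clustering_from_assignment(enz, {"a": 1, "b": 2})
        enz2 = _enz([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], ids=["a", "b", "x"])
        ts = cc.standep_thresholds(enz, cl)
        with pytest.raises(cc.InputError, match="without cluster"):
            cc.standep_core(enz2, cl, ts, cat)


class TestBaselineSchemes:
    def test_global_cutoff_matches_oracle_and_scopes_contexts(self):
        cat = cc.catalog_from_rules([(f"R{i}", "", f"e{i}") for i in range(4)])
        rng = np.random.default_rng(2)
        values = 10.0 ** rng.normal(0, 1, size=(4, 6))
        enz = _enz(values, ids=[f"e{i}" for i in range(4)])
        core = cc.global_core(enz, cat, top_percentile=25.0)
        logs = np.log10(values[values > 0])
        cutoff = oracles.top_percentile(list(logs), 25.0)
        for j, ctx in enumerate(enz.data.columns):
            expected = {
                f"R{i}" for i in range(4) if np.log10(values[i, j]) > cutoff
            }
            assert core.sets[ctx] == expected

    def test_global_all_equal_values_gives_empty_cores(self):
        cat = cc.catalog_from_rules([("R1", "", "a"), ("R2", "", "b")])
        enz = _enz([[7.0, 7.0], [7.0, 7.0]], ids=["a", "b"])
        core = cc.global_core(enz, cat)
        assert all(len(s) == 0 for s in core.sets.values())

    def test_localT1_methods_variant(self):
        # 4 enzymes; lower bound = 25th percentile of pooled log10 values
        cat = cc.catalog_from_rules([(f"R{g}", "", g) for g in "abcd"])
        enz = _enz(
            [
                [1e-3, 1e-3, 1e-3],  # far below the bound -> never core
                [1.0, 9.0, 100.0],
                [10.0, 20.0, 400.0],
                [100.0, 50.0, 2000.0],
            ],
            ids=list("abcd"),
        )
        core = cc.localT1_core(enz, cat, variant="methods")
        assert all("Ra" not in s for s in core.sets.values())
        # enzyme b: active only where above its own log-mean
        logs_b = np.log10([1.0, 9.0, 100.0])
        expect_b = logs_b > logs_b.mean()
        for j, ctx in enumerate(enz.data.columns):
            assert ("Rb" in core.sets[ctx]) == bool(expect_b[j])

    def test_localT1_results_variant_never_unconditionally_inactivates(self):
        cat = cc.catalog_from_rules([("Ra", "", "a"), ("Rb", "", "b")])
        enz = _enz([[1e-3, 10.0], [100.0, 1000.0]], ids=["a", "b"])
        # pooled logs [-3, 1, 2, 3] -> lower bound (25th pct) = 0;
        # enzyme a's own log-mean is -1, below the bound
        methods = cc.localT1_core(enz, cat, variant="methods")
        assert all("Ra" not in s for s in methods.sets.values())
        results = cc.localT1_core(enz, cat, variant="results")
        # cutoff becomes max(own mean, bound) = 0: the strong context survives
        assert "Ra" in results.sets["c1"]
        assert "Ra" not in results.sets["c0"]

    def test_localT2_unconditional_bands(self):
        cat = cc.catalog_from_rules([(f"R{g}", "", g) for g in "abcd"])
        enz = _enz(
            [
                [1e-4, 1e-4, 1e-4],      # below lower bound: never
                [0.5, 5.0, 50.0],        # mid band: above own mean only
                [1000.0, 2000.0, 0.0],   # above upper bound: always, even at 0
                [900.0, 800.0, 700.0],
            ],
            ids=list("abcd"),
        )
        core = cc.localT2_core(enz, cat)
        assert all("Ra" not in s for s in core.sets.values())
        assert all("Rc" in s for s in core.sets.values())
        logs_b = np.log10([0.5, 5.0, 50.0])
        for j, ctx in enumerate(enz.data.columns):
            assert ("Rb" in core.sets[ctx]) == bool(logs_b[j] > logs_b.mean())

    def test_localT2_band_order_error(self):
        cat = cc.catalog_from_rules([("Ra", "", "a"), ("Rb", "", "b")])
        enz = _enz([[1.0, 2.0], [3.0, 4.0]], ids=["a", "b"])
        with pytest.raises(cc.InputError, match="lower bound"):
            cc.localT2_core(
                enz, cat, upper_top_percentile=75.0, lower_top_percentile=25.0
            )
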