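"""Model-extraction-method input construction from threshold distances."""

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


def _thresholds(cutoffs):
    return cc.ThresholdSet(
        pd.DataFrame(
            {
                "theta_raw": 0.0,
                "theta_norm": 50.0,
                "cutoff": pd.Series(cutoffs),
                "special_mean": False,
            }
        )
    )


@pytest.fixture
def simple_setup():
    """Three enzymes in two clusters with fixed cutoffs 0.0 and 1.0."""
    enz = _enz(
        [[1.0, 10.0, 100.0], [10.0, 1.0, 0.0], [100.0, 1000.0, 10.0]],
        ids=["a", "b", "c"],
    )
    cl = cc.clustering_from_assignment(enz, {"a": 1, "b": 1, "c": 2})
    ts = _thresholds({1: 0.0, 2: 1.0})
    return enz, cl, ts


class TestThresholdDistances:
    def test_log_units_and_zero_floor(self, simple_setup):
        enz, cl, ts = simple_setup
        D = cc.threshold_distances(enz, cl, ts)
        assert D.loc["a", "c0"] == pytest.approx(0.0)  # at cutoff
        assert D.loc["a", "c1"] == pytest.approx(1.0)  # one decade above
        assert D.loc["c", "c0"] == pytest.approx(1.0)  # cutoff 1, value 100
        # zero expression: floor = log10(min positive)-1 = -1, D = -1 - 0
        assert D.loc["b", "c2"] == pytest.approx(-1.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        values = 10.0 ** rng.normal(0, 1, size=(5, 3))
        enz = _enz(values)
        cl = cc.clustering_from_assignment(
            enz, {f"e{i}": 1 + i % 2 for i in range(5)}
        )
        ts = _thresholds({1: 0.3, 2: -0.2})
        D = cc.threshold_distances(enz, cl, ts)
        cuts = [0.3 if i % 2 == 0 else -0.2 for i in range(5)]
        floor = np.log10(values.min()) - 1.0
        expected = oracles.threshold_distances(values.tolist(), cuts, floor)
        assert np.allclose(D.to_numpy(), expected, atol=1e-12)


class TestUbiquity:
    def test_piecewise_definition(self):
        cat = cc.catalog_from_rules(
            [("R1", "", "a"), ("R2", "", "b"), ("R3", "", "")]
        )
        D = pd.DataFrame(
            [[0.3, -0.4], [-0.8, -0.2]], index=["a", "b"], columns=["c0", "c1"]
        )
        U = cc.ubiquity_scores(D, cat)
        assert U.loc["R1", "c0"] == 1.0              # D > 0
        assert U.loc["R2", "c0"] == pytest.approx(0.0)   # the global minimum
        assert U.loc["R1", "c1"] == pytest.approx(0.5)   # D = min/2
        assert U.loc["R2", "c1"] == pytest.approx(0.75)
        assert (U.loc["R3"] == -1.0).all()           # gene-free sentinel

    def test_isoenzymes_take_max_and_protected_pinned(self):
        cat = cc.catalog_from_rules([("R1", "", "a or b"), ("R2", "", "a")])
        D = pd.DataFrame(
            [[-1.0, 0.2], [-0.5, -1.0]], index=["a", "b"], columns=["c0", "c1"]
        )
        U = cc.ubiquity_scores(D, cat, protected=["R2"])
        assert U.loc["R1", "c0"] == pytest.approx(0.5)  # max(0, 0.5)
        assert (U.loc["R2"] == 1.0).all()

    def test_no_negative_distances_warns_all_ones(self):
        cat = cc.catalog_from_rules([("R1", "", "a")])
        D = pd.DataFrame([[0.2, 0.4]], index=["a"], columns=["c0", "c1"])
        with pytest.warns(DegenerateDataWarning):
            U = cc.ubiquity_scores(D, cat)
        assert (U.loc["R1"] == 1.0).all()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        D_arr = rng.normal(0, 1, size=(6, 4))
        cat = cc.catalog_from_rules([(f"R{i}", "", f"e{i}") for i in range(6)])
        D = pd.DataFrame(
            D_arr, index=[f"e{i}" for i in range(6)],
            columns=[f"c{j}" for j in range(4)],
        )
        U = cc.ubiquity_scores(D, cat)
        assert np.allclose(U.to_numpy(), oracles.ubiquity(D_arr.tolist()), atol=1e-12)


class TestInitAndGimme:
    def test_scaling_summation_and_sentinels(self):
        cat = cc.catalog_from_rules(
            [("R1", "", "a or b"), ("R2", "", "a"), ("R3", "", "")]
        )
        D = pd.DataFrame(
            [[2.0, -1.0], [0.8, 0.6]], index=["a", "b"], columns=["c0", "c1"]
        )
        W = cc.init_weights(D, cat)
        # enzyme weights: a -> [1, -0.5], b -> [0.4, 0.3]
        assert W.loc["R2", "c0"] == pytest.approx(1.0)   # max distance -> 1
        assert W.loc["R1", "c0"] == pytest.approx(1.4)   # isoenzymes sum
        assert W.loc["R1", "c1"] == pytest.approx(-0.2)
        assert (W.loc["R3"] == 0.0).all()                # gene-free -> 0

    def test_protected_weight_one(self):
        cat = cc.catalog_from_rules([("R1", "", "a"), ("bio", "", "")])
        D = pd.DataFrame([[0.5, -0.5]], index=["a"], columns=["c0", "c1"])
        W = cc.init_weights(D, cat, protected=["bio"])
        assert (W.loc["bio"] == 1.0).all()

    def test_gimme_is_init_with_threshold_one(self):
        cat = cc.catalog_from_rules([("R1", "", "a or b"), ("R2", "", "b")])
        rng = np.random.default_rng(3)
        D = pd.DataFrame(
            rng.normal(size=(2, 3)), index=["a", "b"],
            columns=["c0", "c1", "c2"],
        )
        gim = cc.gimme_vector(D, cat)
        pd.testing.assert_frame_equal(gim.weights, cc.init_weights(D, cat))
        assert gim.threshold == 1.0

    def test_all_zero_distances_warn(self):
        cat = cc.catalog_from_rules([("R1", "", "a")])
        D = pd.DataFrame([[0.0, 0.0]], index=["a"], columns=["c0", "c1"])
        with pytest.warns(DegenerateDataWarning):
            W = cc.init_weights(D, cat)
        assert (W.to_numpy() == 0.0).all()


class TestMBA:
    def test_band_semantics(self):
        cat = cc.catalog_from_rules(
            [("Rhigh", "", "a"), ("Rmed", "", "b"), ("Rboth", "", "a or b")]
        )
        # cutoff (log10) = 1 -> linear 10; a at 12 (=1.2x, high),
        # b exactly at 10 (medium)
        enz = _enz([[12.0], [10.0]], ids=["a", "b"], cols=["c0"])
        cl = cc.clustering_from_assignment(enz, {"a": 1, "b": 1})
        ts = _thresholds({1: 1.0})
        sets = cc.mba_sets(enz, cl, ts, cat)
        high, med = sets["c0"]
        assert "Rhigh" in high and "Rmed" in med
        # reaction with one high and one medium enzyme goes to high only
        assert "Rboth" in high and "Rboth" not in med
        assert high.isdisjoint(med)

    def test_protected_always_high(self):
        cat = cc.catalog_from_rules([("R1", "", "a"), ("bio", "", "")])
        enz = _enz([[0.1]], ids=["a"], cols=["c0"])
        cl = cc.clustering_from_assignment(enz, {"a": 1})
        sets = cc.mba_sets(enz, cl, _thresholds({1: 1.0}), cat, protect=["bio"])
        assert "bio" in sets["c0"][0]

    def test_band_validation(self, simple_setup):
        enz, cl, ts = simple_setup
        cat = cc.catalog_from_rules([("R1", "", "a")])
        with pytest.raises(cc.InputError):
            cc.mba_sets(enz, cl, ts, cat, band=1.0)


class TestIMAT:
    def test_partition_tiles_the_catalog(self):
        rules = [(f"R{i}", "", f"g{i}") for i in range(8)] + [
            ("Rf1", "", ""),
            ("Rf2", "", ""),
        ]
        cat = cc.catalog_from_rules(rules)
        core = cc.CoreReactionSets(
            sets={"c0": {"R0", "R1", "R2", "R3"}},
            provenance={"c0": {}},
            method="test",
        )
        out = cc.imat_sets(core, cat)
        core_set, noncore = out["c0"]
        assert len(noncore) == 4
        assert core_set | noncore | cat.gene_free_reactions == set(cat.reaction_ids)
        assert core_set.isdisjoint(noncore)
        assert not (noncore & cat.gene_free_reactions)


def test_bundle_assembly_and_serialization(default_fixture, default_enzyme_expression, tmp_path):
    fx, enz = default_fixture, default_enzyme_expression
    prof = cc.bin_profiles(enz)
    cl = cc.cluster_profiles(prof, enz, 4)
    ts = cc.standep_thresholds(enz, cl)
    core = cc.standep_core(enz, cl, ts, fx.catalog)
    bundle = cc.build_mem_bundle(enz, cl, ts, fx.catalog, core)
    # gene-associated ubiquity bounded; gene-free flagged
    gene_free = sorted(fx.catalog.gene_free_reactions)
    gene_assoc = [r for r in fx.catalog.reaction_ids if r not in gene_free]
    U = bundle.ubiquity
    assert ((U.loc[gene_assoc] >= 0) & (U.loc[gene_assoc] <= 1)).all().all()
    assert (U.loc[gene_free] == -1).all().all()
    assert bundle.gimme.threshold == 1.0
    cc.write_mem_bundle(bundle, tmp_path)
    for name in ["ubiquity.tsv", "init_weights.tsv", "gimme_weights.tsv", "mem_sets.json"]:
        assert (tmp_path / name).exists()
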