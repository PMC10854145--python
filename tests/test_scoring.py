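import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from iwhmb import network, scoring, synthetic
from iwhmb.io_formats import GeneSetCollection, InteractionNetwork, MutationProfile

SQ3 = math.sqrt(3.0)


class TestWhmb:
    def test_toy_hand_computation(self, toy):
        """Hand evaluation of the weighted burden on the toy path network.

        SET_PATH subnetwork is the path TP53-KRAS-EGFR: the middle node gets
        normalized feature value sqrt(3) for each of the three features
        (values of shape (a, b, a) always normalize to (0, sqrt(3), 0)),
        the ends get 0.  Off-network PTEN weighs 1.
        """
        whmb = toy.whmb
        # S1 mutates TP53 (w=0), PTEN (w=1, off-network), BRCA1
        assert whmb.at["SET_PATH", "S1"] == pytest.approx((0 + 1) / 4)
        # S2 mutates KRAS (w = 3*sqrt(3)) and EGFR (w=0)
        assert whmb.at["SET_PATH", "S2"] == pytest.approx(3 * SQ3 / 4)
        # SET_PAIR: BRCA1 weighs sqrt(3) for degree + sqrt(3) for eigenvector
        assert whmb.at["SET_PAIR", "S1"] == pytest.approx((1 + 2 * SQ3) / 4)
        assert whmb.at["SET_PAIR", "S3"] == pytest.approx(2 * SQ3 / 4)
        assert whmb.at["SET_PATH", "S3"] == 0.0

    def test_empty_intersection_scores_zero(self, toy):
        assert toy.whmb.at["SET_PATH", "S3"] == 0.0

    def test_out_of_network_genes_weigh_one(self):
        sets = GeneSetCollection({"S": ["A", "B", "C", "D"]})
        net = InteractionNetwork(nx.Graph([("X", "Y")]))
        table = network.centrality_table(net, sets)
        profiles = [MutationProfile("s1", {"A": 1, "B": 1})]
        whmb = scoring.compute_whmb(profiles, sets, table, net)
        assert whmb.at["S", "s1"] == pytest.approx(0.5)

    def test_use_counts_multiplies_terms(self, toy):
        table = network.centrality_table(toy.net, toy.sets)
        counted = scoring.compute_whmb(
            toy.profiles, toy.sets, table, toy.net, use_counts=True
        )
        # S1's PTEN has count 2: its weight-1 term doubles in both sets
        assert counted.at["SET_PATH", "S1"] == pytest.approx((0 + 2) / 4)
        assert counted.at["SET_PAIR", "S1"] == pytest.approx((2 + 2 * SQ3) / 4)

    def test_matches_triple_loop_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(8)})
            net = InteractionNetwork(g)
            universe = [f"g{i}" for i in range(12)]  # includes off-network genes
            sets = GeneSetCollection(
                {
                    f"S{j}": [str(x) for x in rng.choice(universe, size=5, replace=False)]
                    for j in range(3)
                }
            )
            profiles = [
                MutationProfile(
                    f"p{k}",
                    {
                        str(x): int(rng.integers(1, 4))
                        for x in rng.choice(universe, size=rng.integers(0, 7), replace=False)
                    },
                )
                for k in range(4)
            ]
            table = network.centrality_table(net, sets)
            for use_counts in (False, True):
                ours = scoring.compute_whmb(profiles, sets, table, net, use_counts)
                oracle = oracles.triple_loop_whmb(profiles, sets, table, net, use_counts)
                assert (ours == oracle).all().all()

    def test_missing_sample_zero_column_with_warning(self, toy):
        table = network.centrality_table(toy.net, toy.sets)
        with pytest.warns(UserWarning, match="absent"):
            whmb = scoring.compute_whmb(
                toy.profiles, toy.sets, table, toy.net, samples=["S1", "S9"]
            )
        assert (whmb["S9"] == 0).all()

    def test_adding_set_gene_mutation_never_decreases_whmb(self, toy):
        table = network.centrality_table(toy.net, toy.sets)
        base = scoring.compute_whmb(toy.profiles, toy.sets, table, toy.net)
        richer = [
            MutationProfile(p.sample_id, {**p.counts, "KRAS": 1}) for p in toy.profiles
        ]
        more = scoring.compute_whmb(richer, toy.sets, table, toy.net)
        assert (more.to_numpy() >= base.to_numpy() - 1e-12).all()

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"S": []})


class TestIwhmb:
    def test_column_zscore_analytic(self):
        whmb = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        out = scoring.compute_iwhmb(whmb)
        assert list(out["s"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_with_warning(self):
        whmb = pd.DataFrame({"s": [5.0, 5.0, 5.0], "t": [1.0, 2.0, 4.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            out = scoring.compute_iwhmb(whmb)
        assert (out["s"] == 0).all()

    def test_fewer_than_two_sets_errors(self):
        with pytest.raises(ValueError, match="2 gene sets"):
            scoring.compute_iwhmb(pd.DataFrame({"s": [1.0]}, index=["a"]))

    def test_per_sample_affine_invariance(self, cohort):
        """z-scoring per sample cancels any positive per-sample rescaling -
        the mechanism that removes the global mutation-burden confound."""
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 3.0, size=cohort.whmb.shape[1])
        b = rng.uniform(-1.0, 1.0, size=cohort.whmb.shape[1])
        transformed = cohort.whmb * a + b
        out = scoring.compute_iwhmb(transformed)
        assert np.abs(out.to_numpy() - cohort.iwhmb.to_numpy()).max() < 1e-9

    def test_renaming_permutes_only(self, toy):
        renamed = toy.whmb.rename(columns={"S1": "Z1"})[["S2", "Z1", "S3"]]
        out = scoring.compute_iwhmb(renamed)
        assert np.allclose(out["Z1"], toy.iwhmb["S1"])


class TestDichotomize:
    def test_threshold_rules(self):
        iwhmb = pd.DataFrame(
            {"s1": [0.01, -0.01], "s2": [0.0, 0.0], "s3": [-2.0, 2.0]},
            index=["SETA", "SETB"],
        )
        labels = scoring.dichotomize(iwhmb, "SETA")
        assert labels["s1"] == "high"
        assert labels["s2"] == "low"  # exactly zero is low
        assert labels["s3"] == "low"

    def test_unknown_set_errors(self, toy):
        with pytest.raises(KeyError):
            scoring.dichotomize(toy.iwhmb, "NOPE")

    def test_mean_zero_row_gives_both_classes(self, cohort):
        for name in cohort.iwhmb.index[:5]:
            labels = scoring.dichotomize(cohort.iwhmb, name)
            if (cohort.iwhmb.loc[name] != 0).any():
                assert set(labels) == {"high", "low"}


class TestBurdens:
    def test_tmb_definition_and_linearity(self):
        profile = MutationProfile("s", {f"g{i}": 1 for i in range(38)})
        assert scoring.tmb([profile], region_mb=38.0)["s"] == 1.0
        doubled = MutationProfile("s", {f"g{i}": 2 for i in range(38)})
        assert scoring.tmb([doubled], region_mb=38.0)["s"] == 2.0
        assert scoring.tmb([MutationProfile("empty")])["empty"] == 0.0

    def test_tmb_region_must_be_positive(self):
        with pytest.raises(ValueError):
            scoring.tmb([], region_mb=0.0)

    def test_cnb_absolute_sum_and_sign_symmetry(self):
        cnv = pd.DataFrame({"s1": [1, -1, 0], "s2": [0, 0, 0]}, index=list("abc"))
        burden = scoring.cnb(cnv)
        assert burden["s1"] == 2 and burden["s2"] == 0
        assert scoring.cnb(-cnv).equals(burden)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2}, {2, 3}, 1 / 3),
            (set(), set(), 0.0),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert scoring.jaccard(a, b) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 20), max_size=10),
        b=st.sets(st.integers(0, 20), max_size=10),
    )
    def test_bounded_and_symmetric(self, a, b):
        j = scoring.jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == scoring.jaccard(b, a)
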