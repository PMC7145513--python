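import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralogon import (
    DataError,
    SimConfig,
    WgdConfig,
    combine_weighted,
    detect_self_anchors,
    hypergeom_tail,
    score_pair_one_outgroup,
    score_pair_self,
    shuffle_null,
    simulate,
    species_weights,
    window_pair_tails,
)
from paralogon.scoring import SpeciesWeights, log_hypergeom_tail
from paralogon.synteny import SyntenyAnchor, Window

from tests.conftest import make_genome
from tests.oracles import hypergeom_tail_enum


class TestHypergeomTail:
    def test_zero_observed_gives_one(self):
        assert hypergeom_tail(100, 30, 10, 0) == 1.0
        assert hypergeom_tail(5, 0, 0, 0) == 1.0

    def test_worked_example_against_enumeration(self):
        # G=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        expected = 5 / 210
        assert math.isclose(hypergeom_tail(10, 5, 4, 4), expected, rel_tol=1e-12)
        assert math.isclose(hypergeom_tail_enum(10, 5, 4, 4), expected, rel_tol=1e-12)

    def test_tail_non_increasing_in_k(self):
        vals = [hypergeom_tail(50, 20, 15, k) for k in range(0, 16)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_parameter_violations_rejected(self):
        for bad in [(10, 11, 5, 1), (10, 5, 11, 1), (10, 5, 4, 5), (10, 3, 5, 4)]:
            with pytest.raises(DataError):
                hypergeom_tail(*bad)

    def test_log_tail_stable_for_large_population(self):
        lt = log_hypergeom_tail(10**6, 500, 400, 350)
        assert np.isfinite(lt) and lt < -100

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_cases_match_enumeration(self, data):
        G = data.draw(st.integers(2, 11))
        K = data.draw(st.integers(0, G))
        n = data.draw(st.integers(0, G))
        k = data.draw(st.integers(0, min(n, K)))
        assert math.isclose(
            hypergeom_tail(G, K, n, k), hypergeom_tail_enum(G, K, n, k), abs_tol=1e-12
        )


class TestSpeciesWeights:
    @staticmethod
    def sim(names, entries):
        s = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), v in entries.items():
            s.loc[a, b] = s.loc[b, a] = v
        return s

    def test_independent_species_get_unit_weight(self):
        w = species_weights(self.sim(["a", "b", "c"], {}))
        assert w.weights == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_clone_pair_shares_one_unit_of_weight(self):
        w = species_weights(self.sim(["a", "a2", "b"], {("a", "a2"): 1.0}))
        assert math.isclose(w.weights["a"], 0.5)
        assert math.isclose(w.weights["a2"], 0.5)
        assert math.isclose(w.weights["a"] + w.weights["a2"], w.weights["b"])

    def test_half_similar_pair(self):
        w = species_weights(self.sim(["a", "b", "c"], {("a", "b"): 0.5}))
        assert math.isclose(w.weights["a"], 2 / 3)
        assert math.isclose(w.weights["b"], 2 / 3)
        assert math.isclose(w.weights["c"], 1.0)


class TestCombineWeighted:
    def test_single_species_identity(self):
        w = SpeciesWeights({"a": 1.0}, pd.DataFrame([[1.0]], index=["a"], columns=["a"]))
        assert math.isclose(combine_weighted({"a": 0.037}, w), 0.037)

    def test_equal_weights_geometric_mean(self):
        s = TestSpeciesWeights.sim(["a", "b"], {})
        w = species_weights(s)
        assert math.isclose(combine_weighted({"a": 0.01, "b": 0.0001}, w), 0.001)

    def test_clone_duplication_invariance(self):
        base = TestSpeciesWeights.sim(["a", "b", "c"], {("a", "b"): 0.3, ("b", "c"): 0.6})
        w0 = species_weights(base)
        q = {"a": 0.004, "b": 0.2, "c": 0.7}
        q0 = combine_weighted(q, w0)
        # duplicate c exactly: similarity 1 with c, c's similarities to others copied
        dup = TestSpeciesWeights.sim(
            ["a", "b", "c", "c2"],
            {("a", "b"): 0.3, ("b", "c"): 0.6, ("b", "c2"): 0.6, ("c", "c2"): 1.0},
        )
        w1 = species_weights(dup)
        q1 = combine_weighted({**q, "c2": q["c"]}, w1)
        assert abs(q1 - q0) < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_clone_invariance_on_random_panels(self, data):
        n = data.draw(st.integers(1, 5))
        names = [f"s{i}" for i in range(n)]
        # off-diagonal similarities kept modest so the weight system stays
        # diagonally dominant, as Jaccard matrices of real panels are
        entries = {}
        for i in range(n):
            for j in range(i + 1, n):
                entries[(names[i], names[j])] = data.draw(
                    st.floats(0, 0.2, allow_nan=False)
                )
        s = TestSpeciesWeights.sim(names, entries)
        qs = {
            sp: data.draw(st.floats(1e-5, 1.0, allow_nan=False))
            for sp in names
        }
        clone_of = data.draw(st.sampled_from(names))
        q0 = combine_weighted(qs, species_weights(s))
        names2 = names + ["clone"]
        entries2 = dict(entries)
        for sp in names:
            if sp != clone_of:
                key = tuple(sorted((sp, clone_of)))
                entries2[(sp, "clone")] = entries[key] if key in entries else entries[(key[1], key[0])] if (key[1], key[0]) in entries else entries[key]
        entries2[(clone_of, "clone")] = 1.0
        s2 = TestSpeciesWeights.sim(names2, entries2)
        q1 = combine_weighted({**qs, "clone": qs[clone_of]}, species_weights(s2))
        assert abs(q1 - q0) < 1e-9

    def test_combined_q_monotone_in_components(self):
        s = TestSpeciesWeights.sim(["a", "b", "c"], {("a", "b"): 0.4})
        w = species_weights(s)
        q = {"a": 0.05, "b": 0.2, "c": 0.9}
        base = combine_weighted(q, w)
        assert combine_weighted({**q, "b": 0.1}, w) < base
        assert combine_weighted({**q, "c": 0.95}, w) > base

    def test_empty_input_rejected(self):
        w = species_weights(TestSpeciesWeights.sim(["a"], {}))
        with pytest.raises(DataError):
            combine_weighted({}, w)


def _anchor(out_win, targets, size, n_tested):
    return SyntenyAnchor(out_win, tuple(targets), size, n_tested)


def _win(chrom, start, ids, size):
    return Window("t", chrom, start, size, tuple(ids))


class TestScorePairOutgroup:
    def _single_anchor(self, k1, k2, n, G=200, K=10, m=4):
        w1 = _win("A", 0, [f"a{i}" for i in range(K)], K)
        w2 = _win("B", 0, [f"b{i}" for i in range(K)], K)
        ow = Window("o", "1", 0, K, tuple(f"o{i}" for i in range(K)))
        anchor = _anchor(ow, [(w1, k1, n), (w2, k2, n)], K, m)
        return anchor, ("a0", "b0"), G

    def test_null_support_gives_q_one(self):
        anchor, pair, G = self._single_anchor(k1=0, k2=0, n=0)
        assert score_pair_one_outgroup(pair, [anchor], G) == 1.0

    def test_direct_formula_instance(self):
        anchor, pair, G = self._single_anchor(k1=7, k2=6, n=9, m=4)
        p1 = hypergeom_tail(G, 10, 9, 7)
        p2 = hypergeom_tail(G, 10, 9, 6)
        expected = min(1.0, p1 * p2 * 4)
        assert math.isclose(score_pair_one_outgroup(pair, [anchor], G), expected, rel_tol=1e-9)

    def test_unsupported_pair_not_scored(self):
        anchor, _, G = self._single_anchor(k1=5, k2=5, n=9)
        assert score_pair_one_outgroup(("zz1", "zz2"), [anchor], G) is None

    def test_min_over_anchors_then_geometric_mean_over_sizes(self):
        a1, pair, G = self._single_anchor(k1=7, k2=6, n=9, m=4)
        a2, _, _ = self._single_anchor(k1=9, k2=8, n=9, m=4)  # stronger, same size
        w1 = _win("A", 0, ["a0"] + [f"c{i}" for i in range(19)], 20)
        w2 = _win("B", 0, ["b0"] + [f"d{i}" for i in range(19)], 20)
        ow = Window("o", "1", 0, 20, tuple(f"o{i}" for i in range(20)))
        a3 = _anchor(ow, [(w1, 12, 15), (w2, 11, 15)], 20, 3)
        q_small = score_pair_one_outgroup(pair, [a1, a2], G)
        q_both = score_pair_one_outgroup(pair, [a1, a2, a3], G)
        q2 = min(1.0, hypergeom_tail(G, 20, 15, 12) * hypergeom_tail(G, 20, 15, 11) * 3)
        q1 = min(
            1.0,
            hypergeom_tail(G, 10, 9, 9) * hypergeom_tail(G, 10, 9, 8) * 4,
        )
        assert math.isclose(q_small, q1, rel_tol=1e-9)  # min over anchors
        assert math.isclose(q_both, math.sqrt(q1 * q2), rel_tol=1e-9)

    def test_true_pairs_score_lower_than_shuffled_labels(self, small_truth, small_cfg):
        from paralogon.scoring import score_candidates
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(0)
        true_pairs = sorted(small_truth.all_wgd_pairs())
        g2s = [b for _, b in true_pairs]
        rng.shuffle(g2s)
        fake = sorted(
            {tuple(sorted((a, b))) for (a, _), b in zip(true_pairs, g2s) if a != b}
            - set(true_pairs)
        )
        orth = {sp: sorted(hs.orthologs) for sp, hs in small_truth.orthologs.items()}
        scores_true = score_candidates(
            small_truth.target, small_truth.outgroups, orth, true_pairs[:150], [], small_cfg
        )
        scores_fake = score_candidates(
            small_truth.target, small_truth.outgroups, orth, fake[:150], [], small_cfg
        )
        qt = [scores_true[p].q_outgroup if p in scores_true else 1.0 for p in true_pairs[:150]]
        qf = [scores_fake[p].q_outgroup if p in scores_fake else 1.0 for p in fake[:150]]
        stat = mannwhitneyu(qt, qf, alternative="less")
        assert stat.pvalue < 1e-10


class TestScorePairSelf:
    def test_symmetric_toy_paralogon_scores_below_001(self):
        n = 20
        gm = make_genome("t", {
            "A": [f"a{i:03d}" for i in range(n)],
            "B": [f"b{i:03d}" for i in range(n)],
        })
        paralogs = [(f"a{i:03d}", f"b{i:03d}") for i in range(n)]
        cfg = WgdConfig(window_sizes=(20,), window_step=20)
        anchors = detect_self_anchors(gm, paralogs, cfg)
        q = score_pair_self(("a005", "b005"), anchors, gm.n_genes, cfg)
        assert q is not None and q < 0.01

    def test_overlapping_windows_not_scored(self):
        gm = make_genome("t", {"1": [f"g{i:03d}" for i in range(30)]})
        paralogs = [("g000", "g001")]
        cfg = WgdConfig(window_sizes=(10,), window_step=5)
        anchors = detect_self_anchors(gm, paralogs, cfg)
        assert score_pair_self(("g000", "g001"), anchors, 30, cfg) is None

    def test_null_self_tails_roughly_uniform(self):
        """On an order-shuffled genome self tails are not anti-conservative."""
        truth = simulate(SimConfig(n_genes=500, n_chromosomes=3, wgd_rounds=1,
                                   retention_prob=0.5, n_outgroups=0, seed=21))
        pairs = sorted(truth.all_wgd_pairs())
        cfg = WgdConfig(window_sizes=(100,))
        fracs = []
        for rep in range(20):
            shuf = shuffle_null(truth.target, seed=rep)
            tails = [
                t for t, *_ in window_pair_tails(
                    shuf, shuf, [p for q in pairs for p in (q, q[::-1])], cfg
                )
            ]
            fracs.append(np.mean([t <= 0.05 for t in tails]) if tails else 0.0)
        assert np.mean(fracs) <= 0.05 + 0.02


class TestWindowPairTails:
    def test_tails_carry_consistent_parameters(self, small_truth, small_cfg):
        og = small_truth.outgroups["outgroup1"]
        orth = sorted(small_truth.orthologs["outgroup1"].orthologs)
        rows = window_pair_tails(og, small_truth.target, orth, small_cfg)
        assert rows
        for tail, G, K, n, k in rows:
            assert 0 < tail <= 1
            assert 0 <= k <= min(n, K) and n <= G == small_truth.target.n_genes
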