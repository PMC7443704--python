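"""Dotprops, similarity scoring (vs brute force), clustering, splitting."""

import numpy as np
import pandas as pd
import pytest

from vpconn.morphology import (DegenerateMorphologyError, DotProps, ScoreTable,
                               cluster_types, linkage_to_newick,
                               match_contralateral, mean_normalized_score,
                               score_matrix, similarity, split_dendrites,
                               to_dotprops, dendrite_branches)
from vpconn.core import BoxVolume
from vpconn.synth import (SynthConfig, generate_connectome,
                          make_clustering_config)
from tests.test_core import make_skeleton

SIGMA = 3000.0


def brute_force_similarity(q: DotProps, t: DotProps, sigma=SIGMA) -> float:
    """Independent oracle: exhaustive all-pairs nearest neighbour."""
    total = 0.0
    for p, tp in zip(q.points, q.tangents):
        d = np.linalg.norm(t.points - p, axis=1)
        j = int(np.argmin(d))          # lowest index on ties
        total += np.exp(-d[j] / sigma) * abs(float(tp @ t.tangents[j]))
    return total


def random_dotprops(rng, n, scale=10_000.0, offset=0.0):
    tg = rng.standard_normal((n, 3))
    tg /= np.linalg.norm(tg, axis=1, keepdims=True)
    return DotProps(rng.uniform(0, scale, (n, 3)) + offset, tg)


class TestToDotprops:
    def test_straight_segment_resamples_to_collinear_points(self):
        sk = make_skeleton("s", [(1, -1, 0, 0, 0), (2, 1, 8000, 0, 0)])
        dp = to_dotprops(sk, spacing=2000.0, k=3)
        assert len(dp.points) == 5
        assert np.allclose(dp.points[:, 1:], 0.0)
        assert np.allclose(np.abs(dp.tangents[:, 0]), 1.0, atol=1e-9)

    def test_corner_tangents_stay_unit_norm(self):
        sk = make_skeleton("s", [(1, -1, 0, 0, 0), (2, 1, 5000, 0, 0),
                                 (3, 2, 5000, 5000, 0)])
        dp = to_dotprops(sk, spacing=1000.0, k=4)
        assert np.allclose(np.linalg.norm(dp.tangents, axis=1), 1.0, atol=1e-9)

    def test_k_larger_than_cloud_clamps(self):
        sk = make_skeleton("s", [(1, -1, 0, 0, 0), (2, 1, 1000, 0, 0)])
        dp = to_dotprops(sk, spacing=1000.0, k=50)
        assert len(dp.points) >= 2

    def test_single_node_skeleton_rejected(self):
        sk = make_skeleton("s", [(1, -1, 0, 0, 0)])
        with pytest.raises(DegenerateMorphologyError):
            to_dotprops(sk)


class TestSimilarity:
    def test_identical_clouds_score_cloud_size(self, rng):
        dp = random_dotprops(rng, 20)
        assert similarity(dp, dp) == pytest.approx(20.0)

    def test_single_point_at_sigma_gives_exp_minus_one(self):
        q = DotProps([[0, 0, 0]], [[1, 0, 0]])
        t = DotProps([[SIGMA, 0, 0]], [[1, 0, 0]])
        assert similarity(q, t) == pytest.approx(np.exp(-1.0))

    def test_orthogonal_tangents_score_zero(self):
        q = DotProps([[0, 0, 0]], [[1, 0, 0]])
        t = DotProps([[0, 0, 0]], [[0, 1, 0]])
        assert similarity(q, t) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = random_dotprops(rng, int(rng.integers(2, 51)))
        t = random_dotprops(rng, int(rng.integers(2, 51)))
        assert similarity(q, t) == pytest.approx(brute_force_similarity(q, t),
                                                 abs=1e-9)

    def test_score_table_overrides_kernel(self):
        table = ScoreTable(np.array([0.0, 1e3, 1e9]), np.array([0.0, 0.5, 1.0]),
                           np.array([[1.0, 2.0], [3.0, 4.0]]))
        q = DotProps([[0, 0, 0]], [[1, 0, 0]])
        t = DotProps([[5000, 0, 0]], [[1, 0, 0]])   # far bin, high |dot| bin
        assert similarity(q, t, score_table=table) == 4.0


class TestMeanNormalizedScore:
    def test_self_score_is_one(self, rng):
        for n in (1, 5, 40):
            dp = random_dotprops(rng, n)
            assert mean_normalized_score(dp, dp) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = random_dotprops(rng, 30), random_dotprops(rng, 12)
        assert mean_normalized_score(a, b) == pytest.approx(
            mean_normalized_score(b, a))

    def test_far_apart_clouds_score_near_zero(self, rng):
        a = random_dotprops(rng, 25)
        b = random_dotprops(rng, 25, offset=1e6)   # ~330 sigma away
        assert mean_normalized_score(a, b) < 0.01


class TestClustering:
    def test_two_identical_one_distant_gives_two_groups(self):
        m = pd.DataFrame([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
                         index=list("abc"), columns=list("abc"))
        labels, _ = cluster_types(m, 0.8)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_cut_at_zero_isolates_every_neuron(self):
        rng = np.random.default_rng(2)
        sim = rng.uniform(0.1, 0.6, (4, 4))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        m = pd.DataFrame(sim, index=list("abcd"), columns=list("abcd"))
        labels, _ = cluster_types(m, 0.0)
        assert labels.nunique() == 4

    def test_non_finite_scores_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]],
                         index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            cluster_types(m)

    def test_recovers_planted_envelope_types(self):
        from sklearn.metrics import adjusted_rand_score
        conn, gt = generate_connectome(make_clustering_config(2, 3, seed=3))
        dps = {s: to_dotprops(conn.skeletons[s], 1000.0)
               for s in sorted(conn.skeletons)}
        labels, z = cluster_types(score_matrix(dps), 0.8)
        truth = [gt.type_labels[s] for s in labels.index]
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        nwk = linkage_to_newick(z, list(labels.index))
        assert nwk.endswith(";") and nwk.count(",") == len(labels) - 1


class TestContralateral:
    def test_exact_mirror_pairs_everyone(self, rng):
        from vpconn.core import NeuronMeta
        dps, meta = {}, {}
        for i in range(5):
            r = random_dotprops(rng, 15, offset=50_000.0)
            l = r.mirrored(0.0)
            dps[f"r{i}"], dps[f"l{i}"] = r, l
            meta[f"r{i}"] = NeuronMeta(f"r{i}", "PN", hemisphere="R",
                                       contralateral_partner=f"l{i}")
            meta[f"l{i}"] = NeuronMeta(f"l{i}", "PN", hemisphere="L",
                                       contralateral_partner=f"r{i}")
        count, pairs = match_contralateral(dps, meta)
        assert count == 10

    def test_generator_bilateral_types_pair_under_jitter(self):
        cfg = SynthConfig(seed=13, rn_counts={}, n_kcs=0, inputs_per_claw=0,
                          bouton_counts={}, rn_input_rate=0.0,
                          partner_degrees=[], noise=500.0)
        conn, gt = generate_connectome(cfg)
        pns = [s for s, m in conn.meta.items() if m.neuron_class == "PN"]
        dps = {s: to_dotprops(conn.skeletons[s], 1000.0) for s in pns}
        count, _ = match_contralateral(dps, conn.meta)
        annotated = sum(1 for s in pns if conn.meta[s].contralateral_partner)
        assert annotated >= 10
        assert count >= int(0.9 * annotated)

    def test_single_hemisphere_input_pairs_nothing(self, rng):
        from vpconn.core import NeuronMeta
        dps = {f"r{i}": random_dotprops(rng, 10) for i in range(3)}
        meta = {k: NeuronMeta(k, "PN", hemisphere="R") for k in dps}
        count, pairs = match_contralateral(dps, meta)
        assert count == 0 and pairs == []


class TestSplitDendrites:
    calyx = BoxVolume("CA", [0, 0, 0], [100, 100, 100])

    def test_planted_claws_recovered_from_generator(self, conn):
        ca = conn.volumes["CA_R"]
        for kc in list(conn.claws)[:5]:
            sk = conn.skeletons[kc]
            dend = split_dendrites(sk, ca)
            planted = set()
            children = sk.children_map()
            for r in conn.claws[kc]:
                stack = [r]
                while stack:
                    n = stack.pop()
                    planted.add(n)
                    stack.extend(children[n])
            assert dend == planted
            assert sorted(dendrite_branches(sk, dend)) == sorted(conn.claws[kc])

    def test_skeleton_outside_calyx_yields_empty(self):
        sk = make_skeleton("s", [(1, -1, 500, 0, 0), (2, 1, 600, 0, 0)])
        assert split_dendrites(sk, self.calyx) == set()

    def test_unbranched_tract_has_no_dendrites(self):
        sk = make_skeleton("s", [(1, -1, -10, 50, 50), (2, 1, 50, 50, 50),
                                 (3, 2, 120, 50, 50)])
        assert split_dendrites(sk, self.calyx) == set()
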