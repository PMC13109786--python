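import numpy as np
import pytest

from gppi.errors import ConfigError
from gppi.graphs import ResidueGraph, build_graph
from gppi.model import (EncoderConfig, GraphBatch, InteractionModel,
                        init_model, predict_pair)
from gppi.synthetic_data import generate_chain


def permute_graph(g: ResidueGraph, perm: np.ndarray) -> ResidueGraph:
    """Relabel nodes by ``perm`` (new index of old node i is inv[i])."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    edges = inv[g.edges]
    swap = edges[:, 0] > edges[:, 1]
    edges[swap] = edges[swap][:, ::-1]
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return ResidueGraph(
        protein_id=g.protein_id,
        node_features=g.node_features[perm],
        coords=g.coords[perm],
        edges=edges[order],
        distances=g.distances[order],
        residue_labels=[g.residue_labels[i] for i in perm],
        cutoff=g.cutoff,
    )


class TestInit:
    def test_same_seed_identical_parameters(self):
        cfg = EncoderConfig(n_layers=2, hidden_dim=16, n_heads=4, seed=5)
        a, b = init_model(cfg), init_model(cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_different_seeds_differ(self):
        a = init_model(EncoderConfig(n_layers=1, hidden_dim=8, n_heads=2, seed=1))
        b = init_model(EncoderConfig(n_layers=1, hidden_dim=8, n_heads=2, seed=2))
        assert any(not np.array_equal(a.params[k].data, b.params[k].data)
                   for k in a.params)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ConfigError):
            EncoderConfig(hidden_dim=63, n_heads=4)

    def test_invalid_layer_count_rejected(self):
        with pytest.raises(ConfigError):
            EncoderConfig(n_layers=0)


def test_attention_weights_sum_to_one_per_neighborhood(chain_pair, small_model):
    """The softmax over each node's in-edges must be a distribution.

    Verified by reproducing the score->softmax stage from the model's own
    parameters and the packed batch layout.
    """
    g, _ = chain_pair
    batch = GraphBatch([g])
    m = small_model
    import gppi.autograd as ag
    x = ag.Tensor(batch.x)
    h = ag.elu(x @ m.params["w_in"] + m.params["b_in"]).data
    s, t = h @ m.params["layer0.w_src"].data, h @ m.params["layer0.w_dst"].data
    msum = s[batch.src] + t[batch.dst] + m.params["layer0.bias"].data
    z = np.where(msum > 0, msum, 0.2 * msum)
    H = m.config.n_heads
    dh = m.config.hidden_dim // H
    scores = np.einsum("ehd,hd->eh", z.reshape(-1, H, dh),
                       m.params["layer0.att"].data.reshape(H, dh))
    scores += batch.dist_norm[:, None] * m.params["layer0.att_dist"].data.reshape(1, H)
    e = np.exp(scores - np.maximum.reduceat(scores, batch.seg_starts[:-1], axis=0)[batch.seg_of])
    alpha = e / np.add.reduceat(e, batch.seg_starts[:-1], axis=0)[batch.seg_of]
    sums = np.add.reduceat(alpha, batch.seg_starts[:-1], axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_embedding_invariant_under_node_permutation(chain_pair, small_model):
    g, _ = chain_pair
    emb, _ = small_model.encode_protein(g)
    perm = np.random.default_rng(3).permutation(g.n_nodes)
    emb_p, _ = small_model.encode_protein(permute_graph(g, perm))
    np.testing.assert_allclose(emb, emb_p, atol=1e-5)


def test_single_layer_two_node_forward_matches_hand_computation(table):
    """Independent scalar-by-scalar forward pass on a 2-node, 1-edge graph."""
    from tests.conftest import make_structure

    st = make_structure([[0, 0, 0], [3.8, 0, 0]], codes="AW")
    g = build_graph(st, table)
    cfg = EncoderConfig(n_layers=1, n_heads=1, hidden_dim=2, embedding_dim=2,
                        dropout=0.0, use_edge_distance=False, seed=0)
    m = init_model(cfg)
    # hand-set every parameter
    m.params["w_in"].data = np.arange(10).reshape(5, 2) / 10.0
    m.params["b_in"].data = np.array([0.05, -0.05])
    m.params["layer0.w_src"].data = np.array([[1.0, 0.5], [0.0, 1.0]])
    m.params["layer0.w_dst"].data = np.array([[0.5, 0.0], [1.0, 1.0]])
    m.params["layer0.bias"].data = np.array([0.1, 0.2])
    m.params["layer0.att"].data = np.array([0.3, -0.4]).reshape(1, 1, 2)
    m.params["layer0.ln_gain"].data = np.array([1.0, 1.0])
    m.params["layer0.ln_bias"].data = np.array([0.0, 0.0])
    m.params["w_pool"].data = np.eye(2)
    m.params["b_pool"].data = np.zeros(2)

    x = g.node_features

    def elu(v):
        return np.where(v > 0, v, np.expm1(v))

    h0 = elu(x @ m.params["w_in"].data + m.params["b_in"].data)
    s = h0 @ m.params["layer0.w_src"].data
    t = h0 @ m.params["layer0.w_dst"].data
    # each node has exactly one in-neighbor -> attention weight is 1, and
    # the single final-layer head contributes its value transform directly
    agg = np.stack([s[1], s[0]])
    pre = h0 + agg
    mu = pre.mean(-1, keepdims=True)
    var = ((pre - mu) ** 2).mean(-1, keepdims=True)
    hn = elu((pre - mu) / np.sqrt(var + 1e-5))
    expected = hn.mean(axis=0) @ m.params["w_pool"].data

    emb, _ = m.encode_protein(g)
    np.testing.assert_allclose(emb, expected, atol=1e-10)


class TestPairPrediction:
    def test_symmetry_over_random_pairs_and_models(self, table):
        rng = np.random.default_rng(0)
        for trial in range(5):
            cfg = EncoderConfig(n_layers=2, n_heads=2, hidden_dim=8,
                                embedding_dim=6, dropout=0.0, seed=trial)
            m = init_model(cfg)
            ga = build_graph(generate_chain(int(rng.integers(10, 30)),
                                            seed=100 + trial), table)
            gb = build_graph(generate_chain(int(rng.integers(10, 30)),
                                            seed=200 + trial), table)
            assert abs(m.predict_pair(ga, gb) - m.predict_pair(gb, ga)) <= 1e-7

    def test_self_pair_cosine_component_is_one(self, chain_pair, small_model):
        g, _ = chain_pair
        emb, _ = small_model.encode_protein(g)
        cos = emb @ emb / (np.linalg.norm(emb) ** 2 + 1e-12)
        assert abs(cos - 1.0) < 1e-9

    def test_probability_strictly_inside_unit_interval(self, chain_pair, small_model):
        g, g2 = chain_pair
        p = small_model.predict_pair(g, g2)
        assert 0.0 < p < 1.0

    def test_probability_invariant_under_node_permutation(self, chain_pair, small_model):
        g, g2 = chain_pair
        p = small_model.predict_pair(g, g2)
        perm = np.random.default_rng(9).permutation(g.n_nodes)
        p2 = small_model.predict_pair(permute_graph(g, perm), g2)
        assert abs(p - p2) <= 1e-5

    def test_repeated_evaluation_bit_stable(self, chain_pair, small_model):
        g, g2 = chain_pair
        assert small_model.predict_pair(g, g2) == small_model.predict_pair(g, g2)

    def test_feature_dimension_mismatch_rejected(self, chain_pair, small_model):
        g, g2 = chain_pair
        bad = ResidueGraph(g.protein_id, g.node_features[:, :4], g.coords,
                           g.edges, g.distances, g.residue_labels, g.cutoff)
        with pytest.raises(ConfigError):
            small_model.predict_pair(bad, g2)


def test_checkpoint_round_trip(tmp_path, chain_pair, small_model):
    g, g2 = chain_pair
    path = tmp_path / "model.npz"
    small_model.save(path)
    loaded = InteractionModel.load(path)
    assert loaded.config == small_model.config
    assert loaded.predict_pair(g, g2) == small_model.predict_pair(g, g2)


def test_cosine_head_variant_runs_and_is_symmetric(chain_pair):
    g, g2 = chain_pair
    m = init_model(EncoderConfig(n_layers=1, n_heads=2, hidden_dim=8,
                                 embedding_dim=4, dropout=0.0,
                                 pair_mode="cosine", seed=3))
    assert abs(m.predict_pair(g, g2) - m.predict_pair(g2, g)) <= 1e-7
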