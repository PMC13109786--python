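"""Siamese graph-attention interaction model.

Both proteins of a pair are encoded by the SAME GATv2 encoder (shared
weights): an input projection lifts the 5-dim residue features to the hidden
width, then ``n_layers`` rounds of multi-head attention message passing
refine the node states, and mean pooling plus a learned projection yields a
fixed-size graph embedding. The pair-scoring head is symmetric by
construction: it sees only the cosine similarity, the element-wise absolute
difference and the element-wise product of the two embeddings, so swapping
the inputs cannot change the logit.

Attention follows the GATv2 formulation: the scoring vector is applied
*after* the LeakyReLU of the combined source+target representation, and the
scores are softmax-normalized over each node's in-neighborhood. Multi-head
outputs are concatenated in intermediate layers and averaged in the final
layer. Each attention layer sits inside a residual connection with layer
normalization; when ``use_edge_distance`` is on, the dimensionless edge
length (distance / cutoff) is appended to the neighbor-pair representation
before scoring.

Everything runs on the package's own autodiff core, so the same forward
pass serves prediction, training and input-gradient saliency.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigError, GraphError
from .graphs import ResidueGraph

_LEAKY_SLOPE = 0.2  # GATv2 convention inside attention scoring


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and initialization parameters of the shared encoder."""

    n_layers: int = 8
    n_heads: int = 4
    hidden_dim: int = 64
    embedding_dim: int = 128
    attention_variant: str = "GATv2"
    dropout: float = 0.1
    use_edge_distance: bool = True
    seed: int = 0
    head_hidden: int = 32          # width of the pair head's hidden layer
    pair_mode: str = "learned"     # "learned" | "cosine"
    dtype: str = "float64"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.hidden_dim % self.n_heads != 0:
            raise ConfigError(
                f"hidden_dim ({self.hidden_dim}) must be divisible by "
                f"n_heads ({self.n_heads})")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        if self.attention_variant != "GATv2":
            raise ConfigError("only the GATv2 attention variant is supported")
        if self.pair_mode not in ("learned", "cosine"):
            raise ConfigError("pair_mode must be 'learned' or 'cosine'")


class GraphBatch:
    """One or more residue graphs packed into a single disconnected graph.

    Edges are expanded to both directions and sorted by target node so the
    per-neighborhood attention softmax can run on contiguous segments.
    """

    def __init__(self, graphs: list[ResidueGraph], dtype=np.float64):
        if not graphs:
            raise GraphError("empty graph batch")
        feats, coords_offset = [], 0
        srcs, dsts, dnorms = [], [], []
        self.graph_slices = []
        for g in graphs:
            n = g.n_nodes
            if n < 1:
                raise GraphError(f"{g.protein_id}: empty graph")
            feats.append(np.asarray(g.node_features, dtype=dtype))
            if g.n_edges:
                e = g.edges + coords_offset
                srcs.append(np.concatenate([e[:, 0], e[:, 1]]))
                dsts.append(np.concatenate([e[:, 1], e[:, 0]]))
                dn = g.distances / g.cutoff  # dimensionless, in (0, 1)
                dnorms.append(np.concatenate([dn, dn]))
            self.graph_slices.append((coords_offset, coords_offset + n))
            coords_offset += n
        self.n_nodes = coords_offset
        self.n_graphs = len(graphs)
        self.x = np.concatenate(feats, axis=0)
        if srcs:
            src = np.concatenate(srcs)
            dst = np.concatenate(dsts)
            dn_all = np.concatenate(dnorms)
            order = np.argsort(dst, kind="stable")
            self.src, self.dst = src[order], dst[order]
            self.dist_norm = dn_all[order].astype(dtype)
            # contiguous segments of equal dst
            self.seg_nodes, starts = np.unique(self.dst, return_index=True)
            self.seg_starts = np.append(starts, self.dst.size)
            self.seg_of = np.searchsorted(self.seg_nodes, self.dst)
            ne = self.src.size
            ones = np.ones(ne, dtype=dtype)
            self.scatter_src = csr_matrix(
                (ones, (self.src, np.arange(ne))), shape=(self.n_nodes, ne))
            self.scatter_dst = csr_matrix(
                (ones, (self.dst, np.arange(ne))), shape=(self.n_nodes, ne))
        else:
            raise GraphError("graph batch contains no edges")
        # mean pooling operator (n_graphs x n_nodes)
        rows = np.concatenate([
            np.full(hi - lo, gi) for gi, (lo, hi) in enumerate(self.graph_slices)
        ])
        vals = np.concatenate([
            np.full(hi - lo, 1.0 / (hi - lo), dtype=dtype)
            for (lo, hi) in self.graph_slices
        ])
        self.pool = csr_matrix(
            (vals, (rows, np.arange(self.n_nodes))),
            shape=(self.n_graphs, self.n_nodes))


def _gat_attention(s: Tensor, t: Tensor, bias: Tensor, att: Tensor,
                   att_dist: Tensor | None, batch: GraphBatch,
                   n_heads: int, head_dim: int) -> Tensor:
    """One fused GATv2 message-passing block.

    Inputs ``s``/``t`` are the source/target linear transforms of the node
    states, (N x H*dh). Computes, per directed edge (src -> dst),
    ``e = att . LeakyReLU(s[src] + t[dst] + bias)`` per head (plus the
    distance term), softmax-normalizes over each in-neighborhood and
    aggregates ``alpha * s[src]`` at the target: returns (N x H*dh).

    Implemented as a single autograd node with a hand-derived adjoint to
    keep the number of edge-sized temporaries low; its correctness is
    pinned by the end-to-end finite-difference gradient check.
    """
    src, dst = batch.src, batch.dst
    starts, seg_of = batch.seg_starts, batch.seg_of
    E = src.size
    H, dh = n_heads, head_dim
    a = att.data.reshape(H, dh)

    s_src = s.data[src]
    m = s_src + t.data[dst]
    m += bias.data
    pos = m > 0
    if ag.KINK_TRACE is not None:
        ag.KINK_TRACE.append(pos.copy())
    z = np.where(pos, m, _LEAKY_SLOPE * m)
    scores = np.einsum("ehd,hd->eh", z.reshape(E, H, dh), a)
    if att_dist is not None:
        scores += batch.dist_norm[:, None] * att_dist.data.reshape(1, H)
    seg_max = np.maximum.reduceat(scores, starts[:-1], axis=0)
    alpha = np.exp(scores - seg_max[seg_of])
    seg_sum = np.add.reduceat(alpha, starts[:-1], axis=0)
    alpha /= seg_sum[seg_of]
    weighted = s_src.reshape(E, H, dh) * alpha[:, :, None]
    out_data = batch.scatter_dst @ weighted.reshape(E, H * dh)

    def backward(g):
        g_flat = g[dst].reshape(E, H, dh)
        g_alpha = np.einsum("ehd,ehd->eh", g_flat, s_src.reshape(E, H, dh))
        g_ssrc = (g_flat * alpha[:, :, None]).reshape(E, H * dh)
        # softmax adjoint per segment and head
        seg_dot = np.add.reduceat(alpha * g_alpha, starts[:-1], axis=0)
        g_scores = alpha * (g_alpha - seg_dot[seg_of])
        if att_dist is not None:
            att_dist._accum(
                (g_scores * batch.dist_norm[:, None]).sum(axis=0).reshape(att_dist.shape))
        att._accum(np.einsum("ehd,eh->hd", z.reshape(E, H, dh),
                             g_scores).reshape(att.shape))
        g_z = np.einsum("eh,hd->ehd", g_scores, a).reshape(E, H * dh)
        g_m = np.where(pos, g_z, _LEAKY_SLOPE * g_z)
        bias._accum(g_m.sum(axis=0))
        g_ssrc += g_m
        s._accum(batch.scatter_src @ g_ssrc)
        t._accum(batch.scatter_dst @ g_m)

    parents = (s, t, bias, att) + (() if att_dist is None else (att_dist,))
    return Tensor._wrap(out_data, parents, backward)


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class InteractionModel:
    """Shared-weight encoder plus symmetric pair-scoring head."""

    N_FEATURES = 5

    def __init__(self, config: EncoderConfig, params: dict[str, Tensor] | None = None,
                 property_table_hash: str = ""):
        self.config = config
        self.property_table_hash = property_table_hash
        self.params = params if params is not None else self._init_params()

    # -- parameters -----------------------------------------------------------
    def _init_params(self) -> dict[str, Tensor]:
        cfg = self.config
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        h, H = cfg.hidden_dim, cfg.n_heads
        dh = h // H
        p: dict[str, np.ndarray] = {}
        p["w_in"] = _glorot(rng, (self.N_FEATURES, h), dtype)
        p["b_in"] = np.zeros(h, dtype=dtype)
        for layer in range(cfg.n_layers):
            last = layer == cfg.n_layers - 1
            out_dim = H * h if last else h
            head_dim = h if last else dh
            pre = f"layer{layer}."
            p[pre + "w_src"] = _glorot(rng, (h, out_dim), dtype)
            p[pre + "w_dst"] = _glorot(rng, (h, out_dim), dtype)
            p[pre + "bias"] = np.zeros(out_dim, dtype=dtype)
            p[pre + "att"] = _glorot(rng, (1, H, head_dim), dtype)
            p[pre + "att_dist"] = np.zeros((1, H), dtype=dtype)
            p[pre + "ln_gain"] = np.ones(h, dtype=dtype)
            p[pre + "ln_bias"] = np.zeros(h, dtype=dtype)
        p["w_pool"] = _glorot(rng, (h, cfg.embedding_dim), dtype)
        p["b_pool"] = np.zeros(cfg.embedding_dim, dtype=dtype)
        if cfg.pair_mode == "cosine":
            p["head_w"] = np.ones((1, 1), dtype=dtype)
            p["head_b"] = np.zeros((1, 1), dtype=dtype)
        else:
            in_dim = 2 * cfg.embedding_dim + 1
            p["head_w1"] = _glorot(rng, (in_dim, cfg.head_hidden), dtype)
            p["head_b1"] = np.zeros(cfg.head_hidden, dtype=dtype)
            p["head_w2"] = _glorot(rng, (cfg.head_hidden, 1), dtype)
            p["head_b2"] = np.zeros((1,), dtype=dtype)
        return {k: Tensor(v, requires_grad=True) for k, v in p.items()}

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def zero_grad(self):
        for t in self.params.values():
            t.zero_grad()

    # -- forward passes -------------------------------------------------------
    def _encode_batch(self, batch: GraphBatch, x: Tensor | None = None,
                      train: bool = False,
                      rng: np.random.Generator | None = None):
        """Run the encoder on a packed batch.

        Returns ``(embeddings (G x d), node_states (N x h))`` as Tensors.
        ``x`` may override the batch's node features (a leaf Tensor for
        saliency gradients).
        """
        cfg = self.config
        P = self.params
        if x is None:
            x = Tensor(batch.x)
        if x.shape[1] != self.N_FEATURES:
            raise ConfigError(
                f"expected {self.N_FEATURES}-dim node features, got {x.shape[1]}")
        h_dim, H = cfg.hidden_dim, cfg.n_heads
        dh = h_dim // H

        h = ag.elu(x @ P["w_in"] + P["b_in"])
        for layer in range(cfg.n_layers):
            last = layer == cfg.n_layers - 1
            head_dim = h_dim if last else dh
            pre = f"layer{layer}."
            s = h @ P[pre + "w_src"]
            t = h @ P[pre + "w_dst"]
            agg = _gat_attention(
                s, t, P[pre + "bias"], P[pre + "att"],
                P[pre + "att_dist"] if cfg.use_edge_distance else None,
                batch, H, head_dim)
            if last:
                agg = agg.reshape(batch.n_nodes, H, h_dim).mean(axis=1)
            h = ag.layer_norm(h + agg, P[pre + "ln_gain"], P[pre + "ln_bias"])
            h = ag.elu(h)
            if train and cfg.dropout > 0:
                h = ag.dropout(h, cfg.dropout, rng)
        pooled = ag.sparse_matmul(batch.pool, h)
        emb = pooled @ P["w_pool"] + P["b_pool"]
        return emb, h

    def _pair_logits(self, emb_a: Tensor, emb_b: Tensor) -> Tensor:
        """Symmetric combination of two embedding matrices -> logits (P x 1)."""
        P = self.params
        dot = (emb_a * emb_b).sum(axis=1, keepdims=True)
        na = ag.sqrt((emb_a * emb_a).sum(axis=1, keepdims=True) + Tensor(1e-12))
        nb = ag.sqrt((emb_b * emb_b).sum(axis=1, keepdims=True) + Tensor(1e-12))
        cos = dot / (na * nb)
        if self.config.pair_mode == "cosine":
            return cos @ P["head_w"] + P["head_b"]
        feats = ag.concat([cos, ag.abs_(emb_a - emb_b), emb_a * emb_b], axis=1)
        hidden = ag.elu(feats @ P["head_w1"] + P["head_b1"])
        return hidden @ P["head_w2"] + P["head_b2"]

    def _forward_pair(self, graph_a: ResidueGraph, graph_b: ResidueGraph,
                      x_a: Tensor | None = None, x_b: Tensor | None = None):
        """Logit of one pair; returns (logit, x_a, x_b) leaf tensors."""
        dtype = np.dtype(self.config.dtype)
        batch_a = GraphBatch([graph_a], dtype=dtype)
        batch_b = GraphBatch([graph_b], dtype=dtype)
        if x_a is None:
            x_a = Tensor(batch_a.x)
        if x_b is None:
            x_b = Tensor(batch_b.x)
        emb_a, _ = self._encode_batch(batch_a, x=x_a)
        emb_b, _ = self._encode_batch(batch_b, x=x_b)
        return self._pair_logits(emb_a, emb_b), x_a, x_b

    # -- public API -----------------------------------------------------------
    def encode_protein(self, graph: ResidueGraph):
        """Graph embedding and final node states (evaluation mode)."""
        batch = GraphBatch([graph], dtype=np.dtype(self.config.dtype))
        emb, nodes = self._encode_batch(batch)
        return emb.data[0], nodes.data

    def predict_pair(self, graph_a: ResidueGraph, graph_b: ResidueGraph) -> float:
        """Interaction probability in (0, 1), evaluation mode."""
        logit, _, _ = self._forward_pair(graph_a, graph_b)
        return float(1.0 / (1.0 + np.exp(-logit.data[0, 0])))

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: parameters + config + table hash."""
        meta = json.dumps({
            "config": asdict(self.config),
            "property_table_hash": self.property_table_hash,
        })
        np.savez(path, __meta__=np.array(meta),
                 **{k: t.data for k, t in self.params.items()})

    @classmethod
    def load(cls, path) -> "InteractionModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: Tensor(z[k].copy(), requires_grad=True)
                      for k in z.files if k != "__meta__"}
        return cls(EncoderConfig(**meta["config"]), params=params,
                   property_table_hash=meta["property_table_hash"])


# -- module-level operation wrappers ------------------------------------------

def init_model(config: EncoderConfig = EncoderConfig(),
               property_table_hash: str = "") -> InteractionModel:
    """Deterministically initialized model (same seed -> same parameters)."""
    return InteractionModel(config, property_table_hash=property_table_hash)


def encode_protein(model: InteractionModel, graph: ResidueGraph):
    return model.encode_protein(graph)


def predict_pair(model: InteractionModel, graph_a: ResidueGraph,
                 graph_b: ResidueGraph) -> float:
    return model.predict_pair(graph_a, graph_b)
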