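"""Gradient-saliency interpretation of a predicted interaction.

For a scored pair, the gradient of the interaction probability with respect
to every input node feature of both proteins is computed by automatic
differentiation; a residue's saliency score is the Euclidean norm of its
5-dim gradient vector. Residues whose score stands far above the protein's
own score distribution (default: more than two standard deviations above the
mean, capped at the top ten) are reported as interaction "hotspots" —
candidate interface residues worth probing by mutagenesis.

The gradient target defaults to the probability itself; a logit-gradient
option avoids vanishing gradients when the sigmoid saturates (the residue
ranking is unchanged because the sigmoid derivative scales all feature
gradients of the pair uniformly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .graphs import ResidueGraph
from .model import InteractionModel


@dataclass
class SaliencyMap:
    """Per-residue non-negative saliency scores for one protein."""

    protein_id: str
    residue_labels: list[str]
    scores: np.ndarray  # (n,) >= 0

    def to_text(self) -> str:
        lines = ["residue\tscore"]
        for lab, s in zip(self.residue_labels, self.scores):
            lines.append(f"{lab}\t{float(s)!r}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class HotspotRule:
    """Selection rule: score strictly above mean + n_sd * sd, top ``cap``."""

    n_sd: float = 2.0
    cap: int = 10


def saliency_map(model: InteractionModel, graph_a: ResidueGraph,
                 graph_b: ResidueGraph, target: str = "probability",
                 aggregate: str = "l2"):
    """Saliency maps for both proteins of a pair (evaluation mode).

    ``target`` is "probability" (the model output, as released) or "logit";
    ``aggregate`` collapses each residue's 5 feature gradients by "l2" norm
    or "abs_sum".
    """
    if target not in ("probability", "logit"):
        raise ValueError(f"unknown saliency target {target!r}")
    if aggregate not in ("l2", "abs_sum"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    dtype = np.dtype(model.config.dtype)
    x_a = ag.Tensor(np.asarray(graph_a.node_features, dtype=dtype),
                    requires_grad=True)
    x_b = ag.Tensor(np.asarray(graph_b.node_features, dtype=dtype),
                    requires_grad=True)
    logit, _, _ = model._forward_pair(graph_a, graph_b, x_a=x_a, x_b=x_b)
    out = ag.sigmoid(logit) if target == "probability" else logit
    out.backward()
    maps = []
    for graph, x in ((graph_a, x_a), (graph_b, x_b)):
        grad = x.grad if x.grad is not None else np.zeros(x.shape)
        if aggregate == "l2":
            scores = np.sqrt((grad * grad).sum(axis=1))
        else:
            scores = np.abs(grad).sum(axis=1)
        maps.append(SaliencyMap(graph.protein_id, list(graph.residue_labels),
                                scores))
    return maps[0], maps[1]


def finite_difference_check(model: InteractionModel, graph_a: ResidueGraph,
                            graph_b: ResidueGraph, n_positions: int = 20,
                            step: float = 1e-4, seed: int = 0,
                            target: str = "probability") -> float:
    """Max relative error between analytic and central-difference gradients.

    Samples random (residue, feature) positions of protein A. Central
    differences are only valid where the model is smooth on the whole
    ``+-step`` interval, so positions whose perturbation flips the sign of
    any LeakyReLU pre-activation (a kink crossing, where the two-sided
    difference quotient does not estimate either one-sided derivative) are
    detected and resampled.
    """
    # full (n, 5) analytic gradient, not the per-residue norm
    dtype = np.dtype(model.config.dtype)
    x_a = ag.Tensor(np.asarray(graph_a.node_features, dtype=dtype),
                    requires_grad=True)
    logit, _, _ = model._forward_pair(graph_a, graph_b, x_a=x_a)
    out = ag.sigmoid(logit) if target == "probability" else logit
    out.backward()
    analytic = x_a.grad

    base = np.asarray(graph_a.node_features, dtype=float)

    def output_and_signs(x):
        g_mod = ResidueGraph(graph_a.protein_id, x, graph_a.coords,
                             graph_a.edges, graph_a.distances,
                             graph_a.residue_labels, graph_a.cutoff)
        ag.KINK_TRACE = []
        try:
            logit, _, _ = model._forward_pair(g_mod, graph_b)
            signs = ag.KINK_TRACE
        finally:
            ag.KINK_TRACE = None
        val = logit.data[0, 0]
        if target == "probability":
            val = 1.0 / (1.0 + np.exp(-val))
        return val, signs

    rng = np.random.default_rng(seed)
    max_rel, accepted, attempts = 0.0, 0, 0
    while accepted < n_positions and attempts < 20 * n_positions:
        attempts += 1
        i = int(rng.integers(base.shape[0]))
        j = int(rng.integers(base.shape[1]))
        xp, xm = base.copy(), base.copy()
        xp[i, j] += step
        xm[i, j] -= step
        fp, signs_p = output_and_signs(xp)
        fm, signs_m = output_and_signs(xm)
        if any(not np.array_equal(a, b) for a, b in zip(signs_p, signs_m)):
            continue  # kink inside the interval: difference quotient invalid
        fd = (fp - fm) / (2 * step)
        denom = max(abs(fd), abs(analytic[i, j]), 1e-12)
        max_rel = max(max_rel, abs(fd - analytic[i, j]) / denom)
        accepted += 1
    return max_rel


def hotspots(smap: SaliencyMap, rule: HotspotRule = HotspotRule()) -> list[str]:
    """Ordered hotspot residue tokens (descending score).

    Residues qualify when their score is strictly greater than
    mean + n_sd * sd of this protein's scores; with a flat score profile
    nothing qualifies. At most ``rule.cap`` residues are returned.
    """
    scores = np.asarray(smap.scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty saliency map")
    threshold = scores.mean() + rule.n_sd * scores.std()
    idx = np.nonzero(scores > threshold)[0]
    # descending score, residue order breaking exact ties deterministically
    idx = idx[np.lexsort((idx, -scores[idx]))][: rule.cap]
    return [smap.residue_labels[i] for i in idx]
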