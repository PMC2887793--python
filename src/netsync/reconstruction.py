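"""Reconstruction of physical connectivity from a weighted network of
synchronization.

Pairs whose (averaged) coherence weight exceeds a threshold are predicted
to be physical links. The threshold can be read off the weight distribution
of all node pairs: just below the onset of global synchronization the
distribution is bimodal — a low mode of disconnected pairs and a high mode
of physically connected pairs — and the antimode between them separates the
classes. Reconstruction quality over the whole threshold sweep is scored by
the ROC curve and its AUC (the probability that a random physical pair
outweighs a random non-physical pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import gaussian_kde
from sklearn import metrics as _skm

from .coherence import CoherenceMatrix
from .networks import adjacency_csr

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "ThresholdEstimate",
    "classify_links",
    "roc_curve",
    "auc",
    "top_l_roc",
    "bimodal_threshold",
    "reconstruct",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Link-prediction confusion counts over all n(n-1)/2 node pairs."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def fpr(self) -> float:
        return self.FP / (self.TN + self.FP)

    @property
    def tpr(self) -> float:
        return self.TP / (self.TP + self.FN)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep of (FPR, TPR); thresholds descend along the curve."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class ThresholdEstimate:
    """Antimode of the all-pairs weight distribution, if bimodal.

    ``separation_quality`` is 1 minus the ratio of the density at the
    antimode to the lower of the two mode peaks (0 when unimodal — then
    ``threshold`` falls back to the median weight).
    """

    threshold: float
    mode_lo: float
    mode_hi: float
    separation_quality: float
    bimodal: bool


def _pair_labels(wns: CoherenceMatrix, truth: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    if truth.number_of_nodes() != wns.n_nodes:
        raise ValueError("WNS/truth size mismatch")
    a = adjacency_csr(truth).toarray().astype(bool)
    iu = np.triu_indices(wns.n_nodes, k=1)
    return wns.weights[iu], a[iu]


def classify_links(
    wns: CoherenceMatrix, threshold: float, truth: nx.Graph
) -> ConfusionCounts:
    """Predict pairs with weight strictly above ``threshold`` as physical
    links and count the confusion table against the substrate."""
    w, y = _pair_labels(wns, truth)
    pred = w > threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & y)),
        FP=int(np.sum(pred & ~y)),
        TN=int(np.sum(~pred & ~y)),
        FN=int(np.sum(~pred & y)),
    )


def roc_curve(wns: CoherenceMatrix, truth: nx.Graph) -> ROCCurve:
    """Full ROC sweep over every distinct weight (ties form a single step)."""
    w, y = _pair_labels(wns, truth)
    if y.all() or not y.any():
        raise ValueError("truth must contain both physical and non-physical pairs")
    fpr, tpr, thr = _skm.roc_curve(y, w, drop_intermediate=False)
    return ROCCurve(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr))
    )


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under an ROC curve."""
    return float(_skm.auc(roc.fpr, roc.tpr))


def top_l_roc(wns: CoherenceMatrix, truth: nx.Graph, L: int) -> ROCCurve:
    """ROC restricted to the thresholds that admit at most the L heaviest
    links; a pointwise prefix of the full curve."""
    w, y = _pair_labels(wns, truth)
    if not 1 <= L <= w.shape[0]:
        raise ValueError("L must be between 1 and n(n-1)/2")
    fpr, tpr, thr = _skm.roc_curve(y, w, drop_intermediate=False)
    n_pos = int(y.sum())
    n_neg = y.shape[0] - n_pos
    n_pred = tpr * n_pos + fpr * n_neg  # predicted positives at each cut
    keep = n_pred <= L + 1e-9
    fpr_k, tpr_k, thr_k = fpr[keep], tpr[keep], thr[keep]
    area = float(np.trapezoid(tpr_k, fpr_k)) if fpr_k.size > 1 else 0.0
    return ROCCurve(thresholds=thr_k, fpr=fpr_k, tpr=tpr_k, auc=area)


def bimodal_threshold(
    wns: CoherenceMatrix, grid_size: int = 512, bw_method: str | float = "scott"
) -> ThresholdEstimate:
    """Antimode of the kernel-smoothed all-pairs weight distribution.

    A Gaussian KDE (Scott bandwidth by default) is evaluated on a uniform
    grid over the weight range; if it has two or more local maxima, the
    threshold is the density minimum between the two largest modes.
    Otherwise the result is flagged unimodal and the median weight is
    returned with zero separation quality.
    """
    w = wns.offdiag()
    if np.unique(w).size < 2:
        raise ValueError("need at least two distinct weights")
    kde = gaussian_kde(w, bw_method=bw_method)
    lo, hi = float(w.min()), float(w.max())
    pad = 0.05 * (hi - lo)
    x = np.linspace(lo - pad, hi + pad, grid_size)
    d = kde(x)
    interior = np.flatnonzero(
        (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:])
    ) + 1
    if interior.size >= 2:
        top2 = interior[np.argsort(d[interior])[-2:]]
        a, b = int(top2.min()), int(top2.max())
        between = np.argmin(d[a : b + 1]) + a
        quality = 1.0 - d[between] / min(d[a], d[b])
        return ThresholdEstimate(
            threshold=float(x[between]),
            mode_lo=float(x[a]),
            mode_hi=float(x[b]),
            separation_quality=float(quality),
            bimodal=True,
        )
    peak = float(x[np.argmax(d)])
    return ThresholdEstimate(
        threshold=float(np.median(w)),
        mode_lo=peak,
        mode_hi=peak,
        separation_quality=0.0,
        bimodal=False,
    )


def reconstruct(wns: CoherenceMatrix, threshold: float) -> nx.Graph:
    """Inferred physical network: all pairs with weight strictly above the
    threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    n = wns.n_nodes
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    sel = wns.weights[iu, ju] > threshold
    g.add_edges_from(zip(iu[sel].tolist(), ju[sel].tolist()))
    return g
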