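"""Node- and pair-level dynamics metrics on community label sequences.

All metrics operate on an N x L matrix of positive integer community labels
(node i at layer t).  Three quantities are computed:

* flexibility — per node, the fraction of layer boundaries at which the
  node changes community: xi_i = g_i / (L - 1).
* allegiance — per pair, the fraction of layers at which the two nodes
  share a community.
* intermittence — per pair, the fraction of layer boundaries at which the
  pair's shared-community indicator flips (together <-> apart).  Two pairs
  can have equal allegiance yet very different intermittence: many short
  co-affiliation bursts score higher than a few long blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NodeFlexibility",
    "PairMetricMatrix",
    "flexibility",
    "allegiance",
    "intermittence",
    "ensemble_mean",
    "threshold_by_allegiance",
]


@dataclass(frozen=True)
class NodeFlexibility:
    xi: np.ndarray       # (N,) in [0, 1]
    g: np.ndarray        # (N,) integer switch counts
    n_layers: int


@dataclass(frozen=True)
class PairMetricMatrix:
    kind: str            # "allegiance" | "intermittence"
    values: np.ndarray   # (N, N) symmetric, in [0, 1]


def _as_labels(seq, min_layers: int = 1) -> np.ndarray:
    """Accept a CommunitySequence-like object or a bare N x L integer array."""
    labels = np.asarray(getattr(seq, "labels", seq))
    if labels.ndim != 2:
        raise ValueError("labels must be an N x L matrix")
    if not np.issubdtype(labels.dtype, np.integer):
        as_int = labels.astype(int)
        if not np.array_equal(as_int, labels):
            raise ValueError("labels must be integers")
        labels = as_int
    if labels.min() < 1:
        raise ValueError("community labels must be positive integers")
    if labels.shape[1] < min_layers:
        raise ValueError(f"need at least L={min_layers} layers, got {labels.shape[1]}")
    return labels


def flexibility(seq) -> NodeFlexibility:
    """xi_i = g_i / (L - 1), with g_i the node's community-switch count."""
    labels = _as_labels(seq, min_layers=2)
    g = (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
    L = labels.shape[1]
    return NodeFlexibility(xi=g / (L - 1), g=g, n_layers=L)


def _together(labels: np.ndarray) -> np.ndarray:
    """(L, N, N) boolean: pair shares a community at each layer."""
    return labels.T[:, :, None] == labels.T[:, None, :]


def allegiance(seq) -> PairMetricMatrix:
    """Fraction of layers at which each pair shares a community (diagonal 1)."""
    labels = _as_labels(seq, min_layers=1)
    values = _together(labels).mean(axis=0)
    return PairMetricMatrix("allegiance", values)


def intermittence(seq) -> PairMetricMatrix:
    """Fraction of layer boundaries at which each pair's co-membership flips."""
    labels = _as_labels(seq, min_layers=2)
    delta = _together(labels)
    flips = (delta[1:] != delta[:-1]).sum(axis=0)
    values = flips / (labels.shape[1] - 1)
    np.fill_diagonal(values, 0.0)
    return PairMetricMatrix("intermittence", values)


def ensemble_mean(members: Sequence | Iterable):
    """Element-wise mean of a detection-ensemble's metric values.

    Accepts a sequence of :class:`NodeFlexibility`, :class:`PairMetricMatrix`
    or bare arrays (all of identical shape/kind) and returns the same type.
    """
    members = list(members)
    if not members:
        raise ValueError("ensemble is empty")
    first = members[0]
    if isinstance(first, NodeFlexibility):
        if any(m.n_layers != first.n_layers or m.xi.shape != first.xi.shape
               for m in members):
            raise ValueError("ensemble members have mismatched shapes")
        xi = np.mean([m.xi for m in members], axis=0)
        g = np.mean([m.g for m in members], axis=0)
        return NodeFlexibility(xi=xi, g=g, n_layers=first.n_layers)
    if isinstance(first, PairMetricMatrix):
        if any(m.kind != first.kind or m.values.shape != first.values.shape
               for m in members):
            raise ValueError("ensemble members have mismatched kind/shape")
        return PairMetricMatrix(first.kind,
                                np.mean([m.values for m in members], axis=0))
    arrs = [np.asarray(m) for m in members]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("ensemble members have mismatched shapes")
    return np.mean(arrs, axis=0)


def threshold_by_allegiance(
    allegiance_matrix: PairMetricMatrix | np.ndarray,
    intermittence_matrix: PairMetricMatrix | np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Upper-triangle intermittence values of pairs with allegiance > threshold.

    The inequality is strict, so threshold=1 always yields an empty set.
    """
    a = np.asarray(getattr(allegiance_matrix, "values", allegiance_matrix))
    x = np.asarray(getattr(intermittence_matrix, "values", intermittence_matrix))
    if a.shape != x.shape:
        raise ValueError("allegiance and intermittence matrices differ in shape")
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    iu = np.triu_indices(a.shape[0], k=1)
    keep = a[iu] > threshold
    return x[iu][keep]
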