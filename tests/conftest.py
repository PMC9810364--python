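"""Shared oracles and fixtures.

The brute-force implementations here are deliberately independent of the
package: plain Python loops over layers and pairs, used as the ground-truth
side of oracle-equivalence tests.
"""

import numpy as np
import pytest


def bf_flexibility(labels):
    """Per-node switch fraction by explicit enumeration."""
    labels = np.asarray(labels)
    n, L = labels.shape
    xi = np.zeros(n)
    for i in range(n):
        g = 0
        for t in range(L - 1):
            if labels[i, t] != labels[i, t + 1]:
                g += 1
        xi[i] = g / (L - 1)
    return xi


def bf_allegiance(labels):
    labels = np.asarray(labels)
    n, L = labels.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            out[j, k] = sum(labels[j, t] == labels[k, t] for t in range(L)) / L
    return out


def bf_intermittence(labels):
    labels = np.asarray(labels)
    n, L = labels.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            delta = [int(labels[j, t] == labels[k, t]) for t in range(L)]
            flips = sum(
                delta[t] * (1 - delta[t + 1]) + delta[t + 1] * (1 - delta[t])
                for t in range(L - 1)
            )
            out[j, k] = flips / (L - 1)
    return out


def set_partitions(n):
    """All partitions of range(n) as restricted-growth label lists."""
    def rec(i, labels, mx):
        if i == n:
            yield tuple(labels)
            return
        for c in range(mx + 1):
            labels[i] = c
            yield from rec(i + 1, labels, max(mx, c + 1))

    yield from rec(0, [0] * n, 0)


def random_label_matrix(rng, n_max=8, l_max=12, k_max=4):
    n = int(rng.integers(2, n_max + 1))
    L = int(rng.integers(2, l_max + 1))
    k = int(rng.integers(1, k_max + 1))
    return rng.integers(1, k + 1, size=(n, L))


def random_symmetric_stack(rng, n, L):
    stack = rng.random((L, n, n))
    stack = (stack + stack.transpose(0, 2, 1)) / 2
    for l in range(L):
        np.fill_diagonal(stack[l], 0)
    return stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
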