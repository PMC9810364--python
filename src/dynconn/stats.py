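"""Bootstrap group comparisons.

Three comparison routines mirror the three analysis figures:

* per-sensor flexibility differences between the change (C) and no-change
  (NC) groups, resampled at the subject level;
* allegiance-thresholded intermittence difference curves, resampled at the
  node-pair level within group;
* temporal-CoV comparisons across groups and interaction contexts, using
  fixed-size replicas resampled at the subject level.

All p-values are two-sided (doubled tail mass of the bootstrap difference
distribution at zero), floored at 1/n so they are never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapResult",
    "ThresholdCurve",
    "bootstrap_mean",
    "bootstrap_group_difference",
    "flexibility_comparison",
    "intermittence_curve",
    "cov_comparison",
    "benjamini_hochberg",
]


@dataclass
class BootstrapResult:
    replicates: np.ndarray
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_replicates: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ThresholdCurve:
    thresholds: np.ndarray
    difference: np.ndarray          # mean NC - C per threshold (NaN if undefined)
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    defined: np.ndarray             # bool: >= min_pairs in both groups
    significant: np.ndarray         # bool: p < 0.05 (and defined)
    significant_fraction: float     # % of defined cells that are significant


def _two_sided_p(replicates: np.ndarray, n: int) -> float:
    frac_le = np.mean(replicates <= 0)
    frac_ge = np.mean(replicates >= 0)
    return float(min(max(2 * min(frac_le, frac_ge), 1.0 / n), 1.0))


def _percentile_ci(replicates: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(replicates, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_mean(values, n: int = 10_000, seed: int = 0) -> BootstrapResult:
    """Bootstrap distribution of the sample mean with a 95% percentile CI."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n, values.size))
    replicates = values[idx].mean(axis=1)
    lo, hi = _percentile_ci(replicates)
    return BootstrapResult(
        replicates=replicates,
        estimate=float(values.mean()),
        ci_low=lo,
        ci_high=hi,
        p_value=_two_sided_p(replicates, n),
        n_replicates=n,
        seed=seed,
    )


def bootstrap_group_difference(group_a, group_b, n: int = 10_000,
                               seed: int = 0) -> BootstrapResult:
    """Bootstrap of mean(A*) - mean(B*); two-sided p from the tail at 0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    rep_a = a[rng.integers(0, a.size, size=(n, a.size))].mean(axis=1)
    rep_b = b[rng.integers(0, b.size, size=(n, b.size))].mean(axis=1)
    replicates = rep_a - rep_b
    lo, hi = _percentile_ci(replicates)
    return BootstrapResult(
        replicates=replicates,
        estimate=float(a.mean() - b.mean()),
        ci_low=lo,
        ci_high=hi,
        p_value=_two_sided_p(replicates, n),
        n_replicates=n,
        seed=seed,
    )


def flexibility_comparison(
    flex_nc: np.ndarray,
    flex_c: np.ndarray,
    sensor_labels=None,
    n: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sensor bootstrap of the NC - C mean flexibility difference.

    ``flex_nc`` / ``flex_c`` are subjects x sensors arrays (NaN marks a
    missing subject/sensor cell).  Subjects are the unit of resampling and
    draws are shared across sensors.  Positive differences mean higher
    flexibility for the no-change group.  Sensors with an empty group are
    skipped with a warning.
    """
    fnc = np.atleast_2d(np.asarray(flex_nc, dtype=float))
    fc = np.atleast_2d(np.asarray(flex_c, dtype=float))
    if fnc.shape[1] != fc.shape[1]:
        raise ValueError("groups disagree on the number of sensors")
    n_sensors = fnc.shape[1]
    if sensor_labels is None:
        sensor_labels = [f"ch{i}" for i in range(n_sensors)]
    rng = np.random.default_rng(seed)
    idx_nc = rng.integers(0, fnc.shape[0], size=(n, fnc.shape[0]))
    idx_c = rng.integers(0, fc.shape[0], size=(n, fc.shape[0]))
    rows = []
    with warnings.catch_warnings():
        # all-NaN sensor columns are detected and skipped below
        warnings.simplefilter("ignore", RuntimeWarning)
        rep_nc_all = np.nanmean(fnc[idx_nc], axis=1)  # (n, n_sensors)
        rep_c_all = np.nanmean(fc[idx_c], axis=1)
    for s in range(n_sensors):
        col_nc = fnc[:, s]
        col_c = fc[:, s]
        if np.all(np.isnan(col_nc)) or np.all(np.isnan(col_c)):
            warnings.warn(f"sensor {sensor_labels[s]!r}: a group is missing; skipped",
                          stacklevel=2)
            continue
        replicates = rep_nc_all[:, s] - rep_c_all[:, s]
        lo, hi = _percentile_ci(replicates)
        p = _two_sided_p(replicates, n)
        rows.append({
            "sensor": sensor_labels[s],
            "difference": float(np.nanmean(col_nc) - np.nanmean(col_c)),
            "ci_low": lo,
            "ci_high": hi,
            "p_value": p,
            "significant": p < 0.05,
        })
    return pd.DataFrame(rows)


def intermittence_curve(
    allegiance_nc, intermittence_nc,
    allegiance_c, intermittence_c,
    thresholds=None,
    n: int = 10_000,
    seed: int = 0,
    min_pairs: int = 10,
) -> ThresholdCurve:
    """NC - C intermittence difference restricted to pairs with allegiance
    above each threshold (strict inequality), bootstrapped per threshold.

    Inputs are flat arrays of pooled pair values per group.  Cells with fewer
    than ``min_pairs`` pairs in either group are undefined and excluded from
    the significant-fraction denominator.
    """
    a_nc = np.asarray(allegiance_nc, float).ravel()
    x_nc = np.asarray(intermittence_nc, float).ravel()
    a_c = np.asarray(allegiance_c, float).ravel()
    x_c = np.asarray(intermittence_c, float).ravel()
    if a_nc.shape != x_nc.shape or a_c.shape != x_c.shape:
        raise ValueError("allegiance/intermittence arrays must align per group")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.01), 10)
    thresholds = np.asarray(thresholds, float)
    nt = thresholds.size
    diff = np.full(nt, np.nan)
    lo = np.full(nt, np.nan)
    hi = np.full(nt, np.nan)
    pvals = np.full(nt, np.nan)
    defined = np.zeros(nt, dtype=bool)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(nt)
    for i, thr in enumerate(thresholds):
        sel_nc = x_nc[a_nc > thr]
        sel_c = x_c[a_c > thr]
        if sel_nc.size < min_pairs or sel_c.size < min_pairs:
            continue
        res = bootstrap_group_difference(sel_nc, sel_c, n=n, seed=int(cell_seeds[i]))
        defined[i] = True
        diff[i] = res.estimate
        lo[i], hi[i] = res.ci_low, res.ci_high
        pvals[i] = res.p_value
    significant = defined & (pvals < 0.05)
    frac = 100.0 * significant.sum() / defined.sum() if defined.any() else float("nan")
    return ThresholdCurve(
        thresholds=thresholds,
        difference=diff,
        ci_low=lo,
        ci_high=hi,
        p_values=pvals,
        defined=defined,
        significant=significant,
        significant_fraction=float(frac),
    )


def _stars(p: float) -> str:
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cov_comparison(
    cells: dict[tuple[str, str], np.ndarray],
    n_replicas: int = 1000,
    replica_size: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Replica-based bootstrap of session-mean CoV across group x context cells.

    ``cells`` maps (group, context) -> per-subject session CoV values, e.g.
    ("C", "social_media").  Each replica is the mean of ``replica_size``
    subjects drawn with replacement (so replicas are defined even when the
    cell is smaller than the replica).  Comparisons: within each context
    (NC vs C) and within each group (context A vs context B).  Stars flag
    p < 0.05 (*) and p < 0.005 (**).
    """
    for key, vals in cells.items():
        if np.asarray(vals).size < 2:
            raise ValueError(f"cell {key} needs at least 2 subjects")
    groups = sorted({g for g, _ in cells})
    contexts = sorted({c for _, c in cells})
    rng = np.random.default_rng(seed)
    replica_means = {}
    for key in sorted(cells):
        vals = np.asarray(cells[key], dtype=float)
        idx = rng.integers(0, vals.size, size=(n_replicas, replica_size))
        replica_means[key] = vals[idx].mean(axis=1)
    rows = []

    def _compare(key_a, key_b, kind):
        reps = replica_means[key_a] - replica_means[key_b]
        p = _two_sided_p(reps, n_replicas)
        lo, hi = _percentile_ci(reps)
        rows.append({
            "comparison": kind,
            "a": "/".join(key_a),
            "b": "/".join(key_b),
            "difference": float(np.mean(cells[key_a]) - np.mean(cells[key_b])),
            "ci_low": lo,
            "ci_high": hi,
            "p_value": p,
            "stars": _stars(p),
        })

    for ctx in contexts:
        present = [g for g in groups if (g, ctx) in cells]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                _compare((present[i], ctx), (present[j], ctx), "group_within_context")
    for g in groups:
        present = [c for c in contexts if (g, c) in cells]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                _compare((g, present[i]), (g, present[j]), "context_within_group")
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask (optional; comparisons are uncorrected by
    default, matching the reported analyses)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = ranked <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask
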