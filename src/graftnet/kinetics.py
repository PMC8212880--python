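"""Kinetic coabundance clustering of time-course proteome profiles.

Diseased (vein graft, VG) and control (inferior vena cava, IVC) profiles are
pooled into a single clustering step: replicates are averaged per timepoint,
each profile is converted to fractional abundances (values sum to 1), and the
pooled profiles are fitted with a finite mixture of diagonal-covariance
Gaussians by expectation-maximization (best of several k-means++ seeded
restarts).  Clusters are then labelled early / late / flat by the position of
the centroid peak, and condition-specific protein sets are extracted: per
phase, the proteins whose kept-condition profile sits in a cluster of that
phase (flat clusters are omitted entirely, control profiles contribute
nothing).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import ParameterError
from .io import AbundanceTable

_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class ClusterModel:
    """Fitted mixture model over fractional kinetic profiles.

    ``assignments`` has one row per profile with columns ``protein_id``,
    ``condition``, ``cluster`` (0-based).  ``phases`` maps each cluster to
    ``early`` / ``late`` / ``flat`` once :func:`classify_phase` has run.
    """

    n_clusters: int
    timepoints: tuple
    centroids: np.ndarray  # (K, T)
    variances: np.ndarray  # (K, T)
    weights: np.ndarray  # (K,)
    assignments: pd.DataFrame
    log_likelihood: float
    loglik_path: tuple
    converged: bool
    reseeded: bool
    phases: tuple | None = None


def fractional_normalize(values) -> np.ndarray | None:
    """Divide a non-negative T-vector by its sum; all-zero profiles are excluded."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ParameterError("profile must be a 1-D vector with T >= 2")
    if np.isnan(v).any() or (v < 0).any():
        raise ParameterError("profile values must be non-negative and observed")
    total = v.sum()
    if total == 0:
        warnings.warn("all-zero profile excluded from fractional normalization")
        return None
    return v / total


def profiles_from_table(table: AbundanceTable, conditions=None, timepoint_order=None):
    """Replicate-average a kinetic abundance table into fractional profiles.

    Returns ``(profiles, timepoints)`` where ``profiles`` is a DataFrame with
    columns ``protein_id``, ``condition`` and one fractional column per
    timepoint, sorted by (protein_id, condition).  Profiles with a missing
    timepoint average or an all-zero trajectory are excluded with a warning.
    """
    ann = table.annotations
    if conditions is None:
        conditions = list(dict.fromkeys(ann["condition"]))
    if timepoint_order is None:
        timepoint_order = list(dict.fromkeys(ann["timepoint"]))
    rows = []
    n_excluded = 0
    for cond in conditions:
        mats = []
        for tp in timepoint_order:
            cols = table.samples_where(condition=cond, timepoint=tp)
            if not cols:
                raise ParameterError(f"no samples for condition {cond!r} timepoint {tp!r}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mats.append(np.nanmean(table.data[cols].to_numpy(), axis=1))
        M = np.column_stack(mats)  # proteins x T
        sums = M.sum(axis=1)
        bad = np.isnan(M).any(axis=1) | (sums == 0)
        n_excluded += int(bad.sum())
        M = M[~bad] / sums[~bad][:, None]
        for pid, frac in zip(np.asarray(table.proteins)[~bad], M):
            rows.append((pid, cond, *frac))
    if n_excluded:
        warnings.warn(f"{n_excluded} profiles excluded (missing timepoint or all-zero)")
    profiles = pd.DataFrame(rows, columns=["protein_id", "condition", *timepoint_order])
    return (
        profiles.sort_values(["protein_id", "condition"], kind="mergesort").reset_index(drop=True),
        list(timepoint_order),
    )


# -- EM mixture ---------------------------------------------------------------


def _log_gauss(X, means, var):
    # (n, K) log density under diagonal Gaussians
    diff = X[:, None, :] - means[None, :, :]
    return -0.5 * (np.log(2 * np.pi * var)[None] + diff**2 / var[None]).sum(axis=2)


class _EMResult(NamedTuple):
    means: np.ndarray
    var: np.ndarray
    weights: np.ndarray
    loglik: float
    path: tuple
    converged: bool
    reseeded: bool


def _em_once(X, K, init_state, max_iter, tol):
    n, T = X.shape
    means, _ = kmeans_plusplus(X, n_clusters=K, random_state=init_state)
    base_var = max(float(X.var(axis=0).mean()), 1e-4)
    var = np.full((K, T), base_var)
    weights = np.full(K, 1.0 / K)
    prev = -np.inf
    path = []
    converged = False
    reseeded = False
    for _ in range(max_iter):
        logp = _log_gauss(X, means, var) + np.log(weights)[None]
        row_ll = logsumexp(logp, axis=1)
        ll = float(row_ll.sum())
        resp = np.exp(logp - row_ll[:, None])
        nk = resp.sum(axis=0)
        empty = nk < 1e-10
        if empty.any():
            # re-seed empty components from the worst-fit profile
            reseeded = True
            worst = int(np.argmin(row_ll))
            for k in np.flatnonzero(empty):
                means[k] = X[worst]
                var[k] = base_var
            weights = np.full(K, 1.0 / K)
            prev = -np.inf
            continue
        path.append(ll)
        if prev > -np.inf:
            if ll < prev - 1e-6 * max(1.0, abs(prev)):  # EM guarantee; numerical slack
                raise AssertionError("log-likelihood decreased during EM")
            if abs(ll - prev) <= tol * max(1.0, abs(ll)):
                converged = True
                break
        prev = ll
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        var = (resp.T @ X**2) / nk[:, None] - means**2
        var = np.maximum(var, _VAR_FLOOR)
    return _EMResult(means, var, weights, path[-1] if path else -np.inf, tuple(path), converged, reseeded)


def fit_kinetic_clusters(
    profiles: pd.DataFrame,
    K: int,
    seed: int = 0,
    restarts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> ClusterModel:
    """Fit K diagonal-Gaussian mixture components to pooled fractional profiles.

    ``profiles`` is the output of :func:`profiles_from_table`.  The best of
    ``restarts`` k-means++ seeded EM runs (by final log-likelihood) is kept;
    hard assignments are maximum-responsibility.  Non-convergence returns the
    best iterate with a warning.
    """
    if K < 2:
        raise ParameterError("K must be >= 2")
    tp_cols = [c for c in profiles.columns if c not in ("protein_id", "condition")]
    X = profiles[tp_cols].to_numpy(dtype=float)
    if len(X) < K:
        raise ParameterError(f"need at least K={K} profiles, got {len(X)}")
    ss = np.random.SeedSequence(seed)
    states = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(restarts, 1))]
    best = None
    for state in states:
        res = _em_once(X, K, state, max_iter, tol)
        if best is None or res.loglik > best.loglik:
            best = res
    if not best.converged:
        warnings.warn("EM did not converge within max_iter; returning best iterate")
    logp = _log_gauss(X, best.means, best.var) + np.log(best.weights)[None]
    hard = np.argmax(logp, axis=1)
    assignments = profiles[["protein_id", "condition"]].copy()
    assignments["cluster"] = hard
    return ClusterModel(
        n_clusters=K,
        timepoints=tuple(tp_cols),
        centroids=best.means,
        variances=best.var,
        weights=best.weights,
        assignments=assignments,
        log_likelihood=best.loglik,
        loglik_path=best.path,
        converged=best.converged,
        reseeded=best.reseeded,
    )


# -- phase labelling and condition filtering ----------------------------------


def classify_phase(
    model: ClusterModel, early_timepoints, late_timepoints, flat_range: float = 0.10
) -> ClusterModel:
    """Label each cluster early / late / flat from its centroid.

    A cluster is ``flat`` if max(centroid) - min(centroid) < ``flat_range``;
    otherwise ``early`` if the centroid peak falls in ``early_timepoints``,
    else ``late``.  The early and late sets must partition the timepoints.
    """
    early = {str(t) for t in early_timepoints}
    late = {str(t) for t in late_timepoints}
    if not early or not late:
        raise ParameterError("early and late timepoint sets must be non-empty")
    tps = set(map(str, model.timepoints))
    if early & late or early | late != tps:
        raise ParameterError("early and late sets must partition the timepoints")
    early_idx = {i for i, t in enumerate(model.timepoints) if str(t) in early}
    phases = []
    for centroid in model.centroids:
        if centroid.max() - centroid.min() < flat_range:
            phases.append("flat")
        elif int(np.argmax(centroid)) in early_idx:
            phases.append("early")
        else:
            phases.append("late")
    return dataclasses.replace(model, phases=tuple(phases))


def condition_filter(model: ClusterModel, keep_condition: str) -> dict:
    """Per phase, the proteins whose kept-condition profile lies in that phase.

    Control-condition profiles are excluded and flat clusters are omitted
    entirely.  Returns ``{"early": frozenset, "late": frozenset}``.
    """
    if model.phases is None:
        raise ParameterError("phases not assigned; run classify_phase first")
    known = set(model.assignments["condition"].unique())
    if keep_condition not in known:
        raise ParameterError(f"unknown condition {keep_condition!r}; profiles have {sorted(known)}")
    kept = model.assignments[model.assignments["condition"] == keep_condition]
    out = {}
    for phase in ("early", "late"):
        clusters = {k for k, ph in enumerate(model.phases) if ph == phase}
        out[phase] = frozenset(kept.loc[kept["cluster"].isin(clusters), "protein_id"])
    return out


class Concordance(NamedTuple):
    n_shared: int
    n_only_a: int
    n_only_b: int
    jaccard: float


def set_concordance(set_a, set_b) -> Concordance:
    """Exact overlap bookkeeping between two protein sets."""
    a, b = set(set_a), set(set_b)
    inter, union = a & b, a | b
    jaccard = len(inter) / len(union) if union else 1.0
    return Concordance(len(inter), len(a - b), len(b - a), jaccard)
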