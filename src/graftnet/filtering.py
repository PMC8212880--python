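"""Static-proteome stage: normalization, ANOVA/FDR filtering, bipartition.

The workflow mirrors a label-free tissue-layer proteome comparison: per-sample
median normalization of area-under-curve abundances, a one-way fixed-effects
ANOVA per protein on log2 values with Benjamini-Hochberg control of the false
discovery rate, optional two-group Welch t tests, and a Ward bipartition of the
retained proteins into a control-predominant and a lesion-predominant cluster.

All tests run on log2-transformed abundances.  Missing values are excluded
per protein; zero abundances are treated as missing on the log scale (with a
warning) because a label-free zero is indistinguishable from non-detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError
from .io import AbundanceTable


@dataclass(frozen=True)
class PredominanceClusters:
    """Bipartition of filtered proteins: cluster1 control-predominant, cluster2 lesion-predominant."""

    cluster1: frozenset
    cluster2: frozenset


# -- normalization ------------------------------------------------------------


def normalize_median(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample so its median abundance equals the global median of medians.

    The global target is the median of the per-sample medians of non-missing
    values; each sample is multiplied by ``target / sample_median``.  Missing
    values are preserved and within-sample rank order is unchanged.
    """
    medians = table.data.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = sorted(medians.index[medians.isna()])
        raise DataError(f"samples with no observed values: {bad}")
    if (medians <= 0).any():
        raise DataError("per-sample medians must be positive for median scaling")
    target = float(medians.median())
    factors = target / medians
    return table.with_data(table.data * factors)


def log2_matrix(table: AbundanceTable) -> pd.DataFrame:
    """log2 abundances with non-positive values marked missing (warned)."""
    data = table.data
    n_zero = int(((data <= 0) & data.notna()).to_numpy().sum())
    if n_zero:
        warnings.warn(f"{n_zero} non-positive abundances treated as missing on log2 scale")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(data.where(data > 0))


# -- multiple testing ---------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- one-way ANOVA ------------------------------------------------------------


def _oneway_f_masked(X: np.ndarray, masks: list[np.ndarray]):
    """Vectorized one-way fixed-effects ANOVA over the rows of ``X``.

    ``masks`` select the sample columns of each group.  Groups contributing
    fewer than 2 non-missing values to a row are excluded from that row's
    test; rows with fewer than 2 usable groups are marked invalid.
    Returns (F, p, valid, k_groups, group_means).
    """
    n_rows = X.shape[0]
    g = len(masks)
    counts = np.zeros((g, n_rows))
    means = np.full((g, n_rows), np.nan)
    ss_within = np.zeros((g, n_rows))
    for i, mask in enumerate(masks):
        sub = X[:, mask]
        cnt = np.sum(~np.isnan(sub), axis=1)
        counts[i] = cnt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(sub, axis=1)
            ss = np.nansum((sub - mu[:, None]) ** 2, axis=1)
        means[i] = mu
        ss_within[i] = ss
    include = counts >= 2
    k = include.sum(axis=0)
    valid = k >= 2
    cnt_inc = np.where(include, counts, 0.0)
    mean_inc = np.where(include, means, 0.0)
    N = cnt_inc.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        grand = (cnt_inc * mean_inc).sum(axis=0) / N
        ssb = (cnt_inc * (mean_inc - grand) ** 2).sum(axis=0)
        ssw = np.where(include, ss_within, 0.0).sum(axis=0)
        df_b = k - 1.0
        df_w = N - k
        F = (ssb / df_b) / (ssw / df_w)
    p = np.full(n_rows, np.nan)
    ok = valid & np.isfinite(F)
    p[ok] = stats.f.sf(F[ok], df_b[ok], df_w[ok])
    # zero within-group variance with non-zero between: F = inf, p = 0
    inf_f = valid & np.isinf(F)
    p[inf_f] = 0.0
    return F, p, valid, k, means


def oneway_f(*groups):
    """One-way fixed-effects ANOVA on explicit group value vectors.

    Returns ``(F, p)``.  This is the same computation :func:`anova_filter`
    applies per protein (there, on log2 abundances).
    """
    if len(groups) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    width = max(a.size for a in arrays)
    X = np.full((1, len(arrays) * width), np.nan)
    masks = []
    for i, a in enumerate(arrays):
        mask = np.zeros(len(arrays) * width, dtype=bool)
        mask[i * width : i * width + a.size] = True
        X[0, i * width : i * width + a.size] = a
        full = np.zeros(len(arrays) * width, dtype=bool)
        full[i * width : (i + 1) * width] = True
        masks.append(full)
    F, p, valid, _, _ = _oneway_f_masked(X, masks)
    if not valid[0]:
        raise DataError("each of at least 2 groups needs >= 2 values")
    return float(F[0]), float(p[0])


def anova_filter(table: AbundanceTable, group_of=None, fdr: float = 0.05):
    """Per-protein one-way ANOVA across conditions with BH-FDR retention.

    ``group_of`` maps sample id to condition (defaults to the table's
    annotations).  Proteins constant across all samples are dropped before
    testing, proteins without >= 2 groups of >= 2 non-missing values are
    skipped; both emit warnings.  Returns ``(records, retained)`` where
    ``records`` is a DataFrame (protein_id, statistic, p, q, per-condition
    log2 means, retained) and ``retained`` is the set with ``q <= fdr``.
    """
    if not 0 < fdr <= 1:
        raise ParameterError("fdr must be in (0, 1]")
    if group_of is None:
        group_of = table.condition_of()
    ann_order = list(dict.fromkeys(group_of[s] for s in table.samples))
    X = log2_matrix(table).to_numpy()
    proteins = np.asarray(table.proteins)

    constant = np.zeros(len(proteins), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng_span = np.nanmax(X, axis=1) - np.nanmin(X, axis=1)
    constant[np.isnan(rng_span) | (rng_span == 0)] = True
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} proteins constant or unmeasured across samples dropped before testing"
        )

    masks = [
        np.array([group_of[s] == cond for s in table.samples]) for cond in ann_order
    ]
    F, p, valid, _, means = _oneway_f_masked(X, masks)
    testable = valid & ~constant
    skipped = (~valid) & ~constant
    if skipped.any():
        warnings.warn(
            f"{int(skipped.sum())} proteins skipped: fewer than 2 groups with >= 2 values"
        )
    records = pd.DataFrame(
        {
            "protein_id": proteins[testable],
            "statistic": F[testable],
            "p": p[testable],
        }
    )
    records["q"] = bh_adjust(records["p"]) if len(records) else np.array([])
    for i, cond in enumerate(ann_order):
        records[f"mean_{cond}"] = means[i][testable]
    records["retained"] = records["q"] <= fdr
    records = records.sort_values(["p", "protein_id"], kind="mergesort").reset_index(drop=True)
    retained = set(records.loc[records["retained"], "protein_id"])
    return records, retained


# -- two-group tests ----------------------------------------------------------


def welch_t(test_values, control_values):
    """Two-sided Welch t test (test minus control). Returns ``(t, df, p)``."""
    a = np.asarray(test_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DataError("both groups need >= 2 non-missing values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise DataError("zero variance in both groups")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def ttest_two_group(table: AbundanceTable, labels) -> pd.DataFrame:
    """Per-protein two-sided Welch t test on log2 values (test vs control).

    ``labels`` maps sample id to ``"test"`` or ``"control"``.  Proteins with
    fewer than 2 usable values in either group, or zero variance in both, are
    dropped with a warning.
    """
    toks = set(labels.values())
    if not toks <= {"test", "control"}:
        raise ParameterError(f"labels must be 'test'/'control', got {sorted(toks)}")
    t_mask = np.array([labels.get(s) == "test" for s in table.samples])
    c_mask = np.array([labels.get(s) == "control" for s in table.samples])
    if t_mask.sum() < 2 or c_mask.sum() < 2:
        raise ParameterError("need >= 2 samples per group")
    X = log2_matrix(table).to_numpy()
    A, B = X[:, t_mask], X[:, c_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        na = np.sum(~np.isnan(A), axis=1)
        nb = np.sum(~np.isnan(B), axis=1)
        ma, mb = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        va = np.nansum((A - ma[:, None]) ** 2, axis=1) / np.maximum(na - 1, 1)
        vb = np.nansum((B - mb[:, None]) ** 2, axis=1) / np.maximum(nb - 1, 1)
    se2 = va / na + vb / nb
    usable = (na >= 2) & (nb >= 2)
    degenerate = usable & (se2 == 0)
    ok = usable & (se2 > 0)
    if (~usable).any():
        warnings.warn(f"{int((~usable).sum())} proteins dropped: fewer than 2 values in a group")
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} proteins dropped: zero variance in both groups")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / np.maximum(na - 1, 1) + (vb / nb) ** 2 / np.maximum(nb - 1, 1))
    proteins = np.asarray(table.proteins)
    records = pd.DataFrame(
        {
            "protein_id": proteins[ok],
            "statistic": t[ok],
            "p": 2 * stats.t.sf(np.abs(t[ok]), df[ok]),
            "mean_test": ma[ok],
            "mean_control": mb[ok],
        }
    )
    records["q"] = bh_adjust(records["p"]) if len(records) else np.array([])
    return records.sort_values(["p", "protein_id"], kind="mergesort").reset_index(drop=True)


# -- bipartition --------------------------------------------------------------


def bipartition_proteins(
    table: AbundanceTable, retained, control_condition: str = "IVC"
) -> PredominanceClusters:
    """Split retained proteins into control- vs lesion-predominant clusters.

    Rows (log2, z-scored) are cut into 2 clusters by Ward/Euclidean
    agglomerative clustering; ``cluster1`` is the cluster with the higher mean
    z-score over ``control_condition`` samples.
    """
    retained = sorted({str(p).upper() for p in retained})
    unknown = [p for p in retained if p not in set(table.proteins)]
    if unknown:
        raise ParameterError(f"retained proteins absent from table: {unknown[:5]}...")
    if len(retained) < 2:
        raise DataError("need at least 2 retained proteins to bipartition")
    control_cols = np.array(
        [c == control_condition for c in (table.condition_of()[s] for s in table.samples)]
    )
    if not control_cols.any():
        raise ParameterError(f"no samples with condition {control_condition!r}")
    X = log2_matrix(table).loc[retained].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    Z = np.nan_to_num(Z, nan=0.0)
    labels = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(Z)
    mean_control = [Z[labels == k][:, control_cols].mean() for k in (0, 1)]
    first = int(np.argmax(mean_control))
    proteins = np.asarray(retained)
    return PredominanceClusters(
        cluster1=frozenset(proteins[labels == first]),
        cluster2=frozenset(proteins[labels != first]),
    )
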