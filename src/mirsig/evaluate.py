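"""Signature evaluation: clustering, PCA classification, ROC, logistic fits.

These are the descriptive and inferential steps applied after the
signature has been selected: unsupervised hierarchical clustering of the
log-expression matrix, reduction to three principal components with a
leave-one-out nearest-centroid classification rate, per-miRNA ROC
analysis of unstable angina (UA) against non-UA samples, logistic
regression adjusted for cardiovascular risk factors and drug use, and
the two-group comparison tests used for the clinical tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    sample_linkage: np.ndarray
    sample_order: list[str]
    mirna_linkage: np.ndarray
    mirna_order: list[str]


def _pairwise_complete_dist(mat: np.ndarray) -> np.ndarray:
    """Euclidean distances using pairwise-complete coordinates (NaN-aware)."""
    d = nan_euclidean_distances(mat)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValueError("some observation pairs share no defined coordinates")
    return d


def hierarchical_cluster(
    log10_expr: pd.DataFrame, method: str = "average", metric: str = "euclidean"
) -> ClusterResult:
    """Cluster both axes of a (miRNA x sample) log10 expression matrix.

    Distances are Euclidean on pairwise-complete values.  scipy's
    deterministic tie handling (lower cluster index first) fixes the
    dendrogram; an all-constant matrix is rejected ("zero variance").
    """
    if metric != "euclidean":
        raise ValueError("only euclidean distances are supported")
    if log10_expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    vals = log10_expr.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size == 0 or np.allclose(finite, finite.flat[0]):
        raise ValueError("zero variance: all defined values are identical")
    z_samples = hierarchy.linkage(squareform(_pairwise_complete_dist(vals.T), checks=False), method=method)
    z_mirnas = hierarchy.linkage(squareform(_pairwise_complete_dist(vals), checks=False), method=method)
    return ClusterResult(
        sample_linkage=z_samples,
        sample_order=[log10_expr.columns[i] for i in hierarchy.leaves_list(z_samples)],
        mirna_linkage=z_mirnas,
        mirna_order=[log10_expr.index[i] for i in hierarchy.leaves_list(z_mirnas)],
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x k
    variance_explained: np.ndarray
    components: pd.DataFrame  # features x k
    k: int


def pca_reduce(log10_expr: pd.DataFrame, k: int = 3) -> PcaResult:
    """Project samples onto the top-k principal components of log10 expression.

    Missing cells are imputed with the miRNA's cohort mean before
    centering (PCA needs complete data; post-filter matrices have few
    missing wells).  Components are unit-norm with the sign fixed so the
    largest-magnitude loading is positive; scores are column-centered.
    """
    n_samples, n_feat = log10_expr.shape[1], log10_expr.shape[0]
    if k > min(n_samples - 1, n_feat):
        raise ValueError(f"k={k} too large for {n_samples} samples x {n_feat} features")
    filled = log10_expr.apply(lambda row: row.fillna(row.mean()), axis=1)
    if filled.isna().any().any():
        raise ValueError("miRNA with no defined values cannot be mean-imputed")
    x = filled.to_numpy(dtype=float).T  # samples x features
    xc = x - x.mean(axis=0)
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:k].T  # features x k
    # sign convention: largest-|loading| positive per component
    for j in range(k):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] *= -1.0
    scores = xc @ comps
    total_var = (xc**2).sum()
    var_exp = (sv[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(
        scores=pd.DataFrame(scores, index=log10_expr.columns, columns=[f"PC{j+1}" for j in range(k)]),
        variance_explained=var_exp,
        components=pd.DataFrame(comps, index=log10_expr.index, columns=[f"PC{j+1}" for j in range(k)]),
        k=k,
    )


def pca_classify(pca: PcaResult, labels: pd.Series, rule: str = "loo_centroid") -> dict:
    """Score how well component space separates the labeled groups.

    Default rule: leave-one-out nearest group centroid (Euclidean) in
    the k-dimensional score space.  Returns per-group correct counts and
    the overall rate.
    """
    if rule != "loo_centroid":
        raise ValueError(f"unknown classification rule {rule!r}")
    labels = labels.reindex(pca.scores.index)
    if labels.isna().any():
        raise ValueError("every scored sample needs a label")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"leave-one-out needs >=2 samples per group; too small: {small}")
    x = pca.scores.to_numpy()
    groups = list(counts.index)
    correct = {g: 0 for g in groups}
    for i in range(x.shape[0]):
        dists = {}
        for g in groups:
            mask = (labels == g).to_numpy()
            mask[i] = False
            dists[g] = np.linalg.norm(x[i] - x[mask].mean(axis=0))
        pred = min(sorted(dists), key=lambda g: dists[g])
        if pred == labels.iloc[i]:
            correct[pred] += 1
    per_group = {
        g: {"correct": correct[g], "n": int(counts[g]), "rate": correct[g] / int(counts[g])}
        for g in groups
    }
    total = sum(correct.values())
    return {"per_group": per_group, "overall_correct": total, "n": int(len(labels)),
            "overall_rate": total / len(labels)}


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def roc_analysis(values: pd.Series | np.ndarray, case: np.ndarray) -> RocResult:
    """ROC analysis of one marker: AUC, Hanley-McNeil CI, Youden cutoff.

    AUC is the rank-based Mann-Whitney estimate U/(n1*n2) with half
    credit for ties; the p-value tests AUC = 0.5 via the normal
    approximation of U.  The cutoff maximizes Youden's J
    (sensitivity + specificity - 1), calling a sample positive when its
    value is >= the cutoff; ties in J break toward higher specificity.
    """
    v = np.asarray(values, dtype=float)
    case = np.asarray(case, dtype=bool)
    if case.all() or not case.any():
        raise ValueError("both classes must be non-empty")
    ok = ~np.isnan(v)
    v, case = v[ok], case[ok]
    n1, n2 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be non-empty after dropping missing values")

    if np.allclose(v, v[0]):
        logger.warning("constant marker values: AUC degenerates to 0.5")
        return RocResult(0.5, (0.5, 0.5), 1.0, float(v[0]), 1.0, 0.0, degenerate=True)

    ranks = stats.rankdata(v)
    u = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    mw = stats.mannwhitneyu(v[case], v[~case], alternative="two-sided", method="asymptotic")
    # Hanley & McNeil variance of the AUC estimate
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    se = np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)

    best = None  # (J, specificity, cutoff, sens, spec)
    for c in np.unique(v):
        pred = v >= c
        sens = (pred & case).sum() / n1
        spec = (~pred & ~case).sum() / n2
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > (best[0], best[1]):
            best = (j, spec, float(c), sens, spec)
    _, _, cutoff, sens, spec = best
    return RocResult(float(auc), (float(lo), float(hi)), float(mw.pvalue), cutoff,
                     float(sens), float(spec))


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogitResult:
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    coef: float
    converged: bool
    flagged: bool = False  # perfect separation / non-convergence


def logistic_adjusted(
    values: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> LogitResult:
    """Adjusted logistic regression of a binary outcome on one marker.

    Fits outcome ~ marker + covariates by maximum likelihood (Newton
    IRLS, tolerance 1e-8, max 100 iterations) and reports the odds
    ratio per unit of the marker (log10 relative expression: per
    10-fold change) with Wald 95% CI.  Perfect separation or
    non-convergence yields a flagged result with an infinite OR.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    x = pd.DataFrame({"marker": np.asarray(values, dtype=float)}, index=outcome.index)
    if covariates is not None:
        missing = covariates.columns[covariates.isna().any()].tolist()
        if missing:
            raise ValueError(f"missing values in covariate(s): {missing}")
        x = pd.concat([x, covariates.astype(float)], axis=1)
    # samples with an undetected marker are dropped (pairwise-available policy)
    keep = x["marker"].notna().to_numpy()
    x, y = x.loc[keep], y[keep]
    if np.allclose(x["marker"], x["marker"].iloc[0]):
        logger.warning("degenerate predictor (constant); OR undefined")
        return LogitResult(np.inf, (np.nan, np.nan), np.nan, np.nan, False, flagged=True)
    exog = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, exog).fit(method="newton", tol=1e-8, maxiter=100, disp=False)
        if not fit.mle_retvals.get("converged", False):
            raise PerfectSeparationError("did not converge")
        coef = float(fit.params["marker"])
        se = float(fit.bse["marker"])
        if not np.isfinite(se) or se > 1e3:
            raise PerfectSeparationError("unstable standard error")
        p = float(fit.pvalues["marker"])
        lo, hi = np.exp(coef - 1.96 * se), np.exp(coef + 1.96 * se)
        return LogitResult(float(np.exp(coef)), (float(lo), float(hi)), p, coef, True)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        logger.warning("logistic fit flagged (separation or non-convergence)")
        return LogitResult(np.inf, (np.nan, np.nan), np.nan, np.nan, False, flagged=True)


# ---------------------------------------------------------------------------
# group comparison tests


def group_compare(data, labels=None, kind: str = "continuous") -> dict:
    """Two-group comparison following the clinical-table conventions.

    Continuous: Shapiro-Wilk normality gate (alpha 0.05 in both groups)
    chooses the pooled two-sided t-test, otherwise Mann-Whitney U.
    Categorical: ``data`` is a 2x2 count table; Pearson chi-square
    without continuity correction unless any expected cell < 5, in
    which case the two-sided Fisher exact test is used.
    """
    if kind == "categorical":
        table = np.asarray(data, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("categorical comparison expects a 2x2 table")
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            res = stats.fisher_exact(table, alternative="two-sided")
            return {"test_name": "fisher_exact", "statistic": float(res.statistic), "p": float(res.pvalue)}
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return {"test_name": "chi2", "statistic": float(chi2), "p": float(p)}

    if kind != "continuous":
        raise ValueError(f"unknown kind {kind!r}")
    v = np.asarray(data, dtype=float)
    lab = np.asarray(labels)
    levels = pd.unique(lab)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a = v[lab == levels[0]]
    b = v[lab == levels[1]]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    normal = True
    for g in (a, b):
        if g.size >= 3 and np.ptp(g) > 0:
            if stats.shapiro(g).pvalue < 0.05:
                normal = False
    if normal:
        if np.ptp(np.concatenate([a, b])) == 0:
            return {"test_name": "t", "statistic": 0.0, "p": 1.0}
        res = stats.ttest_ind(a, b, equal_var=True)
        return {"test_name": "t", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test_name": "mannwhitney", "statistic": float(res.statistic), "p": float(res.pvalue)}
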