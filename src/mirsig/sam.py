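"""Two-class unpaired significance analysis of microarrays (SAM).

Implements the moderated t-like statistic

    d_i = (mean_case_i - mean_control_i) / (s_i + s0)

on log10 relative expression, where s_i is the pooled standard error

    s_i = sqrt[(1/n1 + 1/n2) * (sum of within-group squared deviations)
               / (n1 + n2 - 2)]

and s0 is a small "fudge factor" chosen to decouple d from the
per-feature variance.  The null distribution comes from relabelings of
the samples that preserve group sizes; the false discovery rate at a
threshold t on |d| is

    FDR(t) = pi0 * median_perm #{null |d| >= t} / #{observed |d| >= t}

with pi0 estimated from the fraction of observed d values falling
inside the interquartile range of the pooled null d.  A feature's
q-value is the smallest FDR at which it would be called, made monotone
non-increasing in |d|.

Fold changes are ratios of arithmetic group means on the linear
2^-dCt scale; the published selection rule is fold change > 8 together
with q < 1e-6 (i.e. "< 0.0001%").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SamConfig:
    """Tuning knobs for the SAM run.

    q_max is a proportion: the published "q-value < 0.0001%" threshold
    is 1e-6.  With ~1000 permutations this is operationally q == 0.
    """

    n_permutations: int = 1000
    seed: int = 0
    s0_percentile: str | float = "auto"
    fc_min: float = 8.0
    q_max: float = 1e-6
    min_per_group: int = 2

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be a proportion in (0, 1)")


@dataclass
class SamResult:
    """Per-miRNA SAM scores plus the machinery needed for QQ plots."""

    table: pd.DataFrame  # columns: d, s, mean_case, mean_control, fold_change, q_value
    s0: float
    expected_order_stats: np.ndarray
    null_d: np.ndarray | None = None  # (n_perm, m) matrix of null d values

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DeregulatedSet:
    """The selected signature: miRNAs passing the FC and q thresholds."""

    table: pd.DataFrame  # subset of SamResult.table + 'direction' column
    fc_min: float
    q_max: float

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# statistic


def _group_moments(x: np.ndarray, case: np.ndarray):
    """NaN-aware per-row means, within-group SSQ and counts for both groups.

    x: (m features, n samples); case: boolean (n,).
    """
    xc = x[:, case]
    xk = x[:, ~case]
    n1 = np.sum(~np.isnan(xc), axis=1).astype(float)
    n2 = np.sum(~np.isnan(xk), axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        m1 = np.nansum(xc, axis=1) / np.where(n1 > 0, n1, np.nan)
        m2 = np.nansum(xk, axis=1) / np.where(n2 > 0, n2, np.nan)
        ss1 = np.nansum((xc - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((xk - m2[:, None]) ** 2, axis=1)
    return m1, m2, ss1, ss2, n1, n2


def pooled_se(x: np.ndarray, case: np.ndarray, min_per_group: int = 2):
    """Pooled standard error s_i and group means; rows with <min_per_group
    defined values in either group get NaN."""
    m1, m2, ss1, ss2, n1, n2 = _group_moments(x, case)
    ok = (n1 >= min_per_group) & (n2 >= min_per_group)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2.0))
    s = np.where(ok, s, np.nan)
    m1 = np.where(ok, m1, np.nan)
    m2 = np.where(ok, m2, np.nan)
    return s, m1, m2


def sam_statistic(
    x: np.ndarray, case: np.ndarray, s0: float, min_per_group: int = 2
) -> np.ndarray:
    """SAM d scores for a (features x samples) log10 matrix.

    Rows with fewer than ``min_per_group`` defined values in either
    group yield NaN (excluded from calling).  Raises if no row has
    enough data in both groups.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    s, m1, m2 = pooled_se(x, case, min_per_group)
    if np.all(np.isnan(s)):
        raise ValueError("every feature has a group with too few defined values")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m1 - m2) / (s + s0)
    return d


# ---------------------------------------------------------------------------
# fudge factor


def choose_s0(
    x: np.ndarray,
    case: np.ndarray,
    min_features: int = 20,
    n_windows: int = 10,
    min_per_group: int = 2,
) -> float:
    """Pick s0 minimizing the variance-dependence of d.

    Candidates are the percentiles {0, 5, ..., 100} of the s_i
    distribution (plus 0).  For each candidate the d scores are split
    into windows by s_i quantile and the coefficient of variation of the
    per-window median absolute deviations is computed; the candidate
    with the smallest CV wins, ties broken toward smaller s0.
    Deterministic given the input.
    """
    s, m1, m2 = pooled_se(x, case, min_per_group)
    ok = ~np.isnan(s)
    if ok.sum() < min_features:
        raise ValueError(f"too few features with defined scores ({int(ok.sum())} < {min_features})")
    s_ok = s[ok]
    diff = (m1 - m2)[ok]
    if np.allclose(s_ok, s_ok[0]):
        logger.info("all pooled standard errors equal; s0 = 0")
        return 0.0
    candidates = np.unique(np.percentile(s_ok, np.arange(0, 101, 5)))
    candidates = np.unique(np.concatenate([[0.0], candidates]))
    # fixed s_i-quantile windows shared by all candidates
    edges = np.quantile(s_ok, np.linspace(0, 1, n_windows + 1))
    idx = np.clip(np.searchsorted(edges, s_ok, side="right") - 1, 0, n_windows - 1)
    best = (np.inf, np.inf)  # (cv, s0)
    for s0 in candidates:
        d = diff / (s_ok + s0)
        mads = np.array(
            [
                np.median(np.abs(d[idx == w] - np.median(d[idx == w])))
                for w in range(n_windows)
                if np.any(idx == w)
            ]
        )
        mu = mads.mean()
        cv = np.inf if mu == 0 else mads.std(ddof=0) / mu
        if (cv, s0) < best:
            best = (cv, float(s0))
    return best[1]


# ---------------------------------------------------------------------------
# permutation null


def _relabelings(n: int, n1: int, n_permutations: int, seed: int) -> list[np.ndarray]:
    """Group-size-preserving relabelings as boolean case masks.

    All C(n, n1) relabelings are enumerated when feasible; otherwise
    distinct ones are sampled without replacement from a seeded RNG.
    """
    total = math.comb(n, n1)
    if total <= n_permutations:
        masks = []
        for combo in combinations(range(n), n1):
            m = np.zeros(n, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
        return masks
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    masks = []
    while len(masks) < n_permutations:
        combo = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if combo in seen:
            continue
        seen.add(combo)
        m = np.zeros(n, dtype=bool)
        m[list(combo)] = True
        masks.append(m)
    return masks


def permutation_null(
    x: np.ndarray, case: np.ndarray, cfg: SamConfig, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Null d matrix (one sorted row per relabeling) and its columnwise mean.

    Only features whose observed d is defined enter the null.  When a
    relabeling leaves a feature with too few defined values its null d
    is NaN; order statistics are then formed by quantile interpolation
    so every row has the same length.
    """
    d_obs = sam_statistic(x, case, s0, cfg.min_per_group)
    eligible = ~np.isnan(d_obs)
    xe = x[eligible]
    m = int(eligible.sum())
    masks = _relabelings(x.shape[1], int(case.sum()), cfg.n_permutations, cfg.seed)
    rows = np.empty((len(masks), m))
    probs = np.linspace(0, 1, m)
    for k, mask in enumerate(masks):
        with np.errstate(invalid="ignore", divide="ignore"):
            s, m1, m2 = pooled_se(xe, mask, cfg.min_per_group)
            dk = (m1 - m2) / (s + s0)
        dk = dk[~np.isnan(dk)]
        dk.sort()
        if dk.size == m:
            rows[k] = dk
        elif dk.size == 0:
            rows[k] = np.nan
        else:
            rows[k] = np.quantile(dk, probs)
    expected = np.nanmean(rows, axis=0)
    return rows, expected


# ---------------------------------------------------------------------------
# q-values


def q_values(d_obs: np.ndarray, null_d: np.ndarray) -> np.ndarray:
    """Permutation q-values for the observed d scores.

    For each threshold t (each observed |d|):
      FDR(t) = pi0 * median over relabelings of #{null |d| >= t}
               / #{observed |d| >= t},
    pi0 = fraction of observed d within the pooled null IQR, scaled by
    1/0.5 and capped at 1.  q_i = min FDR over thresholds t <= |d_i|,
    then made monotone non-increasing in |d| and clipped to [0, 1].
    NaN d gives NaN q.
    """
    q = np.full_like(d_obs, np.nan, dtype=float)
    ok = ~np.isnan(d_obs)
    d = d_obs[ok]
    m = d.size
    if m == 0:
        return q

    pooled = null_d[~np.isnan(null_d)]
    if pooled.size == 0:
        q[ok] = 1.0
        return q
    q25, q75 = np.quantile(pooled, [0.25, 0.75])
    pi0 = min(1.0, np.mean((d >= q25) & (d <= q75)) / 0.5) if m else 1.0

    abs_obs = np.abs(d)
    order = np.argsort(abs_obs)  # ascending
    thresholds = abs_obs[order]
    # observed exceedance counts at each threshold (ties share a count)
    sorted_abs = np.sort(abs_obs)
    n_obs_ge = m - np.searchsorted(sorted_abs, thresholds, side="left")
    # null exceedance counts per relabeling, median across relabelings
    null_abs = np.sort(np.abs(null_d), axis=1)
    n_null_ge = null_abs.shape[1] - np.apply_along_axis(
        np.searchsorted, 1, null_abs, thresholds, side="left"
    )
    # rows that were all-NaN (degenerate relabelings) are dropped from the median
    valid_rows = ~np.isnan(null_abs[:, :1]).ravel()
    med_null = np.median(n_null_ge[valid_rows], axis=0) if valid_rows.any() else np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = pi0 * med_null / n_obs_ge
    fdr = np.clip(fdr, 0.0, 1.0)
    # q at threshold t_j = min FDR over thresholds <= t_j; the running min
    # over ascending |d| also enforces monotone non-increasing q in |d|.
    q_at = np.minimum.accumulate(fdr)
    q_sorted = np.empty(m)
    q_sorted[order] = q_at
    # tie consistency: equal |d| get equal q (running min already ensures
    # the later tie has the smaller-or-equal value; unify to the min)
    df = pd.DataFrame({"a": abs_obs, "q": q_sorted})
    q_final = df.groupby("a")["q"].transform("min").to_numpy()
    q[ok] = q_final
    return q


# ---------------------------------------------------------------------------
# fold change and selection


def fold_changes(expr: pd.DataFrame, case: np.ndarray) -> pd.Series:
    """Case/control ratio of arithmetic means of linear-scale expression.

    Means use pairwise-available samples.  A zero or undefined control
    mean yields a missing fold change (logged).
    """
    mean_case = expr.loc[:, expr.columns[case]].mean(axis=1, skipna=True)
    mean_ctrl = expr.loc[:, expr.columns[~case]].mean(axis=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_ctrl
    bad = fc.index[(mean_ctrl <= 0) | mean_ctrl.isna() | mean_case.isna()]
    if len(bad):
        logger.info("fold change undefined for %d miRNA(s)", len(bad))
        fc.loc[bad] = np.nan
    return fc


def sam_analysis(
    em: ExpressionMatrix, case_mask: np.ndarray | pd.Series, cfg: SamConfig | None = None
) -> SamResult:
    """Run the full SAM pipeline on an expression matrix.

    ``case_mask`` marks the case-group samples (aligned with
    ``em.sample_ids``).  Returns per-miRNA d, q, group means and fold
    change, plus the fudge factor and permutation order statistics.
    """
    cfg = cfg or SamConfig()
    case = np.asarray(case_mask, dtype=bool)
    if case.shape[0] != len(em.sample_ids):
        raise ValueError("case mask length does not match sample count")
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    x = em.log10_expr.to_numpy(dtype=float)

    if cfg.s0_percentile == "auto":
        s0 = choose_s0(x, case, min_per_group=cfg.min_per_group)
    else:
        s_all, _, _ = pooled_se(x, case, cfg.min_per_group)
        s0 = float(np.percentile(s_all[~np.isnan(s_all)], float(cfg.s0_percentile)))

    d = sam_statistic(x, case, s0, cfg.min_per_group)
    s, m1_log, m2_log = pooled_se(x, case, cfg.min_per_group)
    null_d, expected = permutation_null(x, case, cfg, s0)
    q = q_values(d, null_d)
    fc = fold_changes(em.expr, case)

    mean_case = em.expr.loc[:, em.expr.columns[case]].mean(axis=1, skipna=True)
    mean_ctrl = em.expr.loc[:, em.expr.columns[~case]].mean(axis=1, skipna=True)
    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fold_change": fc,
            "q_value": q,
        },
        index=em.expr.index,
    )
    return SamResult(table=table, s0=s0, expected_order_stats=expected, null_d=null_d)


def select_signature(sam: SamResult, cfg: SamConfig | None = None) -> DeregulatedSet:
    """Apply the joint fold-change and q-value rule, strict inequalities.

    Selected: (FC > fc_min or FC < 1/fc_min) and q < q_max.  The result
    is ordered by |d| descending and carries an up/down direction flag.
    """
    cfg = cfg or SamConfig()
    t = sam.table
    fc = t["fold_change"]
    q = t["q_value"]
    keep = ((fc > cfg.fc_min) | (fc < 1.0 / cfg.fc_min)) & (q < cfg.q_max)
    keep &= fc.notna() & q.notna()
    sel = t[keep].copy()
    sel["direction"] = np.where(sel["fold_change"] > 1.0, "up", "down")
    sel = sel.loc[sel["d"].abs().sort_values(ascending=False).index]
    return DeregulatedSet(table=sel, fc_min=cfg.fc_min, q_max=cfg.q_max)


def write_sam_table(sam: SamResult, path, sep: str = "\t") -> None:
    """Write the per-miRNA score table (q-value reported in percent)."""
    out = sam.table.copy()
    out["q_value_percent"] = out.pop("q_value") * 100.0
    out.index.name = "mirna_id"
    out.to_csv(path, sep=sep, na_rep="NA")
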