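"""Group-level inference for the blood-pressure / expression study.

Implements the statistical toolkit the analysis chains together: one-way
ANOVA recomputed from printed (n, mean, SD) summaries, the chi-square test
of independence, classic one-way ANCOVA (group factor + covariates, no
interactions) with partial eta squared and Bonferroni-corrected post hoc
subsets, partial correlation by double residualisation, and a priori
sample-size computation for the ANCOVA group effect from the noncentral F
distribution.

All model fits are plain least squares on dummy-coded design matrices;
F statistics for the group effect come from the SSE difference between the
full model and the covariates-only model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "AncovaResult",
    "PartialCorrResult",
    "PowerSpec",
    "anova_from_summaries",
    "chi_square_independence",
    "ancova",
    "bonferroni_subsets",
    "partial_correlation",
    "required_n_ancova",
    "required_n_partial_correlation",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group (n, mean, SD) as printed in a demographics table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD cannot be negative")


def anova_from_summaries(groups: Sequence[GroupSummary]) -> tuple[float, int, int]:
    """One-way ANOVA F from per-group (n, mean, SD) summaries.

    Uses the exact between/within sum-of-squares decomposition, so the
    result is identical to a raw-data one-way ANOVA whose groups have these
    summaries.  Returns (F, df_between, df_within).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], float)
    means = np.array([g.mean for g in groups], float)
    sds = np.array([g.sd for g in groups], float)
    big_n = ns.sum()
    grand = float(ns @ means / big_n)
    ssb = float(ns @ (means - grand) ** 2)
    ssw = float((ns - 1) @ sds**2)
    df1 = len(groups) - 1
    df2 = int(big_n) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


def chi_square_independence(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (chi2, df, p).  Raises on a zero row or column margin, where
    expected counts are undefined.
    """
    obs = np.asarray(counts, float)
    if obs.sum() <= 0:
        raise ValueError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _design(group: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, list]:
    """Full-rank design: intercept + group dummies (first level ref) + covariates."""
    levels = list(dict.fromkeys(group.tolist()))
    n = len(group)
    cols = [np.ones(n)]
    for lev in levels[1:]:
        cols.append((group == lev).astype(float))
    if covariates is not None and covariates.size:
        for j in range(covariates.shape[1]):
            cols.append(covariates[:, j])
    return np.column_stack(cols), levels


def _sse(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), beta, rank


@dataclass
class AncovaResult:
    """Group effect of a one-way ANCOVA: F test, effect size, adjusted means."""

    F: float
    df1: int
    df2: int
    p: float
    partial_eta2: float
    adjusted_means: dict = field(default_factory=dict)
    levels: list = field(default_factory=list)


def ancova(
    outcome: Sequence[float],
    group: Sequence,
    covariates: np.ndarray | None = None,
) -> AncovaResult:
    """One-way ANCOVA of ``outcome`` on a group factor, controlling covariates.

    Classic additive model (no group x covariate interaction): the group
    F compares the full model against the covariates-only model,
    ``F = ((SSE_red - SSE_full)/(k-1)) / (SSE_full/df2)`` with
    ``df2 = N - k - c``.  Partial eta squared is
    ``df1*F / (df1*F + df2)``; adjusted means evaluate the fit at the
    grand covariate means.
    """
    y = np.asarray(outcome, float)
    g = np.asarray(group)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if np.isnan(cov).any():
            raise ValueError("missing values in covariates")
    if np.isnan(y).any():
        raise ValueError("missing values in outcome")

    x_full, levels = _design(g, cov)
    k = len(levels)
    c = 0 if cov is None else cov.shape[1]
    n = len(y)
    df1, df2 = k - 1, n - k - c
    if df2 <= 0:
        raise ValueError("not enough observations for the model")
    sse_full, beta, rank = _sse(x_full, y)
    if rank < x_full.shape[1]:
        # identify which added column is collinear, for the error message
        for j in range(1, x_full.shape[1]):
            if np.linalg.matrix_rank(x_full[:, : j + 1]) < j + 1:
                names = [f"group[{lev}]" for lev in levels[1:]] + [
                    f"covariate[{i}]" for i in range(c)
                ]
                raise ValueError(f"design is rank deficient at column {names[j - 1]}")
    x_red, _ = _design(np.zeros(n, dtype=int), cov)
    sse_red, _, _ = _sse(x_red, y)
    scale = float(np.var(y)) * n
    if sse_full <= max(1e-10, 1e-12 * scale):
        if sse_red - sse_full <= max(1e-10, 1e-12 * scale):
            # covariates already explain everything: the group adds nothing
            F = 0.0
        else:
            raise ValueError("zero residual variance; ANCOVA F undefined")
    else:
        F = ((sse_red - sse_full) / df1) / (sse_full / df2)
    p = float(stats.f.sf(F, df1, df2))
    eta2 = (df1 * F) / (df1 * F + df2)

    cov_means = cov.mean(axis=0) if cov is not None else np.array([])
    adj = {}
    for i, lev in enumerate(levels):
        xrow = np.concatenate([[1.0], np.eye(k - 1)[i - 1] if i else np.zeros(k - 1), cov_means])
        adj[lev] = float(xrow @ beta)
    return AncovaResult(F=float(F), df1=df1, df2=df2, p=p, partial_eta2=float(eta2),
                        adjusted_means=adj, levels=levels)


def bonferroni_subsets(
    outcome: Sequence[float],
    group: Sequence,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[dict, dict]:
    """Bonferroni-corrected pairwise covariate-adjusted comparisons + letters.

    Each pair's two-sided p (from the full-model contrast t test) is
    multiplied by the number of pairs and capped at 1.  Homogeneous-subset
    letters form the usual compact letter display: every maximal clique of
    the "not significantly different" graph receives one letter, cliques
    ordered by their mean adjusted mean, so groups share a letter exactly
    when they belong to a common non-significant subset.

    Returns (pairwise adjusted p by unordered pair, letters by group).
    """
    y = np.asarray(outcome, float)
    g = np.asarray(group)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
    res = ancova(y, g, cov)
    x_full, levels = _design(g, cov)
    k = len(levels)
    sse_full, beta, _ = _sse(x_full, y)
    df2 = res.df2
    sigma2 = sse_full / df2
    xtx_inv = np.linalg.pinv(x_full.T @ x_full)

    def contrast(i: int, j: int) -> np.ndarray:
        row = np.zeros(x_full.shape[1])
        if i > 0:
            row[i] = 1.0  # dummy columns sit at positions 1..k-1
        if j > 0:
            row[j] -= 1.0
        return row

    n_pairs = k * (k - 1) // 2
    pairwise: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(k), 2):
        cvec = contrast(i, j)
        est = float(cvec @ beta)
        se = math.sqrt(sigma2 * float(cvec @ xtx_inv @ cvec))
        t = est / se
        p_adj = min(1.0, 2.0 * float(stats.t.sf(abs(t), df2)) * n_pairs)
        pairwise[frozenset({levels[i], levels[j]})] = p_adj

    def is_clique(subset: tuple) -> bool:
        return all(
            pairwise[frozenset({a, b})] >= alpha
            for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple] = []
    for size in range(k, 0, -1):
        for subset in itertools.combinations(levels, size):
            if is_clique(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    cliques.sort(key=lambda c: np.mean([res.adjusted_means[lev] for lev in c]))
    letters = {lev: "" for lev in levels}
    for idx, clique in enumerate(cliques):
        for lev in clique:
            letters[lev] += chr(ord("a") + idx)
    letters = {lev: "".join(sorted(s)) for lev, s in letters.items()}
    return pairwise, letters


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlation with its degrees of freedom and two-tailed p."""

    r: float
    df: int
    p: float


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> PartialCorrResult | None:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualised on the covariates (plus intercept) by
    least squares; r is the Pearson correlation of the residuals with
    ``df = n - 2 - k`` and a two-tailed p from the t distribution.  With no
    covariates this is the plain Pearson correlation.  Returns None when a
    residual vector is constant.
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    n = len(xv)
    if covariates is None:
        cov = np.ones((n, 1))
        k = 0
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        k = cov.shape[1]
        cov = np.column_stack([np.ones(n), cov])
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    rx = xv - cov @ np.linalg.lstsq(cov, xv, rcond=None)[0]
    ry = yv - cov @ np.linalg.lstsq(cov, yv, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0) or rx.std() == 0 or ry.std() == 0:
        return None
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return PartialCorrResult(r=r, df=df, p=0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, df=df, p=p)


@dataclass(frozen=True)
class PowerSpec:
    """A priori power specification for the ANCOVA group effect."""

    effect_size_f: float = 0.50
    alpha: float = 0.05
    power: float = 0.95
    k_groups: int = 3
    n_covariates: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be positive")
        if self.k_groups < 2:
            raise ValueError("need at least two groups")


def ancova_power(spec: PowerSpec, n_total: int) -> float:
    """Power of the ANCOVA group-effect F test at total sample size N.

    Noncentral F with df1 = k-1, df2 = N - k - c and noncentrality
    lambda = f^2 * N.
    """
    df1 = spec.k_groups - 1
    df2 = n_total - spec.k_groups - spec.n_covariates
    if df2 < 1:
        return 0.0
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    lam = spec.effect_size_f**2 * n_total
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_n_ancova(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest total N whose ANCOVA group-effect power reaches the target."""
    for n in range(spec.k_groups + spec.n_covariates + 2, n_max + 1):
        if ancova_power(spec, n) >= spec.power:
            return n
    raise ValueError(f"power {spec.power} not attainable below N={n_max}")


def required_n_partial_correlation(
    rho: float, alpha: float = 0.05, power: float = 0.95, n_covariates: int = 3,
    two_tailed: bool = True,
) -> int:
    """Smallest n detecting a partial correlation ``rho`` via Fisher's z.

    Approximate: z = atanh(rho) has SE 1/sqrt(n - 3 - k); n is the
    smallest sample size with normal-approximation power at least the
    target.  (Exact G*Power variants differ slightly depending on the test
    family chosen.)
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be in (0, 1) in magnitude")
    z = abs(math.atanh(rho))
    za = stats.norm.isf(alpha / 2 if two_tailed else alpha)
    for n in range(n_covariates + 5, 100_000):
        se = 1.0 / math.sqrt(n - 3 - n_covariates)
        if stats.norm.sf(za - z / se) >= power:
            return n
    raise ValueError("power not attainable")
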