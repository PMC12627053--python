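"""Independent brute-force reference implementations used only by tests.

Each oracle takes the same inputs as the corresponding package function but
computes the statistic along a different route (library call, pair
enumeration, explicit ANOVA table), so agreement between the two is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def kappa_oracle(h, m, q=6):
    """Cohen's kappa via sklearn's confusion-matrix implementation."""
    from sklearn.metrics import cohen_kappa_score

    with np.errstate(invalid="ignore", divide="ignore"):
        k = cohen_kappa_score(h, m, labels=list(range(q)))
    return None if np.isnan(k) else float(k)


def ac1_oracle(h, m, q=6):
    """Gwet's AC1 by direct elementwise evaluation of its definition."""
    h = np.asarray(h, int)
    m = np.asarray(m, int)
    n = len(h)
    po = np.mean(h == m)
    pe = 0.0
    for cat in range(q):
        pi = (np.mean(h == cat) + np.mean(m == cat)) / 2.0
        pe += pi * (1.0 - pi)
    pe /= q - 1
    if pe >= 1.0:
        return None
    return float((po - pe) / (1.0 - pe))


def alpha_ordinal_oracle(h, m, q=6):
    """Krippendorff's alpha by exhaustive enumeration of rating pairs.

    Observed disagreement averages the ordinal metric over the two ratings
    within each unit; expected disagreement over all ordered pairs of the
    pooled ratings.  The metric uses the coincidence-matrix marginal
    frequencies, as in the canonical definition.
    """
    h = np.asarray(h, int)
    m = np.asarray(m, int)
    n = len(h)
    pooled = np.concatenate([h, m])
    n_g = np.bincount(pooled, minlength=q).astype(float)

    def delta2(c, k):
        lo, hi = min(c, k), max(c, k)
        return (n_g[lo : hi + 1].sum() - (n_g[lo] + n_g[hi]) / 2.0) ** 2

    d_obs = np.mean([delta2(a, b) for a, b in zip(h, m)])
    total = 0.0
    cnt = 0
    for i in range(2 * n):
        for j in range(2 * n):
            if i != j:
                total += delta2(pooled[i], pooled[j])
                cnt += 1
    d_exp = total / cnt
    if d_exp == 0:
        return None
    return float(1.0 - d_obs / d_exp)


def icc_oracle(h, m, variant="consistency"):
    """ICC(3,1)/ICC(A,1) via pingouin's mixed-model implementation."""
    import pandas as pd
    import pingouin as pg

    n = len(h)
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), 2),
            "raters": ["h", "m"] * n,
            "ratings": np.column_stack([h, m]).ravel().astype(float),
        }
    )
    icc = pg.intraclass_corr(
        df, targets="targets", raters="raters", ratings="ratings"
    ).set_index("Type")
    key = "ICC(C,1)" if variant == "consistency" else "ICC(A,1)"
    return float(icc.loc[key, "ICC"])


def anova_oracle(groups):
    """One-way ANOVA F via scipy on raw per-group data."""
    from scipy import stats

    return stats.f_oneway(*groups)


def ancova_oracle(y, g, cov):
    """Group-effect F via statsmodels OLS on the same additive model."""
    import pandas as pd
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "g": g})
    terms = []
    for j in range(cov.shape[1]):
        df[f"c{j}"] = cov[:, j]
        terms.append(f"c{j}")
    rhs = " + ".join(terms)
    full = smf.ols(f"y ~ C(g) + {rhs}", df).fit()
    red = smf.ols(f"y ~ {rhs}", df).fit()
    k = df["g"].nunique()
    F = ((red.ssr - full.ssr) / (k - 1)) / (full.ssr / full.df_resid)
    return float(F), int(k - 1), int(full.df_resid)


def partial_corr_precision_oracle(x, y, cov):
    """Partial correlation from the inverse correlation matrix."""
    mat = np.column_stack([x, y, cov])
    prec = np.linalg.inv(np.corrcoef(mat.T))
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def ncf_cdf_series_oracle(x, df1, df2, lam, terms=500):
    """Noncentral-F CDF as a Poisson mixture of central incomplete betas."""
    from scipy import special

    total = 0.0
    log_w = -lam / 2.0
    for j in range(terms):
        w = np.exp(log_w + j * np.log(lam / 2.0) - special.gammaln(j + 1))
        a = df1 / 2.0 + j
        z = df1 * x / (df1 * x + df2)
        total += w * special.betainc(a, df2 / 2.0, z)
    return total
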