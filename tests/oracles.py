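"""Independent textbook-formula oracles used to cross-check the library routes.

These are deliberately naive, loop-based implementations written from the
standard formulas; they must stay independent of the package's code paths
(which go through scipy/statsmodels/pingouin/scikit-learn).
"""

from __future__ import annotations

import numpy as np
import scipy.stats


def oneway_classical(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    F = (ssb / df1) / (ssw / df2)
    p = scipy.stats.f.sf(F, df1, df2)
    return F, df1, df2, p


def oneway_welch(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's unequal-variance one-way ANOVA (Welch 1951)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = 3.0 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    F = a / (1 + 2 * lam * (k - 2) / 3)
    df1 = k - 1
    df2 = 1.0 / lam
    p = scipy.stats.f.sf(F, df1, df2)
    return F, df1, df2, p


def bartlett_stat(groups: list[np.ndarray]) -> tuple[float, float]:
    """Bartlett's chi-square homogeneity statistic."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    v = np.array([g.var(ddof=1) for g in groups])
    N = n.sum()
    sp2 = ((n - 1) * v).sum() / (N - k)
    stat = (N - k) * np.log(sp2) - ((n - 1) * np.log(v)).sum()
    corr = 1 + ((1.0 / (n - 1)).sum() - 1.0 / (N - k)) / (3 * (k - 1))
    stat /= corr
    p = scipy.stats.chi2.sf(stat, k - 1)
    return stat, p


def levene_median(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brown–Forsythe: one-way ANOVA on absolute deviations from medians."""
    z = [np.abs(g - np.median(g)) for g in groups]
    F, df1, df2, p = oneway_classical(z)
    return F, p


def three_way_ss(
    y: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray, c_idx: np.ndarray
) -> dict[str, float]:
    """Balanced three-factor sums of squares by cell-mean decomposition."""
    a_lv, b_lv, c_lv = np.unique(a_idx), np.unique(b_idx), np.unique(c_idx)
    grand = y.mean()

    def mean_where(mask):
        return y[mask].mean()

    ss = {}
    # main effects
    for name, idx, levels in (("a", a_idx, a_lv), ("b", b_idx, b_lv), ("c", c_idx, c_lv)):
        ss[name] = sum(
            (idx == l).sum() * (mean_where(idx == l) - grand) ** 2 for l in levels
        )
    # two-way interactions
    for name, i1, l1, i2, l2 in (
        ("ab", a_idx, a_lv, b_idx, b_lv),
        ("ac", a_idx, a_lv, c_idx, c_lv),
        ("bc", b_idx, b_lv, c_idx, c_lv),
    ):
        total = 0.0
        for u in l1:
            for v in l2:
                mask = (i1 == u) & (i2 == v)
                total += mask.sum() * (
                    mean_where(mask)
                    - mean_where(i1 == u)
                    - mean_where(i2 == v)
                    + grand
                ) ** 2
        ss[name] = total
    # three-way interaction and residual
    abc = 0.0
    resid = 0.0
    for u in a_lv:
        for v in b_lv:
            for w in c_lv:
                mask = (a_idx == u) & (b_idx == v) & (c_idx == w)
                cell = mean_where(mask)
                abc += mask.sum() * (
                    cell
                    - mean_where((a_idx == u) & (b_idx == v))
                    - mean_where((a_idx == u) & (c_idx == w))
                    - mean_where((b_idx == v) & (c_idx == w))
                    + mean_where(a_idx == u)
                    + mean_where(b_idx == v)
                    + mean_where(c_idx == w)
                    - grand
                ) ** 2
                resid += ((y[mask] - cell) ** 2).sum()
    ss["abc"] = abc
    ss["residual"] = resid
    return ss


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression slope/intercept from the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1]), float(beta[0])


def ancova_interaction_F(
    temp: np.ndarray, host01: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Extra-sum-of-squares F for the slope-difference term."""
    X_full = np.column_stack([np.ones_like(temp), temp, host01, temp * host01])
    X_red = X_full[:, :3]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_f, rss_r = rss(X_full), rss(X_red)
    df_den = len(y) - X_full.shape[1]
    F = (rss_r - rss_f) / (rss_f / df_den)
    p = scipy.stats.f.sf(F, 1, df_den)
    return F, p
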