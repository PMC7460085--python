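"""Univariate statistics for the factorial stress experiment.

Two instruments live here.  First, the screening rule used per fatty acid:
within each host × salinity stratum, concentrations are compared across
temperatures with a one-way ANOVA whose flavour is chosen by a Bartlett
pre-test — classical ANOVA when group variances are homogeneous, Welch's
unequal-variance ANOVA otherwise — with a Shapiro–Wilk check of the
residuals reported alongside.  Second, the balanced three-way ANOVA
(host × temperature × salinity) applied to the unsaturation index, together
with a Levene (Brown–Forsythe) homogeneity test over the 18 design cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .fame import DlPolicy, ProfileSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "GroupedValues",
    "auto_anova",
    "bartlett",
    "levene",
    "significance_stars",
    "three_way_anova",
    "univariate_screen",
]


@dataclass
class GroupedValues:
    """Numeric observations split into labelled groups."""

    groups: list[tuple[str, np.ndarray]]
    response_name: str = "value"

    def __post_init__(self) -> None:
        self.groups = [(str(lbl), np.asarray(v, dtype=float)) for lbl, v in self.groups]
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for lbl, v in self.groups:
            if v.size < 2:
                raise ValueError(f"group {lbl!r} needs n >= 2, got {v.size}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"group {lbl!r} contains non-finite values")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([v for _, v in self.groups])

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([[lbl] * v.size for lbl, v in self.groups])


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def bartlett(grouped: GroupedValues) -> tuple[float, float]:
    """Bartlett's chi-square test of equal group variances → (statistic, p)."""
    arrays = [v for _, v in grouped.groups]
    if any(np.var(v, ddof=1) == 0 for v in arrays):
        raise ValueError("a group has zero variance; Bartlett test degenerate")
    stat, p = scipy.stats.bartlett(*arrays)
    return float(stat), float(p)


def levene(grouped: GroupedValues, center: str = "median") -> tuple[int, int, float, float]:
    """Levene/Brown–Forsythe homogeneity test → (df1, df2, statistic, p).

    ``center="median"`` (the default, Brown–Forsythe) is robust to
    non-normal groups; ``center="mean"`` gives the original Levene form.
    """
    arrays = [v for _, v in grouped.groups]
    stat, p = scipy.stats.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(v.size for v in arrays)
    return k - 1, n - k, float(stat), float(p)


@dataclass
class AnovaResult:
    """Outcome of the Bartlett-gated one-way ANOVA."""

    method: str  # "classical" or "welch"
    F: float
    df_num: float
    df_den: float
    p: float
    stars: str
    bartlett_stat: float
    bartlett_p: float
    shapiro_stat: float
    shapiro_p: float


def auto_anova(grouped: GroupedValues, alpha_hetero: float = 0.05) -> AnovaResult:
    """One-way ANOVA with the variance-gated choice of method.

    Bartlett's test decides the route: p < ``alpha_hetero`` sends the
    comparison to Welch's unequal-variance ANOVA, otherwise the classical
    equal-variance ANOVA is used.  Normality of the residuals (observations
    minus group means) is checked with Shapiro–Wilk and reported as a
    warning only — it never changes the routing.
    """
    if not 0.0 < alpha_hetero < 1.0:
        raise ValueError("alpha_hetero must be in (0, 1)")
    b_stat, b_p = bartlett(grouped)
    arrays = [v for _, v in grouped.groups]

    residuals = np.concatenate([v - v.mean() for v in arrays])
    sh_stat, sh_p = scipy.stats.shapiro(residuals)
    if sh_p < 0.05:
        logger.warning(
            "%s: residuals depart from normality (Shapiro p=%.3g)",
            grouped.response_name,
            sh_p,
        )

    k = len(arrays)
    if b_p < alpha_hetero:
        method = "welch"
        df = pd.DataFrame({"y": grouped.values, "g": grouped.labels})
        res = pg.welch_anova(dv="y", between="g", data=df)
        F = float(res["F"].iloc[0])
        df_num = float(res["ddof1"].iloc[0])
        df_den = float(res["ddof2"].iloc[0])
        pcol = "p_unc" if "p_unc" in res.columns else "p-unc"
        p = float(res[pcol].iloc[0])
    else:
        method = "classical"
        F, p = scipy.stats.f_oneway(*arrays)
        df_num = float(k - 1)
        df_den = float(sum(v.size for v in arrays) - k)
        F, p = float(F), float(p)

    return AnovaResult(
        method=method,
        F=F,
        df_num=df_num,
        df_den=df_den,
        p=p,
        stars=significance_stars(p),
        bartlett_stat=b_stat,
        bartlett_p=b_p,
        shapiro_stat=float(sh_stat),
        shapiro_p=float(sh_p),
    )


_TERMS = {
    "C(host)": "host",
    "C(temperature)": "temp",
    "C(salinity)": "sal",
    "C(host):C(temperature)": "host:temp",
    "C(host):C(salinity)": "host:sal",
    "C(temperature):C(salinity)": "temp:sal",
    "C(host):C(temperature):C(salinity)": "host:temp:sal",
    "Residual": "residual",
}


def three_way_anova(data: pd.DataFrame, response: str = "value") -> pd.DataFrame:
    """Full-factorial host × temperature × salinity ANOVA on a balanced design.

    ``data`` needs columns ``host``, ``temperature``, ``salinity`` and the
    response.  Balance is required (every cell the same replicate count);
    the decomposition is then unique — all sums-of-squares types coincide.
    Returns a table indexed by term with df, sum_sq, mean_sq, F, p, stars.
    """
    required = {"host", "temperature", "salinity", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = data.groupby(["host", "temperature", "salinity"], observed=True).size()
    n_cells = data["host"].nunique() * data["temperature"].nunique() * data["salinity"].nunique()
    if len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError("design is unbalanced: every host×temperature×salinity cell needs the same n")

    y = data[response].to_numpy(float)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 1e-12 * max(1.0, float(np.mean(y) ** 2)) * len(y):
        # constant response: the unique decomposition is all-zero
        terms = ["host", "temp", "sal", "host:temp", "host:sal", "temp:sal", "host:temp:sal"]
        a = data["host"].nunique()
        b = data["temperature"].nunique()
        c = data["salinity"].nunique()
        dfs = [a - 1, b - 1, c - 1, (a - 1) * (b - 1), (a - 1) * (c - 1), (b - 1) * (c - 1),
               (a - 1) * (b - 1) * (c - 1)]
        resid_df = len(y) - sum(dfs) - 1
        out = pd.DataFrame(
            {
                "df": dfs + [resid_df],
                "sum_sq": 0.0,
                "mean_sq": 0.0,
                "F": [0.0] * len(terms) + [np.nan],
                "p": [1.0] * len(terms) + [np.nan],
            },
            index=terms + ["residual"],
        )
        out["stars"] = ["n.s."] * len(terms) + [""]
        return out[["df", "sum_sq", "mean_sq", "F", "p", "stars"]]

    model = smf.ols(
        f"Q('{response}') ~ C(host) * C(temperature) * C(salinity)", data=data
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)

    out = table.rename(index=_TERMS).rename(
        columns={"sum_sq": "sum_sq", "PR(>F)": "p"}
    )
    out["df"] = out["df"].astype(int)
    out["mean_sq"] = out["sum_sq"] / out["df"]
    # a term with zero SS over zero residual SS (constant response) is F = 0
    degenerate = (out.index != "residual") & np.isclose(out["sum_sq"], 0) & ~np.isfinite(out["F"])
    out.loc[degenerate, "F"] = 0.0
    out.loc[degenerate, "p"] = 1.0
    out["stars"] = [
        significance_stars(p) if np.isfinite(p) else "" for p in out["p"].fillna(np.nan)
    ]
    return out[["df", "sum_sq", "mean_sq", "F", "p", "stars"]]


def univariate_screen(
    profiles: ProfileSet,
    policy: DlPolicy | None = None,
    alpha_hetero: float = 0.05,
) -> pd.DataFrame:
    """Per-fatty-acid temperature comparisons within each host × salinity stratum.

    For every fatty acid and every (host, salinity) combination, replicate
    concentrations are grouped by temperature and sent through
    :func:`auto_anova`.  Fatty acids with a group entirely below the
    detection limit (or absent) in a stratum are skipped with a logged
    notice, as the comparison is undefined there.  Returns a tidy frame of
    one row per performed test.
    """
    policy = policy or DlPolicy()
    rows = []
    hosts = sorted({p.meta.host for p in profiles})
    salinities = sorted({p.meta.salinity for p in profiles})
    for fa in profiles.fa_inventory:
        for host in hosts:
            for sal in salinities:
                stratum = profiles.subset(host=host, salinity=sal)
                temps = sorted({p.meta.temperature for p in stratum})
                groups = []
                usable = True
                for t in temps:
                    vals = [
                        v
                        for p in stratum.subset(temperature=t)
                        if (v := p.value(fa, policy)) is not None
                    ]
                    if len(vals) < 2 or all(v == 0 for v in vals):
                        usable = False
                        break
                    groups.append((f"T{t:g}", np.asarray(vals)))
                if not usable or len(groups) < 2:
                    logger.info(
                        "skipping %s at host=%s salinity=%g: below detection or missing",
                        fa.label,
                        host,
                        sal,
                    )
                    continue
                try:
                    res = auto_anova(GroupedValues(groups, response_name=fa.label), alpha_hetero)
                except ValueError as exc:
                    logger.info("skipping %s at host=%s salinity=%g: %s", fa.label, host, sal, exc)
                    continue
                rows.append(
                    {
                        "fatty_acid": fa.label,
                        "host": host,
                        "salinity_psu": sal,
                        "method": res.method,
                        "F": res.F,
                        "df_num": res.df_num,
                        "df_den": res.df_den,
                        "p": res.p,
                        "stars": res.stars,
                        "bartlett_p": res.bartlett_p,
                        "shapiro_p": res.shapiro_p,
                    }
                )
    return pd.DataFrame(rows)
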