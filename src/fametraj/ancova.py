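"""The C18 unsaturation index and its host × temperature ANCOVA.

The index is the ratio of the two dominant C18 unsaturated fatty acids,

    FAI18-C = [18:2n-6] / [18:1n-9],

computed per sample from relative concentrations; being a ratio, it is
identical on raw μg·g⁻¹ values and on percentages of TFA.  Within each
salinity, the index is regressed on temperature separately for the two
host-algae strains.  An ANCOVA interaction test (host × temperature in the
model ``fai ~ temperature * host``) decides whether the two regression
slopes are homogeneous: if they differ, the angle between the two lines —
the α-value, a measure of how strongly the host shapes thermal acclimation
— is reported; if they are homogeneous, the model is refit without the
interaction and the adjusted temperature and host effects are reported
instead.  A stratified bootstrap quantifies the uncertainty of α and the
trend of α across the salinity gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .fame import BELOW_DL, DlPolicy, FAProfile, ProfileSet, SampleMeta, parse_fa_name

logger = logging.getLogger(__name__)

__all__ = [
    "AncovaDecision",
    "FAIRecord",
    "RegressionLine",
    "UndefinedIndexError",
    "alpha_angle",
    "alpha_from_slopes",
    "alpha_salinity_trend",
    "fai18c",
    "fai_records",
    "fit_host_regressions",
    "slope_homogeneity",
]

FA_18_2N6 = parse_fa_name("18:2n-6")
FA_18_1N9 = parse_fa_name("18:1n-9")


class UndefinedIndexError(ValueError):
    """The index is undefined: a C18 component is below detection or zero."""


@dataclass(frozen=True)
class FAIRecord:
    """Per-sample FAI18-C value with its factorial metadata."""

    meta: SampleMeta
    fai: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fai) and self.fai > 0):
            raise ValueError(f"fai must be finite and positive, got {self.fai}")


def fai18c(profile: FAProfile) -> FAIRecord:
    """FAI18-C = [18:2n-6] / [18:1n-9] for one sample."""
    num = profile.concentrations.get(FA_18_2N6)
    den = profile.concentrations.get(FA_18_1N9)
    for fa, v in ((FA_18_2N6, num), (FA_18_1N9, den)):
        if v is None or v is BELOW_DL or v == 0:
            raise UndefinedIndexError(
                f"{fa.label} below detection or absent in {profile.meta.sample_id}"
            )
    return FAIRecord(meta=profile.meta, fai=float(num) / float(den))


def fai_records(profiles: ProfileSet) -> list[FAIRecord]:
    """Index for every sample where it is defined; undefined samples are logged and skipped."""
    out = []
    for p in profiles:
        try:
            out.append(fai18c(p))
        except UndefinedIndexError as exc:
            logger.info("skipping sample: %s", exc)
    return out


@dataclass
class RegressionLine:
    """OLS fit of the index on temperature for one host at one salinity."""

    host: str
    salinity: float
    slope: float  # index units per °C
    intercept: float
    n: int
    se_slope: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"regression needs n >= 3, got {self.n}")
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("non-finite regression coefficients")


def _records_frame(records: list[FAIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "host": [r.meta.host for r in records],
            "temperature": [r.meta.temperature for r in records],
            "salinity": [r.meta.salinity for r in records],
            "replicate": [r.meta.replicate for r in records],
            "fai": [r.fai for r in records],
        }
    )


def fit_host_regressions(
    records: list[FAIRecord], salinity: float
) -> dict[str, RegressionLine]:
    """Per-host OLS of fai on temperature (raw °C) at one salinity."""
    df = _records_frame(records)
    df = df[df["salinity"] == salinity]
    out: dict[str, RegressionLine] = {}
    for host, sub in df.groupby("host"):
        if len(sub) < 3 or sub["temperature"].nunique() < 2:
            raise ValueError(
                f"host {host} at salinity {salinity}: need >= 3 records over >= 2 temperatures"
            )
        res = scipy.stats.linregress(sub["temperature"], sub["fai"])
        out[str(host)] = RegressionLine(
            host=str(host),
            salinity=salinity,
            slope=float(res.slope),
            intercept=float(res.intercept),
            n=len(sub),
            se_slope=float(res.stderr),
        )
    return out


def alpha_from_slopes(slope_a: float, slope_b: float) -> float:
    """Angle in degrees between two lines of the given slopes, in [0, 180)."""
    ang = abs(math.atan(slope_a) - math.atan(slope_b))
    return math.degrees(ang) % 180.0


def alpha_angle(line_a: RegressionLine, line_b: RegressionLine) -> float:
    """The α-value: angle between two host regression lines (degrees)."""
    return alpha_from_slopes(line_a.slope, line_b.slope)


@dataclass
class AncovaDecision:
    """Outcome of the slope-homogeneity test at one salinity."""

    salinity: float
    interaction_F: float
    interaction_df: tuple[float, float]
    interaction_p: float
    slopes_homogeneous: bool
    lines: dict[str, RegressionLine]
    alpha_deg: float | None = None  # present iff slopes differ
    adjusted_effects: dict[str, tuple[float, float]] | None = None  # term -> (F, p)
    outlier_ids: list[str] = field(default_factory=list)


def slope_homogeneity(
    records: list[FAIRecord],
    salinity: float,
    interaction_alpha: float = 0.05,
) -> AncovaDecision:
    """Test homogeneity of the two host regression slopes at one salinity.

    Fits ``fai ~ temperature * host`` and examines the interaction F.  When
    the interaction is significant the slopes differ and the α angle is
    computed from the separate host fits; otherwise the ANCOVA is adjusted
    by refitting without the interaction, after flagging (report-only)
    observations with standardized residuals beyond ±3.
    """
    df = _records_frame(records)
    df = df[df["salinity"] == salinity]
    if df.empty:
        raise ValueError(f"no records at salinity {salinity}")
    for host, sub in df.groupby("host"):
        if sub["temperature"].nunique() < 2:
            raise ValueError(f"host {host} must span >= 2 temperatures")
    if df["host"].nunique() != 2:
        raise ValueError("need records for both hosts")

    full = smf.ols("fai ~ temperature * C(host)", data=df).fit()
    if not np.all(np.isfinite(full.params)):
        raise ValueError("non-finite ANCOVA fit")
    table = sm.stats.anova_lm(full, typ=2)
    inter = table.loc["temperature:C(host)"]
    F = float(inter["F"])
    p = float(inter["PR(>F)"])
    dfs = (float(inter["df"]), float(table.loc["Residual", "df"]))

    lines = fit_host_regressions(records, salinity)
    homogeneous = p >= interaction_alpha

    alpha_deg = None
    adjusted = None
    outliers: list[str] = []
    if homogeneous:
        reduced = smf.ols("fai ~ temperature + C(host)", data=df).fit()
        infl = reduced.get_influence()
        z = infl.resid_studentized_internal
        ids = (
            SampleMeta(
                host=r.host,
                temperature=r.temperature,
                salinity=r.salinity,
                replicate=int(r.replicate),
            ).sample_id
            for r in df.itertuples()
        )
        outliers = [rid for rid, flag in zip(ids, np.abs(z) > 3) if flag]
        red_table = sm.stats.anova_lm(reduced, typ=2)
        adjusted = {
            "temperature": (
                float(red_table.loc["temperature", "F"]),
                float(red_table.loc["temperature", "PR(>F)"]),
            ),
            "host": (
                float(red_table.loc["C(host)", "F"]),
                float(red_table.loc["C(host)", "PR(>F)"]),
            ),
        }
    else:
        hosts = sorted(lines)
        alpha_deg = alpha_angle(lines[hosts[0]], lines[hosts[1]])

    return AncovaDecision(
        salinity=salinity,
        interaction_F=F,
        interaction_df=dfs,
        interaction_p=p,
        slopes_homogeneous=homogeneous,
        lines=lines,
        alpha_deg=alpha_deg,
        adjusted_effects=adjusted,
        outlier_ids=outliers,
    )


@dataclass
class AlphaTrendResult:
    """Bootstrap summary of the α angle across the salinity gradient."""

    salinities: list[float]
    alpha_point: dict[float, float]  # α from the observed records
    alpha_boot_mean: dict[float, float]
    alpha_boot_sd: dict[float, float]
    alpha_ci: dict[float, tuple[float, float]]  # 2.5–97.5 percentiles
    trend_slope: float  # slope of point-estimate α on salinity
    trend_p: float  # one-sided: fraction of draws with non-negative slope
    n_boot: int


def _alpha_at(df: pd.DataFrame) -> float:
    slopes = {}
    for host, sub in df.groupby("host"):
        x = sub["temperature"].to_numpy(float)
        y = sub["fai"].to_numpy(float)
        xc = x - x.mean()
        slopes[host] = float(xc @ (y - y.mean()) / (xc @ xc))
    a, b = (slopes[h] for h in sorted(slopes))
    return alpha_from_slopes(a, b)


def alpha_salinity_trend(
    records: list[FAIRecord],
    n_boot: int = 1000,
    seed: int | None = None,
) -> AlphaTrendResult:
    """Stratified bootstrap of α per salinity and of its trend with salinity.

    Replicates are resampled with replacement within each
    host × temperature cell of each salinity stratum.  The trend statistic
    is the least-squares slope of α on salinity; its one-sided p is the
    fraction of bootstrap draws whose slope is non-negative (small p →
    α decreases with salinity).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    df = _records_frame(records)
    salinities = sorted(df["salinity"].unique())
    if len(salinities) < 2:
        raise ValueError("need >= 2 salinities for a trend")

    rng = np.random.default_rng(seed)
    point = {s: _alpha_at(df[df["salinity"] == s]) for s in salinities}

    boot = np.empty((n_boot, len(salinities)))
    for b in range(n_boot):
        for j, s in enumerate(salinities):
            sub = df[df["salinity"] == s]
            parts = []
            for _, cell in sub.groupby(["host", "temperature"]):
                idx = rng.integers(0, len(cell), size=len(cell))
                parts.append(cell.iloc[idx])
            boot[b, j] = _alpha_at(pd.concat(parts))

    sal = np.asarray(salinities, float)
    sal_c = sal - sal.mean()
    slopes = (boot - boot.mean(axis=1, keepdims=True)) @ sal_c / (sal_c @ sal_c)
    point_arr = np.array([point[s] for s in salinities])
    trend_slope = float((point_arr - point_arr.mean()) @ sal_c / (sal_c @ sal_c))
    trend_p = float(np.mean(slopes >= 0))

    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return AlphaTrendResult(
        salinities=list(salinities),
        alpha_point=point,
        alpha_boot_mean={s: float(boot[:, j].mean()) for j, s in enumerate(salinities)},
        alpha_boot_sd={s: float(boot[:, j].std(ddof=1)) for j, s in enumerate(salinities)},
        alpha_ci={s: (float(lo[j]), float(hi[j])) for j, s in enumerate(salinities)},
        trend_slope=trend_slope,
        trend_p=trend_p,
        n_boot=n_boot,
    )
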