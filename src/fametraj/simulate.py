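"""Synthetic replicate data with the statistical structure the analysis assumes.

The packaged parameter table carries, for every cell of the balanced
2 hosts × 3 temperatures × 3 salinities design and each of the 22 detected
fatty acids, the published group mean and standard deviation (μg·g⁻¹), or a
flag: ``below_dl`` for cells reported under the detection limit, and
``missing`` for the eight cells of one design row that the published table
does not print.  Replicates are drawn per cell from a normal distribution
truncated at zero (concentrations cannot be negative); a lognormal noise
model is selectable.  Fatty acids are drawn independently — the published
table gives marginal standard deviations only, so between-fatty-acid
covariance cannot be emulated.

A second generator produces index-versus-temperature records from known
per-host slopes, giving a parameter-recovery harness with an analytically
known α angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ancova import FAIRecord, alpha_from_slopes
from .fame import BELOW_DL, FAProfile, ProfileSet, SampleMeta, parse_fa_name

__all__ = [
    "FAIScenario",
    "ParameterTable",
    "load_reference_parameters",
    "mean_profiles",
    "simulate_fai_scenario",
    "simulate_profiles",
]

_PARAM_COLUMNS = [
    "host",
    "temperature_C",
    "salinity_psu",
    "fatty_acid",
    "mean_ug_per_g",
    "sd_ug_per_g",
    "flag",
]


@dataclass
class ParameterTable:
    """Group means/sds per design cell and fatty acid, with dl/missing flags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_PARAM_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"parameter table lacks columns {sorted(missing)}")
        if self.table.empty:
            raise ValueError("empty parameter table")
        bad_flag = set(self.table["flag"]) - {"ok", "below_dl", "missing"}
        if bad_flag:
            raise ValueError(f"unknown flags {sorted(bad_flag)}")
        ok = self.table[self.table["flag"] == "ok"]
        if (ok["mean_ug_per_g"] < 0).any() or (ok["sd_ug_per_g"] < 0).any():
            raise ValueError("means and sds must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "ParameterTable":
        return cls(pd.read_csv(path))

    @property
    def fatty_acids(self) -> list[str]:
        return sorted(
            self.table["fatty_acid"].unique(), key=lambda s: parse_fa_name(s).sort_key()
        )

    def cells(self):
        """Iterate (host, temperature, salinity) design cells with their rows."""
        return self.table.groupby(["host", "temperature_C", "salinity_psu"], sort=True)


def load_reference_parameters() -> ParameterTable:
    """The packaged group-parameter fixture (published means and sds)."""
    ref = resources.files("fametraj.data").joinpath("group_parameters.csv")
    with resources.as_file(ref) as path:
        return ParameterTable.from_csv(path)


def _draw_cell(mean: float, sd: float, n: int, rng: np.random.Generator, noise: str) -> np.ndarray:
    """n replicate draws for one (design cell, fatty acid) parameter pair."""
    if sd == 0:
        return np.full(n, mean)
    if noise == "truncnorm":
        return truncnorm.rvs(-mean / sd, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    if noise == "lognormal":
        # match the arithmetic mean and sd of the target cell
        sigma2 = np.log(1.0 + (sd / mean) ** 2) if mean > 0 else 0.0
        mu = np.log(mean) - sigma2 / 2.0 if mean > 0 else -np.inf
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    raise ValueError(f"unknown noise model {noise!r}")


def simulate_profiles(
    params: ParameterTable,
    n_rep: int = 3,
    seed: int | None = None,
    noise: str = "truncnorm",
) -> ProfileSet:
    """Draw replicate profiles per design cell from the parameter table.

    ``below_dl`` cells are emitted as the BELOW_DL sentinel, ``missing``
    cells are omitted from the profile.  Fully reproducible given ``seed``.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    profiles = []
    for (host, temp, sal), g in params.cells():
        g = g.sort_values("fatty_acid", key=lambda s: s.map(lambda x: parse_fa_name(x).sort_key()))
        draws: dict = {}
        for row in g.itertuples():
            fa = parse_fa_name(row.fatty_acid)
            if row.flag == "missing":
                continue
            if row.flag == "below_dl":
                draws[fa] = BELOW_DL
            else:
                draws[fa] = _draw_cell(
                    float(row.mean_ug_per_g), float(row.sd_ug_per_g), n_rep, rng, noise
                )
        for rep in range(1, n_rep + 1):
            conc = {
                fa: (BELOW_DL if v is BELOW_DL else float(v[rep - 1]))
                for fa, v in draws.items()
            }
            meta = SampleMeta(host=str(host), temperature=float(temp), salinity=float(sal), replicate=rep)
            profiles.append(FAProfile(meta=meta, concentrations=conc))
    return ProfileSet(profiles)


def mean_profiles(params: ParameterTable) -> ProfileSet:
    """One profile per design cell holding the published cell means verbatim.

    Useful for computations the source reports on group means (totals,
    relative contributions, the index at cell level) rather than on
    replicates.
    """
    profiles = []
    for (host, temp, sal), g in params.cells():
        conc = {}
        for row in g.itertuples():
            fa = parse_fa_name(row.fatty_acid)
            if row.flag == "missing":
                continue
            conc[fa] = BELOW_DL if row.flag == "below_dl" else float(row.mean_ug_per_g)
        meta = SampleMeta(host=str(host), temperature=float(temp), salinity=float(sal), replicate=1)
        profiles.append(FAProfile(meta=meta, concentrations=conc))
    return ProfileSet(profiles)


@dataclass
class FAIScenario:
    """Generating model for index-vs-temperature records with known slopes.

    Per salinity, host LD follows ``intercept_ld + m·slope_ld·T`` and host
    SL ``intercept_sl + m·slope_sl·T`` where ``m`` is that salinity's slope
    multiplier; residuals are normal(0, sigma) and records are truncated to
    stay positive.  The analytic α at a salinity is the angle between the
    two generating lines.
    """

    slope_ld: float = 0.02
    slope_sl: float = -0.02
    intercept_ld: float = 1.2
    intercept_sl: float = 1.9
    sigma: float = 0.1
    temperatures: tuple[float, ...] = (10.0, 18.0, 25.0)
    n_rep: int = 3
    salinity_multipliers: Mapping[float, float] = field(
        default_factory=lambda: {23.5: 1.0}
    )

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if len(self.temperatures) < 2:
            raise ValueError("need >= 2 temperatures")

    def analytic_alpha(self, salinity: float) -> float:
        """Angle (degrees) between the generating lines at one salinity."""
        m = self.salinity_multipliers[salinity]
        return alpha_from_slopes(m * self.slope_ld, m * self.slope_sl)


def simulate_fai_scenario(scenario: FAIScenario, seed: int | None = None) -> list[FAIRecord]:
    """Draw FAIRecords from the scenario's generating lines."""
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    records = []
    lines = {"LD": (scenario.intercept_ld, scenario.slope_ld), "SL": (scenario.intercept_sl, scenario.slope_sl)}
    for sal, mult in scenario.salinity_multipliers.items():
        for host, (b0, b1) in lines.items():
            for t in scenario.temperatures:
                mu = b0 + mult * b1 * t
                for rep in range(1, scenario.n_rep + 1):
                    a = (1e-9 - mu) / scenario.sigma
                    fai = float(
                        truncnorm.rvs(a, np.inf, loc=mu, scale=scenario.sigma, random_state=rng)
                    )
                    meta = SampleMeta(host=host, temperature=float(t), salinity=float(sal), replicate=rep)
                    records.append(FAIRecord(meta=meta, fai=fai))
    return records
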