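"""Readers/writers for the canonical CSV formats and pipeline orchestration.

Canonical long CSV: one row per sample × fatty acid with columns
``sample_id, host, temperature_C, salinity_psu, replicate, fatty_acid,
concentration_ug_per_g`` where an empty cell or the token ``dl`` marks a
signal below the detection limit.  The wide dialect has one row per sample
and one column per canonical fatty-acid label.  Peak tables for
internal-standard quantification use the same metadata columns with
``fatty_acid, area`` instead of concentrations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ancova import alpha_salinity_trend, fai_records, slope_homogeneity
from .fame import (
    BELOW_DL,
    DlPolicy,
    FAProfile,
    FattyAcidParseError,
    ProfileSet,
    SampleMeta,
    class_sums,
    parse_fa_name,
    relative_proportions,
    total_fa,
)
from .quantify import PeakTable, apply_detection_limit, quantify_peaks
from .simulate import ParameterTable, load_reference_parameters, simulate_profiles
from .trajectory import pca_profiles, path_length, trajectory_divergence
from .univariate import levene, GroupedValues, three_way_anova, univariate_screen

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_peak_tables",
    "read_profiles",
    "run_pipeline",
    "write_profiles",
]

_META_COLS = ["sample_id", "host", "temperature_C", "salinity_psu", "replicate"]
_FLOAT_FMT = "%.6g"


class ProfileReadError(ValueError):
    """Aggregated row-level validation failures, each with its row number."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid profile table:\n" + "\n".join(problems))


def write_profiles(pset: ProfileSet, path, dialect: str = "long") -> None:
    """Write a ProfileSet as canonical long or wide CSV."""
    path = Path(path)
    if dialect == "long":
        rows = []
        for p in pset:
            for fa in sorted(p.concentrations, key=lambda f: f.sort_key()):
                c = p.concentrations[fa]
                rows.append(
                    {
                        "sample_id": p.meta.sample_id,
                        "host": p.meta.host,
                        "temperature_C": p.meta.temperature,
                        "salinity_psu": p.meta.salinity,
                        "replicate": p.meta.replicate,
                        "fatty_acid": fa.label,
                        "concentration_ug_per_g": "dl" if c is BELOW_DL else c,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif dialect == "wide":
        wide = pset.to_wide()
        # wide cannot distinguish below-dl from absent; below-dl becomes "dl"
        for p in pset:
            for fa, c in p.concentrations.items():
                if c is BELOW_DL:
                    wide.loc[p.meta.sample_id, fa.label] = "dl"
        out = pset.meta_frame().join(wide)
        out.to_csv(path, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _meta_from_row(row, rowno: int, problems: list[str]) -> SampleMeta | None:
    try:
        return SampleMeta(
            host=str(row["host"]),
            temperature=float(row["temperature_C"]),
            salinity=float(row["salinity_psu"]),
            replicate=int(row["replicate"]),
        )
    except (ValueError, KeyError) as exc:
        problems.append(f"row {rowno}: bad sample metadata ({exc})")
        return None


def read_profiles(path, dialect: str = "long") -> ProfileSet:
    """Read the canonical CSV into a validated ProfileSet.

    Malformed rows are aggregated and reported together with their row
    numbers in a single :class:`ProfileReadError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"concentration_ug_per_g": str} if dialect == "long" else None)
    problems: list[str] = []
    samples: dict[SampleMeta, dict] = {}

    if dialect == "long":
        for i, row in df.iterrows():
            rowno = i + 2  # header is line 1
            meta = _meta_from_row(row, rowno, problems)
            if meta is None:
                continue
            try:
                fa = parse_fa_name(str(row["fatty_acid"]))
            except FattyAcidParseError as exc:
                problems.append(f"row {rowno}: {exc}")
                continue
            raw = row["concentration_ug_per_g"]
            if pd.isna(raw) or str(raw).strip() in ("", "dl", "<dl"):
                conc = BELOW_DL
            else:
                try:
                    conc = float(raw)
                except ValueError:
                    problems.append(f"row {rowno}: unparseable concentration {raw!r}")
                    continue
                if conc < 0:
                    problems.append(f"row {rowno}: negative concentration {conc}")
                    continue
            cell = samples.setdefault(meta, {})
            if fa in cell:
                problems.append(f"row {rowno}: duplicate fatty acid {fa.label} for {meta.sample_id}")
                continue
            cell[fa] = conc
    elif dialect == "wide":
        fa_cols = [c for c in df.columns if c not in _META_COLS]
        for i, row in df.iterrows():
            rowno = i + 2
            meta = _meta_from_row(row, rowno, problems)
            if meta is None:
                continue
            cell = {}
            for c in fa_cols:
                raw = row[c]
                if pd.isna(raw):
                    continue
                try:
                    fa = parse_fa_name(c)
                except FattyAcidParseError as exc:
                    problems.append(f"column {c!r}: {exc}")
                    break
                if str(raw).strip() in ("dl", "<dl"):
                    cell[fa] = BELOW_DL
                    continue
                try:
                    v = float(raw)
                except ValueError:
                    problems.append(f"row {rowno}: unparseable concentration {raw!r} in {c}")
                    continue
                if v < 0:
                    problems.append(f"row {rowno}: negative concentration {v} in {c}")
                    continue
                cell[fa] = v
            if meta in samples:
                problems.append(f"row {rowno}: duplicate sample {meta.sample_id}")
                continue
            samples[meta] = cell
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if problems:
        raise ProfileReadError(problems)

    profiles = []
    for meta, conc in samples.items():
        try:
            profiles.append(FAProfile(meta=meta, concentrations=conc))
        except ValueError as exc:
            problems.append(str(exc))
    if problems:
        raise ProfileReadError(problems)
    return ProfileSet(profiles)


def read_peak_tables(
    path, is_mass_mg: float, sample_mass_g: float, is_label: str = "23:0", dl: float = 0.0
) -> ProfileSet:
    """Read a long peak CSV (metadata + fatty_acid + area) and quantify it."""
    df = pd.read_csv(path)
    profiles = []
    for key, g in df.groupby(["host", "temperature_C", "salinity_psu", "replicate"]):
        meta = SampleMeta(
            host=str(key[0]), temperature=float(key[1]), salinity=float(key[2]), replicate=int(key[3])
        )
        table = PeakTable(
            peaks=list(zip(g["fatty_acid"].astype(str), g["area"].astype(float))),
            is_mass_mg=is_mass_mg,
            sample_mass_g=sample_mass_g,
            is_label=is_label,
        )
        prof = quantify_peaks(table, meta)
        if dl > 0:
            prof = apply_detection_limit(prof, dl)
        profiles.append(prof)
    return ProfileSet(profiles)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable, CLI-overridable)."""

    input_path: str | None = None
    input_kind: str = "long"  # long | wide | peaks | simulate
    out_dir: str = "results"
    dl_policy: str = "zero"
    dl: float = 0.0
    is_label: str = "23:0"
    is_mass_mg: float | None = None
    sample_mass_g: float | None = None
    interaction_alpha: float = 0.05
    pca_scaling: str = "correlation"
    n_boot: int = 0
    n_rep: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.input_kind not in ("long", "wide", "peaks", "simulate"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.input_kind != "simulate" and self.input_path is None:
            raise ValueError("input_path required unless input_kind='simulate'")
        if self.input_kind == "peaks" and (self.is_mass_mg is None or self.sample_mass_g is None):
            raise ValueError("peak quantification requires is_mass_mg and sample_mass_g")
        if not 0 < self.interaction_alpha < 1:
            raise ValueError("interaction_alpha must be in (0, 1)")
        if self.n_boot > 0 and self.seed is None:
            raise ValueError("a seed is required when n_boot > 0")
        if self.input_kind == "simulate" and self.seed is None:
            raise ValueError("a seed is required to simulate")
        DlPolicy(self.dl_policy, self.dl)  # validate

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def policy(self) -> DlPolicy:
        return DlPolicy(self.dl_policy, self.dl)


_ALL_STAGES = ("compose", "univar", "fai", "trajectory")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = _ALL_STAGES) -> dict:
    """Execute the pipeline stages and write result CSVs plus a run manifest.

    Stages: ``compose`` (TFA, proportions, class sums), ``univar``
    (per-fatty-acid screen), ``fai`` (index, three-way ANOVA + Levene,
    per-salinity ANCOVA, optional bootstrap α trend), ``trajectory``
    (per-salinity PCA and divergence).  Returns the in-memory bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    policy = config.policy()
    bundle: dict = {}

    def _stage(name):
        logger.info("stage %s", name)

    try:
        if config.input_kind == "simulate":
            pset = simulate_profiles(load_reference_parameters(), n_rep=config.n_rep, seed=config.seed)
        elif config.input_kind == "peaks":
            pset = read_peak_tables(
                config.input_path, config.is_mass_mg, config.sample_mass_g, config.is_label, config.dl
            )
        else:
            pset = read_profiles(config.input_path, dialect=config.input_kind)
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc
    bundle["profiles"] = pset
    write_profiles(pset, out_dir / "profiles_long.csv")

    if "compose" in stages:
        _stage("compose")
        try:
            rows = []
            for p in pset:
                props = relative_proportions(p, policy)
                cls = class_sums(p, policy)
                base = {
                    "sample_id": p.meta.sample_id,
                    "host": p.meta.host,
                    "temperature_C": p.meta.temperature,
                    "salinity_psu": p.meta.salinity,
                    "replicate": p.meta.replicate,
                    "tfa_ug_per_g": total_fa(p, policy),
                    **{f"pct_{k.value}": v for k, v in cls.items()},
                }
                for fa, pct in props.items():
                    rows.append({**base, "fatty_acid": fa.label, "pct_of_tfa": pct})
            comp = pd.DataFrame(rows)
            comp.to_csv(out_dir / "composition.csv", index=False, float_format=_FLOAT_FMT)
            bundle["composition"] = comp
        except Exception as exc:
            raise RuntimeError(f"[compose] {exc}") from exc

    if "univar" in stages:
        _stage("univar")
        try:
            screen = univariate_screen(pset, policy)
            screen.to_csv(out_dir / "univariate_screen.csv", index=False, float_format=_FLOAT_FMT)
            bundle["univariate_screen"] = screen
        except Exception as exc:
            raise RuntimeError(f"[univar] {exc}") from exc

    if "fai" in stages:
        _stage("fai")
        try:
            records = fai_records(pset)
            fai_df = pd.DataFrame(
                {
                    "sample_id": [r.meta.sample_id for r in records],
                    "host": [r.meta.host for r in records],
                    "temperature": [r.meta.temperature for r in records],
                    "salinity": [r.meta.salinity for r in records],
                    "replicate": [r.meta.replicate for r in records],
                    "fai": [r.fai for r in records],
                }
            )
            fai_df.to_csv(out_dir / "fai_records.csv", index=False, float_format=_FLOAT_FMT)
            bundle["fai_records"] = records

            counts = fai_df.groupby(["host", "temperature", "salinity"]).size()
            if counts.nunique() == 1 and len(counts) == fai_df["host"].nunique() * fai_df[
                "temperature"
            ].nunique() * fai_df["salinity"].nunique():
                anova = three_way_anova(fai_df.rename(columns={"fai": "value"}), response="value")
                anova.to_csv(out_dir / "fai_three_way_anova.csv", float_format=_FLOAT_FMT)
                groups = GroupedValues(
                    [
                        (f"{h}_T{t:g}_S{s:g}", g["fai"].to_numpy())
                        for (h, t, s), g in fai_df.groupby(["host", "temperature", "salinity"])
                    ],
                    response_name="fai",
                )
                df1, df2, stat, p = levene(groups)
                pd.DataFrame(
                    [{"df1": df1, "df2": df2, "statistic": stat, "p": p}]
                ).to_csv(out_dir / "fai_levene.csv", index=False, float_format=_FLOAT_FMT)
                bundle["fai_anova"] = anova
            else:
                logger.warning("index design unbalanced after skips; three-way ANOVA not run")

            decisions = []
            for sal in sorted(fai_df["salinity"].unique()):
                dec = slope_homogeneity(records, sal, config.interaction_alpha)
                decisions.append(dec)
            bundle["ancova"] = decisions
            rows = []
            for dec in decisions:
                row = {
                    "salinity_psu": dec.salinity,
                    "interaction_F": dec.interaction_F,
                    "interaction_p": dec.interaction_p,
                    "slopes_homogeneous": dec.slopes_homogeneous,
                    "alpha_deg": dec.alpha_deg,
                }
                for host, line in dec.lines.items():
                    row[f"slope_{host}"] = line.slope
                    row[f"intercept_{host}"] = line.intercept
                    row[f"se_slope_{host}"] = line.se_slope
                if dec.adjusted_effects:
                    row["adj_temperature_F"], row["adj_temperature_p"] = dec.adjusted_effects["temperature"]
                    row["adj_host_F"], row["adj_host_p"] = dec.adjusted_effects["host"]
                rows.append(row)
            pd.DataFrame(rows).to_csv(out_dir / "ancova_per_salinity.csv", index=False, float_format=_FLOAT_FMT)

            if config.n_boot > 0 and fai_df["salinity"].nunique() >= 2:
                trend = alpha_salinity_trend(records, n_boot=config.n_boot, seed=config.seed)
                pd.DataFrame(
                    {
                        "salinity_psu": trend.salinities,
                        "alpha_deg": [trend.alpha_point[s] for s in trend.salinities],
                        "alpha_boot_mean": [trend.alpha_boot_mean[s] for s in trend.salinities],
                        "alpha_boot_sd": [trend.alpha_boot_sd[s] for s in trend.salinities],
                        "alpha_ci_lo": [trend.alpha_ci[s][0] for s in trend.salinities],
                        "alpha_ci_hi": [trend.alpha_ci[s][1] for s in trend.salinities],
                        "trend_slope": trend.trend_slope,
                        "trend_p": trend.trend_p,
                    }
                ).to_csv(out_dir / "alpha_trend.csv", index=False, float_format=_FLOAT_FMT)
                bundle["alpha_trend"] = trend
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"[fai] {exc}") from exc

    if "trajectory" in stages:
        _stage("trajectory")
        try:
            summary = []
            bundle["trajectories"] = {}
            for sal in sorted({p.meta.salinity for p in pset}):
                res = pca_profiles(pset, sal, scaling=config.pca_scaling, policy=policy)
                bundle["trajectories"][sal] = res
                tag = f"S{sal:g}"
                res.scores.to_csv(out_dir / f"pca_scores_{tag}.csv", float_format=_FLOAT_FMT)
                res.loadings.to_csv(out_dir / f"pca_loadings_{tag}.csv", float_format=_FLOAT_FMT)
                pd.DataFrame(
                    {"axis": [f"PC{i+1}" for i in range(len(res.inertia_pct))], "inertia_pct": res.inertia_pct}
                ).to_csv(out_dir / f"pca_inertia_{tag}.csv", index=False, float_format=_FLOAT_FMT)
                hosts = sorted(res.paths)
                if len(hosts) == 2:
                    angle, label = trajectory_divergence(res.paths[hosts[0]], res.paths[hosts[1]])
                    for host in hosts:
                        pts = res.paths[host]
                        net = (
                            pts[["PC1", "PC2"]].iloc[-1] - pts[["PC1", "PC2"]].iloc[0]
                        )
                        summary.append(
                            {
                                "salinity_psu": sal,
                                "host": host,
                                "net_pc1": net["PC1"],
                                "net_pc2": net["PC2"],
                                "path_length": path_length(pts),
                                "angle_deg": angle,
                                "classification": label,
                            }
                        )
            pd.DataFrame(summary).to_csv(out_dir / "trajectory_summary.csv", index=False, float_format=_FLOAT_FMT)
        except Exception as exc:
            raise RuntimeError(f"[trajectory] {exc}") from exc

    manifest = {
        "package": "fametraj",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": list(stages),
        "n_samples": len(pset),
        "fa_inventory": [fa.label for fa in pset.fa_inventory],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
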