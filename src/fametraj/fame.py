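"""Core data model for fatty-acid profiles.

Fatty acids are named with the shorthand ``X:Yn-Z`` used in lipidology:
``X`` carbons in the chain, ``Y`` double bonds, and ``Z`` the position of
the ultimate double bond counted from the terminal methyl (omega) end.
Saturated acids (``Y = 0``) omit the ``n-Z`` part.  A sample is a vector of
concentrations (μg per g of biomass) over a fatty-acid inventory, keyed by
the factorial metadata of the growth experiment (algal host, temperature,
salinity, replicate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "BELOW_DL",
    "DlPolicy",
    "FAProfile",
    "FattyAcid",
    "ProfileSet",
    "SampleMeta",
    "SaturationClass",
    "class_sums",
    "classify_saturation",
    "parse_fa_name",
    "relative_proportions",
    "total_fa",
]

HOSTS = ("LD", "SL")
TEMPERATURES_C = (10.0, 18.0, 25.0)
SALINITIES_PSU = (23.5, 50.0, 70.0)


class FattyAcidParseError(ValueError):
    """Raised when a fatty-acid label cannot be parsed."""


class _BelowDL:
    """Sentinel for a signal below the detection limit."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "BELOW_DL"


BELOW_DL = _BelowDL()

Concentration = Union[float, _BelowDL]


class SaturationClass(str, Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"


@dataclass(frozen=True)
class FattyAcid:
    """Structured identity of one fatty acid.

    Parameters
    ----------
    carbons
        Chain length (number of carbon atoms), at least 2.
    double_bonds
        Number of double bonds, non-negative.
    omega
        Position of the ultimate double bond from the terminal methyl;
        required when ``double_bonds >= 1`` and forbidden otherwise.
    """

    carbons: int
    double_bonds: int
    omega: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"carbons must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double_bonds must be >= 0, got {self.double_bonds}")
        if self.double_bonds == 0 and self.omega is not None:
            raise ValueError(f"saturated fatty acid cannot carry an omega position: {self!r}")
        if self.double_bonds >= 1 and self.omega is None:
            raise ValueError(f"unsaturated fatty acid requires an omega position: {self!r}")
        if self.omega is not None and self.omega < 1:
            raise ValueError(f"omega must be >= 1, got {self.omega}")

    @property
    def label(self) -> str:
        """Canonical ``X:Y`` / ``X:Yn-Z`` label (ASCII hyphen)."""
        if self.double_bonds == 0:
            return f"{self.carbons}:0"
        return f"{self.carbons}:{self.double_bonds}n-{self.omega}"

    def __str__(self) -> str:
        return self.label

    def sort_key(self) -> tuple[int, int, int]:
        return (self.carbons, self.double_bonds, self.omega or 0)


# "18 : 2 n - 6" with any of ASCII hyphen, minus sign, en dash
_FA_RE = re.compile(r"^\s*(\d+)\s*:\s*(\d+)\s*(?:n\s*[-−–]\s*(\d+)\s*)?$")


def parse_fa_name(name: str) -> FattyAcid:
    """Parse an ``X:Y`` or ``X:Yn-Z`` label into a :class:`FattyAcid`.

    Both the ASCII hyphen and the typographic minus/en-dash are accepted in
    the ``n-Z`` part; the canonical label always uses the ASCII hyphen.

    >>> parse_fa_name("18:2n−6").label
    '18:2n-6'
    """
    if not isinstance(name, str):
        raise FattyAcidParseError(f"expected a string label, got {type(name).__name__}")
    m = _FA_RE.match(name)
    if m is None:
        raise FattyAcidParseError(f"cannot parse fatty-acid label {name!r}")
    carbons, double_bonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) is not None else None
    if double_bonds == 0 and omega is not None:
        raise FattyAcidParseError(f"saturated label {name!r} must not carry an omega position")
    if double_bonds >= 1 and omega is None:
        raise FattyAcidParseError(f"unsaturated label {name!r} is missing its 'n-Z' omega part")
    try:
        return FattyAcid(carbons, double_bonds, omega)
    except ValueError as exc:
        raise FattyAcidParseError(str(exc)) from exc


def classify_saturation(fa: FattyAcid) -> SaturationClass:
    """SFA for 0 double bonds, MUFA for 1, PUFA for 2 or more."""
    if fa.double_bonds == 0:
        return SaturationClass.SFA
    if fa.double_bonds == 1:
        return SaturationClass.MUFA
    return SaturationClass.PUFA


@dataclass(frozen=True)
class DlPolicy:
    """How below-detection-limit cells enter sums and proportions.

    ``kind``: ``"zero"`` counts them as 0, ``"half"`` as ``dl / 2``
    (requires a positive detection limit), ``"exclude"`` drops them.
    """

    kind: str = "zero"
    dl: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "half", "exclude"):
            raise ValueError(f"unknown dl policy {self.kind!r}")
        if self.dl < 0:
            raise ValueError("detection limit must be >= 0")
        if self.kind == "half" and self.dl <= 0:
            raise ValueError("dl policy 'half' requires a positive detection limit")

    def value(self) -> float | None:
        """Numeric stand-in for a below-dl cell, or None to exclude it."""
        if self.kind == "zero":
            return 0.0
        if self.kind == "half":
            return self.dl / 2.0
        return None


@dataclass(frozen=True)
class SampleMeta:
    """Factorial metadata of one biological replicate."""

    host: str
    temperature: float
    salinity: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.host not in HOSTS:
            raise ValueError(f"host must be one of {HOSTS}, got {self.host!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def sample_id(self) -> str:
        t = int(self.temperature) if float(self.temperature).is_integer() else self.temperature
        s = int(self.salinity) if float(self.salinity).is_integer() else self.salinity
        return f"{self.host}_T{t}_S{s}_r{self.replicate}"


@dataclass
class FAProfile:
    """One sample's fatty-acid concentration vector (μg·g⁻¹)."""

    meta: SampleMeta
    concentrations: dict[FattyAcid, Concentration]

    def __post_init__(self) -> None:
        n_quantified = 0
        for fa, c in self.concentrations.items():
            if c is BELOW_DL:
                continue
            if c < 0:
                raise ValueError(f"negative concentration for {fa} in {self.meta.sample_id}")
            n_quantified += 1
        if n_quantified == 0:
            raise ValueError(f"profile {self.meta.sample_id} has no fatty acid above the detection limit")

    def value(self, fa: FattyAcid, policy: DlPolicy | None = None) -> float | None:
        """Concentration of one fatty acid under the dl policy (None = absent/excluded)."""
        policy = policy or DlPolicy()
        c = self.concentrations.get(fa)
        if c is None:
            return None
        if c is BELOW_DL:
            return policy.value()
        return float(c)


def total_fa(profile: FAProfile, policy: DlPolicy | None = None) -> float:
    """Total fatty acids (TFA): sum of all concentrations in μg·g⁻¹."""
    policy = policy or DlPolicy()
    total = 0.0
    for fa in profile.concentrations:
        v = profile.value(fa, policy)
        if v is not None:
            total += v
    return total


def relative_proportions(profile: FAProfile, policy: DlPolicy | None = None) -> dict[FattyAcid, float]:
    """Per-fatty-acid percentage of TFA; values sum to 100."""
    policy = policy or DlPolicy()
    tfa = total_fa(profile, policy)
    if tfa <= 0:
        raise ValueError(f"profile {profile.meta.sample_id} has zero total fatty acids")
    out: dict[FattyAcid, float] = {}
    for fa in sorted(profile.concentrations, key=FattyAcid.sort_key):
        v = profile.value(fa, policy)
        if v is not None:
            out[fa] = 100.0 * (v / tfa)  # ratio first: keeps values within [0, 100]
    return out


def class_sums(profile: FAProfile, policy: DlPolicy | None = None) -> dict[SaturationClass, float]:
    """Percentage of TFA in each saturation class; partitions 100%."""
    props = relative_proportions(profile, policy)
    out = {cls: 0.0 for cls in SaturationClass}
    for fa, pct in props.items():
        out[classify_saturation(fa)] += pct
    return out


@dataclass
class ProfileSet:
    """The pipeline's central table: profiles over the factorial design."""

    profiles: list[FAProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[SampleMeta] = set()
        for p in self.profiles:
            if p.meta in seen:
                raise ValueError(f"duplicate sample {p.meta.sample_id}")
            seen.add(p.meta)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @property
    def fa_inventory(self) -> list[FattyAcid]:
        """Distinct fatty acids across all profiles, in canonical order."""
        fas: set[FattyAcid] = set()
        for p in self.profiles:
            fas.update(p.concentrations)
        return sorted(fas, key=FattyAcid.sort_key)

    def subset(self, **criteria: object) -> "ProfileSet":
        """Profiles whose metadata match every keyword (host=, salinity=, ...)."""
        kept = [
            p
            for p in self.profiles
            if all(getattr(p.meta, k) == v for k, v in criteria.items())
        ]
        return ProfileSet(kept)

    def to_wide(self, policy: DlPolicy | None = None, proportions: bool = False) -> pd.DataFrame:
        """Samples × fatty-acids matrix (NaN where a fatty acid is absent or excluded).

        With ``proportions=True`` rows are % of TFA instead of μg·g⁻¹.
        """
        policy = policy or DlPolicy()
        inventory = self.fa_inventory
        rows = []
        for p in self.profiles:
            if proportions:
                vals = {fa.label: v for fa, v in relative_proportions(p, policy).items()}
            else:
                vals = {
                    fa.label: v
                    for fa in p.concentrations
                    if (v := p.value(fa, policy)) is not None
                }
            rows.append(vals)
        df = pd.DataFrame(rows, index=[p.meta.sample_id for p in self.profiles])
        return df.reindex(columns=[fa.label for fa in inventory])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [p.meta.sample_id for p in self.profiles],
                "host": [p.meta.host for p in self.profiles],
                "temperature_C": [p.meta.temperature for p in self.profiles],
                "salinity_psu": [p.meta.salinity for p in self.profiles],
                "replicate": [p.meta.replicate for p in self.profiles],
            }
        ).set_index("sample_id")


def canonical_order(fas: Iterable[FattyAcid]) -> list[FattyAcid]:
    """Deterministic ordering: by chain length, then double bonds, then omega."""
    return sorted(fas, key=FattyAcid.sort_key)
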