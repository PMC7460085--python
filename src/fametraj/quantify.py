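"""Internal-standard quantification of GC-FID peak tables.

Peak areas from a flame-ionization detector are proportional to analyte
mass, so each fatty acid's concentration follows from its area relative to
the co-injected internal standard (tricosanoic acid, 23:0, absent from the
biological samples) of known mass:

    conc_i [μg·g⁻¹] = (area_i / area_IS) × is_mass [mg] × 1000 / sample_mass [g]

FID response factors are taken as 1.0 for all FAMEs; a per-compound table
can be supplied where calibration data exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fame import BELOW_DL, FAProfile, FattyAcid, SampleMeta, parse_fa_name

__all__ = ["PeakTable", "apply_detection_limit", "quantify_peaks"]


@dataclass
class PeakTable:
    """Integrated GC-FID peaks for one sample.

    ``is_mass_mg`` is the mass of internal standard spiked into the sample
    and ``sample_mass_g`` the extracted biomass; both must come from the
    run's records — there are no silent defaults.
    """

    peaks: list[tuple[str, float]]
    is_mass_mg: float
    sample_mass_g: float
    is_label: str = "23:0"

    def __post_init__(self) -> None:
        if self.is_mass_mg <= 0:
            raise ValueError("internal-standard mass must be > 0")
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be > 0")
        for label, area in self.peaks:
            if area < 0:
                raise ValueError(f"negative peak area for {label!r}")
        n_is = sum(1 for label, _ in self.peaks if label == self.is_label)
        if n_is == 0:
            raise ValueError(f"internal-standard peak {self.is_label!r} not found")
        if n_is > 1:
            raise ValueError(f"internal-standard peak {self.is_label!r} appears {n_is} times")

    @property
    def is_area(self) -> float:
        return next(area for label, area in self.peaks if label == self.is_label)


def quantify_peaks(
    table: PeakTable,
    meta: SampleMeta,
    response_factors: dict[str, float] | None = None,
) -> FAProfile:
    """Convert a peak table to a concentration profile via the internal standard.

    The internal-standard peak itself is excluded from the output.  Zero
    areas yield zero concentrations (flag them with
    :func:`apply_detection_limit` if a detection limit is configured).
    """
    if table.is_area <= 0:
        raise ValueError("internal-standard peak area must be > 0")
    scale = table.is_mass_mg * 1000.0 / table.sample_mass_g  # μg IS per g biomass
    response_factors = response_factors or {}
    concentrations: dict[FattyAcid, float] = {}
    for label, area in table.peaks:
        if label == table.is_label:
            continue
        fa = parse_fa_name(label)
        rf = response_factors.get(label, 1.0)
        concentrations[fa] = rf * area / table.is_area * scale
    return FAProfile(meta=meta, concentrations=concentrations)


def apply_detection_limit(profile: FAProfile, dl: float) -> FAProfile:
    """Replace concentrations below ``dl`` with the BELOW_DL sentinel."""
    if dl < 0:
        raise ValueError("detection limit must be >= 0")
    out = {}
    for fa, c in profile.concentrations.items():
        if c is not BELOW_DL and c < dl:
            out[fa] = BELOW_DL
        else:
            out[fa] = c
    return FAProfile(meta=profile.meta, concentrations=out)
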