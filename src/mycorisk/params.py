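"""Exposure-assessment parameters.

All constants entering the risk indices live in one dataclass so that a single
declarative config file can override any of them.  Defaults describe the adult
Slovak consumer scenario used throughout the package: tolerable weekly mercury
intake of 0.28 mg per 70 kg person, average mushroom consumption of 0.18 kg
fresh weight per week (25.7 g/day), an oral reference dose of
0.0003 mg kg⁻¹ day⁻¹, lifetime exposure (365 days/year over 70 years), a
mushroom dry-matter fraction of 10 %, a geochemical mercury background of
0.06 mg kg⁻¹ DW and the Slovak soil limit of 0.50 mg kg⁻¹ DW.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import DomainError

__all__ = ["ExposureParameters", "load_parameters"]


@dataclass(frozen=True)
class ExposureParameters:
    """Constants of the mercury exposure model.

    Units are stated per field; all values must be strictly positive.
    ``averaging_time`` is expected to equal ``exposure_freq × exposure_duration``
    (the chronic non-carcinogenic convention); a mismatch only warns, because
    some assessments deliberately average over a different horizon.
    """

    background_hg: float = 0.06  # mg kg-1 DW, geochemical background
    soil_limit: float = 0.50  # mg kg-1 DW, regulatory soil limit
    ptwi_per_person: float = 0.28  # mg person-1 week-1
    weekly_consumption_fw: float = 0.18  # kg FW person-1 week-1
    adc: float = 25.7  # g day-1, average daily consumption
    rfdo: float = 0.0003  # mg kg-1 day-1, oral reference dose
    body_weight: float = 70.0  # kg
    exposure_freq: float = 365.0  # days year-1
    exposure_duration: float = 70.0  # years
    averaging_time: float = 25550.0  # days
    dry_matter_fraction: float = 0.10  # dimensionless, in (0, 1]

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not (value > 0):
                raise DomainError(
                    f"{field.name} must be strictly positive, got {value!r}"
                )
        if not self.dry_matter_fraction <= 1.0:
            raise DomainError(
                f"dry_matter_fraction must be in (0, 1], got {self.dry_matter_fraction}"
            )
        expected_at = self.exposure_freq * self.exposure_duration
        if abs(self.averaging_time - expected_at) > 1e-9 * max(1.0, expected_at):
            warnings.warn(
                "averaging_time differs from exposure_freq × exposure_duration "
                f"({self.averaging_time} vs {expected_at}); the target hazard "
                "quotient no longer simplifies to ADC·CE/(RfDo·BW)",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "ExposureParameters":
        return dataclasses.replace(self, **kwargs)


def load_parameters(path: str | Path) -> ExposureParameters:
    """Read exposure parameters from a YAML mapping.

    Keys absent from the file keep their defaults; unknown keys raise, so a
    typo cannot silently leave a default in force.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise DomainError(f"parameter file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ExposureParameters)}
    unknown = set(raw) - known
    if unknown:
        raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
    return ExposureParameters(**{k: float(v) for k, v in raw.items()})
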