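"""Contamination, bioaccumulation, translocation and dietary risk indices.

Every index is a simple ratio of a measured mercury concentration to a
reference quantity, so each function is linear in its concentration argument.
Classification schemes:

* contamination factor ``Cfi = C_soil / C_background`` with Hakanson's four
  half-open classes: low ``[0, 1)``, moderate ``[1, 3)``, considerable
  ``[3, 6)``, very high ``[6, ∞)``;
* bioaccumulation factor ``BCF = C_tissue / C_soil`` — values above 1 mark an
  accumulator, at or below 1 an excluder (the conventional statement leaves
  BCF = 1 unassigned; it is classed as excluder here, the conservative side);
* translocation quotient ``Q_c/s = C_cap / C_stem`` (no classes; > 1 means
  mercury concentrates in the cap);
* %PTWI — a weekly consumption scenario expressed as a percentage of the
  provisional tolerable weekly intake, ``C_FW × W_week / PTWI × 100``; above
  100 % is hazardous;
* THQ — chronic daily oral exposure over the oral reference dose,
  ``(Efr × ED × ADC × CE) / (RfDo × BW × ATn) × 10⁻³`` with ADC in g/day and
  the 10⁻³ factor converting grams to kilograms; above 1 signals potential
  non-carcinogenic risk.

The dietary indices are defined on a fresh-weight (FW) concentration, yet
published per-locality THQ tables for this system are reproduced only when
the concentration is entered on the dry-weight (DW) basis; both bases are
therefore supported and recorded in every result (see docs/methods.md).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .params import ExposureParameters
from .samples import SampleRecord

__all__ = [
    "IndexResult",
    "CFI_CLASSES",
    "contamination_factor",
    "classify_contamination",
    "classify_cfi_set",
    "bioaccumulation_factor",
    "translocation_quotient",
    "dw_to_fw",
    "ptwi_percent",
    "target_hazard_quotient",
    "aggregate_ratios",
]

#: Hakanson contamination classes as (lower, upper, label); bins are
#: half-open [lower, upper) so a boundary value falls in the upper class.
CFI_CLASSES: tuple[tuple[float, float, str], ...] = (
    (0.0, 1.0, "low"),
    (1.0, 3.0, "moderate"),
    (3.0, 6.0, "considerable"),
    (6.0, float("inf"), "very_high"),
)


@dataclass(frozen=True)
class IndexResult:
    """A computed index value with its class label and concentration basis."""

    index_name: str  # Cfi | BCF_cap | BCF_stem | Qcs | PTWI_pct | THQ
    value: float
    class_label: str | None = None
    basis: str = "n/a"  # DW | FW | n/a
    grouping: str | None = None  # locality or species label
    part: str | None = None  # cap | stem

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DomainError(f"{self.index_name} value must be >= 0")


def classify_contamination(cfi: float) -> str:
    if cfi < 0:
        raise DomainError("contamination factor must be >= 0")
    for lower, upper, label in CFI_CLASSES:
        if lower <= cfi < upper:
            return label
    raise DomainError(f"unclassifiable contamination factor {cfi!r}")  # pragma: no cover


def contamination_factor(
    soil_hg: float, params: ExposureParameters | None = None, grouping: str | None = None
) -> IndexResult:
    """Hakanson contamination factor of a soil mercury concentration (DW)."""
    params = params or ExposureParameters()
    if not soil_hg > 0:
        raise DomainError(f"soil_hg must be > 0, got {soil_hg!r}")
    value = soil_hg / params.background_hg
    return IndexResult("Cfi", value, classify_contamination(value), "DW", grouping)


def classify_cfi_set(cfi_values: Iterable[IndexResult]) -> dict[str, int]:
    """Count contamination-factor results per Hakanson class.

    Counts always sum to the number of inputs; a non-Cfi result raises.
    """
    counts = Counter({label: 0 for *_, label in CFI_CLASSES})
    for result in cfi_values:
        if result.index_name != "Cfi":
            raise DomainError(
                f"classify_cfi_set expects Cfi results, got {result.index_name!r}"
            )
        counts[classify_contamination(result.value)] += 1
    return dict(counts)


def bioaccumulation_factor(
    tissue_hg: float,
    soil_hg: float,
    part: str = "cap",
    grouping: str | None = None,
) -> IndexResult:
    """Tissue-to-soil concentration ratio; > 1 marks an accumulator."""
    if part not in ("cap", "stem"):
        raise DomainError(f"part must be 'cap' or 'stem', got {part!r}")
    if not soil_hg > 0:
        raise DomainError(f"soil_hg must be > 0, got {soil_hg!r}")
    if not tissue_hg > 0:
        raise DomainError(f"tissue_hg must be > 0, got {tissue_hg!r}")
    value = tissue_hg / soil_hg
    label = "accumulator" if value > 1 else "excluder"
    return IndexResult(f"BCF_{part}", value, label, "DW", grouping, part)


def translocation_quotient(
    cap_hg: float, stem_hg: float, grouping: str | None = None
) -> IndexResult:
    """Cap-to-stem concentration ratio (mercury mobility within the body)."""
    if not stem_hg > 0:
        raise DomainError(f"stem_hg must be > 0, got {stem_hg!r}")
    if not cap_hg > 0:
        raise DomainError(f"cap_hg must be > 0, got {cap_hg!r}")
    return IndexResult("Qcs", cap_hg / stem_hg, None, "DW", grouping)


def dw_to_fw(conc_dw: float, params: ExposureParameters | None = None) -> float:
    """Convert a dry-weight concentration to fresh weight via the dry-matter fraction."""
    params = params or ExposureParameters()
    if conc_dw < 0:
        raise DomainError(f"conc_dw must be >= 0, got {conc_dw!r}")
    return conc_dw * params.dry_matter_fraction


def ptwi_percent(
    conc_dw: float,
    params: ExposureParameters | None = None,
    grouping: str | None = None,
    part: str | None = None,
) -> IndexResult:
    """Weekly intake from the consumption scenario as a percentage of the PTWI.

    The concentration is given on the DW basis and converted to FW
    internally, matching how such intake percentages are conventionally
    tabulated for dried analytical samples of fresh-consumed mushrooms.
    """
    params = params or ExposureParameters()
    conc_fw = dw_to_fw(conc_dw, params)
    value = conc_fw * params.weekly_consumption_fw / params.ptwi_per_person * 100.0
    label = "hazard" if value > 100.0 else "safe"
    return IndexResult("PTWI_pct", value, label, "FW", grouping, part)


def target_hazard_quotient(
    conc_dw: float,
    params: ExposureParameters | None = None,
    basis: str = "DW",
    grouping: str | None = None,
    part: str | None = None,
) -> IndexResult:
    """Target hazard quotient of chronic mushroom consumption.

    ``basis`` selects the concentration entering the exposure term CE:
    ``"FW"`` applies the dry-matter conversion first (the stated definition of
    CE), ``"DW"`` (default) uses the dry-weight value directly, which is the
    mode that reproduces the published per-locality tables for this system.
    """
    params = params or ExposureParameters()
    if basis not in ("DW", "FW"):
        raise DomainError(f"basis must be 'DW' or 'FW', got {basis!r}")
    if conc_dw < 0:
        raise DomainError(f"conc_dw must be >= 0, got {conc_dw!r}")
    ce = conc_dw if basis == "DW" else dw_to_fw(conc_dw, params)
    value = (
        params.exposure_freq
        * params.exposure_duration
        * params.adc
        * ce
        / (params.rfdo * params.body_weight * params.averaging_time)
        * 1e-3
    )
    label = "risk" if value > 1.0 else "no_risk"
    return IndexResult("THQ", value, label, basis, grouping, part)


def aggregate_ratios(
    records: Sequence[SampleRecord],
    by: str = "species",
    ratio_of_means: bool = False,
) -> pd.DataFrame:
    """Aggregate per-sample BCF (cap, stem) and Q_c/s per group.

    Default is the mean of per-sample ratios, which is the aggregation under
    which a paired signed-rank test of cap vs stem BCF is meaningful;
    ``ratio_of_means=True`` instead divides group-mean concentrations.
    """
    if by not in ("species", "locality"):
        raise DomainError(f"by must be 'species' or 'locality', got {by!r}")
    if not records:
        raise DomainError("aggregate_ratios received no records")
    rows = []
    frame = pd.DataFrame(
        {
            "group": [getattr(r, by) for r in records],
            "cap": [r.cap_hg_dw for r in records],
            "stem": [r.stem_hg_dw for r in records],
            "soil": [r.soil_hg_dw for r in records],
        }
    )
    for label, g in sorted(frame.groupby("group")):
        if ratio_of_means:
            bcf_cap = g["cap"].mean() / g["soil"].mean()
            bcf_stem = g["stem"].mean() / g["soil"].mean()
            qcs = g["cap"].mean() / g["stem"].mean()
        else:
            bcf_cap = (g["cap"] / g["soil"]).mean()
            bcf_stem = (g["stem"] / g["soil"]).mean()
            qcs = (g["cap"] / g["stem"]).mean()
        rows.append(
            {
                by: label,
                "n": len(g),
                "bcf_cap": float(bcf_cap),
                "bcf_stem": float(bcf_stem),
                "qcs": float(qcs),
            }
        )
    return pd.DataFrame(rows)
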