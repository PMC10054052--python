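"""End-to-end driver: records → summaries → indices → tests → report tables.

:func:`run_pipeline` assembles the four report tables of a locality-level
mercury risk assessment:

* ``table_soil`` — per-locality soil summary, contamination factor and class;
* ``table_tissue`` — per-locality cap/stem summaries;
* ``table_bcf`` — per-species mean BCF (cap, stem), the paired cap-vs-stem
  signed-rank p-value, and mean Q_c/s;
* ``table_health`` — per-locality %PTWI and THQ for caps and stems, computed
  from the locality mean concentration (the convention under which published
  tables of this kind are built), plus class labels;

and a ``flags`` mapping with the regulatory screening results: localities
whose mean soil mercury exceeds the soil limit, (locality, part) pairs with
THQ > 1, and pairs with %PTWI > 100.

Everything is deterministic given the inputs; running twice yields
identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as mstats
from .errors import DegenerateSampleError, EmptyInputError
from .indices import (
    CFI_CLASSES,
    aggregate_ratios,
    contamination_factor,
    ptwi_percent,
    target_hazard_quotient,
)
from .params import ExposureParameters
from .samples import SampleRecord, summaries_to_frame, summarize_by

__all__ = ["ReportBundle", "run_pipeline", "locality_stats"]

log = logging.getLogger(__name__)

#: Relative distance to a class-bin edge below which a value is flagged as
#: boundary-sensitive in the log.
_EDGE_WARN_REL = 0.01


@dataclass
class ReportBundle:
    table_soil: pd.DataFrame
    table_tissue: pd.DataFrame
    table_bcf: pd.DataFrame
    table_health: pd.DataFrame
    flags: dict[str, list] = field(default_factory=dict)
    thq_basis: str = "DW"


def _warn_near_edges(cfi: float, locality: str) -> None:
    for lower, _upper, _label in CFI_CLASSES[1:]:
        if cfi > 0 and abs(cfi - lower) <= _EDGE_WARN_REL * lower:
            log.warning(
                "contamination factor %.4g for %s is within 1%% of the class "
                "edge at %g; classification is rounding-sensitive",
                cfi,
                locality,
                lower,
            )


def run_pipeline(
    records: Sequence[SampleRecord],
    params: ExposureParameters | None = None,
    thq_basis: str = "DW",
    ratio_of_means: bool = False,
) -> ReportBundle:
    """Compute the full risk-assessment report from validated records."""
    params = params or ExposureParameters()
    records = list(records)
    if not records:
        raise EmptyInputError("run_pipeline received no records")
    summaries = summarize_by(records, "locality")
    summary_frame = summaries_to_frame(summaries)

    soil_rows = []
    health_rows = []
    for s in summaries:
        cfi = contamination_factor(s.soil_mean, params, grouping=s.locality)
        _warn_near_edges(cfi.value, s.locality)
        soil_rows.append(
            {
                "locality": s.locality,
                "n": s.n,
                "soil_mean": s.soil_mean,
                "soil_sd": s.soil_sd,
                "soil_min": s.soil_min,
                "soil_max": s.soil_max,
                "cfi": cfi.value,
                "cfi_class": cfi.class_label,
                "exceeds_soil_limit": s.soil_mean > params.soil_limit,
            }
        )
        row: dict[str, object] = {"locality": s.locality}
        for part in ("cap", "stem"):
            mean = getattr(s, f"{part}_mean")
            ptwi = ptwi_percent(mean, params, grouping=s.locality, part=part)
            thq = target_hazard_quotient(
                mean, params, basis=thq_basis, grouping=s.locality, part=part
            )
            row[f"ptwi_{part}"] = ptwi.value
            row[f"ptwi_{part}_class"] = ptwi.class_label
            row[f"thq_{part}"] = thq.value
            row[f"thq_{part}_class"] = thq.class_label
        health_rows.append(row)

    table_soil = pd.DataFrame(soil_rows)
    table_tissue = summary_frame[
        ["locality", "n"]
        + [f"{p}_{s}" for p in ("cap", "stem") for s in ("mean", "sd", "min", "max")]
    ].copy()
    table_health = pd.DataFrame(health_rows)

    bcf = aggregate_ratios(records, by="species", ratio_of_means=ratio_of_means)
    p_values = []
    for species in bcf["species"]:
        sub = [r for r in records if r.species == species]
        cap_ratio = np.array([r.cap_hg_dw / r.soil_hg_dw for r in sub])
        stem_ratio = np.array([r.stem_hg_dw / r.soil_hg_dw for r in sub])
        try:
            res = mstats.wilcoxon_vs_value(cap_ratio - stem_ratio, 0.0)
            p_values.append(res.p_value)
        except DegenerateSampleError:
            p_values.append(float("nan"))
    table_bcf = bcf.assign(wilcoxon_cap_vs_stem_p=p_values)

    flags = {
        "soil_limit_exceeded": table_soil.loc[
            table_soil["exceeds_soil_limit"], "locality"
        ].tolist(),
        "thq_over_1": [
            (row["locality"], part)
            for _, row in table_health.iterrows()
            for part in ("cap", "stem")
            if row[f"thq_{part}"] > 1.0
        ],
        "ptwi_over_100": [
            (row["locality"], part)
            for _, row in table_health.iterrows()
            for part in ("cap", "stem")
            if row[f"ptwi_{part}"] > 100.0
        ],
    }
    log.info(
        "pipeline: %d records, %d localities, %d soil-limit exceedance(s), "
        "%d THQ>1 cell(s)",
        len(records),
        len(summaries),
        len(flags["soil_limit_exceeded"]),
        len(flags["thq_over_1"]),
    )
    return ReportBundle(table_soil, table_tissue, table_bcf, table_health, flags, thq_basis)


def locality_stats(
    records: Sequence[SampleRecord], variable: str = "soil_hg_dw"
) -> pd.DataFrame:
    """Per-locality signed-rank comparison against the pooled median.

    Mirrors the survey's presentation: the pooled all-locality median is the
    reference line, and each locality is tested against it with the
    one-sample Wilcoxon signed-rank test.  Localities whose every value
    equals the median get p = NaN (test undefined).
    """
    values = np.array([getattr(r, variable) for r in records], dtype=float)
    localities = np.array([r.locality for r in records])
    pooled_median = float(np.median(values))
    rows = []
    for locality in sorted(set(localities)):
        sample = values[localities == locality]
        try:
            res = mstats.wilcoxon_vs_value(sample, pooled_median)
            stat, p, stars = res.statistic, res.p_value, res.stars
        except DegenerateSampleError:
            stat, p, stars = float("nan"), float("nan"), "ns"
        rows.append(
            {
                "locality": locality,
                "n": int(sample.size),
                "median": float(np.median(sample)),
                "direction": "higher" if np.median(sample) > pooled_median else "lower",
                "statistic": stat,
                "p_value": p,
                "stars": stars,
            }
        )
    return pd.DataFrame(rows).assign(pooled_median=pooled_median)
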