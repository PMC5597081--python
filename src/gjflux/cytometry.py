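"""Flow-cytometry population summaries and normalization chains.

Event tables are tidy data frames with one row per event and columns
``fluorescence``, ``condition``, ``timepoint`` and ``stain``. Populations are
summarized by their geometric mean; the recycling (efflux) readout and the
surface/total receptor-ratio uptake normalization follow the assay's anchor
conventions: efflux curves are normalized to each condition's saturated t=0
level and then to the reference condition at t = 7.5 min (x100).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE_TIME_MIN = 7.5


@dataclass
class EffluxCurve:
    """Percent-remaining efflux curves, anchored at the reference condition."""

    table: pd.DataFrame  # condition, timepoint_min, percent_remaining
    reference_condition: str
    reference_time_min: float = REFERENCE_TIME_MIN


def geometric_mean(values) -> float:
    """Geometric mean exp(mean(log x)) of a population.

    Non-positive events are excluded with a warning carrying the dropped
    count; an empty population after filtering is an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n_dropped = int(np.sum(x <= 0))
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} non-positive event(s) before geometric mean",
            stacklevel=2,
        )
        x = x[x > 0]
    if x.size == 0:
        raise ValueError("no positive events to summarize")
    return float(np.exp(np.mean(np.log(x))))


def population_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean and event count per (condition, timepoint, stain)."""
    keys = [k for k in ("condition", "timepoint", "stain") if k in events.columns]
    rows = []
    for key, grp in events.groupby(keys):
        if not isinstance(key, tuple):
            key = (key,)
        rows.append(
            dict(zip(keys, key))
            | {"geometric_mean": geometric_mean(grp["fluorescence"]), "n_events": len(grp)}
        )
    return pd.DataFrame(rows)


def efflux_normalize(
    events: pd.DataFrame,
    reference_condition: str,
    reference_time_min: float = REFERENCE_TIME_MIN,
    saturation_time_min: float = 0.0,
) -> EffluxCurve:
    """Transferrin-efflux normalization chain.

    Per condition, the geometric mean at each timepoint is divided by that
    condition's saturated level at t = 0 (post-uptake). All conditions are
    then divided by the reference condition's value at the reference time
    (default 7.5 min) and expressed as a percentage, so the reference
    condition maps to exactly 100% at that time.
    """
    summary = population_summary(events)
    if "timepoint" not in summary.columns:
        raise ValueError("events must carry a 'timepoint' column")
    rows = []
    sat = {}
    for cond, grp in summary.groupby("condition"):
        at_zero = grp[np.isclose(grp["timepoint"], saturation_time_min)]
        if at_zero.empty:
            raise ValueError(
                f"condition {cond!r} lacks the t={saturation_time_min} saturation population"
            )
        sat[cond] = float(at_zero["geometric_mean"].iloc[0])
    ref = summary[
        (summary["condition"] == reference_condition)
        & np.isclose(summary["timepoint"], reference_time_min)
    ]
    if ref.empty:
        raise ValueError(
            f"reference condition {reference_condition!r} lacks the "
            f"t={reference_time_min} anchor population"
        )
    ref_value = float(ref["geometric_mean"].iloc[0]) / sat[reference_condition]
    for rec in summary.itertuples():
        rows.append(
            {
                "condition": rec.condition,
                "timepoint_min": float(rec.timepoint),
                "percent_remaining": 100.0
                * (rec.geometric_mean / sat[rec.condition])
                / ref_value,
            }
        )
    table = pd.DataFrame(rows).sort_values(["condition", "timepoint_min"]).reset_index(drop=True)
    return EffluxCurve(
        table=table,
        reference_condition=reference_condition,
        reference_time_min=reference_time_min,
    )


def surface_total_ratio(
    surface_events,
    total_events,
    isotype_surface_events,
    isotype_total_events,
) -> float:
    """Background-subtracted surface/total receptor ratio.

    ``(g(surface) - g(isotype_surface)) / (g(total) - g(isotype_total))``
    with isotype geometric means subtracted as background. A non-positive
    denominator signals failed staining and is an error.
    """
    num = geometric_mean(surface_events) - geometric_mean(isotype_surface_events)
    den = geometric_mean(total_events) - geometric_mean(isotype_total_events)
    if den <= 0:
        raise ValueError(
            "total signal does not exceed isotype background (failed staining)"
        )
    if num < 0:
        logger.warning("surface signal below isotype background; ratio is negative")
    return num / den


def uptake_normalize(
    uptake_events,
    ratio: float,
    control_value: float | None = None,
) -> float:
    """Uptake geometric mean divided by the surface/total ratio.

    When ``control_value`` is given (the same quantity for control cells),
    the result is expressed relative to it.
    """
    if ratio <= 0:
        raise ValueError("surface/total ratio must be positive")
    value = geometric_mean(uptake_events) / ratio
    if control_value is not None:
        if control_value <= 0:
            raise ValueError("control value must be positive")
        value = value / control_value
    return value
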