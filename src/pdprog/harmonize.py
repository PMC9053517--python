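"""Scale harmonization: percent transform and within-cohort baseline z-scores.

Raw scores on heterogeneous instruments are made comparable in three steps:
bounded scales are rescaled to percentages of their range; follow-up is capped
(72 months by default); and every scale is standardized to the baseline mean
and SD of its own cohort, so that cross-cohort differences in instruments or
administration (e.g. semantic fluency timing) are absorbed.  An optional
direction flip makes "worse" the positive direction on every scale before
PCA; it defaults off, leaving raw directions intact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import DegenerateScaleError, RangeError
from .scales import DEFAULT_SCALES, ScaleDefinition, scales_by_id

logger = logging.getLogger(__name__)

DEFAULT_FOLLOWUP_CAP_MONTHS = 72.0


def to_percent(raw, scale: ScaleDefinition):
    """Map raw values to percent of the scale range: 100*(raw-min)/(max-min).

    Open-ended scales (no fixed maximum) pass through unchanged.  Values
    outside a fixed range raise :class:`RangeError`.
    """
    raw_arr = np.asarray(raw, float)
    if scale.open_ended:
        return raw if np.isscalar(raw) else raw_arr
    bad = (raw_arr < scale.min) | (raw_arr > scale.max)
    if np.any(bad):
        offender = raw_arr[bad].flat[0]
        raise RangeError(
            f"value {offender} outside range [{scale.min}, {scale.max}] of scale {scale.scale_id}"
        )
    pct = 100.0 * (raw_arr - scale.min) / (scale.max - scale.min)
    return float(pct) if np.isscalar(raw) else pct


def apply_followup_cap(visits: pd.DataFrame, cap_months: float = DEFAULT_FOLLOWUP_CAP_MONTHS):
    """Drop visits beyond ``cap_months`` after study entry.

    Time since entry is taken from a ``time_from_entry`` column when present,
    otherwise from each subject's earliest ``time_from_onset``.
    """
    if "time_from_entry" in visits.columns:
        t_entry = visits["time_from_entry"]
    else:
        first = visits.groupby("subject_id")["time_from_onset"].transform("min")
        t_entry = visits["time_from_onset"] - first
    return visits.loc[t_entry * 12.0 <= cap_months].reset_index(drop=True)


def standardize_baseline(
    visits: pd.DataFrame, scales=DEFAULT_SCALES, value_col: str = "raw_value"
) -> pd.DataFrame:
    """Baseline-referenced z-scores within each cohort x scale.

    Each subject's earliest visit with a nonmissing value defines that
    subject's baseline; the cohort x scale baseline mean and SD (n-1
    denominator) standardize all of that cohort's visits for the scale.
    Returns the input with a ``z_value`` column appended.

    Raises
    ------
    DegenerateScaleError
        If a cohort x scale has fewer than 2 baseline values or zero SD.
    """
    df = visits.copy()
    df["z_value"] = np.nan
    for (cohort, scale_id), idx in df.groupby(["cohort", "scale_id"]).groups.items():
        sub = df.loc[idx]
        base_idx = sub.sort_values("time_from_onset", kind="stable").groupby("subject_id").head(1).index
        base = df.loc[base_idx, value_col]
        if len(base) < 2:
            raise DegenerateScaleError(
                f"cohort {cohort}, scale {scale_id}: <2 baseline observations"
            )
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            raise DegenerateScaleError(f"cohort {cohort}, scale {scale_id}: zero baseline SD")
        df.loc[idx, "z_value"] = (df.loc[idx, value_col] - mu) / sd
    return df


def flip_direction(z_values, scale: ScaleDefinition):
    """Negate z-scores of scales where higher raw values mean better function,
    so larger harmonized values always mean worse function."""
    return z_values if scale.higher_is_worse else -z_values


def harmonize(
    visits: pd.DataFrame,
    scales=DEFAULT_SCALES,
    cap_months: float = DEFAULT_FOLLOWUP_CAP_MONTHS,
    percent: bool = True,
    flip: bool = False,
) -> pd.DataFrame:
    """Full harmonization: percent transform, follow-up cap, baseline z-scores,
    optional direction flip.  Returns the long table with a ``z_value`` column.

    Note the percent transform is an affine map per scale, so it cannot change
    the z-scores; it is retained so intermediate percent tables match the
    conventional reporting scale.
    """
    by_id = scales_by_id(scales)
    df = visits.copy()
    unknown = set(df["scale_id"]) - set(by_id)
    if unknown:
        raise KeyError(f"visits reference undefined scales: {sorted(unknown)}")
    if percent:
        df["pct_value"] = df["raw_value"]
        for sid, sdef in by_id.items():
            mask = df["scale_id"] == sid
            if mask.any():
                df.loc[mask, "pct_value"] = to_percent(df.loc[mask, "raw_value"].to_numpy(), sdef)
        value_col = "pct_value"
    else:
        value_col = "raw_value"
    df = apply_followup_cap(df, cap_months)
    df = standardize_baseline(df, scales, value_col=value_col)
    if flip:
        for sid, sdef in by_id.items():
            mask = df["scale_id"] == sid
            df.loc[mask, "z_value"] = flip_direction(df.loc[mask, "z_value"], sdef)
    n_dropped = len(visits) - len(df)
    if n_dropped:
        logger.info("harmonize: %d visits beyond the %.0f-month cap removed", n_dropped, cap_months)
    return df
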