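"""Thioflavin-T aggregation-kinetics extraction and sigmoid fitting.

Aggregate-bound ThT intensity is summed per frame over segmented
aggregates (threshold 250 a.u., components of more than 9 pixels) and
fitted with a four-parameter logistic

    I(t) = baseline + amplitude / (1 + exp(-growth_rate * (t - t_mid)))

The lag time is reported with the tangent-intercept convention: the
tangent at the point of maximum slope crosses the baseline at
lag = t_mid - 2 / growth_rate. The plateau time is the first time the
fitted curve reaches baseline + 0.95 * amplitude,
plateau = t_mid + ln(19) / growth_rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from aggremorph.image import Image
from aggremorph.segment import segment_aggregates, KINETICS_THRESHOLD, MIN_AREA_EXCLUSIVE
from aggremorph.synthdata import KineticsTrace, logistic

PLATEAU_FRACTION = 0.95
_PLATEAU_LOGIT = math.log(PLATEAU_FRACTION / (1 - PLATEAU_FRACTION))  # ln 19


@dataclass
class KineticsFit:
    baseline: float
    amplitude: float
    t_mid: float
    growth_rate: float
    lag_time: float       # NaN when lag_defined is False
    plateau_time: float
    rmse: float
    lag_defined: bool = True
    condition: str = "unseeded"
    replicate_id: int = 0


def extract_trace(stack: list[Image], times: np.ndarray,
                  threshold: float = KINETICS_THRESHOLD,
                  min_area_exclusive: int = MIN_AREA_EXCLUSIVE,
                  condition: str = "unseeded", replicate_id: int = 0,
                  ) -> KineticsTrace:
    """Aggregate-bound intensity vs time from a time-lapse stack.

    Per frame, aggregates are segmented with the kinetics threshold and
    size rule, and the intensity of all detected-aggregate pixels is
    summed. Frames with no detections contribute zero.
    """
    times = np.asarray(times, dtype=float)
    if len(stack) != len(times):
        raise ValueError("stack and time grid lengths differ")
    dt = np.diff(times)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("frame intervals are not uniform")
    totals = []
    for img in stack:
        regions = segment_aggregates(img, intensity_threshold=threshold,
                                     min_area_exclusive=min_area_exclusive)
        totals.append(sum(r.total_intensity for r in regions))
    return KineticsTrace(times=times, intensity=np.asarray(totals, dtype=float),
                         condition=condition, replicate_id=replicate_id)


def blank_subtract(trace: KineticsTrace, blank: KineticsTrace) -> KineticsTrace:
    """Pointwise blank subtraction on a matching time grid."""
    if not np.array_equal(trace.times, blank.times):
        raise ValueError("time grids do not match")
    return KineticsTrace(times=trace.times.copy(),
                         intensity=trace.intensity - blank.intensity,
                         condition=trace.condition,
                         replicate_id=trace.replicate_id)


def fit_sigmoid(trace: KineticsTrace, n_starts: int = 8,
                flat_rel_tol: float = 0.02) -> KineticsFit:
    """Least-squares logistic fit with multi-start initialisation.

    ``t_mid`` starting points are spread over the observed time span;
    the best (lowest SSE) converged fit is kept. A trace whose fitted
    amplitude is below ``flat_rel_tol`` of its mean level (or whose
    range is zero) is reported as flat: amplitude ~ 0 and the lag
    flagged undefined rather than an error.
    """
    t = trace.times
    y = trace.intensity
    if len(t) < 10:
        raise ValueError("need at least 10 time points to fit")
    span = np.ptp(y)
    level = max(abs(y).max(), 1.0)
    if span <= flat_rel_tol * level:
        base = float(np.mean(y))
        return KineticsFit(baseline=base, amplitude=0.0, t_mid=float("nan"),
                           growth_rate=float("nan"), lag_time=float("nan"),
                           plateau_time=float("nan"),
                           rmse=float(np.std(y)), lag_defined=False,
                           condition=trace.condition, replicate_id=trace.replicate_id)

    t_range = t[-1] - t[0]
    rate0 = 10.0 / t_range
    best = None
    bounds = ([y.min() - span, 0.0, 1e-6, t[0] - t_range],
              [y.max() + span, 4 * span, 10.0, t[-1] + t_range])
    for frac in np.linspace(0.1, 0.9, n_starts):
        p0 = (float(y[:3].mean()), float(span), rate0, float(t[0] + frac * t_range))
        try:
            popt, _ = curve_fit(logistic, t, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((logistic(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    sse, (baseline, amplitude, rate, t_mid) = best
    rmse = math.sqrt(sse / len(t))
    if amplitude <= flat_rel_tol * level:
        return KineticsFit(baseline=float(baseline), amplitude=float(amplitude),
                           t_mid=float(t_mid), growth_rate=float(rate),
                           lag_time=float("nan"), plateau_time=float("nan"),
                           rmse=rmse, lag_defined=False,
                           condition=trace.condition, replicate_id=trace.replicate_id)
    return KineticsFit(
        baseline=float(baseline),
        amplitude=float(amplitude),
        t_mid=float(t_mid),
        growth_rate=float(rate),
        lag_time=float(t_mid - 2.0 / rate),
        plateau_time=float(t_mid + _PLATEAU_LOGIT / rate),
        rmse=rmse,
        lag_defined=True,
        condition=trace.condition,
        replicate_id=trace.replicate_id,
    )


def compare_conditions(fits: list[KineticsFit]) -> pd.DataFrame:
    """Per-condition mean ± sd of lag, plateau and amplitude.

    Single-replicate groups report sd as NaN. When both seeded and
    unseeded groups are present, a ``lag_reduction_min`` column carries
    mean(unseeded lag) - mean(seeded lag) on every row.
    """
    rows = []
    frame = pd.DataFrame([vars(f) for f in fits])
    for cond, grp in frame.groupby("condition", sort=True):
        rows.append({
            "condition": cond,
            "n": len(grp),
            "lag_mean_min": grp["lag_time"].mean(),
            "lag_sd_min": grp["lag_time"].std(ddof=1) if len(grp) > 1 else np.nan,
            "plateau_mean_min": grp["plateau_time"].mean(),
            "plateau_sd_min": grp["plateau_time"].std(ddof=1) if len(grp) > 1 else np.nan,
            "amplitude_mean_au": grp["amplitude"].mean(),
            "amplitude_sd_au": grp["amplitude"].std(ddof=1) if len(grp) > 1 else np.nan,
        })
    out = pd.DataFrame(rows)
    conds = set(out["condition"])
    if {"seeded", "unseeded"} <= conds:
        unseeded = out.loc[out["condition"] == "unseeded", "lag_mean_min"].iloc[0]
        seeded = out.loc[out["condition"] == "seeded", "lag_mean_min"].iloc[0]
        out["lag_reduction_min"] = unseeded - seeded
    return out


def read_plate_reader_csv(path, fmt: str = "long") -> list[KineticsTrace]:
    """Read plate-reader kinetics tables.

    ``long`` format: columns time_min, replicate_id, intensity_au,
    condition. ``wide`` format: a time_min column plus one intensity
    column per replicate (column name used as replicate id; an optional
    ``condition`` prefix before an underscore is honoured, e.g.
    ``seeded_1``).
    """
    df = pd.read_csv(path)
    traces = []
    if fmt == "long":
        for (cond, rep), grp in df.groupby(["condition", "replicate_id"], sort=True):
            grp = grp.sort_values("time_min")
            traces.append(KineticsTrace(times=grp["time_min"].to_numpy(),
                                        intensity=grp["intensity_au"].to_numpy(),
                                        condition=str(cond), replicate_id=int(rep)))
    elif fmt == "wide":
        t = df["time_min"].to_numpy(dtype=float)
        for i, col in enumerate(c for c in df.columns if c != "time_min"):
            cond = col.rsplit("_", 1)[0] if "_" in col else "unseeded"
            traces.append(KineticsTrace(times=t, intensity=df[col].to_numpy(dtype=float),
                                        condition=cond, replicate_id=i))
    else:
        raise ValueError("fmt must be 'long' or 'wide'")
    return traces
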