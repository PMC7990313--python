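"""Cross-trajectory summary statistics and publication-style tables.

Replicate trajectories (conventionally labelled I, II, III) are summarised
by the arithmetic mean and the sample (n-1) standard deviation, rounded
half-up at the printed precision.  Percent decreases between a first and a
last analysis window are rounded half-up to integers.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "summarize",
    "percent_decrease",
    "summary_table",
    "parse_window",
    "run_pipeline",
]


def run_pipeline(config, out_dir, seed: int | None = None):
    """Execute the full analysis pipeline; see :func:`pepdyn.pipeline.run_pipeline`."""
    from .pipeline import run_pipeline as _run  # deferred: avoids import cycle

    return _run(config, out_dir, seed=seed)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (2.5 -> 3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize(values, decimals: int = 2) -> tuple[float, float | None]:
    """(mean, sample SD) of replicate values, rounded half-up.

    With fewer than 2 values the SD is undefined and returned as None.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no values to summarize")
    mean = round_half_up(float(vals.mean()), decimals)
    if vals.size < 2:
        return mean, None
    sd = float(np.sqrt(np.sum((vals - vals.mean()) ** 2) / (vals.size - 1)))
    return mean, round_half_up(sd, decimals)


def percent_decrease(first: float, last: float) -> int:
    """round(100 * (first - last) / first), half-up to integer."""
    if first <= 0:
        raise ValueError("first-window mean must be positive")
    return int(round_half_up(100.0 * (first - last) / first, 0))


def summary_table(
    per_trajectory: dict[str, dict[str, float]],
    decimals: int = 2,
) -> pd.DataFrame:
    """Rows = trajectory labels, columns = systems, plus Average and
    Standard Deviation footer rows."""
    df = pd.DataFrame(per_trajectory).T  # trajectories x systems
    footer_mean, footer_sd = {}, {}
    for col in df.columns:
        mean, sd = summarize(df[col].to_numpy(), decimals)
        footer_mean[col] = mean
        footer_sd[col] = sd
    out = pd.concat(
        [
            df,
            pd.DataFrame([footer_mean], index=["Average"]),
            pd.DataFrame([footer_sd], index=["Standard Deviation"]),
        ]
    )
    out.index.name = "Trajectory"
    return out


def parse_window(spec: str | tuple, t_start: float, t_end: float) -> tuple[float, float]:
    """Resolve a window spec against a trajectory time span (ps).

    Accepts explicit (t0, t1) tuples, or strings "first:Xns"/"last:Xns"
    (also Xps) mirroring the first/last analysis-window convention.
    """
    if isinstance(spec, tuple):
        return float(spec[0]), float(spec[1])
    kind, _, amount = spec.partition(":")
    amount = amount.strip().lower()
    if amount.endswith("ns"):
        span = float(amount[:-2]) * 1000.0
    elif amount.endswith("ps"):
        span = float(amount[:-2])
    else:
        span = float(amount)
    if kind == "first":
        return t_start, min(t_start + span, t_end)
    if kind == "last":
        return max(t_end - span, t_start), t_end
    raise ValueError(f"bad window spec {spec!r}")
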