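"""Resampling statistics for longitudinal session series.

The bootstrap slope test asks whether a per-day quantity (median speed,
flickering fraction, ...) trends across days: the observed least-squares
slope of value against day is compared with slopes recomputed after full
reshuffling of all values across day labels (10 000 permutations).  The
trend is significantly positive (negative) when the observed slope
exceeds the 95th (falls below the 5th) percentile of the surrogate
slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BootstrapSlopeResult", "bootstrap_slope_test"]


@dataclass
class BootstrapSlopeResult:
    """Observed slope versus its permutation null."""

    slope: float
    surrogate_q05: float
    surrogate_q95: float
    direction: str               # "positive" | "negative" | "none"
    n_surrogates: int
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.direction != "none"


def bootstrap_slope_test(
    values_per_day: list[np.ndarray],
    n_surrogates: int = 10_000,
    seed: int | np.random.Generator = 0,
    chunk: int = 2000,
) -> BootstrapSlopeResult:
    """Permutation test on the least-squares slope across days.

    ``values_per_day`` holds the raw per-day samples (one array per day,
    at least 3 days with at least one value each).  All raw values are
    pooled and permuted across day labels — full dataset reshuffling —
    preserving the value multiset while destroying temporal order.
    Constant values give slope 0 and direction "none".
    """
    days = [np.atleast_1d(np.asarray(v, dtype=float)) for v in values_per_day]
    if len(days) < 3:
        raise ValueError("slope test needs at least 3 days")
    if any(len(v) == 0 for v in days):
        raise ValueError("every day needs at least one value")
    x = np.concatenate([np.full(len(v), i, dtype=float) for i, v in enumerate(days)])
    y = np.concatenate(days)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    w = xc / denom                      # slope = w @ y
    slope = float(w @ y)

    if np.ptp(y) == 0:
        return BootstrapSlopeResult(
            slope=0.0, surrogate_q05=0.0, surrogate_q95=0.0,
            direction="none", n_surrogates=n_surrogates,
        )

    surrogate = np.empty(n_surrogates)
    done = 0
    while done < n_surrogates:
        m = min(chunk, n_surrogates - done)
        perm = np.argsort(rng.random((m, len(y))), axis=1)
        surrogate[done : done + m] = y[perm] @ w
        done += m

    q05, q95 = np.percentile(surrogate, [5, 95])
    if slope > q95:
        direction = "positive"
    elif slope < q05:
        direction = "negative"
    else:
        direction = "none"
    return BootstrapSlopeResult(
        slope=slope,
        surrogate_q05=float(q05),
        surrogate_q95=float(q95),
        direction=direction,
        n_surrogates=n_surrogates,
    )
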