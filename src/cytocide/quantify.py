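"""Count rates, control normalization, and outgrowth detection.

Gated event counts are converted to count rates (events/s) using the
volumetric acquisition duration, then scaled against the assay's own
controls:

    normalized = (rate_sample - rate_NC) / (rate_PC - rate_NC)

so the no-bacteria negative control maps to 0 and the untreated growth
control to 1.  Values are clamped below at 0 (sub-NC rates are noise) but
not above 1 (super-PC rates are real growth variation).  The normalized
scale is what the bactericidal classification threshold (default 0.1)
applies to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .fcs_io import AcquisitionMeta

__all__ = [
    "CountResult",
    "count_rate",
    "normalize_rate",
    "GrowthTest",
    "detect_growth",
]


@dataclass
class CountResult:
    """Gated count for one sample, as a rate and (optionally) normalized."""

    sample_id: str
    n_gated: int
    duration_s: float
    rate: float
    normalized: float | None = None
    role: str = ""
    concentration: float | None = None


def count_rate(n_gated: int, acq: AcquisitionMeta) -> float:
    """Events per second over the acquisition duration."""
    if n_gated < 0:
        raise ValueError("n_gated must be >= 0")
    if acq.duration_s is None or acq.duration_s <= 0:
        raise ValueError("acquisition duration must be > 0")
    return n_gated / acq.duration_s


def normalize_rate(rate_sample: float, rate_nc: float, rate_pc: float) -> float:
    """Scale a sample rate onto the [NC=0, PC=1] control axis.

    Raises when the growth control does not exceed the negative control --
    that assay's growth control failed and nothing can be normalized.
    """
    if rate_pc <= rate_nc:
        raise ValueError(
            f"growth-control rate ({rate_pc:g}) must exceed the "
            f"negative-control rate ({rate_nc:g}); failed growth control"
        )
    value = (rate_sample - rate_nc) / (rate_pc - rate_nc)
    return max(value, 0.0)


class GrowthTest(NamedTuple):
    growth_flag: bool | None  # None = undetermined (too few replicates)
    t: float
    df: float
    p: float
    n_pairs: int


def detect_growth(replicates: Sequence[tuple[float, float]],
                  alpha: float = 0.05) -> GrowthTest:
    """Did the culture grow between time zero and the 4 h read?

    ``replicates`` holds (rate_t0, rate_t4) pairs from independent repeats.
    A one-sided Welch t-test (t4 > t0; growth direction is known a priori)
    at ``alpha`` sets the flag.  With fewer than 2 pairs the output is
    descriptive only and the flag is undetermined.
    """
    pairs = [(float(a), float(b)) for a, b in replicates]
    if any(a < 0 or b < 0 for a, b in pairs):
        raise ValueError("rates must be >= 0")
    t0 = np.array([a for a, _ in pairs])
    t4 = np.array([b for _, b in pairs])
    if len(pairs) < 2:
        diff = float(t4.mean() - t0.mean()) if pairs else 0.0
        return GrowthTest(None, diff, 0.0, 1.0, len(pairs))
    if np.ptp(t0) == 0 and np.ptp(t4) == 0 and t0[0] == t4[0]:
        # degenerate: both arms constant and equal; no evidence of growth
        return GrowthTest(False, 0.0, float(2 * len(pairs) - 2), 1.0, len(pairs))
    res = stats.ttest_ind(t4, t0, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    return GrowthTest(bool(p < alpha), float(res.statistic), float(res.df),
                      p, len(pairs))
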