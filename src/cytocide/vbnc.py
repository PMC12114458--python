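"""Live/dead/membrane-compromised quantification from SYTO9/PI dual stain.

SYTO9 (green, FL1) enters all cells; propidium iodide (red, FL3) enters
only membrane-compromised cells.  Quadrant gating on compensated (FL1,
FL3) therefore reads:

* FL1+ FL3-  -> live (intact membrane),
* FL3+ FL1-  -> dead,
* FL1+ FL3+  -> double-positive: membrane-compromised / VBNC-candidate,
* FL1- FL3-  -> unstained/background.

Quadrant cuts are anchored on the unstained control (per-channel quantile
of the log intensities, default 99.5%), with boundary events assigned to
the positive side.  At most ``cap`` events (default 5000) are analyzed per
sample, subsampled uniformly with a fixed seed.  Optical spillover between
the green and red detectors can be removed with a 2x2 compensation matrix,
either supplied or estimated from single-stain controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fcs_io import EventTable

__all__ = [
    "StainControls",
    "QuadrantResult",
    "compensate",
    "estimate_spillover",
    "quadrant_fractions",
]

_FL_H = ("FL1-H", "FL3-H")
_FL_A = ("FL1-A", "FL3-A")


@dataclass
class StainControls:
    """Controls acquired alongside each dual-stain analysis."""

    unstained: EventTable
    heat_killed: EventTable | None = None
    single_stain_fl1: EventTable | None = None
    single_stain_fl3: EventTable | None = None


@dataclass
class QuadrantResult:
    n_analyzed: int
    fractions: dict[str, float]  # live, dead, double_positive, unstained
    cuts: tuple[float, float]  # (fl1_cut, fl3_cut), log10 units
    compensation_applied: bool
    spillover: tuple[tuple[float, float], tuple[float, float]] | None = None


def compensate(table: EventTable, spillover: Sequence[Sequence[float]]) -> EventTable:
    """Undo (FL1, FL3) optical mixing: observed @ inverse(spillover).

    Applies to the height channels and, when present, the matching area
    channels.  Compensated negatives are floored at 0.
    """
    spill = np.asarray(spillover, dtype=float)
    if spill.shape != (2, 2):
        raise ValueError("spillover must be a 2x2 matrix")
    try:
        inv = np.linalg.inv(spill)
    except np.linalg.LinAlgError:
        raise ValueError("spillover matrix is singular") from None
    events = table.events.copy()
    for pair in (_FL_H, _FL_A):
        if all(table.has_channel(c) for c in pair):
            idx = [table.channel_names.index(c) for c in pair]
            events[:, idx] = np.maximum(events[:, idx] @ inv, 0.0)
    return table.with_events(events)


def estimate_spillover(single_stain_fl1: EventTable,
                       single_stain_fl3: EventTable,
                       unstained: EventTable,
                       positive_quantile: float = 0.995) -> np.ndarray:
    """Spillover coefficients from single-stain controls.

    Each off-diagonal is the median background-subtracted secondary/primary
    intensity ratio among stain-positive events of the corresponding
    single-stain control; diagonals are 1.
    """
    bg = [float(np.median(unstained.channel(c))) for c in _FL_H]
    cuts = [float(np.quantile(unstained.channel(c), positive_quantile))
            for c in _FL_H]

    def _ratio(control: EventTable, primary: int) -> float:
        secondary = 1 - primary
        prim = control.channel(_FL_H[primary])
        sec = control.channel(_FL_H[secondary])
        positive = prim > cuts[primary]
        n_pos = int(positive.sum())
        # a handful of events above the quantile cut is what an unstained
        # sample produces by construction; a usable single-stain control
        # must carry a real positive population
        if n_pos < 100:
            raise ValueError(
                f"only {n_pos} stain-positive events in the {_FL_H[primary]} "
                "single-stain control; need >= 100"
            )
        num = sec[positive] - bg[secondary]
        den = prim[positive] - bg[primary]
        ratio = float(np.median(num / den))
        return max(ratio, 0.0)

    s12 = _ratio(single_stain_fl1, 0)  # FL1 signal bleeding into FL3
    s21 = _ratio(single_stain_fl3, 1)  # FL3 signal bleeding into FL1
    return np.array([[1.0, s12], [s21, 1.0]])


def quadrant_fractions(sample: EventTable, controls: StainControls,
                       cap: int = 5000, cut_quantile: float = 0.995,
                       spillover: Sequence[Sequence[float]] | None = None,
                       seed: int = 0) -> QuadrantResult:
    """Quadrant fractions of a dual-stained, bacteria-gated sample.

    When a spillover matrix is supplied (or both single-stain controls are
    present, in which case it is estimated), the sample *and* the unstained
    control are compensated before the cuts are taken, so cuts and events
    live in the same space.
    """
    if controls.unstained is None:
        raise ValueError("an unstained control is required for quadrant cuts")
    if not 0 < cut_quantile < 1:
        raise ValueError("cut_quantile must be in (0, 1)")
    if cap < 1:
        raise ValueError("cap must be >= 1")

    matrix = None
    if spillover is not None:
        matrix = np.asarray(spillover, dtype=float)
    elif (controls.single_stain_fl1 is not None
          and controls.single_stain_fl3 is not None):
        matrix = estimate_spillover(controls.single_stain_fl1,
                                    controls.single_stain_fl3,
                                    controls.unstained)
    unstained = controls.unstained
    if matrix is not None:
        sample = compensate(sample, matrix)
        unstained = compensate(unstained, matrix)

    cuts = tuple(
        float(np.quantile(np.log10(np.maximum(unstained.channel(c), 1.0)),
                          cut_quantile))
        for c in _FL_H
    )
    fl1 = np.log10(np.maximum(sample.channel("FL1-H"), 1.0))
    fl3 = np.log10(np.maximum(sample.channel("FL3-H"), 1.0))
    n = len(fl1)
    if n > cap:
        idx = np.random.default_rng(seed).choice(n, size=cap, replace=False)
        fl1, fl3 = fl1[idx], fl3[idx]
        n = cap
    if n == 0:
        raise ValueError("sample has no events to analyze")

    fl1_pos = fl1 >= cuts[0]  # boundary assigned to the positive side
    fl3_pos = fl3 >= cuts[1]
    fractions = {
        "live": float(np.mean(fl1_pos & ~fl3_pos)),
        "dead": float(np.mean(fl3_pos & ~fl1_pos)),
        "double_positive": float(np.mean(fl1_pos & fl3_pos)),
        "unstained": float(np.mean(~fl1_pos & ~fl3_pos)),
    }
    return QuadrantResult(
        n_analyzed=n,
        fractions=fractions,
        cuts=cuts,
        compensation_applied=matrix is not None,
        spillover=None if matrix is None else tuple(map(tuple, matrix.tolist())),
    )
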