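"""MBC calling on two-fold dilution ladders and EN 13727-style log reductions.

Each concentration of a two-fold ladder is classified from its normalized
count: strictly below the threshold (default 0.1) means the disinfectant
killed the inoculum there ("above_or_MBC"), otherwise "not_MBC".  The MBC
is the lowest concentration of the contiguous killed run starting at the
top of the ladder (strict policy); an isolated killed well between
surviving wells does not call the MBC under the strict policy, which is the
conservative reading of "the lowest concentration in the series causing"
the count collapse.

Log reductions compare viable counts before and after treatment,
``LR = log10(n0 / nd)``; a reduction of >= 5 log10 is the bactericidal
criterion for suspension tests in the medical area.  Counts below the
detection limit are censored: the reported LR is then a lower bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .quantify import CountResult

__all__ = [
    "ABOVE_OR_MBC",
    "NOT_MBC",
    "BACTERICIDAL_LOG_REDUCTION",
    "DilutionLadder",
    "MBCCall",
    "LogReduction",
    "classify_concentration",
    "call_mbc",
    "log_reduction",
]

ABOVE_OR_MBC = "above_or_MBC"
NOT_MBC = "not_MBC"

#: suspension-test bactericidal criterion: >= 5 log10 reduction in viables
BACTERICIDAL_LOG_REDUCTION = 5.0


@dataclass
class DilutionLadder:
    """Per-concentration normalized counts for one (strain, disinfectant)."""

    disinfectant: str
    strain: str
    concentrations: list[float]  # strictly decreasing, two-fold steps
    results: dict[float, CountResult]
    pc: CountResult | None = None
    nc: CountResult | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 2:
            raise ValueError("ladder needs >= 2 concentrations")
        if np.any(conc <= 0) or not np.allclose(conc[:-1] / conc[1:], 2.0,
                                                rtol=1e-9):
            raise ValueError("concentrations must be two-fold descending")


@dataclass
class MBCCall:
    """Outcome of MBC determination on one ladder."""

    status: str  # called | censored_above_range | censored_below_range
    mbc: float | None
    labels: dict[float, str]
    threshold_used: float
    policy: str = "strict"
    #: every tested concentration killed: the true MBC may lie below the
    #: lowest tested concentration (reported as called-at-lowest-tested)
    below_range: bool = False


def classify_concentration(normalized: float, threshold: float = 0.1) -> str:
    """Strict rule: normalized count < threshold means bactericidal there."""
    if normalized < 0:
        raise ValueError("normalized count must be >= 0")
    return ABOVE_OR_MBC if normalized < threshold else NOT_MBC


def call_mbc(ladder: DilutionLadder, threshold: float = 0.1,
             policy: str = "strict") -> MBCCall:
    """Call the MBC from a ladder of normalized counts.

    ``strict``: scan from the highest concentration down; the MBC is the
    lowest concentration of the contiguous killed run starting at the top.
    A surviving top concentration censors the call above the tested range;
    a fully killed ladder is called at the lowest tested concentration with
    a below-range annotation.  ``lowest_passing``: the minimum killed
    concentration regardless of contiguity.
    """
    if policy not in ("strict", "lowest_passing"):
        raise ValueError("policy must be 'strict' or 'lowest_passing'")
    conc = sorted(ladder.concentrations, reverse=True)
    labels: dict[float, str] = {}
    for c in conc:
        result = ladder.results.get(c)
        if result is None or result.normalized is None:
            raise ValueError(f"missing normalized count for concentration {c}")
        labels[c] = classify_concentration(result.normalized, threshold)

    if policy == "strict":
        run_low: float | None = None
        for c in conc:  # top -> bottom
            if labels[c] == ABOVE_OR_MBC:
                run_low = c
            else:
                break
        if run_low is None:
            return MBCCall("censored_above_range", None, labels, threshold, policy)
        below = labels[conc[-1]] == ABOVE_OR_MBC and run_low == conc[-1]
        return MBCCall("called", run_low, labels, threshold, policy,
                       below_range=below)

    passing = [c for c in conc if labels[c] == ABOVE_OR_MBC]
    if not passing:
        return MBCCall("censored_above_range", None, labels, threshold, policy)
    mbc = min(passing)
    return MBCCall("called", mbc, labels, threshold, policy,
                   below_range=(mbc == conc[-1] and len(passing) == len(conc)))


@dataclass
class LogReduction:
    """log10 reduction in viable counts with detection-limit censoring."""

    n0: float
    nd: float
    detection_limit: float
    lr: float
    bactericidal: bool
    censored: bool  # nd below the detection limit: lr is a lower bound


def log_reduction(n0: float, nd: float, limit: float = 1.0) -> LogReduction:
    """EN 13727-style log reduction ``log10(n0 / max(nd, limit))``."""
    if n0 <= 0:
        raise ValueError("initial viable count n0 must be > 0")
    if nd < 0:
        raise ValueError("surviving count nd must be >= 0")
    if limit <= 0:
        raise ValueError("detection limit must be > 0")
    censored = nd < limit
    lr = math.log10(n0 / max(nd, limit))
    return LogReduction(n0=n0, nd=nd, detection_limit=limit, lr=lr,
                        bactericidal=lr >= BACTERICIDAL_LOG_REDUCTION,
                        censored=censored)
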