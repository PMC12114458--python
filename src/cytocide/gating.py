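"""Gating strategy for label-free bacteria detection.

The pipeline mirrors the manual strategy used on a small-particle
acquisition, in fixed order (each step only removes events):

1. **Hardware-style threshold** -- drop events with FSC-H below a fixed
   intensity (default 1000, set from control data so that bacterial events
   are retained while electronic/background noise is suppressed).
2. **Doublet exclusion** -- on a pulse area vs. height pair (default
   SSC-A/SSC-H), singlets have area proportional to height; events whose
   area/height ratio is a robust outlier (median + k * scaled MAD) are
   coincident particles and are excluded.
3. **Bacteria gate** -- the SYTO9-positive population of the stained
   growth control (green fluorescence above the 99.5th percentile of an
   unstained control) is back-gated onto log10 forward/side scatter; the
   gate is the convex hull of the smallest set of 2-D histogram bins
   holding a configured mass (default 98%) of those events.  The gate is
   then inherited by every label-free treated sample in the assay.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .fcs_io import EventTable, canonical_channel

__all__ = [
    "Gate",
    "GatingConfig",
    "DoubletResult",
    "transform_log",
    "apply_event_threshold",
    "exclude_doublets",
    "build_bacteria_gate",
    "apply_gate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GatingConfig:
    """Tunable gating parameters (all defaults per the reference assay)."""

    fsc_h_threshold: float = 1000.0
    doublet_channels: tuple[str, str] = ("SSC-A", "SSC-H")  # (area, height)
    doublet_ratio_k: float = 3.0
    syto9_channel: str = "FL1-H"
    syto9_cut_quantile: float = 0.995
    #: absolute SYTO9 intensity cut used when no unstained control exists
    syto9_abs_cut: float = 1000.0
    density_mass: float = 0.98
    transform_floor: float = 1.0
    density_grid: int = 64

    def __post_init__(self) -> None:
        if self.fsc_h_threshold < 0:
            raise ValueError("fsc_h_threshold must be >= 0")
        if not 0 < self.density_mass <= 1:
            raise ValueError("density_mass must be in (0, 1]")
        if self.transform_floor <= 0 or self.syto9_abs_cut <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.syto9_cut_quantile < 1:
            raise ValueError("syto9_cut_quantile must be in (0, 1)")


@dataclass(frozen=True)
class Gate:
    """Geometric region over an ordered channel pair in transformed space."""

    kind: str  # polygon | rectangle
    channels: tuple[str, str]
    vertices: tuple[tuple[float, float], ...]  # polygon vertices or 2 corners
    transform_tag: str = "log10-floored"
    transform_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("polygon", "rectangle"):
            raise ValueError("kind must be 'polygon' or 'rectangle'")
        if self.transform_tag not in ("log10-floored", "linear"):
            raise ValueError("unknown transform_tag")
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "channels",
                           tuple(canonical_channel(c) for c in self.channels))
        if self.kind == "polygon":
            if len(verts) < 3:
                raise ValueError("polygon needs >= 3 vertices")
            if not Polygon(verts).is_simple:
                raise ValueError("polygon must be simple (non-self-intersecting)")
        elif len(verts) != 2:
            raise ValueError("rectangle is given by 2 corners")

    def geometry(self) -> Polygon:
        if self.kind == "polygon":
            return Polygon(self.vertices)
        (x0, y0), (x1, y1) = self.vertices
        return shapely.box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))

    @property
    def area(self) -> float:
        """Region area in transformed units."""
        return self.geometry().area

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for transformed coordinates."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.geometry(), pts)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "channels": list(self.channels),
            "vertices": [list(v) for v in self.vertices],
            "transform_tag": self.transform_tag,
            "transform_floor": self.transform_floor,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Gate":
        return cls(
            kind=payload["kind"],
            channels=tuple(payload["channels"]),
            vertices=tuple(tuple(v) for v in payload["vertices"]),
            transform_tag=payload.get("transform_tag", "log10-floored"),
            transform_floor=payload.get("transform_floor", 1.0),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Gate":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _floored_log10(values: np.ndarray, floor: float) -> np.ndarray:
    return np.log10(np.maximum(values, floor))


def transform_log(table: EventTable, channels: Sequence[str],
                  floor: float = 1.0) -> EventTable:
    """Replace the named channels by ``log10(max(value, floor))``."""
    events = table.events.copy()
    for ch in channels:
        idx = table.channel_names.index(canonical_channel(ch))
        events[:, idx] = _floored_log10(events[:, idx], floor)
    return table.with_events(events)


def apply_event_threshold(table: EventTable, cfg: GatingConfig) -> EventTable:
    """Drop events below the FSC-H hardware-style threshold (inclusive keep)."""
    fsc = table.channel("FSC-H")
    keep = fsc >= cfg.fsc_h_threshold
    n_removed = int((~keep).sum())
    log.info("FSC-H threshold %g removed %d of %d events",
             cfg.fsc_h_threshold, n_removed, table.n_events)
    return table.select(keep)


class DoubletResult(NamedTuple):
    table: EventTable
    n_excluded: int  # area/height ratio outliers (doublets)
    n_zero_height: int  # unusable events with zero pulse height


def exclude_doublets(table: EventTable, cfg: GatingConfig) -> DoubletResult:
    """Exclude coincident-particle events by robust area/height outlier test.

    The per-event ratio r = area/height is compared against
    ``median(r) + k * 1.4826 * MAD(r)`` (MAD scaled for SD consistency).
    A degenerate MAD of 0 excludes nothing.  Zero-height events cannot be
    ratioed; they are dropped as noise and counted separately.
    """
    if table.n_events == 0:
        return DoubletResult(table, 0, 0)
    area = table.channel(cfg.doublet_channels[0])
    height = table.channel(cfg.doublet_channels[1])
    usable = height > 0
    n_zero = int((~usable).sum())
    ratio = np.full(table.n_events, np.nan)
    ratio[usable] = area[usable] / height[usable]
    med = np.nanmedian(ratio) if usable.any() else 0.0
    mad = 1.4826 * np.nanmedian(np.abs(ratio - med)) if usable.any() else 0.0
    if mad > 0:
        is_doublet = usable & (ratio > med + cfg.doublet_ratio_k * mad)
    else:
        is_doublet = np.zeros(table.n_events, dtype=bool)
    n_doublets = int(is_doublet.sum())
    log.info("doublet exclusion removed %d doublets and %d zero-height events",
             n_doublets, n_zero)
    return DoubletResult(table.select(usable & ~is_doublet), n_doublets, n_zero)


def build_bacteria_gate(control: EventTable,
                        unstained: EventTable | None,
                        cfg: GatingConfig | None = None) -> Gate:
    """Back-gate the SYTO9-positive control population into a scatter gate.

    SYTO9-positive events are those whose green fluorescence exceeds the
    configured quantile of the unstained control (or an absolute fallback
    cut when no unstained control is available).  Those events are projected
    onto floored-log10 (FSC-H, SSC-H); the gate is the convex hull of the
    densest histogram bins holding ``density_mass`` of them.
    """
    cfg = cfg or GatingConfig()
    fl1 = control.channel(cfg.syto9_channel)
    if unstained is not None and unstained.n_events:
        cut = float(np.quantile(unstained.channel(cfg.syto9_channel),
                                cfg.syto9_cut_quantile))
    else:
        cut = cfg.syto9_abs_cut
    positive = fl1 > cut
    n_pos = int(positive.sum())
    if n_pos < 100:
        raise ValueError(
            f"only {n_pos} SYTO9-positive events in the control; acquire a "
            "larger stained control (>= 100 positive events required)"
        )
    x = _floored_log10(control.channel("FSC-H")[positive], cfg.transform_floor)
    y = _floored_log10(control.channel("SSC-H")[positive], cfg.transform_floor)

    grid = cfg.density_grid
    counts, xe, ye = np.histogram2d(x, y, bins=grid)
    order = np.argsort(counts.ravel())[::-1]
    csum = np.cumsum(counts.ravel()[order])
    needed = cfg.density_mass * n_pos
    n_bins = int(np.searchsorted(csum, needed - 1e-9) + 1)
    chosen = order[:n_bins]
    ix, iy = np.unravel_index(chosen, counts.shape)
    # all four corners of each selected bin, so the hull covers the bins
    corners_x = np.concatenate([xe[ix], xe[ix + 1], xe[ix], xe[ix + 1]])
    corners_y = np.concatenate([ye[iy], ye[iy], ye[iy + 1], ye[iy + 1]])
    pts = np.column_stack([corners_x, corners_y])
    try:
        hull = ConvexHull(pts)
        vertices = tuple(map(tuple, pts[hull.vertices]))
        kind = "polygon"
    except QhullError:  # degenerate (collinear) control cloud
        vertices = ((pts[:, 0].min(), pts[:, 1].min()),
                    (pts[:, 0].max(), pts[:, 1].max()))
        kind = "rectangle"
    log.info("bacteria gate from %d SYTO9+ events (cut %.4g): %s with %d vertices",
             n_pos, cut, kind, len(vertices))
    return Gate(kind=kind, channels=("FSC-H", "SSC-H"), vertices=vertices,
                transform_tag="log10-floored", transform_floor=cfg.transform_floor)


def apply_gate(table: EventTable, gate: Gate) -> tuple[EventTable, int]:
    """Events inside the gate (boundary points count as inside).

    Raw intensities are transformed according to the gate's transform tag
    before the membership test.
    """
    xraw = table.channel(gate.channels[0])
    yraw = table.channel(gate.channels[1])
    if gate.transform_tag == "log10-floored":
        x = _floored_log10(xraw, gate.transform_floor)
        y = _floored_log10(yraw, gate.transform_floor)
    elif gate.transform_tag == "linear":
        x, y = xraw, yraw
    else:  # pragma: no cover - rejected at construction
        raise ValueError(f"cannot apply transform {gate.transform_tag!r}")
    if table.n_events == 0:
        return table, 0
    inside = gate.contains(x, y)
    return table.select(inside), int(inside.sum())
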