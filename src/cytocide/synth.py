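"""Synthetic cytometer: seeded event-cloud generator for pipeline testing.

The generator emulates a volumetric small-particle acquisition of a
disinfectant efficacy assay:

* a **growth control** (untreated bacteria after the ~4 h outgrowth,
  SYTO9-stained so the bacteria gate can be back-gated from green
  fluorescence),
* a **negative control** (no bacteria; instrument/debris noise only),
* one **treated** sample per concentration of a two-fold dilution ladder,
* optional **dual-stain** (SYTO9/PI) samples for live/dead/membrane-
  compromised quantification.

Bacterial scatter clusters are log-normal per channel with configurable
FSC/SSC correlation; debris is exponential in linear intensity space and
sits well below the bacteria cluster.  Dose dependence follows a Hill
survival curve ``s(c) = floor + (1-floor) / (1 + (c/c50)^hill)``.  Cells
killed by a membrane-disrupting disinfectant do not all remain intact
particles: the killed fraction is split between a "damaged" population
(shifted/broadened scatter) and fully lysed material (emitted as debris),
with the retained-particle fraction following a second Hill curve in dose.
Doublets are formed by summing random singlet pairs with separate area and
height gains, which inflates pulse area relative to height exactly as real
coincident particles do.

Everything is driven by a single integer seed; per-sample sub-streams are
derived by stable hashing of (role, concentration index) so each sample is
reproducible independently of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fcs_io import AcquisitionMeta, EventTable, CANONICAL_CHANNELS

__all__ = [
    "PopulationModel",
    "KillCurve",
    "SyntheticConfig",
    "default_populations",
    "simulate_sample",
    "simulate_experiment",
    "simulate_stained_sample",
]

_SCATTER = ("FSC-H", "SSC-H")
_FLUOR = ("FL1-H", "FL3-H")
_HEIGHTS = _SCATTER + _FLUOR

#: Unstained-cell fluorescence background (log10 mean, log10 sd).
BACKGROUND_FL = (1.3, 0.3)

#: Reference sampled volume (uL) at which ``n0_events`` is defined; expected
#: cell counts scale linearly with the sampled volume (hence with duration
#: at fixed flow rate).
REFERENCE_VOLUME_UL = 25.0


@dataclass(frozen=True)
class PopulationModel:
    """One event population in (FSC, SSC, FL1, FL3) pulse-height space.

    ``distribution='lognormal'`` draws log10 intensities from a normal with
    the given per-channel location/scale and an FSC/SSC correlation;
    ``'exponential'`` draws linear intensities from independent
    exponentials with the per-channel ``linear_scale`` (debris/noise).
    """

    name: str
    log10_mean: Mapping[str, float] = field(default_factory=dict)
    log10_sd: Mapping[str, float] = field(default_factory=dict)
    corr_fsc_ssc: float = 0.6
    weight: float = 1.0
    distribution: str = "lognormal"
    linear_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1 < self.corr_fsc_ssc < 1:
            raise ValueError("corr_fsc_ssc must be in (-1, 1)")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.distribution == "lognormal" and any(
            sd <= 0 for sd in self.log10_sd.values()
        ):
            raise ValueError("log10_sd values must be > 0")

    def draw_heights(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n x 4`` matrix of pulse heights over (FSC-H, SSC-H, FL1-H, FL3-H)."""
        if n == 0:
            return np.empty((0, 4))
        if self.distribution == "exponential":
            cols = [rng.exponential(self.linear_scale.get(ch, 25.0), size=n)
                    for ch in _HEIGHTS]
            return np.column_stack(cols)
        mu = np.array([self.log10_mean[ch] for ch in _HEIGHTS])
        sd = np.array([self.log10_sd[ch] for ch in _HEIGHTS])
        z = rng.standard_normal((n, 4))
        rho = self.corr_fsc_ssc
        z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
        return 10.0 ** (mu + sd * z)


@dataclass(frozen=True)
class KillCurve:
    """Hill-type dose-response for surviving fraction.

    ``survival(c) = floor + (1 - floor) / (1 + (c / c50)^hill)``; monotone
    non-increasing with ``survival(0) = 1``.
    """

    c50: float
    hill: float = 4.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.c50 <= 0:
            raise ValueError("c50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not 0 <= self.floor <= 1:
            raise ValueError("floor must be in [0, 1]")

    def survival(self, c: float) -> float:
        if c < 0:
            raise ValueError("concentration must be >= 0")
        if c == 0:
            return 1.0
        return self.floor + (1.0 - self.floor) / (1.0 + (c / self.c50) ** self.hill)


def default_populations() -> list[PopulationModel]:
    """Stock populations for a bacteria-vs-debris scatter scene.

    Intact bacteria form a compact high-scatter cluster (SYTO9-bright when
    stained); disinfectant-damaged cells sit ~0.3 log10 lower in forward
    scatter with 1.5x the side-scatter spread; debris is exponential and
    concentrated well below the bacteria cluster.
    """
    intact = PopulationModel(
        name="intact",
        log10_mean={"FSC-H": 4.3, "SSC-H": 4.0, "FL1-H": 4.0, "FL3-H": 1.6},
        log10_sd={"FSC-H": 0.15, "SSC-H": 0.15, "FL1-H": 0.25, "FL3-H": 0.3},
        corr_fsc_ssc=0.6,
    )
    damaged = PopulationModel(
        name="damaged",
        log10_mean={"FSC-H": 4.0, "SSC-H": 4.0, "FL1-H": 2.0, "FL3-H": 2.0},
        log10_sd={"FSC-H": 0.15, "SSC-H": 0.225, "FL1-H": 0.3, "FL3-H": 0.3},
        corr_fsc_ssc=0.6,
    )
    debris = PopulationModel(
        name="debris",
        distribution="exponential",
        linear_scale={"FSC-H": 250.0, "SSC-H": 150.0, "FL1-H": 30.0, "FL3-H": 25.0},
    )
    return [intact, damaged, debris]


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete description of one simulated assay.

    Defaults describe a plausible bench assay: ~500 bacteria-like events
    sampled in 25 uL before outgrowth, a ~30x outgrowth over the 4 h
    incubation, a six-step two-fold ladder, 5% doublets, modest green-to-red
    spillover and ~2 background events per second in the no-bacteria
    control.
    """

    seed: int = 0
    populations: Sequence[PopulationModel] = field(default_factory=default_populations)
    kill: KillCurve = field(default_factory=lambda: KillCurve(c50=2.0, hill=4.0))
    ladder: Sequence[float] = (10.0, 5.0, 2.5, 1.25, 0.625, 0.3125)
    n0_events: float = 500.0
    growth_factor: float = 30.0
    doublet_fraction: float = 0.05
    doublet_area_gain: float = 2.0
    doublet_height_gain: float = 1.3
    spillover: Sequence[Sequence[float]] = ((1.0, 0.05), (0.10, 1.0))
    nc_event_rate: float = 2.0
    acquisition: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    #: lysed-vs-retained split of killed cells: retained fraction follows
    #: 1 / (1 + (c / (lysis_c50_ratio * c50))^hill)
    lysis_c50_ratio: float = 1.0
    #: log-normal CV of the singlet pulse area around its height
    singlet_area_cv: float = 0.05

    def __post_init__(self) -> None:
        ladder = np.asarray(self.ladder, dtype=float)
        if ladder.size < 2:
            raise ValueError("ladder needs >= 2 concentrations")
        ratios = ladder[:-1] / ladder[1:]
        if np.any(ladder <= 0) or not np.allclose(ratios, 2.0, rtol=1e-9):
            raise ValueError("ladder must be strictly decreasing two-fold steps")
        if not 0 <= self.doublet_fraction <= 0.2:
            raise ValueError("doublet_fraction must be in [0, 0.2]")
        if self.growth_factor < 1:
            raise ValueError("growth_factor must be >= 1")
        if self.n0_events < 0 or self.nc_event_rate < 0:
            raise ValueError("event counts/rates must be >= 0")

    def population(self, name: str) -> PopulationModel:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"no population named {name!r}")

    def retained_fraction(self, c: float) -> float:
        """Fraction of killed cells that remain damaged particles (not lysed)."""
        if c <= 0:
            return 1.0
        c50 = self.lysis_c50_ratio * self.kill.c50
        return 1.0 / (1.0 + (c / c50) ** self.kill.hill)


def _rng_for(cfg: SyntheticConfig, label: str) -> np.random.Generator:
    """Stable per-sample RNG sub-stream keyed by (seed, label)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(key,)))


def _volume_scale(cfg: SyntheticConfig) -> float:
    return cfg.acquisition.volume_ul / REFERENCE_VOLUME_UL


def _heights_to_events(heights: np.ndarray, rng: np.random.Generator,
                       cfg: SyntheticConfig) -> np.ndarray:
    """Expand (FSC,SSC,FL1,FL3) heights to the full 8-channel H/A layout.

    Singlet pulse area tracks height with a small log-normal jitter.
    """
    n = heights.shape[0]
    jitter = np.exp(rng.normal(0.0, cfg.singlet_area_cv, size=(n, 4)))
    areas = heights * jitter
    out = np.empty((n, 8))
    for j, ch in enumerate(_HEIGHTS):
        col = CANONICAL_CHANNELS.index(ch)
        out[:, col] = heights[:, j]
        out[:, col + 1] = areas[:, j]  # the -A channel follows its -H
    return out


def _form_doublets(events: np.ndarray, cfg: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Replace random singlet pairs by summed doublet events.

    With doublet fraction f, d of the emitted events are doublets where
    d = f * N / (1 + f): each doublet consumes two singlets and emits one.
    """
    n = events.shape[0]
    d = int(round(cfg.doublet_fraction * n / (1.0 + cfg.doublet_fraction)))
    if d == 0 or n < 2 * d:
        return events
    idx = rng.permutation(n)
    a, b, rest = idx[:d], idx[d:2 * d], idx[2 * d:]
    pair_mean = 0.5 * (events[a] + events[b])
    doublets = pair_mean.copy()
    for j in range(0, 8, 2):
        doublets[:, j] = cfg.doublet_height_gain * pair_mean[:, j]
        doublets[:, j + 1] = cfg.doublet_area_gain * pair_mean[:, j + 1]
    return np.vstack([events[rest], doublets])


def _with_background_fl(pop: PopulationModel) -> PopulationModel:
    """Unstained variant of a cell population (fluorescence at background)."""
    if pop.distribution != "lognormal":
        return pop
    mu, sd = BACKGROUND_FL
    log10_mean = dict(pop.log10_mean)
    log10_sd = dict(pop.log10_sd)
    for ch in _FLUOR:
        log10_mean[ch] = mu
        log10_sd[ch] = sd
    return replace(pop, log10_mean=log10_mean, log10_sd=log10_sd)


_ROLES = ("treated", "growth_control", "negative_control", "unstained")


def simulate_sample(cfg: SyntheticConfig, concentration: float | None = None,
                    role: str = "treated") -> EventTable:
    """Draw one event table for the given assay role.

    * ``growth_control`` -- ~``n0_events * growth_factor`` SYTO9-stained
      intact cells plus background debris.
    * ``unstained`` -- the same cells with fluorescence at background (used
      to anchor the SYTO9-positive cut).
    * ``negative_control`` -- debris only, at ``nc_event_rate`` per second.
    * ``treated`` -- surviving intact cells per the kill curve, retained
      damaged particles, and debris augmented by lysed material.

    Counts are Poisson around their expectations; doublets are then formed
    from the cell events.  Events below any hardware-style threshold are
    still emitted -- thresholding belongs to the gating pipeline.
    """
    if role not in _ROLES:
        raise ValueError(f"role must be one of {_ROLES}")
    if (concentration is not None) != (role == "treated"):
        raise ValueError("concentration must be given exactly for role='treated'")
    ladder = np.asarray(cfg.ladder, dtype=float)
    if role == "treated":
        matches = np.isclose(ladder, concentration, rtol=1e-9)
        if not matches.any():
            raise ValueError(f"concentration {concentration} not in ladder {list(ladder)}")
        conc_index = int(np.argmax(matches))
        label = f"treated:{conc_index}"
    else:
        label = role
    rng = _rng_for(cfg, label)

    scale = _volume_scale(cfg)
    duration = cfg.acquisition.duration_s
    n_grown = cfg.n0_events * cfg.growth_factor * scale
    debris_mean = cfg.nc_event_rate * duration

    intact = cfg.population("intact")
    damaged = cfg.population("damaged")
    debris = cfg.population("debris")

    blocks: list[np.ndarray] = []
    n_cells = 0
    if role == "negative_control":
        n_debris = rng.poisson(debris_mean)
    elif role in ("growth_control", "unstained"):
        pop = intact if role == "growth_control" else _with_background_fl(intact)
        n_cells = rng.poisson(n_grown)
        blocks.append(pop.draw_heights(n_cells, rng))
        n_debris = rng.poisson(debris_mean)
    else:  # treated
        s = cfg.kill.survival(concentration)
        retained = cfg.retained_fraction(concentration)
        killed = cfg.n0_events * scale * (1.0 - s)
        n_surv = rng.poisson(n_grown * s)
        n_dam = rng.poisson(killed * retained)
        n_cells = n_surv + n_dam
        blocks.append(_with_background_fl(intact).draw_heights(n_surv, rng))
        blocks.append(damaged.draw_heights(n_dam, rng))
        n_debris = rng.poisson(debris_mean + killed * (1.0 - retained))
    blocks.append(debris.draw_heights(n_debris, rng))

    heights = np.vstack(blocks) if blocks else np.empty((0, 4))
    events = _heights_to_events(heights, rng, cfg)
    if n_cells and cfg.doublet_fraction > 0:
        cells = _form_doublets(events[:n_cells], cfg, rng)
        events = np.vstack([cells, events[n_cells:]])
    # arrival times are uniform over the acquisition, so event order is a
    # uniform shuffle of the draws
    events = events[rng.permutation(events.shape[0])]
    sample_id = label.replace(":", "_c")
    return EventTable(events, list(CANONICAL_CHANNELS), cfg.acquisition, sample_id)


def true_mbc(cfg: SyntheticConfig, threshold: float = 0.1) -> float | None:
    """Ground-truth MBC: lowest ladder concentration with survival < threshold.

    Returns ``None`` when even the highest tested concentration leaves more
    than the threshold fraction surviving (censored above the range).
    """
    called = None
    for c in sorted(cfg.ladder, reverse=True):
        if cfg.kill.survival(c) < threshold:
            called = c
        else:
            break
    return called


def simulate_experiment(cfg: SyntheticConfig) -> tuple[dict, dict]:
    """Simulate a full assay: controls plus one treated table per ladder step.

    Returns ``(tables, truth)`` where ``tables`` maps ``'growth_control'``,
    ``'negative_control'``, ``'unstained'`` and each concentration (float)
    to an :class:`EventTable`, and ``truth`` records the generator-side MBC
    and per-concentration surviving fractions for parameter-recovery tests.
    """
    tables: dict = {
        "growth_control": simulate_sample(cfg, role="growth_control"),
        "negative_control": simulate_sample(cfg, role="negative_control"),
        "unstained": simulate_sample(cfg, role="unstained"),
    }
    survival = {}
    for c in cfg.ladder:
        tables[float(c)] = simulate_sample(cfg, concentration=float(c))
        survival[float(c)] = cfg.kill.survival(float(c))
    mbc = true_mbc(cfg)
    truth = {
        "true_mbc": mbc,
        "true_mbc_index": (None if mbc is None
                           else int(np.argmax(np.isclose(cfg.ladder, mbc)))),
        "surviving_fraction": survival,
        "seed": cfg.seed,
    }
    return tables, truth


_STAIN_CLASSES = ("live", "dead", "injured", "debris")

#: log10 (mean, sd) of (FL1, FL3) for each dual-stain class: live cells are
#: SYTO9-bright with PI at background, dead cells PI-bright with green at
#: background (PI displaces/quenches SYTO9 in membrane-compromised cells),
#: injured (membrane-compromised, VBNC-candidate) cells bright in both.
_STAIN_FL = {
    "live": ((4.0, 0.25), (1.3, 0.3)),
    "dead": ((1.3, 0.3), (3.8, 0.25)),
    "injured": ((3.8, 0.25), (3.6, 0.25)),
}


def simulate_stained_sample(cfg: SyntheticConfig,
                            fractions: Sequence[float],
                            n_events: int = 5000) -> EventTable:
    """Dual-stain (SYTO9/PI) sample with known class fractions.

    ``fractions`` is (live, dead, injured, debris) and must sum to 1; the
    configured spillover matrix mixes the true (FL1, FL3) signals into the
    observed channels.  A heat-killed control corresponds to
    ``(0, 1 - debris, 0, debris)``.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 4 non-negative values summing to 1")
    spill = np.asarray(cfg.spillover, dtype=float)
    if spill.shape != (2, 2):
        raise ValueError("spillover must be a 2x2 matrix")
    label = "stained:" + ",".join(f"{v:.6g}" for v in fr)
    rng = _rng_for(cfg, label)
    counts = rng.multinomial(n_events, fr)

    intact = cfg.population("intact")
    debris = cfg.population("debris")
    blocks = []
    for cls, n in zip(_STAIN_CLASSES, counts):
        if cls == "debris":
            blocks.append(debris.draw_heights(n, rng))
            continue
        (mu1, sd1), (mu3, sd3) = _STAIN_FL[cls]
        pop = replace(
            intact,
            log10_mean={**dict(intact.log10_mean), "FL1-H": mu1, "FL3-H": mu3},
            log10_sd={**dict(intact.log10_sd), "FL1-H": sd1, "FL3-H": sd3},
        )
        blocks.append(pop.draw_heights(n, rng))
    heights = np.vstack(blocks)
    heights[:, 2:4] = heights[:, 2:4] @ spill  # optical mixing of (FL1, FL3)
    events = _heights_to_events(heights, rng, cfg)
    events = events[rng.permutation(events.shape[0])]
    return EventTable(events, list(CANONICAL_CHANNELS), cfg.acquisition,
                      "stained")
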