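"""End-to-end orchestration: sample plan in, structured efficacy report out.

A :class:`SamplePlan` maps each acquisition (a file, or a synthetic
reference) to its (strain, disinfectant) assay, role and concentration.
:func:`run_pipeline` then runs, per assay:

    threshold -> doublet exclusion -> bacteria gate -> count rate
    -> control normalization -> MBC call

and emits one JSON-serializable report with a per-sample event-count audit
trail (raw >= post-threshold >= post-doublet >= gated).  Reports are
deterministic given the plan and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .dose_response import DilutionLadder, call_mbc
from .fcs_io import AcquisitionMeta, EventTable, read_events
from .gating import (GatingConfig, apply_event_threshold, apply_gate,
                     build_bacteria_gate, exclude_doublets)
from .quantify import CountResult, count_rate, normalize_rate
from .synth import KillCurve, SyntheticConfig, simulate_sample

__all__ = ["PlanRow", "SamplePlan", "PlanValidationError", "run_pipeline"]

_ROLES = ("treated", "growth_control", "negative_control", "unstained",
          "single_stain", "heat_killed")


class PlanValidationError(ValueError):
    """The sample plan violates the assay structure; lists offending rows."""


@dataclass(frozen=True)
class PlanRow:
    strain: str
    disinfectant: str
    role: str
    source: str = "synthetic"  # file path, or the literal "synthetic"
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}")


@dataclass
class SamplePlan:
    rows: list[PlanRow]
    gating: GatingConfig = field(default_factory=GatingConfig)
    threshold: float = 0.1
    policy: str = "strict"
    seed: int = 0
    synthetic: SyntheticConfig | None = None

    def assays(self) -> dict[tuple[str, str], list[PlanRow]]:
        groups: dict[tuple[str, str], list[PlanRow]] = {}
        for row in self.rows:
            groups.setdefault((row.strain, row.disinfectant), []).append(row)
        return groups

    def validate(self) -> None:
        problems: list[str] = []
        if not self.rows:
            problems.append("plan has no rows")
        for (strain, dis), rows in self.assays().items():
            tag = f"assay ({strain}, {dis})"
            for role in ("growth_control", "negative_control"):
                n = sum(r.role == role for r in rows)
                if n != 1:
                    problems.append(f"{tag}: needs exactly one {role}, has {n}")
            conc = sorted((r.concentration for r in rows if r.role == "treated"),
                          reverse=True)
            if any(c is None for c in conc):
                problems.append(f"{tag}: treated rows must carry a concentration")
            elif conc:
                if len(conc) < 2:
                    problems.append(f"{tag}: ladder needs >= 2 concentrations")
                elif any(abs(a / b - 2.0) > 1e-9 for a, b in zip(conc, conc[1:])):
                    problems.append(f"{tag}: concentrations {conc} are not "
                                    "two-fold descending")
            if any(r.source == "synthetic" for r in rows) and self.synthetic is None:
                problems.append(f"{tag}: synthetic rows but no synthetic config")
        if problems:
            raise PlanValidationError("; ".join(problems))

    # -- construction -----------------------------------------------------

    @classmethod
    def synthetic_default(cls, seed: int = 0,
                          cfg: SyntheticConfig | None = None,
                          strain: str = "strain1",
                          disinfectant: str = "disinfectantA") -> "SamplePlan":
        """A complete single-assay plan over the synthetic generator."""
        cfg = replace(cfg, seed=seed) if cfg is not None else SyntheticConfig(seed=seed)
        rows = [
            PlanRow(strain, disinfectant, "growth_control"),
            PlanRow(strain, disinfectant, "negative_control"),
            PlanRow(strain, disinfectant, "unstained"),
        ]
        rows += [PlanRow(strain, disinfectant, "treated", concentration=float(c))
                 for c in cfg.ladder]
        return cls(rows=rows, seed=seed, synthetic=cfg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SamplePlan":
        payload = yaml.safe_load(Path(path).read_text())
        rows = [PlanRow(**row) for row in payload.get("rows", [])]
        gating = GatingConfig(**payload.get("gating", {}))
        synth_cfg = None
        if "synthetic" in payload:
            synth_cfg = _synthetic_from_dict(payload["synthetic"])
        return cls(
            rows=rows,
            gating=gating,
            threshold=float(payload.get("threshold", 0.1)),
            policy=payload.get("policy", "strict"),
            seed=int(payload.get("seed", 0)),
            synthetic=synth_cfg,
        )


def _synthetic_from_dict(payload: dict) -> SyntheticConfig:
    payload = dict(payload)
    if "kill" in payload:
        payload["kill"] = KillCurve(**payload["kill"])
    if "acquisition" in payload:
        payload["acquisition"] = AcquisitionMeta(**payload["acquisition"])
    if "ladder" in payload:
        payload["ladder"] = tuple(float(c) for c in payload["ladder"])
    return SyntheticConfig(**payload)


def _load_table(row: PlanRow, plan: SamplePlan) -> EventTable:
    if row.source == "synthetic":
        return simulate_sample(plan.synthetic, row.concentration, row.role)
    return read_events(row.source)


def _process(table: EventTable, plan: SamplePlan,
             gate=None) -> tuple[EventTable, dict[str, int]]:
    """Threshold -> doublets -> (optional) gate; returns table + audit."""
    audit = {"raw": table.n_events}
    table = apply_event_threshold(table, plan.gating)
    audit["post_threshold"] = table.n_events
    table, _, _ = exclude_doublets(table, plan.gating)
    audit["post_doublet"] = table.n_events
    if gate is not None:
        table, n_inside = apply_gate(table, gate)
        audit["gated"] = n_inside
    return table, audit


def run_pipeline(plan: SamplePlan) -> dict[str, Any]:
    """Run every assay in the plan and return the structured report."""
    plan.validate()
    report: dict[str, Any] = {
        "version": __version__,
        "seed": plan.seed,
        "threshold": plan.threshold,
        "policy": plan.policy,
        "gating": asdict(plan.gating),
        "assays": {},
    }
    for (strain, dis), rows in plan.assays().items():
        by_role = {r.role: r for r in rows if r.role != "treated"}
        treated = sorted((r for r in rows if r.role == "treated"),
                         key=lambda r: -r.concentration)

        pc_raw = _load_table(by_role["growth_control"], plan)
        nc_raw = _load_table(by_role["negative_control"], plan)
        unstained = (_load_table(by_role["unstained"], plan)
                     if "unstained" in by_role else None)

        pc_pre, pc_audit = _process(pc_raw, plan)
        gate = build_bacteria_gate(pc_pre, unstained, plan.gating)
        pc_gated, n_pc = apply_gate(pc_pre, gate)
        pc_audit["gated"] = n_pc

        audit = {"growth_control": pc_audit}
        acq = pc_raw.acquisition
        rate_pc = count_rate(n_pc, acq)

        _, nc_audit = _process(nc_raw, plan, gate)
        audit["negative_control"] = nc_audit
        rate_nc = count_rate(nc_audit["gated"], nc_raw.acquisition)

        results: dict[float, CountResult] = {}
        counts_rows = []
        for row in treated:
            table = _load_table(row, plan)
            _, t_audit = _process(table, plan, gate)
            audit[f"treated_{row.concentration:g}"] = t_audit
            rate = count_rate(t_audit["gated"], table.acquisition)
            normalized = normalize_rate(rate, rate_nc, rate_pc)
            result = CountResult(
                sample_id=table.sample_id or f"treated_{row.concentration:g}",
                n_gated=t_audit["gated"],
                duration_s=table.acquisition.duration_s,
                rate=rate, normalized=normalized,
                role="treated", concentration=row.concentration,
            )
            results[float(row.concentration)] = result
            counts_rows.append(vars(result).copy())

        ladder = DilutionLadder(
            disinfectant=dis, strain=strain,
            concentrations=[float(r.concentration) for r in treated],
            results=results,
            pc=CountResult("PC", n_pc, acq.duration_s, rate_pc, 1.0,
                           role="growth_control"),
            nc=CountResult("NC", nc_audit["gated"], nc_raw.acquisition.duration_s,
                           rate_nc, 0.0, role="negative_control"),
        )
        mbc = call_mbc(ladder, plan.threshold, plan.policy)
        report["assays"][f"{strain}|{dis}"] = {
            "strain": strain,
            "disinfectant": dis,
            "rate_pc": rate_pc,
            "rate_nc": rate_nc,
            "counts": counts_rows,
            "audit": audit,
            "mbc_call": {
                "status": mbc.status,
                "mbc": mbc.mbc,
                "below_range": mbc.below_range,
                "threshold_used": mbc.threshold_used,
                "policy": mbc.policy,
                "labels": {f"{c:g}": lab for c, lab in mbc.labels.items()},
            },
        }
    return report
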