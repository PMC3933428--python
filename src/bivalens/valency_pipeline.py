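"""Dock → buried-surface → classify over ensembles; fraction aggregation.

For every frame of a dimer ensemble, a ligand is docked onto each monomer
from the binding-mode template, the surface area buried between the two
docked ligands (by default restricted to their carboxy-terminal domains) is
computed, and the frame is called bivalent-competent when that area is at
or below a small zero tolerance — zero buried surface means no steric
contact between the ligands, so both binding sites could be occupied
simultaneously.  Per-trajectory bivalent fractions are averaged across
trajectories with equal weight per trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import (DEFAULT_RADII, Ensemble, Selection, Structure,
                           assign_radii)
from .surface import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, buried_surface
from .template_docking import (DEFAULT_FIT_RMSD_CEILING, BindingTemplate,
                               DockedComplex, dock_dimer)

#: Buried areas at or below this (Å²) count as "no buried surface".
DEFAULT_ZERO_TOLERANCE = 1.0

ScoringMode = Literal["cterm_domain", "whole_ligand"]


@dataclass
class PipelineConfig:
    """All tunables of the per-frame classification, with defaults."""

    scoring_mode: ScoringMode = "cterm_domain"
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = DEFAULT_N_POINTS
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE
    fit_rmsd_ceiling: float = DEFAULT_FIT_RMSD_CEILING
    frame_stride: int = 1
    radius_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self):
        if self.scoring_mode not in ("cterm_domain", "whole_ligand"):
            raise ValueError("scoring_mode must be 'cterm_domain' or "
                             "'whole_ligand'")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be nonnegative")


@dataclass
class FrameValencyRecord:
    """Classification result for one sampled frame."""

    trajectory_id: str
    frame_index: int
    frame_time: float        # ns
    buried_area: float       # Å²
    bivalent_competent: bool
    fit_rmsd_1: float        # Å
    fit_rmsd_2: float        # Å
    dock_quality_ok: bool = True


@dataclass
class EnsembleSummary:
    """Bivalent fractions per trajectory and their cross-trajectory mean."""

    per_trajectory_fraction: dict[str, float]
    mean_fraction: float
    weighted_mean_fraction: float
    n_frames_per_trajectory: dict[str, int]
    zero_tolerance: float
    records: list[FrameValencyRecord]

    def to_json(self, config: PipelineConfig | None = None) -> str:
        payload = {
            "per_trajectory_fraction": self.per_trajectory_fraction,
            "mean_fraction": self.mean_fraction,
            "weighted_mean_fraction": self.weighted_mean_fraction,
            "n_frames_per_trajectory": self.n_frames_per_trajectory,
            "zero_tolerance_A2": self.zero_tolerance,
            "n_dock_quality_flagged": sum(
                0 if r.dock_quality_ok else 1 for r in self.records),
        }
        if config is not None:
            payload["config"] = {
                "scoring_mode": config.scoring_mode,
                "probe_radius_A": config.probe_radius,
                "n_sphere_points": config.n_sphere_points,
                "zero_tolerance_A2": config.zero_tolerance,
                "fit_rmsd_ceiling_A": config.fit_rmsd_ceiling,
                "frame_stride": config.frame_stride,
            }
        return json.dumps(payload, indent=2, sort_keys=True)


def records_to_dataframe(records: Sequence[FrameValencyRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "trajectory_id": [r.trajectory_id for r in records],
        "frame_index": [r.frame_index for r in records],
        "time_ns": [r.frame_time for r in records],
        "buried_area_A2": [r.buried_area for r in records],
        "bivalent_competent": [r.bivalent_competent for r in records],
        "fit_rmsd_1_A": [r.fit_rmsd_1 for r in records],
        "fit_rmsd_2_A": [r.fit_rmsd_2 for r in records],
        "dock_quality_ok": [r.dock_quality_ok for r in records],
    })


def _scoring_coords(docked: DockedComplex, ligand: Structure,
                    mode: ScoringMode,
                    radius_table: dict[str, float],
                    ) -> tuple[np.ndarray, np.ndarray]:
    lig = assign_radii(ligand, radius_table)
    if mode == "cterm_domain" and docked.cterm_mask.size == len(lig):
        keep = docked.cterm_mask
    else:
        keep = np.ones(len(lig), dtype=bool)
    return lig.coord[keep], lig.radius[keep]


def classify_frame(frame: Structure, monomer_1: Selection,
                   monomer_2: Selection, template: BindingTemplate,
                   config: PipelineConfig | None = None,
                   trajectory_id: str = "traj", frame_index: int = 0,
                   frame_time: float | None = None) -> FrameValencyRecord:
    """Dock both ligands onto one frame and apply the zero-tolerance rule.

    ``bivalent_competent`` is True iff the buried area between the two
    docked ligands' scoring selections is ≤ ``config.zero_tolerance``
    (inclusive: a frame exactly at tolerance counts as bivalent-competent).
    """
    config = config or PipelineConfig()
    import warnings as _warnings
    from .errors import DockQualityWarning
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", DockQualityWarning)
        docked = dock_dimer(frame, monomer_1, monomer_2, template,
                            fit_rmsd_ceiling=config.fit_rmsd_ceiling)
    quality_ok = not any(
        issubclass(w.category, DockQualityWarning) for w in caught)
    ca, ra = _scoring_coords(docked, docked.ligand_1, config.scoring_mode,
                             config.radius_table)
    cb, rb = _scoring_coords(docked, docked.ligand_2, config.scoring_mode,
                             config.radius_table)
    buried = buried_surface(ca, ra, cb, rb,
                            probe_radius=config.probe_radius,
                            n_sphere_points=config.n_sphere_points)
    return FrameValencyRecord(
        trajectory_id=trajectory_id,
        frame_index=frame_index,
        frame_time=float(frame_index if frame_time is None else frame_time),
        buried_area=buried.value,
        bivalent_competent=buried.value <= config.zero_tolerance,
        fit_rmsd_1=docked.fit_rmsd_1,
        fit_rmsd_2=docked.fit_rmsd_2,
        dock_quality_ok=quality_ok,
    )


def analyze_ensemble(ensemble: Ensemble, monomer_1: Selection,
                     monomer_2: Selection, template: BindingTemplate,
                     config: PipelineConfig | None = None,
                     ) -> list[FrameValencyRecord]:
    """Classify every ``frame_stride``-th frame of an ensemble, in order."""
    config = config or PipelineConfig()
    records = []
    for k in range(0, len(ensemble), config.frame_stride):
        records.append(classify_frame(
            ensemble.frames[k], monomer_1, monomer_2, template, config,
            trajectory_id=ensemble.trajectory_id, frame_index=k,
            frame_time=ensemble.time_of(k)))
    return records


def summarize(trajectory_records: Mapping[str, Sequence[FrameValencyRecord]],
              zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
              ) -> EnsembleSummary:
    """Aggregate per-frame records into bivalent fractions.

    Each trajectory's fraction is (# bivalent-competent frames)/(# frames);
    ``mean_fraction`` is the unweighted arithmetic mean over trajectories
    (each trajectory counts equally regardless of length), and
    ``weighted_mean_fraction`` pools all frames.
    """
    if not trajectory_records:
        raise ValueError("need at least one trajectory")
    fractions: dict[str, float] = {}
    counts: dict[str, int] = {}
    all_records: list[FrameValencyRecord] = []
    for traj_id, records in trajectory_records.items():
        records = list(records)
        if not records:
            raise ValueError(f"trajectory {traj_id!r} has no records")
        n_biv = sum(1 for r in records if r.bivalent_competent)
        fractions[traj_id] = n_biv / len(records)
        counts[traj_id] = len(records)
        all_records.extend(records)
    mean = float(np.mean(list(fractions.values())))
    weighted = (sum(1 for r in all_records if r.bivalent_competent)
                / len(all_records))
    return EnsembleSummary(
        per_trajectory_fraction=fractions,
        mean_fraction=mean,
        weighted_mean_fraction=float(weighted),
        n_frames_per_trajectory=counts,
        zero_tolerance=zero_tolerance,
        records=all_records,
    )
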