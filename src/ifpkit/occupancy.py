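"""Occupancy statistics, heat-map matrices and RMSD traces.

Occupancy of an interaction channel is the percent of trajectory frames in
which the channel's geometric criteria are satisfied. No autocorrelation
correction is applied: frames are counted as-is, matching the plain
percent-of-frames definition used in MD contact analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

from ifpkit.errors import ConfigurationError
from ifpkit.geometry import kabsch_superpose, rmsd
from ifpkit.interactions import Channel, InteractionSpec, evaluate_channel
from ifpkit.trajectory import Trajectory, resolve_selection

__all__ = [
    "EventMatrix",
    "OccupancyReport",
    "build_event_matrix",
    "occupancy",
    "heatmap_matrix",
    "rmsd_trace",
]


@dataclass
class EventMatrix:
    """frames x channels boolean matrix of per-frame interaction events."""

    values: np.ndarray  # (n_frames, n_channels) bool
    channel_labels: list
    frame_labels: Optional[list] = None
    spec: Optional[InteractionSpec] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ConfigurationError("event matrix must be 2-D (frames x channels)")
        if self.values.shape[1] != len(self.channel_labels):
            raise ConfigurationError(
                f"{self.values.shape[1]} columns but {len(self.channel_labels)} labels")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_labels,
                            index=self.frame_labels)


@dataclass
class OccupancyReport:
    """Per-channel occupancy percentages for one compound/trajectory.

    ``occupancy_percent`` is exactly ``100 * event_count / frame_count``
    (kept as an exact rational internally; the float view rounds only at
    formatting time, reported to one decimal place in rendered tables).
    """

    compound: str
    channel_labels: list
    event_counts: list
    frame_count: int
    spec: InteractionSpec = field(default_factory=InteractionSpec)

    def __post_init__(self):
        if self.frame_count < 1:
            raise ConfigurationError("occupancy undefined for zero frames")
        if len(self.event_counts) != len(self.channel_labels):
            raise ConfigurationError("event count / label length mismatch")

    def occupancy_exact(self, label) -> Fraction:
        i = self.channel_labels.index(label)
        return Fraction(100 * int(self.event_counts[i]), self.frame_count)

    @property
    def occupancy_percent(self) -> dict:
        return {lab: float(Fraction(100 * int(c), self.frame_count))
                for lab, c in zip(self.channel_labels, self.event_counts)}

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy_percent
        return pd.DataFrame({
            "compound": self.compound,
            "channel": self.channel_labels,
            "occupancy_percent": [occ[lab] for lab in self.channel_labels],
            "event_count": [int(c) for c in self.event_counts],
            "frame_count": self.frame_count,
        })

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "frame_count": self.frame_count,
            "channels": [
                {"channel": lab, "event_count": int(c),
                 "occupancy_percent": float(Fraction(100 * int(c), self.frame_count))}
                for lab, c in zip(self.channel_labels, self.event_counts)
            ],
            "spec": self.spec.to_dict(),
        }


def build_event_matrix(traj: Trajectory, channels, spec: InteractionSpec,
                       allow_no_hydrogen: bool = False) -> EventMatrix:
    """Evaluate every channel on every frame of a trajectory."""
    cols = [evaluate_channel(traj, ch, spec, allow_no_hydrogen=allow_no_hydrogen)
            for ch in channels]
    values = (np.column_stack(cols) if cols
              else np.empty((traj.n_frames, 0), dtype=bool))
    return EventMatrix(values=values, channel_labels=[ch.label for ch in channels],
                       frame_labels=(list(traj.frame_labels)
                                     if traj.frame_labels is not None else None),
                       spec=spec)


def occupancy(matrix: EventMatrix, compound: str = "compound") -> OccupancyReport:
    """Percent-of-frames occupancy per channel of an event matrix."""
    if matrix.n_frames < 1:
        raise ConfigurationError("occupancy undefined for zero frames")
    counts = matrix.values.sum(axis=0).tolist()
    return OccupancyReport(compound=compound,
                           channel_labels=list(matrix.channel_labels),
                           event_counts=counts, frame_count=matrix.n_frames,
                           spec=matrix.spec or InteractionSpec())


def heatmap_matrix(reports) -> pd.DataFrame:
    """compounds x channels occupancy matrix from a list of reports.

    Channels missing from a compound's report are NaN (an empty CSV cell),
    deliberately distinct from an observed 0% occupancy. Row order follows
    the input; column order is first-seen order across reports.
    """
    labels = [r.compound for r in reports]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate compound labels in {labels}")
    columns: list = []
    for r in reports:
        for lab in r.channel_labels:
            if lab not in columns:
                columns.append(lab)
    data = []
    for r in reports:
        occ = r.occupancy_percent
        data.append([occ.get(c, np.nan) for c in columns])
    return pd.DataFrame(data, index=pd.Index(labels, name="compound"),
                        columns=columns)


def rmsd_trace(traj: Trajectory, reference_frame: int = 0,
               fit_selection: str = "* * N,CA,C,O",
               report_selection: str = "LIG * *") -> np.ndarray:
    """Per-frame RMSD trace after superposition on a reference frame.

    Each frame is rigidly superposed onto ``reference_frame`` using the
    atoms of ``fit_selection`` (default: protein backbone N, CA, C, O), and
    the RMSD of ``report_selection`` (default: the ligand) is reported after
    applying that transform. Selections are a selector string or a list of
    selector strings (union of matches), syntax as in
    :func:`ifpkit.trajectory.resolve_selection`, with ``*`` allowed for the
    residue name.
    """
    if not 0 <= reference_frame < traj.n_frames:
        raise ConfigurationError(
            f"reference_frame {reference_frame} out of range (n_frames={traj.n_frames})")
    fit_idx = _resolve_loose(traj, fit_selection)
    rep_idx = _resolve_loose(traj, report_selection)
    if len(fit_idx) < 3:
        raise ConfigurationError(
            f"fit selection resolves to {len(fit_idx)} atoms; superposition needs >= 3")
    ref_fit = traj.coords[reference_frame][fit_idx]
    ref_rep = traj.coords[reference_frame][rep_idx]
    trace = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[i][fit_idx], ref_fit)
        moved = traj.coords[i][rep_idx] @ R.T + t
        trace[i] = rmsd(moved, ref_rep)
    return trace


def _resolve_loose(traj: Trajectory, selector):
    """resolve_selection, additionally allowing '*' residue names and lists."""
    if isinstance(selector, (list, tuple)):
        seen = []
        for sel in selector:
            for i in _resolve_loose(traj, sel):
                if i not in seen:
                    seen.append(i)
        return sorted(seen, key=lambda i: traj.atoms[i].serial)
    tokens = selector.split()
    if tokens and tokens[0] == "*":
        names = None
        if len(tokens) == 3 and tokens[2] != "*":
            names = {n.strip() for n in tokens[2].split(",")}
        hits = [(a.serial, i) for i, a in enumerate(traj.atoms)
                if names is None or a.name in names]
        if not hits:
            from ifpkit.errors import SelectionError
            raise SelectionError(f"selector {selector!r} matched no atoms")
        return [i for _, i in sorted(hits)]
    return resolve_selection(traj, selector)
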