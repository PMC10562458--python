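"""Larval locomotion analysis for the bright/dark photomotor assay.

Larvae are recorded in a 96-well plate under a programmed light cycle:
an accommodation period in the dark followed by alternating dark and
bright phases.  The tracking system exports one row per larva per
1-minute bin (velocity, distance moved, moving duration).  This module
annotates those bins with the light schedule, computes per-phase medians
and the logarithmic bright/dark velocity ratio used as a locomotor
light-response index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHASE_LABELS = ("accommodation", "dark", "bright")

#: Offset added to both velocities before taking the log ratio, so that
#: zero-activity larvae still yield a finite ratio.
RATIO_OFFSET = 0.001


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered light-cycle phases, each a (label, whole minutes) pair.

    The default protocol is 30 min dark accommodation followed by six
    cycles of 10 min dark / 10 min bright, 150 min (2.5 h) in total.
    """

    phases: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for label, minutes in self.phases:
            if label not in PHASE_LABELS:
                raise ValueError(f"unknown phase label {label!r}")
            if not (isinstance(minutes, (int, np.integer)) and minutes > 0):
                raise ValueError("phase durations must be positive whole minutes")

    @classmethod
    def default(cls) -> "PhaseSchedule":
        phases = [("accommodation", 30)]
        for _ in range(6):
            phases += [("dark", 10), ("bright", 10)]
        return cls(tuple(phases))

    @property
    def total_minutes(self) -> int:
        return sum(m for _, m in self.phases)

    def per_minute_labels(self) -> np.ndarray:
        """Phase label of every 1-minute bin, index 0 = first minute.

        Phase boundaries are half-open [start, end): a bin belongs to the
        phase containing its start minute.
        """
        out: list[str] = []
        for label, minutes in self.phases:
            out.extend([label] * minutes)
        return np.asarray(out, dtype=object)

    @classmethod
    def from_dict(cls, spec: Sequence) -> "PhaseSchedule":
        """Build from a YAML-friendly list of [label, minutes] pairs."""
        return cls(tuple((str(l), int(m)) for l, m in spec))


@dataclass
class BehaviorSummary:
    """Per-larva medians by phase plus the log bright/dark velocity ratio.

    Fields belonging to a phase that is absent from the track are None
    and the missing phase is recorded in ``missing_phases``.
    """

    velocity_dark: float | None = None
    velocity_bright: float | None = None
    moving_duration_dark: float | None = None
    moving_duration_bright: float | None = None
    distance_dark: float | None = None
    distance_bright: float | None = None
    accommodation_activity: float | None = None
    log_bright_dark_ratio: float | None = None
    missing_phases: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "velocity_dark": self.velocity_dark,
            "velocity_bright": self.velocity_bright,
            "moving_duration_dark": self.moving_duration_dark,
            "moving_duration_bright": self.moving_duration_bright,
            "distance_dark": self.distance_dark,
            "distance_bright": self.distance_bright,
            "accommodation_activity": self.accommodation_activity,
            "log_bright_dark_ratio": self.log_bright_dark_ratio,
        }


def annotate_phases(track: pd.DataFrame, schedule: PhaseSchedule) -> pd.DataFrame:
    """Label each 1-minute bin of a track with its light-cycle phase.

    ``track`` needs a ``bin_index`` column (0-based minute index); bins
    beyond the schedule are an error, schedule beyond the track is
    ignored with a warning.
    """
    labels = schedule.per_minute_labels()
    out = track.copy()
    if len(out) == 0:
        out["phase"] = pd.Series(dtype=object)
        return out
    if "bin_index" in out.columns:
        idx = out["bin_index"].to_numpy(dtype=int)
    else:
        idx = np.arange(len(out))
    if idx.min() < 0:
        raise ValueError("bin_index must be non-negative")
    if idx.max() >= len(labels):
        raise ValueError(
            f"track has bins up to {idx.max()} but schedule covers only "
            f"{len(labels)} minutes"
        )
    if idx.max() + 1 < len(labels):
        warnings.warn(
            f"schedule covers {len(labels)} min but track ends at bin "
            f"{idx.max()}; trailing schedule ignored",
            stacklevel=2,
        )
    out["phase"] = labels[idx]
    return out


def log_bright_dark_ratio(v_bright: float, v_dark: float) -> float:
    """ln((v_bright + 0.001) / (v_dark + 0.001)).

    The offset is applied to both values unconditionally so the ratio is
    finite for any non-negative velocities and exactly 0 when both are 0.
    """
    if v_bright < 0 or v_dark < 0:
        raise ValueError("velocities must be non-negative")
    return math.log((v_bright + RATIO_OFFSET) / (v_dark + RATIO_OFFSET))


def phase_medians(annotated: pd.DataFrame) -> BehaviorSummary:
    """Per-phase medians of velocity, moving duration and distance.

    The accommodation activity is the median velocity during the
    accommodation phase.  The bright/dark ratio is left unset; use
    :func:`summarize_larva` for the full summary.
    """
    if "phase" not in annotated.columns:
        raise ValueError("track must be annotated with phases first")
    summary = BehaviorSummary()
    for phase in ("dark", "bright"):
        sub = annotated[annotated["phase"] == phase]
        if len(sub) == 0:
            summary.missing_phases.append(phase)
            continue
        setattr(summary, f"velocity_{phase}", float(sub["velocity"].median()))
        if "moving_duration" in sub.columns:
            setattr(
                summary,
                f"moving_duration_{phase}",
                float(sub["moving_duration"].median()),
            )
        if "distance" in sub.columns:
            setattr(summary, f"distance_{phase}", float(sub["distance"].median()))
    acc = annotated[annotated["phase"] == "accommodation"]
    if len(acc) == 0:
        summary.missing_phases.append("accommodation")
    else:
        summary.accommodation_activity = float(acc["velocity"].median())
    return summary


def summarize_larva(
    track: pd.DataFrame, schedule: PhaseSchedule | None = None
) -> BehaviorSummary:
    """Annotate a single larva's track and compute the full summary."""
    schedule = schedule or PhaseSchedule.default()
    annotated = (
        track if "phase" in track.columns else annotate_phases(track, schedule)
    )
    summary = phase_medians(annotated)
    if summary.velocity_bright is not None and summary.velocity_dark is not None:
        summary.log_bright_dark_ratio = log_bright_dark_ratio(
            summary.velocity_bright, summary.velocity_dark
        )
    return summary


def read_tracks(path) -> pd.DataFrame:
    """Read a 1-min binned tracking export (CSV).

    Expected columns: larva_id, bin_index, velocity, distance,
    moving_duration — the long-format flattening of the per-well sheets
    the tracking software exports.
    """
    df = pd.read_csv(path)
    required = {"larva_id", "bin_index", "velocity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracking export lacks columns: {sorted(missing)}")
    return df


def summarize_tracks(
    tracks: pd.DataFrame,
    schedule: PhaseSchedule | None = None,
    exclude: Iterable | None = None,
) -> pd.DataFrame:
    """Per-larva behavior summaries for a long-format multi-larva table.

    ``exclude`` lists larva_ids flagged by visual inspection of the raw
    movies (mis-tracked wells); they are dropped, not zeroed.
    """
    schedule = schedule or PhaseSchedule.default()
    excluded = set(exclude) if exclude is not None else set()
    rows = []
    for larva_id, sub in tracks.groupby("larva_id", sort=True):
        if larva_id in excluded:
            continue
        summary = summarize_larva(sub.sort_values("bin_index"), schedule)
        rows.append({"larva_id": larva_id, **summary.as_dict()})
    return pd.DataFrame(rows)
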