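"""Synthetic inputs with known ground truth for every pipeline stage.

The screening pipeline consumes fluorescence movies of the beating
embryonic heart, trunk projections of the intersegmental vessels (ISVs),
1-min binned locomotion tables, plate-structured per-larva measurement
tables and qPCR Ct tables.  Each generator here emulates one of those
acquisitions with configurable parameters and returns the ground truth
alongside, so every downstream stage can be verified by parameter
recovery without any microscope or tracking hardware.

All generators are deterministic: the same config and seed produce
bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .behavior import PhaseSchedule, log_bright_dark_ratio

# --------------------------------------------------------------------------
# heart movies
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HeartSimConfig:
    """Two-chamber pulsating heart movie.

    The ventricle is a filled ellipse whose area oscillates sinusoidally
    between the end-systolic area ``esv`` and the end-diastolic area
    ``edv`` at ``beat_rate``; the atrium is a second ellipse in
    anti-phase, scaled by ``atrium_scale``.  Intensities are additive
    Gaussian around a bright foreground on a dark background.  The frame
    rate is explicit metadata — every rate the pipeline reports carries
    its time base from here.
    """

    n_frames: int = 100
    fps: float = 20.0
    beat_rate: float = 2.0          # beats per second
    edv: float = 3000.0             # end-diastolic ventricle area, px^2
    esv: float = 1500.0             # end-systolic ventricle area, px^2
    atrium_scale: float = 0.8
    noise_sd: float = 0.0           # intensity units
    pixel_size: float = 1.0         # um per px
    seed: int = 0
    image_shape: tuple[int, int] = (192, 192)
    intensity_fg: float = 200.0
    intensity_bg: float = 10.0
    aspect: float = 1.5             # ventricle major/minor axis ratio

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0 <= self.esv <= self.edv):
            raise ValueError("require 0 <= esv <= edv")
        if self.beat_rate >= self.fps / 2:
            raise ValueError(
                f"beat_rate {self.beat_rate}/s violates the Nyquist limit for "
                f"fps {self.fps} (need beat_rate < fps/2)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class HeartMovie:
    """A simulated heart movie plus its ground truth."""

    stack: np.ndarray                  # (n_frames, rows, cols) float32
    area_trace: pd.DataFrame           # frame, time_s, ventricle_area, atrium_area
    true_ef: float                     # percent, from the EF formula on (edv, esv)
    true_beat_count: int               # ventricle-area maxima within the movie
    heart_mask: np.ndarray             # bool, union of both chambers at max extent
    config: HeartSimConfig


def _ellipse_mask(shape, center, area, aspect) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if area <= 0:
        return mask
    semi_major = math.sqrt(area * aspect / math.pi)
    semi_minor = semi_major / aspect
    rr, cc = _draw_ellipse(center[0], center[1], semi_minor, semi_major, shape=shape)
    mask[rr, cc] = True
    return mask


def make_heart_movie(config: HeartSimConfig) -> HeartMovie:
    """Render a heart movie with analytically known area trace and EF.

    The ventricle area at time t is
    ``esv + (edv - esv) * (1 + cos(2*pi*beat_rate*(t - t0))) / 2`` with
    the recording starting two frames before the first end-diastole
    (t0 = 2/fps), so every systolic minimum and diastolic maximum lies
    strictly inside the window, comfortably away from its edges.  True
    EF is the EF formula applied exactly to (edv, esv); the true beat
    count is the number of diastolic maxima within the movie.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    t = np.arange(config.n_frames) / config.fps
    t0 = 2.0 / config.fps
    phase = 2 * math.pi * config.beat_rate * (t - t0)
    v_area = config.esv + (config.edv - config.esv) * (1 + np.cos(phase)) / 2
    a_area = config.atrium_scale * (
        config.esv + (config.edv - config.esv) * (1 - np.cos(phase)) / 2
    )
    v_center = (int(rows * 0.33), cols // 2)
    a_center = (int(rows * 0.72), cols // 2)

    stack = np.empty((config.n_frames, rows, cols), dtype=np.float32)
    heart_mask = np.zeros((rows, cols), dtype=bool)
    for k in range(config.n_frames):
        vm = _ellipse_mask((rows, cols), v_center, v_area[k], config.aspect)
        am = _ellipse_mask((rows, cols), a_center, a_area[k], config.aspect)
        heart_mask |= vm | am
        frame = np.full((rows, cols), config.intensity_bg, dtype=np.float32)
        frame[vm | am] = config.intensity_fg
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd, size=frame.shape).astype(
                np.float32
            )
        stack[k] = frame

    duration = config.n_frames / config.fps
    # ventricle-area maxima occur at t = t0 + m / beat_rate, m = 0, 1, ...
    true_beats = max(0, math.ceil(config.beat_rate * (duration - t0) - 1e-12))
    if config.edv == config.esv:
        true_beats = 0  # constant area: no cycles at all
    true_ef = (
        0.0 if config.edv == 0 else (config.edv - config.esv) / config.edv * 100.0
    )
    trace = pd.DataFrame(
        {
            "frame": np.arange(config.n_frames),
            "time_s": t,
            "ventricle_area": v_area,
            "atrium_area": a_area,
        }
    )
    return HeartMovie(stack, trace, true_ef, true_beats, heart_mask, config)


# --------------------------------------------------------------------------
# trunk vasculature
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrunkSimConfig:
    """Trunk projection with regularly spaced bright ISV stripes.

    Stripes are elongated ellipses (major axis = ``isv_length``, minor
    axis = ``isv_width``) so that second-moment axis measurement on the
    rasterized object recovers the configured axes to within a pixel.
    """

    n_isv: int = 12
    isv_length: float = 100.0       # px, major axis
    isv_width: float = 10.0         # px, minor axis
    spacing: float = 30.0           # px between stripe centers
    image_shape: tuple[int, int] = (200, 420)
    intensity_fg: float = 200.0
    intensity_bg: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_isv < 0:
            raise ValueError("n_isv must be >= 0")
        if self.isv_length <= self.isv_width:
            raise ValueError("isv_length must exceed isv_width")
        rows, cols = self.image_shape
        if self.isv_length + 4 > rows:
            raise ValueError("stripes do not fit vertically in image_shape")
        if self.n_isv > 0:
            extent = self.first_center_col + (self.n_isv - 1) * self.spacing
            if extent + self.isv_width / 2 + 2 > cols:
                raise ValueError("stripes overflow the image horizontally")

    @property
    def first_center_col(self) -> float:
        return self.spacing  # left margin of one spacing unit


@dataclass
class TrunkImage:
    image: np.ndarray                  # float32 intensity
    label_mask: np.ndarray             # int32, 0 = background, 1..n_isv
    truth: pd.DataFrame                # per-stripe center and true axes
    band_row: int                      # row crossing all stripes
    config: TrunkSimConfig


def make_trunk_image(config: TrunkSimConfig) -> TrunkImage:
    """Render the ISV band: ``n_isv`` vertical stripes at known positions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    labels = np.zeros((rows, cols), dtype=np.int32)
    band_row = rows // 2
    records = []
    for i in range(config.n_isv):
        cc_center = config.first_center_col + i * config.spacing
        rr, cc = _draw_ellipse(
            band_row,
            cc_center,
            config.isv_length / 2,
            config.isv_width / 2,
            shape=(rows, cols),
        )
        labels[rr, cc] = i + 1
        records.append(
            {
                "label": i + 1,
                "center_row": band_row,
                "center_col": cc_center,
                "true_major_axis": config.isv_length,
                "true_minor_axis": config.isv_width,
            }
        )
    image = np.full((rows, cols), config.intensity_bg, dtype=np.float32)
    image[labels > 0] = config.intensity_fg
    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape).astype(np.float32)
    truth = pd.DataFrame(
        records,
        columns=[
            "label",
            "center_row",
            "center_col",
            "true_major_axis",
            "true_minor_axis",
        ],
    )
    return TrunkImage(image, labels, truth, band_row, config)


# --------------------------------------------------------------------------
# locomotion tracks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorSimConfig:
    """One larva's 1-min binned activity under the light schedule.

    Velocities are mm/min per bin; accommodation happens in the dark and
    uses the dark-phase velocity.  Gaussian noise is clipped at zero —
    the simplest model that still exercises the median-based estimators.
    """

    schedule: PhaseSchedule = field(default_factory=PhaseSchedule.default)
    v_dark: float = 120.0
    v_bright: float = 60.0
    move_frac_dark: float = 0.6
    move_frac_bright: float = 0.35
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.v_dark, self.v_bright) < 0:
            raise ValueError("velocities must be >= 0")
        if not (0 <= self.move_frac_dark <= 1 and 0 <= self.move_frac_bright <= 1):
            raise ValueError("moving fractions must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_behavior_track(config: BehaviorSimConfig) -> pd.DataFrame:
    """Per-bin table (bin_index, velocity, distance, moving_duration, phase).

    One row per schedule minute; with ``noise_sd == 0`` every dark (and
    accommodation) bin has velocity ``v_dark`` and every bright bin
    ``v_bright``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.schedule.per_minute_labels()
    n = len(labels)
    base_v = np.where(labels == "bright", config.v_bright, config.v_dark).astype(float)
    base_mf = np.where(
        labels == "bright", config.move_frac_bright, config.move_frac_dark
    ).astype(float)
    velocity = base_v + (
        rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    )
    velocity = np.clip(velocity, 0.0, None)
    moving = np.clip(
        base_mf
        + (
            rng.normal(0.0, config.noise_sd / 100.0, size=n)
            if config.noise_sd > 0
            else 0.0
        ),
        0.0,
        1.0,
    )
    return pd.DataFrame(
        {
            "bin_index": np.arange(n),
            "velocity": velocity,
            "distance": velocity * 1.0,  # mm per 1-min bin
            "moving_duration": moving * 60.0,  # seconds per bin
            "phase": labels,
        }
    )


# --------------------------------------------------------------------------
# plate-structured screens
# --------------------------------------------------------------------------

#: Realistic control distributions for a 4-5 dpf larva, per metric:
#: (median, between-larva SD).  Units: um, beats/min, %, counts, px^2,
#: mm/min; the bright/dark ratio is derived, not drawn.
DEFAULT_CONTROL_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "body_length_um": (3600.0, 150.0),
    "heart_rate_bpm": (150.0, 12.0),
    "ejection_fraction_pct": (55.0, 6.0),
    "isv_count": (26.0, 2.0),
    "isv_median_area_px2": (550.0, 60.0),
    "velocity_dark": (120.0, 30.0),
    "velocity_bright": (60.0, 18.0),
    "accommodation_activity": (100.0, 25.0),
}

SCREEN_METRICS = list(DEFAULT_CONTROL_DISTRIBUTIONS) + ["log_bright_dark_ratio"]


@dataclass(frozen=True)
class ScreenSimConfig:
    """Plate-structured per-larva measurement tables with known effects.

    Each compound is tested on ``n_replicates`` plates with
    ``n_larvae_per_group`` larvae each; every plate also carries its own
    control group (the vehicle wells).  ``effects`` maps compound ->
    metric -> multiplicative shift of the control median; a compound
    with multiplier 1.0 everywhere is null by construction.  Plate batch
    effects are additive offsets drawn per plate and metric, scaled by
    ``plate_offset_sd`` in units of the metric's SD.
    """

    n_compounds: int = 10
    n_larvae_per_group: int = 10
    n_controls_per_plate: int = 20
    compounds_per_plate: int = 10
    n_replicates: int = 2
    control_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_DISTRIBUTIONS)
    )
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mortality_prob: float = 0.0
    effusion_prob: float = 0.0
    plate_offset_sd: float = 0.5
    control_label: str = "DMSO"
    concentration_um: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 0 or self.n_larvae_per_group < 1:
            raise ValueError("need n_compounds >= 0 and n_larvae_per_group >= 1")
        if self.n_controls_per_plate < 1:
            raise ValueError("every plate must carry a control group")
        for p in (self.mortality_prob, self.effusion_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")

    def compound_names(self) -> list[str]:
        return [f"compound_{i + 1:03d}" for i in range(self.n_compounds)]


def make_screen_dataset(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, dict]:
    """One row per larva with plate/treatment structure and ground truth.

    Returns ``(records, truth)`` where ``truth`` holds the effect
    multipliers and the per-plate batch offsets actually applied.  Dead
    larvae carry no morphology metrics (NaN), only the alive flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    compounds = config.compound_names()
    metrics = list(config.control_distributions)

    # assign compounds to plates, replicate by replicate
    plates: list[tuple[str, list[str]]] = []
    for rep in range(config.n_replicates):
        for p_start in range(0, max(len(compounds), 1), config.compounds_per_plate):
            members = compounds[p_start : p_start + config.compounds_per_plate]
            plate_id = f"R{rep + 1}P{p_start // config.compounds_per_plate + 1}"
            plates.append((plate_id, members))

    plate_offsets: dict[str, dict[str, float]] = {}
    rows = []
    larva_counter = 0
    for rep_plate_idx, (plate_id, members) in enumerate(plates):
        rep = int(plate_id[1 : plate_id.index("P")])
        offsets = {
            m: float(rng.normal(0.0, config.plate_offset_sd * sd))
            for m, (_, sd) in config.control_distributions.items()
        }
        plate_offsets[plate_id] = offsets
        groups = [(config.control_label, config.n_controls_per_plate)] + [
            (c, config.n_larvae_per_group) for c in members
        ]
        for treatment, n in groups:
            eff = config.effects.get(treatment, {})
            is_control = treatment == config.control_label
            for _ in range(n):
                larva_counter += 1
                dead = (not is_control) and rng.random() < config.mortality_prob
                effusion = (
                    False
                    if dead
                    else (not is_control) and rng.random() < config.effusion_prob
                )
                row = {
                    "larva_id": f"L{larva_counter:05d}",
                    "experiment_id": plate_id,
                    "treatment": treatment,
                    "concentration_um": 0.0 if is_control else config.concentration_um,
                    "replicate": rep,
                    "alive": not dead,
                    "effusion": effusion,
                }
                for m, (median, sd) in config.control_distributions.items():
                    if dead:
                        row[m] = np.nan
                        continue
                    mult = 1.0 if is_control else float(eff.get(m, 1.0))
                    value = rng.normal(median * mult, sd) + offsets[m]
                    if m == "isv_count":
                        value = max(0.0, round(value))
                    row[m] = value
                if dead:
                    row["log_bright_dark_ratio"] = np.nan
                else:
                    row["log_bright_dark_ratio"] = log_bright_dark_ratio(
                        max(row["velocity_bright"], 0.0),
                        max(row["velocity_dark"], 0.0),
                    )
                rows.append(row)
    records = pd.DataFrame(rows)
    truth = {
        "effects": {c: dict(config.effects.get(c, {})) for c in compounds},
        "plate_offsets": plate_offsets,
        "metrics": metrics + ["log_bright_dark_ratio"],
    }
    return records, truth


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------


def make_qpcr_dataset(
    genes: list[str],
    groups: list[str],
    true_fold_changes: Mapping[str, Mapping[str, float]],
    sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 6,
    reference_gene: str = "rps11",
    baseline_group: str | None = None,
    reference_ct: float = 16.0,
    base_delta_ct: float = 6.0,
) -> pd.DataFrame:
    """Ct table (sample_id, group, gene, Ct) with a reference gene.

    ``true_fold_changes[group][gene]`` is the expression fold change of
    that group relative to the baseline group (default: first group);
    unlisted entries default to 1.  With ``sd == 0`` the ddCt stage
    recovers the configured fold changes exactly under the 2^-ddCt
    convention.  Six replicate pools per group by default.
    """
    if reference_gene in genes:
        raise ValueError("reference gene must not appear in the target gene list")
    if not groups:
        raise ValueError("need at least one group")
    baseline_group = baseline_group if baseline_group is not None else groups[0]
    if baseline_group not in groups:
        raise ValueError("baseline_group must be among groups")
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        fcs = true_fold_changes.get(group, {})
        for r in range(n_replicates):
            sample_id = f"{group}_rep{r + 1}"
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "gene": reference_gene,
                    "ct": reference_ct,
                }
            )
            for gene in genes:
                fc = float(fcs.get(gene, 1.0))
                if fc <= 0:
                    raise ValueError("fold changes must be positive")
                delta_ct = base_delta_ct - math.log2(fc)
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "gene": gene,
                        "ct": reference_ct + delta_ct + noise,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# disk output helpers (TIFF stacks, CSV tables, JSON ground truth)
# --------------------------------------------------------------------------


def write_heart_movie(movie: HeartMovie, out_dir, name: str = "heart") -> Path:
    """Write a movie as multi-page TIFF + JSON sidecar with fps/truth."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{name}.tif"
    tifffile.imwrite(tif, movie.stack)
    sidecar = {
        "fps": movie.config.fps,
        "pixel_size": movie.config.pixel_size,
        "true_ef": movie.true_ef,
        "true_beat_count": movie.true_beat_count,
    }
    (out / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    movie.area_trace.to_csv(out / f"{name}_truth_trace.csv", index=False)
    return tif


def write_trunk_image(trunk: TrunkImage, out_dir, name: str = "trunk") -> Path:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{name}.tif"
    tifffile.imwrite(tif, trunk.image)
    tifffile.imwrite(out / f"{name}_labels.tif", trunk.label_mask.astype(np.uint16))
    trunk.truth.to_csv(out / f"{name}_truth.csv", index=False)
    (out / f"{name}.json").write_text(
        json.dumps({"n_isv": trunk.config.n_isv, "band_row": trunk.band_row}, indent=2)
    )
    return tif
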