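"""End-to-end orchestration: records -> statistics -> static report.

``run_pipeline`` takes a validated :class:`PipelineConfig`, obtains a
per-larva records table (either a CSV produced by the quantification
stages or a simulated screen), runs batch correction and the screen
statistics, classifies compounds, and writes a results directory:

    records.csv    one row per larva (alive, dead or excluded-with-reason)
    results.csv    one row per (treatment, metric) comparison
    summary.json   screen-level counts/percentages and compound groups
    heatmap.svg    the green/magenta/grey score heatmap
    pipeline.log   stage-by-stage log with in/out counts and exclusions

Everything is deterministic under a fixed config and seed.  The heatmap
is written as plain SVG rectangles so the cell colors remain machine-
readable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import screen_stats
from .behavior import PhaseSchedule
from .screen_stats import (
    DEFAULT_ALPHA,
    DEFAULT_CONTROL_LABEL,
    FAMILY_ORDER,
    GROUP_NONE,
)
from .synthetic_data import ScreenSimConfig, make_screen_dataset

logger = logging.getLogger("zfscreen")


@dataclass
class PipelineConfig:
    """Everything the pipeline run needs, with documented defaults.

    fps (frames/s) and pixel_size (um/px) are acquisition metadata for
    the imaging stages; min_area (px^2) is the small-object filter;
    peak detection uses min_distance samples and a prominence threshold
    as a fraction of the dynamic range.
    """

    out_dir: str = "results"
    seed: int = 0
    fps: float | None = 20.0
    pixel_size: float = 1.0
    min_area: float = 50.0
    peak_min_distance: int | None = None
    peak_prominence_frac: float = 0.10
    alpha: float = DEFAULT_ALPHA
    batch_correct: bool = True
    control_label: str = DEFAULT_CONTROL_LABEL
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule.default)
    records_csv: str | None = None        # existing per-larva table, or
    screen_sim: dict = field(default_factory=dict)  # kwargs for ScreenSimConfig

    def validate(self) -> None:
        if self.fps is None or self.fps <= 0:
            raise ValueError("config must state a positive fps")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.records_csv is not None and not Path(self.records_csv).exists():
            raise ValueError(f"records_csv {self.records_csv!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "schedule" in raw:
            raw["schedule"] = PhaseSchedule.from_dict(raw["schedule"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# --------------------------------------------------------------------------
# heatmap rendering (plain SVG)
# --------------------------------------------------------------------------

_GREEN = (0, 153, 51)
_MAGENTA = (204, 0, 204)
_GREY = "#c8c8c8"


def _score_color(scaled: float) -> str:
    """White at 0, full green at +1, full magenta at -1."""
    s = float(np.clip(scaled, -1.0, 1.0))
    target = _GREEN if s >= 0 else _MAGENTA
    t = abs(s)
    rgb = tuple(round(255 + (c - 255) * t) for c in target)
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def render_heatmap(
    results: pd.DataFrame,
    path,
    groups: pd.Series | None = None,
    cell: int = 18,
    label_width: int = 150,
    header: int = 110,
) -> Path:
    """Write the screen score heatmap as an SVG file.

    Every metric column is independently rescaled to [-1, 1] by its
    maximum |score|; masked (non-significant) cells are grey.  Row
    blocks are ordered by compound group, then name.  Each cell is an
    SVG <rect> whose fill encodes the scaled score, so the written file
    round-trips back to signs and masks.
    """
    if len(results) == 0:
        raise ValueError("need at least one result row")
    metrics = list(dict.fromkeys(results["metric"]))
    if groups is None:
        groups = screen_stats.classify_all(results)
    order_key = {g: i for i, g in enumerate(list(FAMILY_ORDER) + [GROUP_NONE])}
    treatments = sorted(
        results["treatment"].unique(),
        key=lambda t: (order_key.get(groups.get(t, GROUP_NONE), 99), str(t)),
    )
    score = results.pivot(index="treatment", columns="metric", values="score")
    scale = {
        m: (score[m].abs().max() if np.isfinite(score[m].abs().max()) else np.nan)
        for m in metrics
    }
    width = label_width + cell * len(metrics) + 10
    height = header + cell * len(treatments) + 10
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="sans-serif" font-size="10">'
    ]
    for j, m in enumerate(metrics):
        x = label_width + j * cell + cell / 2
        parts.append(
            f'<text x="{x}" y="{header - 6}" text-anchor="start" '
            f'transform="rotate(-60 {x} {header - 6})">{m}</text>'
        )
    for i, tr in enumerate(treatments):
        y = header + i * cell
        parts.append(
            f'<text x="{label_width - 6}" y="{y + cell - 5}" '
            f'text-anchor="end">{tr} [{groups.get(tr, GROUP_NONE)}]</text>'
        )
        for j, m in enumerate(metrics):
            v = score.at[tr, m] if (tr in score.index and m in score.columns) else None
            masked = v is None or (isinstance(v, float) and np.isnan(v))
            if masked or not scale[m] or np.isnan(scale[m]) or scale[m] == 0:
                fill = _GREY
                data = "masked"
            else:
                fill = _score_color(v / scale[m])
                data = f"{v:.6g}"
            x = label_width + j * cell
            parts.append(
                f'<rect x="{x}" y="{y}" width="{cell - 1}" height="{cell - 1}" '
                f'fill="{fill}" data-treatment="{tr}" data-metric="{m}" '
                f'data-score="{data}"/>'
            )
    parts.append("</svg>")
    out = Path(path)
    out.write_text("\n".join(parts))
    return out


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------


def _load_records(config: PipelineConfig) -> pd.DataFrame:
    if config.records_csv is not None:
        logger.info("stage records: reading %s", config.records_csv)
        return pd.read_csv(config.records_csv)
    sim_kwargs = dict(config.screen_sim)
    sim_kwargs.setdefault("seed", config.seed)
    sim = ScreenSimConfig(**sim_kwargs)
    logger.info(
        "stage records: simulating screen (%d compounds, %d larvae/group, seed %d)",
        sim.n_compounds,
        sim.n_larvae_per_group,
        sim.seed,
    )
    records, _ = make_screen_dataset(sim)
    return records


def run_pipeline(config: PipelineConfig) -> Path:
    """Run records -> statistics -> report; returns the results directory.

    Any stage failure raises with the failing stage named; excluded
    larvae and rejected datasets are logged with their reasons.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        stage = "records"
        records = _load_records(config)
        n_dead = int((~records["alive"]).sum()) if "alive" in records.columns else 0
        logger.info(
            "stage records: %d larvae in (%d dead, excluded from metric "
            "comparisons; they enter mortality only)",
            len(records),
            n_dead,
        )
        records.to_csv(out_dir / "records.csv", index=False)

        stage = "statistics"
        results = screen_stats.run_screen(
            records,
            alpha=config.alpha,
            batch_corrected=config.batch_correct,
            control_label=config.control_label,
        )
        n_sig = int(results["significant"].sum())
        logger.info(
            "stage statistics: %d comparisons, %d significant at alpha=%g "
            "(batch correction %s)",
            len(results),
            n_sig,
            config.alpha,
            "on" if config.batch_correct else "off",
        )
        results.to_csv(out_dir / "results.csv", index=False)

        stage = "summary"
        summary = screen_stats.summarize_screen(
            results, records, control_label=config.control_label
        )
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("stage summary: %d compounds summarized", summary["n_compounds"])

        stage = "heatmap"
        groups = screen_stats.classify_all(results)
        render_heatmap(results, out_dir / "heatmap.svg", groups=groups)
        logger.info("stage heatmap: wrote %s", out_dir / "heatmap.svg")
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from None
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir
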