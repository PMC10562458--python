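"""Segmentation of heart chambers and intersegmental vessels.

Masks are produced by a pluggable backend.  The reference backend is a
classical one — global automatic (Otsu) thresholding plus connected
components, with ventricle/atrium assignment by the relative position of
the two largest components.  Learned backends (e.g. U-Net predictors)
can be plugged in as any callable mapping an image to a boolean
foreground mask; they are not part of this package.

Post-segmentation quality rules applied downstream:

* objects with area strictly below a threshold are removed;
* a heart movie in which any frame lacks a ventricle segmentation is
  rejected as a whole, propagating as missing values for that larva.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

#: Default minimum object area in px^2 for the small-object filter.
DEFAULT_MIN_AREA = 50.0

VENTRICLE = "ventricle"
ATRIUM = "atrium"
ISV = "isv"


@dataclass
class LabelMask:
    """Integer label image plus a class name for every nonzero label."""

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=dict)
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"class_map lacks labels {sorted(missing)}")

    def areas(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts) if v != 0}

    def labels_of_class(self, cls: str) -> list[int]:
        return [lab for lab, c in self.class_map.items() if c == cls]

    def area_of_class(self, cls: str) -> float:
        areas = self.areas()
        return float(sum(areas.get(lab, 0) for lab in self.labels_of_class(cls)))


# --------------------------------------------------------------------------
# backends
# --------------------------------------------------------------------------


def threshold_backend(image: np.ndarray, invert: bool = False) -> np.ndarray:
    """Global Otsu threshold; ``invert`` selects dark-on-bright foreground."""
    image = np.asarray(image, dtype=float)
    if image.size == 0 or np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=bool)
    t = threshold_otsu(image)
    return (image < t) if invert else (image > t)


BACKENDS: dict[str, Callable[..., np.ndarray]] = {"threshold": threshold_backend}


def _resolve_backend(backend) -> Callable[..., np.ndarray]:
    if callable(backend):
        return backend
    try:
        return BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend {backend!r}") from None


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def segment_isvs(
    projection: np.ndarray,
    backend: str | Callable = "threshold",
    min_area: float = 0.0,
    **params,
) -> LabelMask:
    """Binary ISV segmentation of a maximum-intensity projection.

    The foreground is partitioned into connected components, one label
    per candidate ISV.  An empty or all-background image yields an empty
    mask, not an error.
    """
    projection = np.asarray(projection)
    if projection.ndim != 2:
        raise ValueError("expected a single-channel 2D projection")
    fg = _resolve_backend(backend)(projection, **params)
    labels = _cc_label(fg, connectivity=2)
    mask = LabelMask(
        labels, {int(lab): ISV for lab in np.unique(labels) if lab != 0}
    )
    if min_area > 0:
        mask = filter_small_objects(mask, min_area)
    return mask


def segment_heart_frames(
    movie: np.ndarray | Sequence[np.ndarray],
    backend: str | Callable = "threshold",
    min_area: float = DEFAULT_MIN_AREA,
    **params,
) -> list[LabelMask]:
    """Per-frame ventricle/atrium masks for a heart movie.

    At most one ventricle and one atrium label per frame: the two
    largest surviving components are kept, the upper one (smaller
    centroid row) is the ventricle — matching the lateral mounting in
    which the ventricle sits above the atrium.  A single surviving
    component is taken to be the ventricle.
    """
    frames = [np.asarray(f) for f in movie]
    if not frames:
        return []
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("movie frames must share one shape")
    fn = _resolve_backend(backend)
    masks: list[LabelMask] = []
    for k, frame in enumerate(frames):
        fg = fn(frame, **params)
        cc = _cc_label(fg, connectivity=2)
        values, counts = np.unique(cc, return_counts=True)
        comps = [
            (int(v), int(c)) for v, c in zip(values, counts) if v != 0 and c >= min_area
        ]
        comps.sort(key=lambda vc: -vc[1])
        out = np.zeros(shape, dtype=np.int32)
        class_map: dict[int, str] = {}
        if comps:
            chosen = comps[:2]
            centroid_rows = {
                v: float(np.nonzero(cc == v)[0].mean()) for v, _ in chosen
            }
            chosen.sort(key=lambda vc: centroid_rows[vc[0]])
            out[cc == chosen[0][0]] = 1
            class_map[1] = VENTRICLE
            if len(chosen) == 2:
                out[cc == chosen[1][0]] = 2
                class_map[2] = ATRIUM
        masks.append(LabelMask(out, class_map, frame_index=k))
    return masks


def filter_small_objects(mask: LabelMask, min_area: float) -> LabelMask:
    """Drop labels whose area is strictly below ``min_area`` (px^2).

    Surviving labels keep their numbers; idempotent and monotone in the
    threshold.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    areas = mask.areas()
    keep = {lab for lab, a in areas.items() if a >= min_area}
    labels = np.where(np.isin(mask.labels, sorted(keep)), mask.labels, 0)
    class_map = {lab: cls for lab, cls in mask.class_map.items() if lab in keep}
    return LabelMask(labels, class_map, frame_index=mask.frame_index)


def validate_heart_dataset(masks: Sequence[LabelMask]) -> tuple[bool, str]:
    """Accept a heart movie only if every frame has a ventricle label.

    Rejection must propagate as missing EF/heart-rate values for the
    larva — never as silent zeros.
    """
    masks = list(masks)
    if not masks:
        return False, "empty dataset: no frames"
    bad = [
        m.frame_index if m.frame_index is not None else i
        for i, m in enumerate(masks)
        if not m.labels_of_class(VENTRICLE)
    ]
    if bad:
        shown = ", ".join(str(b) for b in bad[:5])
        more = "" if len(bad) <= 5 else f" (+{len(bad) - 5} more)"
        return False, f"{len(bad)} frame(s) without ventricle: {shown}{more}"
    return True, "ok"
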