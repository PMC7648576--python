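"""Nuclear segmentation and ring-background-corrected intensity measurement.

Nuclei are segmented from the histone-marker channel (or, in reporter-driven
mode, from the reporter channel) as 4-connected components above a global
automatic threshold, filtered by area.  The local background of each nucleus
is the ring between a 4x and a 2x morphological dilation of the object,
excluding pixels claimed by the inner dilation of any other object.  The
corrected nuclear intensity of a channel is the object mean minus the ring
mean — the quantity all downstream partitioning statistics are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

#: 3x3 square structuring element; one dilation "step" is one application of it
STRUCT3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold and size filters for object segmentation.

    ``threshold_method`` is ``"otsu"`` (global Otsu on the image histogram),
    ``"robust"`` (image median + ``robust_k`` robust standard deviations,
    MAD-based — suited to sparse punctate channels whose foreground fraction
    is far too small for a histogram split), or ``"fixed"`` with
    ``fixed_threshold`` set.  Objects whose pixel count lies outside
    ``[min_area, max_area]`` are discarded; objects touching the image border
    are kept but flagged.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    robust_k: float = 8.0
    min_area: int = 5
    max_area: int = 2000

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "robust", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")
        if self.min_area < 1 or self.max_area < self.min_area:
            raise ValueError("require 1 <= min_area <= max_area")


#: defaults for compact bud-neck objects: small bright punctae covering far
#: less than a percent of the frame, where a histogram split is degenerate
BUDNECK_CONFIG = SegmentationConfig(threshold_method="robust", min_area=2, max_area=40)


@dataclass
class LabelMask:
    """Labelled objects of one channel.

    ``labels`` holds 0 for background and consecutive integers 1..n for the
    objects (4-connected components).  ``border_objects`` flags labels that
    touch the image border; ``notes`` records provenance caveats (e.g. the
    reporter-driven mode's blindness to reporter-negative nuclei).
    """

    labels: np.ndarray
    channel_role: str
    border_objects: set[int] = field(default_factory=set)
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_ids(self) -> list[int]:
        return list(range(1, self.n_objects + 1))


@dataclass
class NucleusMeasure:
    """Raw, ring-background and corrected intensities of one segmented nucleus.

    Per channel: ``mean[ch]`` over object pixels, ``ring_mean[ch]`` over the
    background ring, and ``corrected[ch] = mean[ch] - ring_mean[ch]``.  When
    the ring is empty (``ring_area == 0``) the corrected values are NaN and
    ``background_undefined`` is set.
    """

    object_id: int
    centroid: tuple[float, float]
    area: int
    ring_area: int
    mean: dict[str, float]
    ring_mean: dict[str, float]
    corrected: dict[str, float]
    on_border: bool = False
    background_undefined: bool = False

    # convenience accessors for the two standard channel roles
    @property
    def mean_marker(self) -> float:
        return self.mean.get("marker", float("nan"))

    @property
    def mean_reporter(self) -> float:
        return self.mean.get("reporter", float("nan"))

    @property
    def ring_mean_reporter(self) -> float:
        return self.ring_mean.get("reporter", float("nan"))

    @property
    def corrected_marker(self) -> float:
        return self.corrected.get("marker", float("nan"))

    @property
    def corrected_reporter(self) -> float:
        return self.corrected.get("reporter", float("nan"))


def _threshold(image: np.ndarray, config: SegmentationConfig) -> float | None:
    if config.threshold_method == "fixed":
        return float(config.fixed_threshold)
    if np.ptp(image) == 0:
        return None  # constant image: nothing to segment
    if config.threshold_method == "robust":
        med = float(np.median(image))
        mad = float(np.median(np.abs(image - med)))
        return med + config.robust_k * 1.4826 * mad
    return float(threshold_otsu(image))


def _segment(image: np.ndarray, config: SegmentationConfig, role: str) -> LabelMask:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    thr = _threshold(image, config)
    if thr is None:
        return LabelMask(labels=np.zeros(image.shape, dtype=np.int32), channel_role=role)

    fg = image > thr
    raw = cc_label(fg, connectivity=1)
    labels = np.zeros(image.shape, dtype=np.int32)
    border: set[int] = set()
    next_id = 1
    for prop in regionprops(raw):
        if not (config.min_area <= prop.area <= config.max_area):
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        labels[rr, cc] = next_id
        if (rr.min() == 0 or cc.min() == 0
                or rr.max() == image.shape[0] - 1 or cc.max() == image.shape[1] - 1):
            border.add(next_id)
        next_id += 1
    return LabelMask(labels=labels, channel_role=role, border_objects=border)


def segment_nuclei(image: np.ndarray, config: SegmentationConfig | None = None) -> LabelMask:
    """Segment nuclei from the histone-marker channel.

    Connected components (4-connectivity) above a global automatic threshold,
    filtered by the config's area band.  A constant image yields zero objects.
    """
    return _segment(image, config or SegmentationConfig(), role="marker")


def segment_reporter_nuclei(image_reporter: np.ndarray,
                            config: SegmentationConfig | None = None) -> LabelMask:
    """Segment nuclei from the reporter channel itself (alternative mode).

    Identical algorithm to :func:`segment_nuclei` applied to the reporter.
    Nuclei lacking reporter signal are invisible in this mode, so cells with
    no reporter in one or both nuclei drop out of any downstream analysis;
    the returned mask records that caveat in its notes.
    """
    mask = _segment(image_reporter, config or SegmentationConfig(), role="reporter")
    mask.notes["caveat"] = (
        "segmented from the reporter channel: reporter-negative nuclei are "
        "not detected and their cells are excluded from analysis")
    return mask


def segment_budneck(image_budneck: np.ndarray,
                    config: SegmentationConfig | None = None) -> LabelMask:
    """Segment compact bud-neck objects from the bud-neck marker channel."""
    return _segment(image_budneck, config or BUDNECK_CONFIG, role="budneck")


def dilate(mask: np.ndarray, steps: int) -> np.ndarray:
    """``steps`` applications of a 3x3 square dilation (0 steps = identity)."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return mask.astype(bool).copy()
    return ndimage.binary_dilation(mask, structure=STRUCT3, iterations=steps)


def background_ring(mask: LabelMask, inner_steps: int = 2,
                    outer_steps: int = 4) -> dict[int, np.ndarray]:
    """Per-object background rings between the outer and inner dilations.

    ring(k) = dilate^outer(object k) minus dilate^inner of *any* object (which
    subsumes object k's own inner dilation), clipped to the image.  Excluding
    every object's inner dilation keeps neighbouring nuclear signal out of the
    ring; rings of two objects may overlap, and such diffuse-background pixels
    count for both.
    """
    if not (0 <= inner_steps < outer_steps):
        raise ValueError("require 0 <= inner_steps < outer_steps")
    any_inner = dilate(mask.labels > 0, inner_steps)
    rings: dict[int, np.ndarray] = {}
    for k in mask.object_ids():
        obj = mask.labels == k
        rings[k] = dilate(obj, outer_steps) & ~any_inner
    return rings


def measure_objects(mask: LabelMask, rings: dict[int, np.ndarray],
                    channels: dict[str, np.ndarray]) -> list[NucleusMeasure]:
    """Measure raw, ring and corrected mean intensities per object and channel."""
    for name, img in channels.items():
        if img.shape != mask.labels.shape:
            raise ValueError(
                f"channel {name!r} shape {img.shape} != mask shape {mask.labels.shape}")

    measures: list[NucleusMeasure] = []
    for k in mask.object_ids():
        obj = mask.labels == k
        ring = rings.get(k, np.zeros_like(obj))
        area = int(obj.sum())
        ring_area = int(ring.sum())
        rr, cc = np.nonzero(obj)
        centroid = (float(rr.mean()), float(cc.mean()))
        mean, ring_mean, corrected = {}, {}, {}
        for name, img in channels.items():
            m = float(img[obj].mean())
            mean[name] = m
            if ring_area > 0:
                b = float(img[ring].mean())
                ring_mean[name] = b
                corrected[name] = m - b
            else:
                ring_mean[name] = float("nan")
                corrected[name] = float("nan")
        measures.append(NucleusMeasure(
            object_id=k, centroid=centroid, area=area, ring_area=ring_area,
            mean=mean, ring_mean=ring_mean, corrected=corrected,
            on_border=k in mask.border_objects,
            background_undefined=ring_area == 0))
    return measures
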