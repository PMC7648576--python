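"""Synthetic two-channel microscopy scenes of dividing yeast cells.

Generates seeded scenes of budding-yeast cells around mitotic exit: each
telophase cell contributes a pair of nascent nuclei (mother and daughter),
S-phase and G1 cells contribute a single nucleus.  Every nucleus appears in
a histone-marker channel; the reporter channel carries signal only in the
nuclei that the cell's ground-truth partitioning category names; an optional
third channel carries a bud-neck marker between the two nuclei of a pair
that has not yet completed cytokinesis.

Nuclei are rendered as hard discs (so area-based flux oracles are exact),
then blurred by a Gaussian point-spread function, added to a linearly
varying background, and optionally degraded by shot (Poisson) and read
(Gaussian) noise.  All randomness flows from a single scene seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

CATEGORIES = ("asymmetric_daughter", "asymmetric_mother", "symmetric", "none")
STAGES = ("telophase", "s_phase", "g1")

#: channel order of the rendered stack
CHANNEL_ROLES = ("marker", "reporter", "budneck")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap at the requested density."""


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one simulated cell.

    ``daughter_center`` and the daughter reporter amplitude are ``None`` for
    single-nucleus (S-phase / G1) cells.  Mother vs daughter identity is
    explicit ground truth; nothing downstream may infer it from nucleus size.
    """

    cell_id: int
    mother_center: tuple[int, int]
    daughter_center: tuple[int, int] | None
    nucleus_radius: float
    marker_amplitude: float
    reporter_amp_mother: float
    reporter_amp_daughter: float | None
    true_category: str
    cell_stage: str
    budneck_present: bool
    budneck_center: tuple[float, float] | None

    def __post_init__(self) -> None:
        if self.true_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.true_category!r}")
        if self.cell_stage not in STAGES:
            raise ValueError(f"unknown stage {self.cell_stage!r}")
        if self.cell_stage != "telophase":
            if self.daughter_center is not None:
                raise ValueError("single-nucleus cells must not carry a daughter nucleus")

    @property
    def nuclei(self) -> list[tuple[str, tuple[int, int], float]]:
        """(role, center, reporter amplitude) for each nucleus of this cell."""
        out = [("mother" if self.cell_stage == "telophase" else "single",
                self.mother_center, self.reporter_amp_mother)]
        if self.daughter_center is not None:
            out.append(("daughter", self.daughter_center, float(self.reporter_amp_daughter)))
        return out


@dataclass(frozen=True)
class SceneParams:
    """Rendering and population parameters of a synthetic scene.

    Default intensities give a marker signal-to-noise ratio of ~10: amplitude
    100 over background 10 under shot noise (sd ≈ sqrt(110) ≈ 10.5 a.u.).
    ``category_mixture`` orders as :data:`CATEGORIES`; the default reflects a
    largely asymmetric wild-type telophase population.  ``stage_counts``, when
    given, fixes the exact number of cells per stage and overrides
    ``stage_mixture``.
    """

    n_cells: int = 20
    image_shape: tuple[int, int] = (512, 512)
    nucleus_radius: float = 4.0
    pair_separation: float = 14.0
    marker_amplitude: float = 100.0
    reporter_amplitude: float = 80.0
    amplitude_cv: float = 0.15
    category_mixture: tuple[float, float, float, float] = (0.72, 0.0, 0.13, 0.15)
    stage_mixture: tuple[float, float, float] = (0.6, 0.3, 0.1)
    stage_counts: dict[str, int] | None = None
    budneck_fraction: float = 0.5
    budneck_radius: float = 1.5
    budneck_amplitude: float = 120.0
    background_level: float = 10.0
    background_gradient: tuple[float, float] = (0.005, 0.005)
    psf_sigma: float = 1.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    max_placement_tries: int = 2000

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not math.isclose(sum(self.category_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("category_mixture must sum to 1")
        if self.stage_counts is None and not math.isclose(sum(self.stage_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("stage_mixture must sum to 1")
        if self.stage_counts is not None:
            if set(self.stage_counts) - set(STAGES):
                raise ValueError("stage_counts keys must be stages")
            if sum(self.stage_counts.values()) != self.n_cells:
                raise ValueError("stage_counts must sum to n_cells")


@dataclass
class SyntheticScene:
    """A fully specified synthetic scene: parameters plus per-cell ground truth."""

    params: SceneParams
    cells: list[CellTruth]
    seed: int

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.params.image_shape

    def nucleus_count(self) -> int:
        return sum(len(c.nuclei) for c in self.cells)

    def truth_table(self) -> pd.DataFrame:
        """One row per nucleus, with its cell's category/stage and bud-neck truth."""
        rows = []
        for c in self.cells:
            for role, (r, col), amp in c.nuclei:
                rows.append({
                    "cell_id": c.cell_id,
                    "role": role,
                    "row": r,
                    "col": col,
                    "radius": c.nucleus_radius,
                    "marker_amplitude": c.marker_amplitude,
                    "reporter_amplitude": amp,
                    "category": c.true_category,
                    "stage": c.cell_stage,
                    "budneck_present": c.budneck_present,
                    "budneck_row": c.budneck_center[0] if c.budneck_center else np.nan,
                    "budneck_col": c.budneck_center[1] if c.budneck_center else np.nan,
                })
        return pd.DataFrame(rows)


def _category_amplitudes(category: str, amp: float) -> tuple[float, float]:
    """Reporter amplitudes (mother, daughter) implied by a category."""
    if category == "asymmetric_daughter":
        return 0.0, amp
    if category == "asymmetric_mother":
        return amp, 0.0
    if category == "symmetric":
        return amp, amp
    return 0.0, 0.0


def _min_center_distance(params: SceneParams, dilation_steps: int = 4) -> float:
    # a 3x3 dilation iterated k times grows an object by at most k*sqrt(2)
    # in Euclidean distance; nuclei of distinct cells must not overlap after
    # that growth.
    reach = params.nucleus_radius + dilation_steps * math.sqrt(2.0)
    return 2.0 * reach + 1.0


def generate_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Generate a seeded scene with rejection-sampled, non-overlapping cells.

    Nuclei of distinct cells are guaranteed not to overlap even after a 4x
    morphological dilation, so background rings of different cells never
    touch foreign nuclear signal.  Raises :class:`PlacementError` when the
    requested density cannot be met within ``params.max_placement_tries``
    tries per cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = params.image_shape
    r = params.nucleus_radius
    # leave room for the ring (4 dilation steps) and most of the blur tail
    margin = int(math.ceil(r + 4 + 3 * params.psf_sigma)) + 1
    if shape[0] <= 2 * margin or shape[1] <= 2 * margin:
        raise ValueError(f"image_shape {shape} too small for nucleus radius {r}")

    if params.stage_counts is not None:
        stages: list[str] = []
        for s in STAGES:
            stages += [s] * params.stage_counts.get(s, 0)
        rng.shuffle(stages)  # type: ignore[arg-type]
    else:
        stages = list(rng.choice(STAGES, size=params.n_cells, p=params.stage_mixture))
    categories = rng.choice(CATEGORIES, size=params.n_cells, p=params.category_mixture)

    min_d = _min_center_distance(params)
    placed: list[tuple[float, float]] = []  # all nucleus centers so far

    def ok(center: tuple[int, int]) -> bool:
        return all((center[0] - p[0]) ** 2 + (center[1] - p[1]) ** 2 >= min_d ** 2
                   for p in placed)

    cells: list[CellTruth] = []
    for i in range(params.n_cells):
        stage = stages[i]
        for _try in range(params.max_placement_tries):
            c0 = (int(rng.integers(margin, shape[0] - margin)),
                  int(rng.integers(margin, shape[1] - margin)))
            if stage == "telophase":
                theta = rng.uniform(0, 2 * math.pi)
                c1 = (int(round(c0[0] + params.pair_separation * math.sin(theta))),
                      int(round(c0[1] + params.pair_separation * math.cos(theta))))
                if not (margin <= c1[0] < shape[0] - margin and margin <= c1[1] < shape[1] - margin):
                    continue
                if ok(c0) and ok(c1):
                    placed.extend([c0, c1])
                    break
            else:
                if ok(c0):
                    placed.append(c0)
                    break
        else:
            raise PlacementError(
                f"could not place cell {i} of {params.n_cells} after "
                f"{params.max_placement_tries} tries; scene density exceeds the "
                f"non-overlap limit for shape {shape} at min distance {min_d:.1f} px")

        amp = params.reporter_amplitude
        if params.amplitude_cv > 0:
            amp = float(max(amp * (1 + params.amplitude_cv * rng.standard_normal()),
                            0.2 * params.reporter_amplitude))
        if stage == "telophase":
            cat = str(categories[i])
            m_amp, d_amp = _category_amplitudes(cat, amp)
            budneck = bool(rng.random() < params.budneck_fraction)
            midpoint = ((c0[0] + c1[0]) / 2.0, (c0[1] + c1[1]) / 2.0)
            cells.append(CellTruth(
                cell_id=i, mother_center=c0, daughter_center=c1,
                nucleus_radius=r, marker_amplitude=params.marker_amplitude,
                reporter_amp_mother=m_amp, reporter_amp_daughter=d_amp,
                true_category=cat, cell_stage=stage,
                budneck_present=budneck,
                budneck_center=midpoint if budneck else None))
        else:
            # single-nucleus cells carry no reporter: they are the population
            # from which the reporter-absent threshold is calibrated
            cells.append(CellTruth(
                cell_id=i, mother_center=c0, daughter_center=None,
                nucleus_radius=r, marker_amplitude=params.marker_amplitude,
                reporter_amp_mother=0.0, reporter_amp_daughter=None,
                true_category="none", cell_stage=stage,
                budneck_present=False, budneck_center=None))

    return SyntheticScene(params=params, cells=cells, seed=seed)


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    r0 = max(int(math.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(math.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    sub = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = sub
    return mask


def background_surface(params: SceneParams) -> np.ndarray:
    """The noise-free background plane: level plus linear gradient from the origin."""
    rows, cols = np.mgrid[0:params.image_shape[0], 0:params.image_shape[1]].astype(float)
    gy, gx = params.background_gradient
    return params.background_level + gy * rows + gx * cols


def render_channels(scene: SyntheticScene) -> dict[str, np.ndarray]:
    """Render the marker, reporter and bud-neck channels of a scene.

    Each nucleus is a hard disc of its amplitude, blurred with a Gaussian PSF,
    added to the background surface; Poisson shot noise and then Gaussian read
    noise are applied if enabled.  All channels share geometry and seed-derived
    noise streams, so rendering is deterministic for a fixed scene.
    """
    from scipy.ndimage import gaussian_filter

    p = scene.params
    shape = p.image_shape
    signals = {role: np.zeros(shape, dtype=float) for role in CHANNEL_ROLES}

    for cell in scene.cells:
        for _role, center, rep_amp in cell.nuclei:
            disc = _disc_mask(shape, center, cell.nucleus_radius)
            signals["marker"][disc] += cell.marker_amplitude
            if rep_amp > 0:
                signals["reporter"][disc] += rep_amp
        if cell.budneck_present and cell.budneck_center is not None:
            disc = _disc_mask(shape, cell.budneck_center, p.budneck_radius)
            signals["budneck"][disc] += p.budneck_amplitude

    bg = background_surface(p)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=scene.seed, spawn_key=(1,)))
    out: dict[str, np.ndarray] = {}
    for role in CHANNEL_ROLES:
        img = signals[role]
        if p.psf_sigma > 0:
            img = gaussian_filter(img, p.psf_sigma, mode="constant")
        img = img + bg
        if p.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if p.read_noise_sd > 0:
            img = img + rng.normal(0.0, p.read_noise_sd, size=shape)
        out[role] = img
    return out


def encode_uint16(image: np.ndarray) -> np.ndarray:
    """Round and clip a float image to the 16-bit unsigned range used on disk."""
    return np.clip(np.rint(image), 0, 65535).astype(np.uint16)


def write_fixture(scene: SyntheticScene, images: dict[str, np.ndarray],
                  directory: str | Path, *, stack: bool = False) -> dict[str, Path]:
    """Write a scene to disk: TIFF channel(s), ground-truth CSV, parameter JSON.

    Images are encoded as 16-bit unsigned TIFF.  With ``stack=True`` a single
    multi-channel stack (channel axis first, ordered as :data:`CHANNEL_ROLES`)
    is written instead of one file per channel.  Returns the paths written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if stack:
        arr = np.stack([encode_uint16(images[r]) for r in CHANNEL_ROLES])
        paths["stack"] = directory / "channels.tif"
        tifffile.imwrite(paths["stack"], arr, photometric="minisblack")
    else:
        for role in CHANNEL_ROLES:
            if role in images:
                paths[role] = directory / f"{role}.tif"
                tifffile.imwrite(paths[role], encode_uint16(images[role]))

    paths["truth"] = directory / "truth.csv"
    scene.truth_table().to_csv(paths["truth"], index=False)

    paths["params"] = directory / "scene.json"
    meta = {"seed": scene.seed, "params": asdict(scene.params),
            "channel_roles": list(CHANNEL_ROLES)}
    paths["params"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
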