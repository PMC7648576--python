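"""Shared fixtures and independent test oracles.

The oracles here are deliberately naive re-derivations (brute-force
morphology, greedy centroid matching, exact rational hypergeometric
enumeration) kept independent of the library code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from asympart import SceneParams, generate_scene, render_channels


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic scene: 20 cells, SNR ~10, seed 7."""
    params = SceneParams(n_cells=20)
    scene = generate_scene(params, seed=7)
    return scene, render_channels(scene)


@pytest.fixture(scope="session")
def clean_pair_scene():
    """A small noise-free, flat-background, unblurred telophase-only scene."""
    params = SceneParams(
        n_cells=8, stage_counts={"telophase": 8, "s_phase": 0, "g1": 0},
        psf_sigma=0.0, shot_noise=False, read_noise_sd=0.0,
        background_gradient=(0.0, 0.0), amplitude_cv=0.0)
    scene = generate_scene(params, seed=11)
    return scene, render_channels(scene)


# --------------------------------------------------------------------------
# oracles


def brute_dilate(mask: np.ndarray, steps: int) -> np.ndarray:
    """Pixelwise 3x3 neighbourhood-max dilation, repeated ``steps`` times."""
    m = mask.astype(bool)
    for _ in range(steps):
        p = np.pad(m, 1)
        out = np.zeros_like(m)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                out |= p[1 + dr:1 + dr + m.shape[0], 1 + dc:1 + dc + m.shape[1]]
        m = out
    return m


def greedy_match(truth_xy: np.ndarray, found_xy: np.ndarray,
                 max_distance: float) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-centroid matching (truth index, found index)."""
    if len(truth_xy) == 0 or len(found_xy) == 0:
        return []
    d = np.sqrt(((truth_xy[:, None, :] - found_xy[None, :, :]) ** 2).sum(axis=2))
    matches = []
    used_t, used_f = set(), set()
    for flat in np.argsort(d, axis=None):
        ti, fi = np.unravel_index(flat, d.shape)
        if d[ti, fi] > max_distance:
            break
        if ti in used_t or fi in used_f:
            continue
        matches.append((int(ti), int(fi)))
        used_t.add(int(ti))
        used_f.add(int(fi))
    return matches


def fisher_enumeration_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = prob(a)
    cutoff = p_obs * Fraction(10 ** 7 + 1, 10 ** 7)  # float-tie tolerance
    total = sum((prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                 if prob(x) <= cutoff), Fraction(0))
    return float(min(total, Fraction(1)))


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact rational enumeration."""
    denom = comb(N, n)
    total = sum((Fraction(comb(K, x) * comb(N - K, n - x), denom)
                 for x in range(k, min(K, n) + 1)), Fraction(0))
    return float(min(total, Fraction(1)))
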