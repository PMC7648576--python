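"""Telophase-pair classification and asymmetry statistics.

The reporter-presence threshold is calibrated from the corrected reporter
intensities of S-phase cells, whose nuclei lack the reporter: any corrected
intensity at or below the calibrated statistic of that reference population
counts as "reporter absent".  Each telophase mother/daughter pair is then
classified by which of its nuclei carry reporter signal, and summarised by

    AI = |daughter - mother| / (daughter + mother)

the asymmetry index, ranging from 1 (total asymmetry, signal in one nucleus
only) to 0 (total symmetry), and by the cumulative intensity, the sum of the
two corrected nuclear reporter values.  Pairs can additionally be staged as
before/after cytokinesis by the presence of a bud-neck marker object between
the two nuclei.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import LabelMask, NucleusMeasure

log = logging.getLogger(__name__)

PAIR_CATEGORIES = ("asymmetric_daughter", "asymmetric_mother", "symmetric", "none")


@dataclass(frozen=True)
class ThresholdModel:
    """Reporter-presence threshold calibrated from a reference population.

    ``statistic`` records how the threshold was derived, e.g.
    ``("percentile", 95.0)``, ``("max", None)`` or ``("fixed", value)``;
    ``reference_summary`` is the (median, q1, q3) of the reference values.
    """

    threshold: float
    statistic: tuple[str, float | None]
    n_reference: int
    reference_summary: tuple[float, float, float]

    def present(self, corrected_reporter: float) -> bool:
        """Strictly above the threshold counts as reporter present."""
        return corrected_reporter > self.threshold


@dataclass
class CellPair:
    """A telophase mother/daughter nucleus pair and its derived statistics.

    ``ai`` and ``cumulative`` are NaN until computed; ``ai`` is NaN whenever
    the cumulative corrected intensity is zero.  ``role_known`` is False for
    heuristically paired nuclei whose mother/daughter identity was not
    annotated; for those, the two asymmetric categories are reported merged
    as ``asymmetric`` in tallies.
    """

    pair_id: str
    mother: NucleusMeasure
    daughter: NucleusMeasure
    category: str | None = None
    ai: float = float("nan")
    cumulative: float = float("nan")
    cytokinesis_stage: str = "unknown"
    role_known: bool = True


def calibrate_threshold(reference_values: Sequence[float],
                        statistic: tuple[str, float | None] = ("max", None),
                        ) -> ThresholdModel:
    """Calibrate the reporter-absent threshold from S-phase corrected intensities.

    The reference population operationally defines "no reporter", so the
    default threshold is its maximum corrected intensity: anything a
    reporter-free nucleus can show counts as absence.  ``statistic``
    alternatives: ``("percentile", q)`` (linear interpolation; robust to
    reference outliers) and ``("fixed", value)``, which ignores the reference
    values beyond recording their summary.
    """
    values = np.asarray([v for v in reference_values if np.isfinite(v)], dtype=float)
    name, param = statistic
    if values.size == 0 and name != "fixed":
        raise ValueError(
            "no reference values: annotate S-phase cells or supply a fixed threshold")

    if name == "percentile":
        thr = float(np.percentile(values, float(param)))
    elif name == "max":
        thr = float(values.max())
    elif name == "fixed":
        thr = float(param)
    else:
        raise ValueError(f"unknown threshold statistic {name!r}")

    if values.size:
        summary = (float(np.median(values)),
                   float(np.percentile(values, 25)),
                   float(np.percentile(values, 75)))
        n_ref = int(values.size)
    else:
        summary = (float("nan"),) * 3
        n_ref = 0
    return ThresholdModel(threshold=thr, statistic=(name, param),
                          n_reference=n_ref, reference_summary=summary)


def pair_telophase(measures: Sequence[NucleusMeasure],
                   annotations: pd.DataFrame | None = None,
                   *, max_distance: float = 20.0) -> list[CellPair]:
    """Pair nuclei into telophase mother/daughter pairs.

    Annotation mode (``annotations`` given): pairs are taken verbatim from a
    table with columns ``pair_id``, ``mother_object_id``, ``daughter_object_id``;
    a reference to a missing object id raises with the offending ids listed.

    Heuristic mode: mutual-nearest-neighbour centroid pairs within
    ``max_distance`` pixels; roles are unknown (mother slot = lower object id)
    and unpaired nuclei are excluded with a logged count.
    """
    by_id = {m.object_id: m for m in measures}

    if annotations is not None:
        missing = sorted(
            set(annotations["mother_object_id"]).union(annotations["daughter_object_id"])
            - set(by_id))
        if missing:
            raise KeyError(f"annotation references missing object ids: {missing}")
        return [CellPair(pair_id=str(row.pair_id),
                         mother=by_id[row.mother_object_id],
                         daughter=by_id[row.daughter_object_id])
                for row in annotations.itertuples(index=False)]

    ids = sorted(by_id)
    if not ids:
        return []
    cents = np.array([by_id[i].centroid for i in ids])
    d2 = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = d2.argmin(axis=1)

    pairs: list[CellPair] = []
    used: set[int] = set()
    for i, j in enumerate(nearest):
        j = int(j)
        if i in used or j in used or i >= j:
            continue
        if nearest[j] == i and d2[i, j] <= max_distance ** 2:
            a, b = by_id[ids[i]], by_id[ids[j]]
            pairs.append(CellPair(pair_id=f"h{len(pairs)}", mother=a, daughter=b,
                                  role_known=False))
            used.update((i, j))
    n_unpaired = len(ids) - 2 * len(pairs)
    if n_unpaired:
        log.info("pair_telophase: %d nuclei left unpaired", n_unpaired)
    return pairs


def classify_pair(pair: CellPair, model: ThresholdModel) -> str:
    """Assign a pair to a category from the thresholded presence of its reporter.

    Presence is strict (corrected > threshold): (False, False) -> ``none``,
    (True, True) -> ``symmetric``, daughter only -> ``asymmetric_daughter``,
    mother only -> ``asymmetric_mother``.  Undefined corrected values yield
    ``unknown`` (excluded from tallies).
    """
    m = pair.mother.corrected_reporter
    d = pair.daughter.corrected_reporter
    if not (np.isfinite(m) and np.isfinite(d)):
        return "unknown"
    pm, pd_ = model.present(m), model.present(d)
    if pm and pd_:
        return "symmetric"
    if pd_:
        return "asymmetric_daughter"
    if pm:
        return "asymmetric_mother"
    return "none"


def asymmetry_index(mother_value: float, daughter_value: float) -> float:
    """AI = |daughter - mother| / (daughter + mother), in [0, 1].

    1 means total asymmetry (all signal in one nucleus), 0 total symmetry.
    Negative inputs (background over-subtraction) are clamped to zero with a
    logged note; a zero sum leaves the index undefined (NaN).
    """
    m, d = _clamp_nonneg(mother_value, daughter_value)
    total = m + d
    if total == 0:
        return float("nan")
    return abs(d - m) / total


def cumulative_intensity(pair: CellPair) -> float:
    """Mother + daughter corrected reporter intensity (negatives clamped to 0)."""
    m, d = _clamp_nonneg(pair.mother.corrected_reporter,
                         pair.daughter.corrected_reporter)
    return m + d


def _clamp_nonneg(*values: float) -> tuple[float, ...]:
    clamped = tuple(max(float(v), 0.0) for v in values)
    n_neg = sum(1 for v in values if v < 0)
    if n_neg:
        log.debug("clamped %d negative corrected intensities to 0", n_neg)
    return clamped


def stage_cytokinesis(pair: CellPair, budneck_measures: Sequence[NucleusMeasure] | None,
                      max_distance: float = 15.0) -> str:
    """Stage a pair before/after cytokinesis from bud-neck marker objects.

    ``before`` if any bud-neck object centroid lies within ``max_distance``
    pixels of the inter-nuclear midpoint, else ``after``; ``unknown`` when no
    bud-neck channel was analysed.
    """
    if budneck_measures is None:
        return "unknown"
    mid = ((pair.mother.centroid[0] + pair.daughter.centroid[0]) / 2.0,
           (pair.mother.centroid[1] + pair.daughter.centroid[1]) / 2.0)
    for b in budneck_measures:
        if math.dist(b.centroid, mid) <= max_distance:
            return "before"
    return "after"


def classify_pairs(pairs: Iterable[CellPair], model: ThresholdModel,
                   budneck_measures: Sequence[NucleusMeasure] | None = None,
                   *, budneck_max_distance: float = 15.0) -> list[CellPair]:
    """Fill category, AI, cumulative intensity and cytokinesis stage in place."""
    out = []
    for pair in pairs:
        pair.category = classify_pair(pair, model)
        m, d = _clamp_nonneg(pair.mother.corrected_reporter,
                             pair.daughter.corrected_reporter)
        pair.cumulative = m + d if np.isfinite(m + d) else float("nan")
        pair.ai = asymmetry_index(m, d)
        pair.cytokinesis_stage = stage_cytokinesis(pair, budneck_measures,
                                                   budneck_max_distance)
        out.append(pair)
    return out


def tally_categories(pairs: Iterable[CellPair], *, merge_asymmetric: bool = False,
                     ) -> dict[str, int]:
    """Count classified pairs per category; optionally merge the two asymmetric
    orientations into a single ``asymmetric`` bin (the reporting convention for
    screens where only 'reporter in one nucleus' matters)."""
    counts: dict[str, int] = {}
    for p in pairs:
        cat = p.category
        if cat is None or cat == "unknown":
            continue
        if merge_asymmetric and cat in ("asymmetric_daughter", "asymmetric_mother"):
            cat = "asymmetric"
        counts[cat] = counts.get(cat, 0) + 1
    return counts
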