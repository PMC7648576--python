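"""End-to-end driver: simulate -> quantify -> classify -> compare.

Runs the full analysis on either a freshly simulated scene or an existing
fixture directory, writing every intermediate table, a JSON summary with the
configuration hash and per-stage object counts, and a run log that records
attrition at each filtering step.  Identical config + seed + inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import imagegen, io, partition, segmentation, stats
from .config import RunConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def match_nuclei(truth: pd.DataFrame, measures, max_distance: float = 3.0) -> pd.DataFrame:
    """Match ground-truth nuclei to measured objects by nearest centroid.

    Greedy one-to-one matching in increasing distance order; unmatched truth
    rows get ``object_id`` -1.  Used both to derive annotations on synthetic
    fixtures (standing in for manual cell selection) and to score recovery.
    """
    truth = truth.reset_index(drop=True)
    if not measures or truth.empty:
        out = truth.copy()
        out["object_id"] = -1
        out["match_distance"] = np.nan
        return out
    cents = np.array([m.centroid for m in measures])
    obj_ids = np.array([m.object_id for m in measures])
    t_pos = truth[["row", "col"]].to_numpy(dtype=float)
    d = np.sqrt(((t_pos[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))

    assigned = np.full(len(truth), -1, dtype=int)
    dist_out = np.full(len(truth), np.nan)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_t: set[int] = set()
    used_o: set[int] = set()
    for ti, oi in order:
        if d[ti, oi] > max_distance:
            break
        if ti in used_t or oi in used_o:
            continue
        assigned[ti] = obj_ids[oi]
        dist_out[ti] = d[ti, oi]
        used_t.add(int(ti))
        used_o.add(int(oi))
    out = truth.copy()
    out["object_id"] = assigned
    out["match_distance"] = dist_out
    return out


def annotations_from_truth(matched: pd.DataFrame) -> tuple[pd.DataFrame, list[int]]:
    """Derive pair annotations and the S-phase reference object list from a
    matched ground-truth table (the synthetic analog of manual annotation)."""
    pairs = []
    telo = matched[matched["stage"] == "telophase"]
    for cell_id, grp in telo.groupby("cell_id"):
        roles = dict(zip(grp["role"], grp["object_id"]))
        if roles.get("mother", -1) >= 0 and roles.get("daughter", -1) >= 0:
            pairs.append({"pair_id": f"cell{cell_id}",
                          "mother_object_id": int(roles["mother"]),
                          "daughter_object_id": int(roles["daughter"])})
    sphase = matched[(matched["stage"] == "s_phase") & (matched["object_id"] >= 0)]
    return pd.DataFrame(pairs), [int(o) for o in sphase["object_id"]]


def quantify(channels: dict[str, np.ndarray], config: RunConfig):
    """Segment the marker channel, build rings, and measure all channels."""
    mask = segmentation.segment_nuclei(channels["marker"], config.segmentation)
    rings = segmentation.background_ring(mask, config.inner_steps, config.outer_steps)
    measured_channels = {r: img for r, img in channels.items() if r != "budneck"}
    measures = segmentation.measure_objects(mask, rings, measured_channels)

    budneck_measures = None
    if "budneck" in channels:
        bn_mask = segmentation.segment_budneck(channels["budneck"],
                                               config.budneck_segmentation)
        # staging only needs centroids; no background ring for punctae
        budneck_measures = segmentation.measure_objects(
            bn_mask, {}, {"budneck": channels["budneck"]})
    return mask, measures, budneck_measures


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs under ``config.out_dir``.

    Returns the summary bundle (also written as ``summary.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_hash {config.config_hash()}", f"seed {config.seed}"]

    # --- stage: simulate or load ------------------------------------------
    try:
        if config.input_dir is None:
            scene = imagegen.generate_scene(config.scene, config.seed)
            channels = imagegen.render_channels(scene)
            channels = {r: imagegen.encode_uint16(img).astype(float)
                        for r, img in channels.items()}
            fixture_dir = out_dir / "fixture"
            imagegen.write_fixture(scene, channels, fixture_dir)
            truth = scene.truth_table()
        else:
            fixture_dir = Path(config.input_dir)
            channels = {}
            for role in config.channel_roles:
                p = fixture_dir / f"{role}.tif"
                if p.exists():
                    channels[role] = io.read_image(p)
            if "marker" not in channels:
                raise FileNotFoundError(f"no marker channel found in {fixture_dir}")
            truth_path = fixture_dir / "truth.csv"
            truth = io.read_table(truth_path) if truth_path.exists() else None
    except Exception as exc:
        raise StageError("simulate/load", str(exc)) from exc
    log_lines.append(f"channels {sorted(channels)}")

    # --- stage: quantify ---------------------------------------------------
    try:
        mask, measures, budneck_measures = quantify(channels, config)
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc
    n_all = len(measures)
    if config.exclude_border:
        measures_kept = [m for m in measures if not m.on_border]
    else:
        measures_kept = list(measures)
    log_lines.append(f"objects_segmented {n_all}")
    log_lines.append(f"objects_border_excluded {n_all - len(measures_kept)}")
    io.write_table(io.measures_frame(measures), out_dir / "measures.csv")

    # --- stage: classify ---------------------------------------------------
    try:
        if truth is not None:
            matched = match_nuclei(truth, measures_kept)
            annotations, sphase_ids = annotations_from_truth(matched)
            by_id = {m.object_id: m for m in measures_kept}
            reference = [by_id[i].corrected.get("reporter", np.nan) for i in sphase_ids]
            model = partition.calibrate_threshold(reference, config.threshold_statistic)
            pairs = partition.pair_telophase(measures_kept, annotations)
        else:
            if config.threshold_statistic[0] != "fixed":
                raise ValueError("without annotations, a fixed threshold is required")
            model = partition.calibrate_threshold([], config.threshold_statistic)
            pairs = partition.pair_telophase(
                measures_kept, max_distance=config.pairing_max_distance)
        pairs = partition.classify_pairs(pairs, model, budneck_measures,
                                         budneck_max_distance=config.budneck_max_distance)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    log_lines.append(f"threshold {model.threshold:.6g} (n_ref {model.n_reference})")
    log_lines.append(f"pairs {len(pairs)}")
    io.write_table(io.pairs_frame(pairs), out_dir / "pairs.csv")

    # --- stage: compare ----------------------------------------------------
    tallies = partition.tally_categories(pairs, merge_asymmetric=True)
    n_classified = sum(tallies.values())
    fractions = {k: v / n_classified for k, v in tallies.items()} if n_classified else {}

    cumulative_by_cat: dict[str, list[float]] = {}
    for p in pairs:
        if p.category in (None, "unknown") or not np.isfinite(p.cumulative):
            continue
        cat = ("asymmetric" if p.category.startswith("asymmetric") else p.category)
        cumulative_by_cat.setdefault(cat, []).append(p.cumulative)
    summaries = {cat: vars(stats.summarize(v)) for cat, v in
                 sorted(cumulative_by_cat.items()) if v}
    kw = None
    multi = [v for v in cumulative_by_cat.values() if len(v) >= 2]
    if len(multi) >= 2:
        res = stats.kruskal_wallis(multi)
        kw = {"H": res.statistic, "p_value": res.p_value,
              "n_per_group": list(res.n_per_group)}

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {
            "objects_segmented": n_all,
            "objects_border_excluded": n_all - len(measures_kept),
            "pairs": len(pairs),
            "pairs_unknown": sum(p.category == "unknown" for p in pairs),
        },
        "threshold": {"value": model.threshold,
                      "statistic": list(model.statistic),
                      "n_reference": model.n_reference},
        "category_tallies": dict(sorted(tallies.items())),
        "category_fractions": dict(sorted(fractions.items())),
        "cumulative_summaries": summaries,
        "kruskal_wallis_cumulative": kw,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
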