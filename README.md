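# asympart

Quantification of asymmetric transcription-factor partitioning between the
nascent mother and daughter nuclei of dividing budding yeast, from
two-channel fluorescence microscopy.

At the end of mitosis, the *S. cerevisiae* transcription factor Ace2
accumulates in the daughter-cell nucleus only. Genetic screens use this
localization as a reporter for cell polarity: mutants are scored by whether a
fluorescently tagged Ace2 sits in one nucleus (asymmetric), both
(symmetric), or neither. `asympart` implements the quantitative image
analysis behind such screens, the statistics used to compare conditions, and
the screen-level bookkeeping — together with a seeded synthetic-scene
generator that provides ground-truth test data, since every stage must be
verifiable without access to raw microscope images.

## What it computes

Given a nuclear-marker channel (e.g. a histone-CFP fusion), a reporter
channel (e.g. Ace2-YFP) and optionally a bud-neck marker (Myo1-RFP):

1. **Segmentation** — nuclei are 4-connected components above a global
   automatic threshold on the marker channel, filtered by area.
2. **Ring background** — for each nucleus, the local background is the pixel
   set between a 4× and a 2× morphological dilation of the object (3×3
   structuring element per step), excluding pixels claimed by the inner
   dilation of any object. The *corrected* nuclear intensity of a channel is

   `corrected = mean(object) − mean(ring)`.

3. **Threshold calibration** — S-phase cells carry no nuclear reporter, so
   the corrected reporter intensities of an annotated S-phase population
   define "reporter absent": by default the threshold is their maximum
   (a 95th-percentile or fixed alternative is configurable).
4. **Pair classification** — each annotated (or mutual-nearest-neighbour
   paired) telophase mother/daughter pair is classified from the thresholded
   presence of reporter in its two nuclei: `asymmetric_daughter`,
   `asymmetric_mother`, `symmetric`, or `none`. Two summary statistics are
   attached per pair: the **asymmetry index**

   `AI = |I_d − I_m| / (I_d + I_m)  ∈ [0, 1]`

   (1 = total asymmetry, 0 = total symmetry, on corrected intensities
   `I_d`, `I_m`), and the **cumulative intensity** `I_d + I_m`. Pairs are
   staged before/after cytokinesis by the presence of a bud-neck object at
   the inter-nuclear midpoint.
5. **Statistics** — Fisher's exact test on category proportions,
   Kruskal–Wallis and Wilcoxon rank-sum tests on intensities, Wilson 95%
   confidence intervals for proportions, and median/quartile summaries.
6. **Screen module** — reconciliation of two independent scorers with a
   third resolving discrepancies, tabulation of the packaged hit-gene table
   (phenotype classes I/II/III, functional categories), one-sided Fisher
   functional enrichment against a user-supplied gene→category background,
   and coverage arithmetic.

## Worked example

```python
from asympart import RunConfig, SceneParams, run_pipeline

config = RunConfig(
    seed=7,
    out_dir="demo_run",
    scene=SceneParams(n_cells=40,
                      stage_counts={"telophase": 28, "s_phase": 10, "g1": 2}),
)
summary = run_pipeline(config)
print("threshold:", round(summary["threshold"]["value"], 2),
      "from", summary["threshold"]["n_reference"], "S-phase nuclei")
print("tallies:", summary["category_tallies"])
print("median cumulative:", {k: round(v["median"], 1)
                             for k, v in summary["cumulative_summaries"].items()})
```

prints

```
threshold: 1.26 from 10 S-phase nuclei
tallies: {'asymmetric': 21, 'none': 3, 'symmetric': 4}
median cumulative: {'asymmetric': 61.5, 'none': 0.5, 'symmetric': 120.1}
```

The simulated scene contained 28 dividing cells drawn from a mixture of 72%
asymmetric / 13% symmetric / 15% reporter-free; all 28 pairs were recovered
and the tallies (75% / 14% / 11%) recover that mixture within sampling
error. The reporter-absent threshold (1.26 a.u.) was calibrated from the 10
S-phase nuclei in the same scene. Symmetric pairs carry roughly twice the
cumulative reporter signal of asymmetric ones (120 vs 62 a.u.) because the
generator places the same per-nucleus amplitude in both nuclei — the same
qualitative pattern seen in real symmetric mutants. `demo_run/` now holds
the rendered TIFFs, ground truth, per-nucleus measurements, per-pair
classifications and a JSON summary stamped with the configuration hash.

The same pipeline is available as a CLI:

```sh
asympart simulate --seed 7 --out fx/
asympart quantify --marker fx/marker.tif --reporter fx/reporter.tif --out measures.csv
asympart classify --measures measures.csv --sphase sphase.csv --out pairs.csv
asympart compare  --pairs pairs.csv --out comparison.json
asympart screen   --out screen.json
asympart run      --config config.yaml --seed 7 --out run/
```

## Layout

- `src/asympart/imagegen.py` — synthetic scenes with full ground truth
- `src/asympart/segmentation.py` — nuclei/bud-neck segmentation, rings, measurement
- `src/asympart/partition.py` — threshold calibration, pairing, classification, AI
- `src/asympart/stats.py` — exact and rank tests, proportion CIs, summaries
- `src/asympart/screen.py` — scorer reconciliation, tabulation, enrichment
- `src/asympart/{config,pipeline,io,cli}.py` — configuration, driver, I/O, CLI
- `docs/methods.md` — model, parameters, numerical choices and limitations
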