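# Methods

## The measurement model

The pipeline quantifies how a nuclear reporter partitions between the two
nascent nuclei of a dividing yeast cell. Its core assumptions:

- Nuclei are compact, roughly disc-shaped objects bright in a constitutive
  nuclear-marker channel, so a single global threshold separates them from
  background. No watershed splitting is attempted; the telophase geometry of
  interest (two nuclei ~14 px apart at ~4 px radius) keeps objects disjoint.
- Local background varies smoothly on the scale of a nucleus, so the mean
  over a ring 2–4 dilation steps away estimates the background under the
  object. The ring excludes the inner dilation of *every* object (a
  neighbouring nucleus must not inflate a background estimate); where rings
  of two objects overlap, those diffuse-background pixels count for both.
- "Reporter absent" is defined operationally by a reference population of
  S-phase cells, which exclude the reporter from the nucleus. Any corrected
  intensity a reporter-free nucleus can show must count as absence, so the
  default threshold is the maximum of the reference values; presence is
  strict (`corrected > threshold`), keeping boundary values negative.
- Mother/daughter identity comes from annotation, never from nucleus size:
  delayed daughters can be larger than mothers, so size-based inference
  would bias exactly the mutants of interest.

The per-pair statistics are the asymmetry index
`AI = |I_d − I_m| / (I_d + I_m)` and the cumulative intensity `I_d + I_m`,
both on corrected intensities with negative values (background
over-subtraction) clamped to zero and the clamp count logged. AI uses the
absolute difference, forced by its stated 0–1 range for both orientations;
it is undefined (NaN) when the cumulative intensity is zero. Classification
and AI are computed on corrected rather than raw intensities, consistent
with every other step of the measurement chain.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `inner_steps`, `outer_steps` | 2, 4 | ring = 4× minus 2× dilation; one step = one 3×3 dilation (iterate-N semantics; the dilation unit is otherwise ambiguous) |
| threshold method (nuclei) | Otsu | "automatic" global threshold; fixed value available |
| threshold method (bud neck) | median + 8·MAD | the punctate channel's foreground fraction (<0.1%) is far too small for a histogram split; Otsu lands inside the noise and shatters the background |
| area band (nuclei) | 5–2000 px | rejects specks and fused blobs at radius ~4 px |
| area band (bud neck) | 2–40 px | a whole nucleus bleeding into the channel is rejected |
| threshold statistic | max of reference | see above; `("percentile", 95)` available when the reference may contain outliers (a p95 threshold concedes ~5% false presence per reporter-free nucleus by construction) |
| pairing `max_distance` | 20 px | mutual-nearest-neighbour gate, above the 14 px pair separation and below the ~20 px inter-cell clearance |
| bud-neck `max_distance` | 15 px | a bud-neck object within this range of the inter-nuclear midpoint stages the pair "before cytokinesis" |
| border objects | excluded | measured and flagged, but dropped from pair statistics by default |

Intensities are in arbitrary units (a.u.) throughout; images are written as
16-bit unsigned TIFF and processed as floats.

## The synthetic-scene generator

Scenes emulate fields of dividing cells at mitotic exit: telophase cells
contribute a mother and a daughter nucleus 14 px apart, S-phase and G1 cells
one nucleus. Nuclei are hard discs (radius 4 px) of constant amplitude —
chosen so area-based flux oracles are exact — blurred by a Gaussian PSF
(σ = 1 px), on a linear background (10 a.u. + 0.005 a.u./px per axis),
degraded by Poisson shot noise and Gaussian read noise (sd 2 a.u.). Marker
amplitude 100 a.u. gives a marker SNR of ~10. Reporter amplitude (80 a.u.,
15% cell-to-cell CV) appears exactly in the nuclei named by the cell's
ground-truth category; the default category mixture (72% daughter-only
asymmetric, 13% symmetric, 15% none) reflects a largely asymmetric
wild-type telophase population. Bud necks are small bright discs at the
pair midpoint in half of the telophase cells. Placement is
rejection-sampled so nuclei of distinct cells stay disjoint even after a 4×
dilation, and all randomness flows from one seed.

What the generator does **not** model: 3-D structure, photobleaching,
uneven illumination beyond the linear gradient, camera binning, cell bodies
or cytoplasmic reporter pools, and segmentation-confusing contacts between
cells. Passing the recovery tests therefore demonstrates that the
measurement chain is correct under its own assumptions — not that the
segmentation would survive crowded or low-contrast real fields.

## Numerical choices and degenerate inputs

- Percentiles and quartiles use linear interpolation everywhere.
- The two-sided Fisher p-value is the probability-mass convention (sum of
  tables no more likely than observed, with a 1+1e-7 relative tolerance for
  float ties), matching mainstream statistics packages; enrichment tests are
  one-sided (greater). No multiple-testing correction is applied anywhere.
- Wilcoxon rank-sum: exact enumeration when the smaller sample has ≤8
  tie-free observations, else a continuity-corrected normal approximation
  with tie-corrected variance; the method used is recorded. Kruskal–Wallis
  uses midranks with tie correction and a χ² p-value; all-identical pooled
  data short-circuit to H = 0, p = 1.
- Proportion CIs default to Wilson score, whose bounds are exactly 0 at 0/n
  and exactly 1 at n/n (both occur in screen data); Clopper–Pearson is
  available.
- Constant images segment to zero objects (not an error). Objects with an
  empty background ring carry NaN corrected intensities and a flag; such
  pairs classify as `unknown` and leave all tallies.
- Screen percentages round half-up to integers, the reporting convention of
  the tabulated screen summaries.
- A scene that cannot be placed at the requested density fails with an
  explicit error after a bounded number of rejection-sampling tries.

## Design notes

- Manual steps of the original protocol (telophase selection, S-phase
  annotation, mother/daughter assignment) are replaced by annotation tables;
  a mutual-nearest-neighbour heuristic pairing mode exists for synthetic
  data and leaves roles marked unknown. The two asymmetric orientations are
  tracked separately and merged into one "asymmetric" bin for screen-style
  tallies.
- Background rings are computed per object rather than as one shared
  background region; with the every-object exclusion rule the difference is
  immaterial for diffuse background but per-object rings keep the estimate
  local.
- Reporter-driven segmentation (for experiments lacking a marker channel) is
  the same algorithm on the reporter image; its output records the caveat
  that reporter-negative nuclei are invisible, so category tallies from that
  mode exclude reporter-free cells by construction.

## Known limitations

- In the exact zero-noise limit with a background gradient, absence calls
  rest on a ±5×10⁻³ a.u. bias: a pair nucleus's ring is truncated on the
  partner side, so its background sample is spatially offset in a way the
  isolated reference nuclei do not share. At any realistic noise level the
  calibrated threshold sits two orders of magnitude above this bias and
  classification accuracy is ≥95%; the bias only surfaces when both noise
  sources are switched off while the gradient is kept.
- Otsu's global threshold assumes the marker histogram is effectively
  bimodal. On nearly noise-free images with a steep background ramp it can
  place the threshold inside the ramp; the area band and border flagging
  absorb the resulting artefacts in practice.
- Recovery and determinism tests run on scenes of 20–140 cells on 512²–1024²
  frames, sizes at which every stage completes in seconds on one core.
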