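# Methods

## Model and assumptions

`octstrut` detects metallic stent struts in polar IVOCT pullback runs.
The physical model is the standard one for metal in OCT: a strut is a
near-total reflector, so along its A-line the intensity profile shows a
high, narrow peak followed immediately by a trailing shadow that extends
to the far edge of the frame; vessel tissue instead scatters, producing
a peak at the lumen boundary that decays roughly exponentially with
depth. Because the shadow is aligned with the beam, it appears as a
nearly horizontal dark band in the polar frame, bounded above and below
by long bright-to-dark transitions.

The pipeline assumes:

* **one strut per A-line** — overlapping stents are out of scope;
* the **z-offset is already corrected**, so catheter ring artifacts are
  frame-constant vertical lines near depth 0;
* struts are reflective metal; bioabsorbable struts (dark boxes without
  a bright spot) are not detectable by this model;
* the angular axis wraps: row 0 and row `n_alines − 1` are neighbours,
  and every distance on that axis is computed modulo `n_alines`.

## Pipeline parameters

All tunables live in `DetectionParameters`. The pixel-valued defaults
are calibrated for the clinical 504 A-lines × 960 depth-sample frame:

| parameter | default | meaning |
|---|---|---|
| `noise_percentile` | 0.05 | fraction of the global histogram zeroed as noise |
| `shadow_intensity_percentile` | 0.89 | ROI-histogram percentile defining "shadow-dark" |
| `sliding_shadow_size` | 30 px | continuous low-intensity window that counts as a shadow |
| `slope_threshold` | −48 /px | peak-to-shadow slope at/below which a peak is a candidate |
| `gaussian_sigma` | 1.5 px | smoothing before edge detection |
| `edge_length_threshold` | 100 px | minimum depth extent of a shadow edge |
| `clustering_distance_threshold` | 4 px | single-linkage merge distance |
| `guide_wire_distance_threshold` | 40 px | max frame-to-frame wire displacement |
| `acceptance_distance` | 10 px (≈ 0.05 mm) | match tolerance vs reference positions |

Percentiles use a rank-based convention (order statistic at rank
`⌈p·N⌉`, no interpolation) appropriate for integer 16-bit data.
`scaled_for(n_alines, n_depth)` rescales the defaults for other frame
sizes: depth-axis windows scale with the depth ratio, the slope
threshold scales inversely (the same intensity drop happens over fewer
pixels), isotropic distances scale with the mean axis ratio, and the
clustering threshold is left alone because candidates of one strut sit
on consecutive A-line rows at any angular sampling.

Constants the model leaves open are fixed as implementation choices and
exposed in the configuration:

* **Edge response threshold** — Otsu's threshold computed on the *log*
  of the positive compass responses of each frame. Edge strength spans
  orders of magnitude (strut-blob transitions dwarf the tissue→shadow
  boundary), so a linear-domain Otsu locks onto the blobs and misses the
  shadow boundary entirely. An absolute override is available.
* **Edge shadow-contrast gate** (`edge_contrast_ratio` = 2) — an
  accepted edge must separate a bright side from a side at least twice
  darker (brightest nearby row vs darkest nearby row over the edge
  span). Per-frame automatic thresholding has nothing meaningful to find
  on a shadow-free frame (the response distribution is unimodal) and
  would otherwise fabricate long false edges there. The min/max over a
  4-row neighbourhood makes the gate robust to narrow shadows (the guide
  wire's band is only ~3 rows) and to the 1–2 row offset between the
  extracted edge row and the true boundary.
* **Catheter line detector** — a depth column is an artifact line when
  ≥ 95% of its rows in the z-minimum image exceed the noise floor;
  only the leftmost 25% of columns are searched.
* **Non-bright recovery window** — anchored on the *deeper* of the two
  edge start columns (−10/+30 px at clinical scale). Edge runs can begin
  shallow of the strut where tissue contrast already exists; anchoring
  on the shallow start lets foreground tissue win the per-row maximum
  and displaces the recovered strut. At least 2 supra-threshold pixels
  are required.
* **Guide-wire track** — the longest run of consecutive frames whose
  closest-to-catheter detections chain within the distance threshold;
  accepted as a wire at ≥ 80% frame coverage. At most one detection per
  frame is flagged (the nearest within the acceptance distance).
* **Stented segment** — per-frame strut counts smoothed with a 5-frame
  moving average; the segment is the longest run with smoothed count
  ≥ 3. Filtered detections are re-flagged, never deleted, so the full
  audit trail survives in the output CSV.
* **Sweep convention** — the "max shadow intensity threshold" is varied
  as the derived intensity value (±20% of the computed percentile
  threshold), since ±20% of the 0.89 percentile itself would exceed 1.

Tie-breaks: A-line peak ties resolve toward the smallest depth (the
front edge is the quantity of interest); strut positions round to the
nearest integer, ties to even; the angular coordinate of a cluster is a
circular mean, so clusters straddling the frame seam land on the correct
row.

## Synthetic phantoms

The generator (`octstrut.synthetic`) emulates the image structure the
detector relies on, at a desk-scale geometry of 64 frames × 128 A-lines
× 256 depth samples so the full suite runs in seconds; parameters rescale
through the same `scaled_for` path used for real-size data.

What it models: exponential tissue attenuation from a lumen boundary
that varies along the pullback and around the circumference (so no
tissue column is frame-constant, as with a moving vessel); multiplicative
gamma speckle (mean 1, shape from the requested coefficient of
variation — the standard stand-in for coherent-imaging speckle) plus an
additive exponential background; struts as bright tapered blobs with
full-depth shadows in the four status classes (apposed on the lumen,
covered under a 6 px tissue layer, malapposed 10 px in front of the
lumen, non-bright: buried 25 px deep with brightness 1100, comparable to
the tissue peak of 1200 — too dim for the slope test but above typical
shadow intensities); a bright guide wire near the catheter drifting
continuously across frames; frame-constant catheter artifact columns;
and strut-free margin frames (8 on each side).

What it does not model: sunflower and seam artifacts, residual blood or
bubble noise, the true OCT point-spread function, motion between
A-lines, or realistic stent mesh geometry (struts are independent
rings). Passing phantom tests therefore demonstrates the pipeline's
contracts — correct thresholds, clustering, edge logic, wire and segment
filters — not clinical-grade performance; the clinically reported
accuracy of this class of method can only be established on expert-
annotated pullbacks.

The phantom conditions are fixed study conditions, not tuning knobs: the
standard high-quality scenario has 8 struts per frame over frames 8–55
(384 ground-truth positions), speckle cv 0.3, and a guide wire; the
low-quality variant triples the speckle and dims the struts.

## Numerical and degenerate-input behaviour

* Percentile thresholds are exact order statistics (`np.partition`), so
  they always equal an observed pixel value; a constant image yields
  that constant.
* A shadow window truncated by the far image edge is accepted when at
  least half of it remains, so deep struts near the border still cast a
  detectable shadow.
* Empty inputs degrade cleanly: all-zero A-lines yield no peak; frames
  without edges keep no clusters; a pullback with no qualifying frames
  yields an empty stented segment and every detection flagged; a
  single-frame pullback cannot define wire continuity and is left
  untouched.
* Single-linkage merging is *strictly below* the threshold and is
  implemented as connected components, hence independent of input order.
* Matching is an optimal one-to-one assignment per frame
  (`linear_sum_assignment` with out-of-tolerance pairs priced
  prohibitively): it maximises within-tolerance matches, then minimises
  total distance, and is therefore reproducible and order-free.

## Known limitations

* Struts whose shadow is entirely blurred away (severe restenosis) or
  that consist of a shadow with no bright spot at all are beyond the
  model, as are bioabsorbable struts.
* Touching struts can merge into one cluster; the method does not split
  clusters using stent-design patterns.
* The guide-wire filter assumes the wire is closer to the catheter than
  any strut; a severely malapposed strut in front of the wire would
  confuse the track.
* The slope threshold is expressed in raw intensity units per pixel and
  is therefore tied to the acquisition's intensity scale; data on a
  different scale needs a rescaled threshold (the scale-invariance is
  exact and tested).
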