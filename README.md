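# gazerf

Analysis of feature-selective neuronal responses during natural-image free
viewing.

When a primate freely views a scene, every fixation is a single trial:
gaze places a different image patch in each neuron's receptive field (RF)
several times per second. `gazerf` implements an analysis pipeline for
such recordings, built around *return fixations* — moments when gaze
revisits an image location it has seen before:

* **Self-consistency** — the Pearson correlation *r* of a unit's
  per-fixation responses across return-fixation pairs (distance ≤ 1 dva,
  within or across presentations), the single-trial analogue of
  split-half reliability. Computed in fixed windows, 50-ms sliding bins,
  distance-threshold profiles, and presentation-time curves, with a
  decorrelation rule that removes pairs whose neighboring fixations are
  within 4 dva.
* **Response latency** — the time the current-return self-consistency
  curve first exceeds the previous-return curve, with pair-resampling
  bootstrap, hierarchical regularization over arrays/banks/electrodes,
  and an imputation cascade with per-area defaults.
* **Face selectivity** — FSI = (a − b)/(a + b) over mean face and nonface
  fixation responses, with matched-saccade controls (templates and
  controls start ≤ 1 dva apart and end ≥ 4 dva apart) that hold the
  presaccadic stimulus fixed.
* **Model-based RF inference** — ridge readouts of patch features on a
  15 × 15 fixation-anchored offset grid (−7..7 dva), cross-validated over
  images, summarized by elliptical-Gaussian fits
  (FWHM = 2.355·√(ab)), with saccade-aligned RF1/RF2/midpoint time
  courses and normalized-saccade joint maps for remapping analyses.
* **Statistics** — monkey-weighted permutation tests (the unit of
  permutation is the fixation pair), hierarchical bootstrap CIs, rank
  tests, and two-stage Benjamini–Krieger–Yekutieli FDR control.

A synthetic-session generator (`gazerf.synthetic`) produces complete
sessions — procedural images with optional face ROIs, realistic gaze
(fixations 276 ± 49 ms, saccades 50 ± 5 ms and 5.4 ± 0.9 dva, frequent
return fixations), and ground-truth retinotopic responses from Gaussian
RFs with known centers, sizes and lags — so every estimator is validated
by parameter recovery. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Simulate a session whose four units have a 100-ms response lag, detect
events, and run the three core estimators:

```python
import gazerf as gz
from gazerf.consistency import BinSpec
from gazerf.rfmap import (RF_GRID, extract_patch_features, get_extractor,
                          offset_grid, offset_feature_stack, map_rf,
                          fit_gaussian_rf)

synth = gz.make_benchmark_session("lagged-100", seed=7, n_images=20,
                                  n_presentations=100, n_units=4)
session = synth.session

fix, sacc = gz.detect_session(session)
fix = gz.attach_images(gz.select_fixations(fix, session.schedule),
                       session.schedule)

pairs = gz.decorrelate_pairs(gz.build_pairs(fix, "current_return", 1.0), fix)
prev = gz.decorrelate_pairs(gz.build_pairs(fix, "previous_return", 1.0), fix)
source = gz.ResponseSource(session)
bins = BinSpec()

unit = session.unit_ids[0]
binned = source.binned(unit, fix["onset"].to_numpy(), bins)
resp = source.window_rates(unit, fix["onset"].to_numpy(), 140.0, 290.0)
sc = gz.pair_self_consistency(pairs, resp, fix, decorrelate=True)

tc_c = gz.sc_timecourse(pairs, binned, fix, bins, decorrelate=True)
tc_p = gz.sc_timecourse(prev, binned, fix, bins, decorrelate=True)
latency = gz.crossing_latency(tc_c, tc_p)

grids = extract_patch_features(session.images, RF_GRID,
                               get_extractor("gabor-bank"))
valid = fix[fix["valid"]].reset_index(drop=True)
ox, oy = offset_grid()
stack = offset_feature_stack(grids, valid["image_id"].to_numpy(),
                             valid["x"].to_numpy(), valid["y"].to_numpy(),
                             ox, oy)
resp = source.window_rates(unit, valid["onset"].to_numpy(), 140.0, 290.0)
rfmap = map_rf(stack, resp, valid["image_id"].to_numpy())
g = fit_gaussian_rf(rfmap.mean_map(), ox, oy)
```

Output:

```text
481 valid fixations, 409 saccades
u00: return self-consistency r = 0.72 over 155 pairs
u00: crossing-point latency = 125 ms (simulated lag 100 ms)
u00: RF center (-0.07, -0.09) dva, FWHM 2.64 dva  [truth: (+0, +0), sigma 1]
```

Reading the numbers: responses in the post-latency window correlate at
r = 0.72 across revisits of the same image location — this unit is
feature-selective and gaze-specific. The current/previous-return crossing
point lands one 25-ms bin from the simulated 100-ms lag. The model-based
map, fitted with a *different* feature bank than the one that generated
the responses, localizes the foveal ground-truth RF to within 0.1 dva.

There is also a small CLI for session-level steps:

```bash
gazerf simulate --preset noiseless-retinotopic --seed 7 --out DIR
gazerf validate DIR
gazerf detect DIR
gazerf sc DIR --rule current_return --threshold 1 --window 25 100
```

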