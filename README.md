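# territoria

Quantitative analysis of chromosome-territory organization in 2D confocal
projections of cultured nuclei.

## The problem

Whole-chromosome paint probes visualize the discrete nuclear region — the
*territory* — occupied by one chromosome, alongside a DAPI counterstain that
delineates the nucleus and approximates local DNA density. Comparing
territory organization across conditions (e.g. proliferating myoblasts,
differentiated myotubes, rhabdomyosarcoma lines) requires turning
two-channel z-stacks into per-nucleus numbers: nuclear shape, how much of
the nucleus a chromosome occupies, how peripherally it sits, whether it
fragments, whether it sits in dense or open chromatin, and — the most
discriminating readout — whether it prefers the major nuclear axis more
than random positioning would predict.

`territoria` implements that measurement pipeline as a tested Python
library, together with a synthetic-scene generator with full ground truth,
so every stage is verifiable without microscopy data.

## What it computes

For a DAPI projection `I` and paint projection `P`:

- **Segmentation** — nuclei: non-local-means smoothing, Kapur
  maximum-entropy threshold (the level `t` maximizing
  `H({I ≤ t}) + H({I > t})`, `H` = Shannon entropy of the class-normalized
  histogram), radius-2 morphological closing, then discard components
  > 10,000 px or touching the frame. Territories: radius-2 median filter,
  Kapur threshold restricted to intranuclear pixels, keep components with
  area in [100, 10,000] px.
- **Morphometry** — moment-equivalent-ellipse axes (full lengths, µm),
  area, eccentricity `e = √(1 − (b/a)²)`, orientation; fragmentation score
  = number of paint signals per nucleus, dichotomized at ≤ 2 / > 2.
- **Radial profiles** — each nucleus is split into 6 concentric rings of
  equal width in normalized distance-to-edge `ρ = 1 − d_edge/d_edge,max`
  (ring 1 central, ring 6 peripheral); per-ring paint-signal fractions and
  DAPI means.
- **DNA-density ratio** — `R = median(DAPI | territory) /
  median(DAPI | nucleus)`, invariant to staining/illumination scale.
- **Axial orientation** — `θ` = angle between the major-axis line and the
  nucleus-to-territory centroid vector, folded to [0°, 180°);
  *major-parallel* iff `θ ≤ 45°` or `θ ≥ 135°`; per-cell classification for
  diploid (both-minor vs one-plus-major) and aneuploid (≥ 50 % major)
  schemes.
- **Null models and tests** — the probability that a *randomly* placed
  territory is major-parallel: 0.5 (naive), `(2/π)·arctan(a/b)` for a
  uniform point in the nuclear ellipse (closed-form axis-length
  correction), or Monte-Carlo over the actual mask; exact two-sided
  binomial (minimum-likelihood) and Fisher tests, Welch *t*, coefficients
  of variation.

## Worked example

`python examples/03_axial_orientation_stats.py` renders 100 single-nucleus
scenes whose territories have a true major-parallel probability of 0.75,
runs the full segmentation + measurement pipeline, and tests the measured
fraction against two random-positioning nulls:

```
measured major-parallel: 71/97 = 0.73 (true probability 0.75)
vs naive null p0 = 0.5:            p = 5.46e-06
vs ellipse-corrected p0 = 0.626:    p = 3.53e-02
```

97 of 100 territories survive segmentation; the measured fraction (0.73)
recovers the generated bias. The preference is highly significant against
the naive null and still significant against the ellipse-corrected null
`p0 = (2/π)·arctan(1.5) ≈ 0.626`, i.e. it is not an artifact of nuclear
elongation. An unbiased cohort in the same run yields `39/98, p = 0.054` —
no false preference. The other examples demonstrate segmentation against
ground truth (`01`), radial profiles and the peripheral DAPI rise (`02`),
and the batch pipeline with its CSV/provenance outputs (`04`).

A thin CLI wraps the same library for batch use:

```bash
territoria simulate --cohort-spec cohort.yaml --seed 1 --out-dir scenes/
territoria run --config run.yaml
```

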