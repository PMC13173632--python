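# cervitrace

Cervical length (CL) measured by transvaginal ultrasound is a standard
predictor of spontaneous preterm birth (sPTB), but in the first
trimester the cervix is often curved, and the conventional straight
calipers systematically under-read it.  `cervitrace` implements an
automated measurement pipeline for this setting and the statistics to
evaluate it as a screening marker:

1. **Segmentation** — a modified ResUNet (U-Net with a ResNet-style
   residual encoder) labels the endocervical canal in a midsagittal
   grayscale frame, trained with a combined binary cross-entropy +
   log-Dice objective:

   L = L_BCE + L_LogDice,  with
   L_BCE = −(1/N) Σᵢ [xᵢ log x̃ᵢ + (1−xᵢ) log(1−x̃ᵢ)] and
   L_LogDice = −log[(2 Σᵢ xᵢx̃ᵢ + s) / (Σᵢ xᵢ + Σᵢ x̃ᵢ + s)]

2. **Caliper** — the binary mask is skeletonized into an ordered canal
   trace from the internal to the external os, from which three CLs
   are derived: the *single-line* chord ‖os_int − os_ext‖, the
   *two-line* sum of chords joined at the point of greatest curvature,
   and the *AI-line* traced arc length Σ‖pᵢ₊₁ − pᵢ‖.

3. **Screening evaluation** — multiples of the median (MoM = CL /
   population median), Shapiro–Wilk + t tests + one-way ANOVA across
   outcome groups, covariate-adjusted logistic regression, AUROC with
   DeLong confidence intervals and the paired DeLong test comparing
   two measurement methods on the same subjects.

Because clinical images cannot be redistributed, the package ships a
first-class **phantom module**: synthetic speckle images of a bright
glandular band around a darker curved canal whose centerline is an
explicit parametric curve, so the true chord and arc length are known
analytically — every stage of the pipeline is validated against that
geometry, and a cohort generator emulates the screening population for
the statistics layer.

## Worked example

A semicircular canal of radius 15 mm has chord 30 mm but arc
15π ≈ 47.12 mm.  Running `python examples/02_measure_lengths.py`:

```
single-line:  30.00 mm   (true chord 30.00)
two-line:     42.43 mm   (true 42.43)
AI-line:      47.19 mm   (true arc 47.12)
AI-line error vs analytic arc: 0.13%
```

The straight caliper misses 17 mm of cervix on this geometry; the
traced arc recovers it to 0.13%.  On the screening side,
`python examples/04_screening_evaluation.py` evaluates a synthetic
cohort of 1585 term + 79 preterm pregnancies in which only the arc
length separates the outcome groups:

```
AUROC for sPTB <37 weeks (shorter length => higher risk):
  single-line: 51.8% (95% CI 45.7-58.0)
     two-line: 55.5% (95% CI 49.4-61.6)
      ai-line: 69.8% (95% CI 64.7-74.9)

paired DeLong ai_vs_single: delta AUROC +0.180, p = 3.91e-12
```

— the mechanism by which an arc-length caliper outperforms chord-based
ones when the cervix is curved.  `examples/03_train_segmenter.py`
trains the tiny network preset end to end on a CPU and prints the
held-out Dice overlap (≈0.96 after 25 epochs on 60 small phantoms).

## Command line

A thin CLI wraps the library: `cervitrace phantom`, `train`,
`segment`, `measure`, `evaluate` and `demo` (a small end-to-end run).
For instance:

```bash
cervitrace phantom --out phantoms/ --count 5 --seed 1
cervitrace measure --masks phantoms/ --out measurements.csv
```

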