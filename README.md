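# motorpop

Analysis pipeline for trial-structured population calcium imaging during
a push/pull lever task, for researchers asking how motor-cortex layer-5B
populations encode movement *timing* versus movement *type*: most
neurons respond identically to opposing movements (movement-invariant),
a minority respond differently (movement bias), and only the latter
carry movement-type information decodable trial by trial.

The package implements, with a synthetic ground-truth generator to
validate every step:

- **Preprocessing** — motion index `MI_f = Σ_i (c_{f+1,i} − c_{f,i})²`
  over a forelimb ROI, 1 s LOESS smoothing, ΔF/F₀ with
  F₀ = 5th percentile of the 1 Hz low-passed trace, motion-index onset
  detection, trial alignment.
- **Response classification** — two bootstrap tests (baseline-to-peak CI
  vs 0; 250 ms bin CIs vs baseline CI) classify neurons as
  movement-related / reward-phase / non-responsive, then the same
  contrast across movements yields movement-invariant vs push/pull bias
  and bias types 1–4.
- **Onset detection** — slope-sum function (Savitzky–Golay 27 frames
  order 2, 375 ms window, 10%-of-peak threshold), calibrated on
  simulated linear ramps with known onsets.
- **Decoding** — leave-one-out Gaussian naive Bayes per neuron with a
  simulated-null session threshold (mean + 2 SD) and HDA flags;
  leave-one-out logistic regression for the population, with ordered and
  random neuron-removal curves against a shuffled-label chance band.
- **Trajectories** — PCA on boxcar-filtered, whitened peri-movement
  activity;
  `d'(t) = |m_push − m_pull| / √(0.5 (v_push + v_pull))`
  per PC with trial-shuffle significance.
- **Spatiotemporal statistics** — pairwise activity correlations and ROI
  distances, bootstrapped HDA-vs-population median differences, HDA time
  course, and the REML mixed model
  `r ~ distance × accuracy + (1|movement) + (1|animal)`.

## Worked example

The numbered scripts under `analysis/` run the stages on a 50-neuron,
20-trials-per-movement synthetic session (written to
`results/session/`); each re-runs its predecessors deterministically.

```sh
$ python analysis/04_classify.py
movement-related: 45/50 neurons (90.0%)
bias of movement-related neurons: {'invariant': 29, 'push': 8, 'pull': 8}
bias types: {1: 12, 2: 1, 3: 1}
planted invariant neurons recovered as invariant: 100%
```

The generator planted 29 invariant, 16 bias and 5 non-responsive
neurons: the bootstrap classification recovers the invariant majority
and the push/pull split exactly here, and the bias-type table shows the
expected dominance of type 1 (responses in both movements, larger in the
preferred one).

```sh
$ python analysis/05_decode.py
session null threshold: 0.722
median single-neuron max accuracy: 0.750
HDA neurons: 15/50
population max accuracy (best 250 ms bin): 1.000
ordered removal reaches chance after 15/50 neurons removed
```

The null threshold (0.722) is what label-free data of this trial count
reaches by chance; 15 neurons beat it (the planted bias neurons plus
borderline cases), the pooled population decodes the movement type
perfectly, and removing the most informative neurons first collapses the
population decoder after ~15 removals — the information lives in a small
subpopulation.

```sh
$ python analysis/06_trajectories.py
16 PCs explain 91.2% of variance
1 separable PC(s); largest significant d' = 19.17 on PC1
```

The same pipeline runs from the command line
(`motorpop report --seed 0 --out results/session`) or from Python via
`motorpop.run_pipeline`.

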