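# micsp

Analysis toolbox for seven-class motor-imagery EEG: preprocessing,
event-related spectral features, and three one-vs-rest multiclass common
spatial pattern (CSP) variants with cross-validated SVM classification.
Includes a synthetic EEG generator with planted ground truth so every stage
is testable without recorded data.

## What it does

* **io_preprocess** — `Epochs` container (trials × channels × samples, labels
  1–7) with an HDF5 on-disk format, channel layouts (`name,x,y` CSV), and the
  preprocessing chain: common average reference, zero-phase Butterworth
  band-pass, anti-aliased downsampling, interval cropping.
* **spectral_features** — event-related spectral perturbation (ERSP) maps in
  dB vs. a pre-cue baseline (STFT: 0.5 s Hann, 90% overlap, 1–35 Hz at
  0.5 Hz); per-frequency band-power curves with paired t-tests across
  subjects; power spectral entropy (Shannon entropy of the 5–35 Hz Welch
  spectrum, in nats); the spatial distribution coefficient (entropy over
  channels of relative task-vs-rest alpha power change); per-electrode
  topography values.
* **csp** — trace-normalized covariance estimation with identity shrinkage,
  whitening, and three filter banks per class: `multi_csp`
  (whiten-then-diagonalize), `gecsp` (generalized eigenproblem, algebraically
  equivalent), and `strcsp` (denominator regularized by a stationarity
  penalty — matrix-absolute-value of per-trial covariance deviations — plus a
  Tikhonov term; reduces exactly to `gecsp` at α = β = 0). Spatial patterns
  via the inverse filter matrix.
* **classify** — log-variance features from the top-k filters of every class
  bank, linear SVM (one-vs-one), stratified tenfold cross-validation with
  leak-free nested selection of k and (α, β) over the 10-point grid
  {0, 2⁻⁸ … 2⁰}, and method comparison tables with paired t-tests.
* **synth** — 64-channel 10/20-style montage, band-limited mu/beta sources at
  hand/foot sensorimotor sites mixed with Gaussian spatial spreads,
  class-dependent ERD (compound-limb classes attenuate more sources over
  broader bands), 1/f + spatially correlated noise, optional nonstationarity
  (source-gain drift and sparse artifacts). Deterministic per seed, with the
  mixing matrix and amplitude schedule returned as ground truth.
* **pipeline / cli** — the two end-to-end workflows: six-group feature
  comparison (BH vs LH, BH vs RH, LH&RF vs LH, RH&LF vs RH, LH&RF vs F,
  RH&LF vs F) and a methods × subjects classification benchmark, with CSV/JSON
  reports and a reproducibility manifest.

## CLI

```bash
micsp simulate --seed 42 --out data.h5 --truth-out truth        # synthetic session
micsp preprocess data.h5 prep.h5 --band 1 40 --target-fs 200    # CAR/filter/decimate
micsp ersp prep.h5 --class-id 1 --channel C3 --out ersp.csv     # time-frequency map
micsp pse prep.h5 --channel CZ                                  # entropy per class
micsp sdc prep.h5 --task-class 5                                # spatial distribution
micsp filters prep.h5 --method strcsp --alpha 0.25 --out bank.h5
micsp evaluate prep.h5 --method strcsp --k-grid 1:6 \
    --alpha-grid paper --beta-grid paper --folds 10 --seed 7
micsp benchmark s1.h5 s2.h5 --methods multi_csp,gecsp,strcsp --outdir results
micsp compare-groups s1.h5 s2.h5 --outdir results               # six-group features
micsp layout --out layout.csv                                   # default montage
```

`--alpha-grid/--beta-grid paper` expands to {0, 2⁻⁸, …, 2⁰}; `a:b` expands to
an integer range; comma-separated values are taken literally.

## Acceptance

`tests/test_acceptance.py` holds the acceptance suite: exact CSP algebra on
random SPD covariance sets, closed-form toys, entropy closed forms, a planted
−6.02 dB ERD oracle, recovery of planted mixing columns from fitted spatial
patterns, chance-level behavior without class contrast, ≥90% tenfold accuracy
at high SNR for all three methods, the directional advantage of the
stationarity-regularized variant under covariance drift, and the
compound-vs-simple PSE/SDC group findings across ten synthetic subjects.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

reruns a fast subset of those recomputations and writes the report (an empty
JSON object — acceptance for this package is property-based; there are no
numeric targets to reproduce).
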