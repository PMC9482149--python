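# conchvision

Looming-stimulus psychophysics and camera-eye optics for gastropod
spatial vision.

Strombid conch snails carry unusually large camera-type eyes for
herbivorous gastropods, and respond to an expanding ("looming") disc on
a monitor — a proxy for an approaching predator — with a graded
withdrawal sequence of proboscis and eyestalks.  `conchvision`
implements the computational side of a behavioural + anatomical study
of that visual system, for researchers in visual ecology and
neuroethology who want to design calibrated looming experiments,
analyse responder tables with exact small-sample statistics, or derive
optical performance figures from retinal sections:

* **Stimulus generation** — expanding discs with exponential or linear
  angular-size trajectories (0 → 83 deg of the visual field over 10 s or
  5 s), labelled by Michelson contrast
  `C = (L_max − L_min) / (L_max + L_min)`, and isoluminant checkerboard
  stimuli whose grey disc matches the space-average luminance of black
  and white checks (0.3–3.2 deg check widths), rendered to 8-bit
  greyscale PNG frames.
* **Threshold inference** — responder counts per stimulus level with
  Wilson score intervals; each level compared with the control loom by
  Fisher's exact test with Bonferroni correction; the detection
  threshold is the weakest significant level, and the minimum resolvable
  angle α_min is twice the smallest detectable check width.  Spearman
  rank correlations (exact permutation p-values at small n) and a paired
  Wilcoxon repeat check complete the battery.
* **Eye optics** — inter-receptor angle Δφ = s/f, angular resolution
  2Δφ, optical sensitivity
  `S = (π/4)² A² (d/f)² (1 − e^(−kx))` (µm² sr), retinal cell-census
  extrapolation from block-face section counts, and acuity-limited image
  blurring through the Gaussian modulation transfer function
  `MTF(ν) = exp(−3.56 (α_min ν)²)`.
* **Synthetic observers** — no behavioural raw data are deposited for
  this system, so a generative module simulates trial tables from a
  log-normal psychometric function with guess/lapse rates, escalating
  ethogram event sequences, and level-dependent re-emergence times, so
  the full pipeline is testable and its parameter-recovery behaviour
  measurable.

## Worked example

```python
import conchvision as cv
from conchvision import synthobs

# Eye optics from section measurements (µm): rhabdom separation 6.5,
# focal length 720, aperture 630, rhabdom 6.6 x 70.9, k = 0.0067 /µm.
anat = cv.EyeAnatomy()
print(round(cv.inter_receptor_angle(6.5, 720.0), 2))   # 0.52  (deg)
print(cv.reported_resolution(anat))                    # 1.04  (deg, 2 x rounded dphi)
print(round(cv.optical_sensitivity(anat), 2))          # 7.78  (µm² sr)

# Behavioural threshold on a simulated near-threshold observer
design = synthobs.resolution_design()                  # 8 check widths + control, 19 x 2 trials
params = cv.ObserverParams(threshold=0.45, slope=0.05, individual_sd=0.05)
trials = cv.simulate_trials(design, params, seed=1)
res = cv.DetectionThresholdModel.from_trials(trials, "resolution").fit()
print(res.summary())
```

The summary ends with:

```
Threshold level:   0.53 (check width (deg))
Min resolvable angle (2x threshold): 1.06 deg
Spearman level vs re-emergence: rho=0.964, p=0.002778 (n=7)
Repeat effect (paired Wilcoxon): V=1, p=0.5
```

Read: an observer whose true threshold sits at 0.45 deg responds
reliably from the 0.53 deg check width upward (38/38 responders,
adjusted p ≈ 0 versus 1/38 in the control) and essentially never below
it, so the smallest *detectable* check of the discrete series is
0.53 deg and the minimum resolvable angle — one full black-plus-white
period of the finest detectable checkerboard — is 1.06 deg.  The
re-emergence time (latency to resume grazing after withdrawal) rises
with check width, and the two repeats do not differ.

The same objects drive the command line:

```bash
conchvision stimuli  --out out/stim --seed 1          # manifest (+ --render for PNG frames)
conchvision simulate --out out/sim  --seed 1 --experiment resolution
conchvision analyze resolution --trials out/sim/trials.csv --out out/ana
conchvision optics   --census census.csv --out out/optics
conchvision blur snail.png blurred.png --mra 1.06 --ppd 8
```

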