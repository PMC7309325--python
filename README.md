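# respvol

Non-contact respiratory volume estimation from depth-image sequences.

A depth camera pointed at a person's torso sees the chest wall bulge
toward it with every breath. If the *respiration-related region* R of
the image can be isolated, the air volume moved per frame is the surface
integral of the depth change over that region,

    V(t) = Σ_{r ∈ R_t} (U_t(r) − U_{t−1}(r)) · C(d(r))²,
    C(d) = 0.0041·d + 0.0046   [mm per pixel at depth d mm],

and a breath's tidal volume is the valley-to-peak rise of the running
sum of {V(t)}. The hard part is R_t: arms rest at the same depth as the
chest, bodies sway, sensors are noisy. `respvol` isolates the region
with level-set active contours that combine

* **spatial information** — a Chan-Vese evolution with a chest-wall
  shape prior, measured in a pose-normalized frame, which separates the
  chest wall where depth values alone are ambiguous;
* **temporal information** — a region-information weight p(x) (1 inside
  the chest wall, decaying outside) steering the segmentation of each
  frame-to-frame difference image;
* **an adaptive transfer** — pixels segmented as respiration-related in
  the previous frame carry a capped bonus weight (threshold TH = 1), so
  weak but sustained motion (shallow abdominal breathing) is retained
  while one-off events (jolts, noise) never accumulate weight.

The package also ships the full evaluation formulary (per-breath tidal
volume error, volume waveform error, absolute-agreement ICC,
Kruskal-Wallis + Dunn method comparison) and a synthetic breathing-chest
phantom with analytically known ground truth, which is the validation
surface for everything above.

Intended users: researchers in camera-based physiological monitoring
and biomedical image analysis who need a reference implementation of
spatio-temporal level-set respiratory segmentation, or a controlled
phantom to stress their own.

## Worked example

Generate a two-minute breathing phantom, run the adaptive pipeline, and
compare against the analytic truth:

```python
import respvol as rv

cfg = rv.scenario("clean")                # 120 s, 16 fps, 120x160 px
seq, truth = rv.generate(cfg)

run = rv.RunConfig(method="adaptive",
                   cal_slope=cfg.calibration.slope,
                   cal_intercept=cfg.calibration.intercept)
res = rv.run_pipeline(seq, truth.torso_mask, run)

print(len(res.waveform.breaths), "breaths,",
      f"mean tidal {res.waveform.tidal_volumes.mean():.1f} mL,",
      f"truth {truth.tidal_ml:.1f} mL")

ref = truth.waveform
rv.detect_breaths(ref)
rep = rv.evaluate_waveforms(ref, res.waveform)
print(f"tidal error {rep.tidal_volume_error_pct:.2f}%  "
      f"waveform error {rep.volume_waveform_error_pct:.2f}%  "
      f"ICC {rep.icc:.4f}")
```

Output:

```
30 breaths, mean tidal 283.5 mL, truth 292.2 mL
tidal error 2.99%  waveform error 14.20%  ICC 0.9793
```

All 30 breaths are found; the mean per-breath tidal volume error is
about 3% (the first breath reads low while the adaptive region is still
being annexed — steady-state breaths are within ~3%), and the estimated
volume trajectory tracks the analytic one closely (ICC ≈ 0.98).

The same run from the shell:

```sh
respvol phantom --scenario clean --out seq.npz --truth-dir truth/
respvol segment --seq seq.npz --prior truth/torso_mask.png --out W.png
respvol track   --seq seq.npz --chest-wall W.png --method adaptive --out R.npz
respvol volume  --seq seq.npz --masks R.npz --out wave.csv --breaths breaths.csv
respvol evaluate --estimate wave.csv --reference truth/waveform.csv
```

`--method {spatial,temporal,adaptive}` switches between the fixed
chest-wall mask, the static region weights, and the adaptive transfer —
the three-way comparison that motivates the method: on a phantom with
sensor noise, postural sway and non-respiratory jolts, the tidal-volume
error orders adaptive < temporal < spatial and the ICC orders the same
way in reverse.

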