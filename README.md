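# leadtrack

Tracking of an implantable cardioverter-defibrillator (ICD) lead tip in
kilovoltage cone-beam CT (CBCT) projections, for motion monitoring during
stereotactic arrhythmia radioablation (STAR).

During STAR the target — a ventricular tachycardia substrate — moves with
both breathing and the heartbeat. The distal ICD lead electrode anchored in
the right ventricle is a radio-opaque surrogate for that motion and is
visible in the kV projections acquired while the gantry-mounted
source–imager pair rotates around the patient. `leadtrack` turns a
projection stack into a 3D cardiorespiratory trajectory:

1. **2D segmentation.** The planning-CT lead-tip coordinate is forward
   projected onto the imager for every gantry angle and a 70 × 70 px search
   region extracted around it. A bank of cylinder templates (the lead as
   seen from that angle, rotated in-plane at 5° intervals — 8 rotations for
   breath-hold scans, 20 for free-breathing, abdominal-compression and
   high-frequency-ventilation scans — at three sizes) is slid across the
   region with normalized cross-correlation (NCC); the best placement,
   rotation and size give the segmented position.
2. **Online outlier filtering.** Segmentations whose superior–inferior
   pixel value deviates by more than 25 px (20 mm at 0.8 mm/px) from an
   iteratively updated running mean of accepted values are rejected.
3. **2D → 3D estimation.** A single projection resolves only two position
   components; the depth along the ray is unmeasured. Target positions over
   the scan are modeled as draws from a 3D Gaussian N(μ, Σ); the nine
   parameters are fitted by maximum likelihood over all angled 2D
   observations (each sees the Gaussian's marginal onto its resolved
   plane), and per projection the unresolved depth is estimated as the
   conditional mean E[w | u, v] of the fitted Gaussian, leaving the
   observed in-plane coordinates untouched.
4. **Metrics.** 2D success fraction (< 2 mm in both imager axes), motion
   displacement relative to the scan-mean position (5th–95th percentiles),
   the fraction of 3D estimates within 2 mm on all axes, and a Wilcoxon
   signed-rank comparison of filtered versus unfiltered estimates.

Patient CBCT data are not distributable, so the package ships a digital
phantom: a cylinder-shaped lead tip moving with configurable respiratory
(cos⁴ waveform) and cardiac (sinusoidal) motion, rendered into kV
projections with controllable contrast, noise and wire clutter, together
with exact 2D/3D ground truth.

## Worked example

```python
from leadtrack import (DatasetConfig, MotionModel, RunConfig,
                       generate_dataset, run_pipeline)

cfg = DatasetConfig(
    motion=MotionModel.for_mode("FB", resp_amplitude=(2, 8, 3),
                                cardiac_amplitude=(1, 1.5, 1)),
    noise_sd=0.1,
)
paths = generate_dataset(cfg, seed=7, outdir="scan")
report = run_pipeline(RunConfig(
    projections=paths["projections"], geometry=paths["geometry"],
    planning_tip=paths["planning_tip"], ground_truth=paths["ground_truth"],
    outdir="scan/out", mode="FB",
))
print(f"2D success: {report['segmentation']['fraction_success']:.1%}")
print(f"rejected:   {report['rejection_rate']:.1%}")
p5, med, p95 = report["displacement_mm"]["si"]
print(f"SI displacement p5/median/p95: {p5:.2f} / {med:.2f} / {p95:.2f} mm")
print(f"3D estimates within 2 mm of reference: "
      f"{report['estimation_filtered']['fraction_lt2mm']:.1%}")
```

Output:

```
2D success: 100.0%
rejected:   0.0%
SI displacement p5/median/p95: 0.29 / 2.56 / 5.45 mm
3D estimates within 2 mm of reference: 100.0%
```

The scan is a 368-projection free-breathing acquisition with 8 mm
superior–inferior respiratory excursion and a 1.5 mm cardiac component. All
368 template matches land within 2 mm of the ground-truth projection, the
outlier filter finds nothing to reject at this noise level, the recovered
SI displacement distribution reflects the simulated breathing (the 95th
percentile sits at 5.45 mm — the cos⁴ waveform spends most of each cycle
near exhale, so the percentile is below the 8 mm peak amplitude), and every
3D estimate agrees with the ground-truth-derived reference trajectory to
within 2 mm per axis.

The same pipeline is available from the shell:

```sh
leadtrack simulate --mode FB --seed 7 --out scan
leadtrack run --projections scan/projections.tiff --geometry scan/geometry.json \
    --planning-tip scan/planning_tip.json --ground-truth scan/ground_truth.csv \
    --mode FB --out scan/out
```

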