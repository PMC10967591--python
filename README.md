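# flockmotion

Calibrated real-world speed estimation from video trajectories of animals
moving on a plane, plus the standard multi-object tracking and segmentation
evaluation metrics, validated end to end on a synthetic flock simulator with
known ground-truth kinematics.

The package is aimed at researchers monitoring poultry (or any floor-bound
animals) with an overhead camera and an off-the-shelf segmentation/tracking
model. It does **not** re-implement any tracker: it consumes tracker output
in the MOTChallenge CSV dialect (and optional instance masks) and answers two
questions:

1. **How fast are the animals actually moving, in m/s?** An oblique camera
   distorts pixel displacements. Four pixel corners of a floor rectangle of
   known physical size determine a 3×3 homography H that rectifies the view
   to a top-down plane in which one pixel corresponds to a fixed physical
   distance *W* (m/px). The speed of a track over the frame window [N, M] is

   &nbsp;&nbsp;&nbsp;&nbsp;**V = ΔY · W / ((M − N) · Δt)**,&nbsp;&nbsp;Δt = 1/fps

   with ΔY its displacement in the rectified view (vertical-only in the
   faithful default, full planar Euclidean on request). At the default
   18 FPS, Δt = 55.56 ms.

2. **How good is the tracking?** The CLEAR-MOT protocol (per-frame gated
   minimum-cost assignment with match persistence) tallies false positives
   FP, misses and identity switches IDS into

   &nbsp;&nbsp;&nbsp;&nbsp;**MOTA = 1 − (FP + Miss + IDS) / GT**,

   and an optimal global trajectory mapping yields the identity metrics
   IDP, IDR and their harmonic mean **IDF1 = 2·IDP·IDR/(IDP+IDR)**. Mask
   quality is scored as mean intersection-over-union (mIoU) over classes,
   speed accuracy as the RMSE between estimated and true speeds (m/s), and
   throughput as frames per second.

Because real ground-truth speeds are rarely available, the `simulate` module
generates flocks of 1–20 birds under a correlated random walk (mean speed
0.05 m/s inside a 0–0.21 m/s envelope, reflective arena walls), projects
them through a configurable perspective camera, and degrades the perfect
tracks with centroid jitter, missed detections, false positives and
persistent identity swaps. Two presets bracket realistic observation
quality: `"dyed"` (individually colour-marked birds, low noise) and
`"undyed"` (visually similar birds, elevated noise).

## Worked example

```python
import warnings
from flockmotion import (SimConfig, ObservationModel, SpeedConfig, simulate_flock,
                         degrade, fit_homography, compute_speeds, summarize_speeds,
                         evaluate, speed_rmse)

cfg = SimConfig(n_birds=5, duration_frames=720, seed=42,
                noise=ObservationModel.preset("dyed"))
gt = simulate_flock(cfg)                                   # known truth
pred = degrade(gt.pixel_tracks, cfg.noise, seed=42,        # "tracker output"
               frame_size=cfg.frame_size)

h = fit_homography(cfg.camera_quad, cfg.arena_corners())   # calibrate
speed_cfg = SpeedConfig(fps=18, window=18)                 # 1 s windows
truth = compute_speeds(gt.pixel_tracks, speed_cfg, h=h)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")                        # short FP tracklets
    est = compute_speeds(pred, speed_cfg, h=h)

summary = summarize_speeds(est)["cohort"]
report = evaluate(gt.pixel_tracks, pred)
report.rmse = speed_rmse(truth, est)
print(report.summary())
print(f"mean speed {summary['mean_mps']:.3f} m/s, "
      f"range [{summary['velocity_range_mps'][0]:.3f}, "
      f"{summary['velocity_range_mps'][1]:.3f}] m/s")
```

prints

```
MOTA        0.9747
IDF1        0.9872
IDP         0.9989
IDR         0.9758
IDS              0
FP               4
Miss            87
RMSE        0.0055 m/s
mean speed 0.033 m/s, range [0.000, 0.074] m/s
```

Reading: on 720 frames of 5 simulated birds, the low-noise observation model
loses 87 detections and invents 4, never swaps an identity (MOTA 0.97,
IDF1 0.99), and estimates windowed speeds to 0.0055 m/s RMSE. The reported
mean of 0.033 m/s is *below* the configured 0.05 m/s because the faithful
vertical-only displacement mode underestimates oblique motion; pass
`mode="euclidean"` to `SpeedConfig` for the full planar speed.

## Command line

The same pipeline is scriptable:

```sh
flockmotion simulate --seed 7 --preset undyed --out run/
flockmotion calibrate --config run/calibration.json --out run/homography.json
flockmotion speed     --tracks run/pred.csv --calibration run/calibration.json --out run/speeds/
flockmotion evaluate  --gt run/gt.csv --pred run/pred.csv --out run/report.json
```

All outputs are deterministic given `--seed` and carry provenance headers
(tool version, config hash, seed).

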