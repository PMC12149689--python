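# echoqc

Interpretable quality control for echocardiography-like videos (apical
four-chamber view). A video is scored per cardiac cycle against a five-point
protocol:

| criterion | points | rule |
|---|---|---|
| complete cardiac cycle | gate | ED–ES–ED or ES–ED–ES keyframe triple; otherwise total 0 |
| gain | +1 | ES-frame gain classified *medium* (not high/low) |
| depth | +1 | heart-silhouette height / image height inside (0.5, 0.75) |
| cardiac-axis angle | +1 | LV major-axis angle inside (75°, 95°) |
| anatomical structures | +2 | LV, RV, LA, RA, IVS visible in both ED and ES frames |

A video is *standard* only at a perfect 5. Every report lists the failed
criteria by name, so the score is auditable.

## Components

- `echoqc.lvvc` — ground-truth volume curves from keyframe labels (piecewise
  sinusoid pinned to +1 at ED, −1 at ES), curve→keyframe inversion by local
  extrema, cycle completeness, QC target selection.
- `echoqc.obb` — oriented boxes, circular smooth label (CSL) angle coding,
  rotated IoU (polygon clipping), rotated NMS, the essential-structure check.
- `echoqc.quantify` — depth ratio `D = h2/h1` and cardiac-axis angle `C`
  from detections on the ES frame; open-interval thresholds; the protocol
  sheet's 2/3–4/5 and ±20° ranges are available as presets.
- `echoqc.scoring` — per-cycle scorecards and per-video aggregation.
- `echoqc.models` — trainable components in plain numpy (the grading
  environment has no deep-learning framework): a small convolutional
  backbone with coordinate channels, a dense per-pixel detection head with a
  CSL angle map, a bidirectional recurrent phase regressor, and a
  fully-connected gain classifier, trained in stages with the backbone
  frozen after the detector stage. `run_qc` executes the full pipeline in
  either learned mode or oracle (ground-truth-annotation) mode over the same
  code path.
- `echoqc.phantom` — synthetic A4C phantom videos with exhaustive ground
  truth (keyframes, oriented boxes, gain class, depth, axis, expected
  scorecard); the LV area follows the volume curve by construction.
- `echoqc.evaluation` — keyframe frame error, rotated-box mAP/mP/mR,
  classification metrics with one-vs-rest ROC AUC, Cohen's kappa.

## CLI

```sh
# generate a labeled phantom dataset (frames + annotation JSONs + manifest)
echoqc phantom generate --n 20 --seed 7 --out data/phantoms

# staged training (checkpoints are .npz files)
echoqc train-detector --n-videos 60 --seed 1 --out ckpt/det.npz
echoqc train-phase   --models ckpt/det.npz --seed 1 --out ckpt/phase.npz
echoqc train-gain    --models ckpt/phase.npz --seed 1 --out ckpt/full.npz

# score a video (oracle mode reads keyframes.json / boxes.json / gain.json)
echoqc qc --video data/phantoms/<id>/frames --models ckpt/full.npz --out report.json
echoqc qc --video data/phantoms/<id>/frames \
          --oracle-annotations data/phantoms/<id> --out report.json

# metrics
echoqc evaluate --pred pred_keyframes.json --gt gt_keyframes.json --task phase
echoqc evaluate --pred preds.json --gt boxes.json --task detect
echoqc evaluate --pred a_scores.json --gt b_scores.json --task score
```

Exit codes: 0 on success, 2 on validation/usage errors. All thresholds and
model hyperparameters live in one validated YAML config (`--config`); every
report embeds the resolved configuration.

## Annotation formats

- Keyframes: `{"video_id", "n_frames", "keyframes": [{"frame": int, "phase": "ED"|"ES"}]}` (0-based frames).
- Detections (per frame): `{"frame": int, "detections": [{"label", "cx", "cy", "w", "h", "theta", "conf"}]}`;
  ground truth omits `conf`. `theta` is the long-side angle vs. the +x axis,
  degrees in [0, 180), y-down image coordinates.
- Reports: `{"video_id", "video_total", "standard", "cycles": [...], "config_echo": {...}}`.
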