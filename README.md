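# pupilgaze

Pupil segmentation and gaze estimation toolkit for head-mounted
near-infrared eye tracking, with a built-in synthetic data generator.

Components:

- **synthdata** — seeded generator of synthetic dark-pupil eye frames with
  exact ground truth (center, ellipse, mask, closed flag) plus nuisance
  features (glints, eyelid occlusion, illumination gradients, noise), a
  70/15/15 dataset splitter, and synthetic calibration/gaze sessions from
  a known generating polynomial.
- **segnet** — gated encoder-decoder segmentation network: five down
  blocks (4x conv + batch norm + LeakyReLU, 2x2 average pooling) down to a
  1/16-resolution bottleneck, an eye-closure head whose probability drives
  a Heaviside gate `G = H(1 - Pclose - eps)` that can skip the decoder
  entirely, and four up blocks with content-aware reassembly (CARAFE)
  x2 upsampling and skip connections. Joint loss: Dice (pupil) + binary
  cross-entropy (closure). Implemented on a small in-repo NumPy
  reverse-mode autodiff engine with an Adam optimizer — no deep-learning
  framework required. Default configuration: ~239 k parameters, ~0.96 MB
  at 4 bytes/parameter.
- **pupilgeom** — pupil center (intensity-weighted centroid of the largest
  8-connected component) and ellipse axes/orientation from second-order
  moments; 5-pixel center-error criterion.
- **gazemap** — six-point second-order polynomial calibration
  `u = A0 + A1 x + A2 y + A3 x^2 + A4 xy + A5 y^2` (and the first-order
  variant), direct solve at exactly m points, least squares beyond.
- **metrics** — 5-pixel detection rate, precision = sumTP/(sumTP+sumFP),
  RMSE, angular error between gaze vectors, screen-point-to-gaze-vector
  geometry, localization error, and k-fold cross-validation.
- **cli** — `pupilgaze` command with `synth`, `train`, `track`,
  `calibrate`, `predict`, `evaluate`, and `pipeline` subcommands.

## CLI

```bash
# synthesize a dataset (PNG frames + annotations.csv + masks/ + split.json)
pupilgaze synth --n 200 --seed 0 --out data/

# train on synthetic data (or --data DIR for an existing dataset)
pupilgaze train --n 200 --seed 0 --out run/          # add --resume ckpt.npz to continue

# segment + measure pupils
pupilgaze track --checkpoint run/checkpoint.npz --frames data/ --out track.csv

# fit / apply the polynomial gaze mapping
pupilgaze calibrate --in calib.csv --order 2 --out model.json
pupilgaze predict --model model.json --in pupils.csv --out gaze.csv

# score detections
pupilgaze evaluate --pred track.csv --truth data/annotations.csv --out report.json

# end-to-end: synth -> train -> calibrate -> track -> evaluate
pupilgaze pipeline --seed 0 --out run/               # --oracle bypasses the network
```

All commands accept `--config run.yaml`; see `pupilgaze.config` for the
blocks (`synth`, `net`, `train`, `calib`, `eval`) and their defaults
(training defaults: Adam, learning rate 0.001, betas 0.9/0.999, batch 8).

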