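# surromod

Surface-surrogate respiratory motion modeling, end to end and fully
synthetic:

* **`surromod.synthetic`** — generates irregular breathing signals
  (cycle-wise period/amplitude variability, baseline drift, sensor noise),
  deforming torso surfaces sampled as 11 laser-line point clouds at 3 Hz
  with an abdomen-leads-thorax lag, hysteretic tumor trajectories that are
  affine in the latent signal and its time derivative, and sparse
  cine-like tumor observations with a finite exposure window.
* **`surromod.surrogates`** — extracts four scalar surrogates per frame:
  abdominal point height (AP), thoracic point height (TP), radial distance
  mean (RDM), and a surface-derived volume (SDV) integrated over a
  15 x 15 cm region of interest, with sliding-compensation interpolation
  at fixed coordinates.
* **`surromod.baseline`** — detects full-exhalation minima and subtracts a
  running-median baseline (symmetric window of seven minima).
* **`surromod.motion_model`** — the amplitude + derivative position model
  `x(A, A') = x0 + A xA + A' xAprime`, least-squares training, residual
  summaries (mean and 90th percentile of Euclidean magnitudes).
* **`surromod.phase_method`** — a 4DCT-style phase-binned comparator.
* **`surromod.experiments`** — the two-part study: per-surrogate
  train-on-session-1 / validate-on-sessions-2-and-3 comparison, and a
  training-set-size sweep; principal-axes projection and modeled-vs-
  measured correlation.

Units are millimetres and seconds; coordinates are x lateral,
y craniocaudal (cranial positive), z vertical (anterior positive).

## Command line

```sh
surromod simulate --seed 1 --outdir study/           # write a 3-session study
surromod extract  --outdir study/                    # surrogate traces
surromod fit      --outdir study/ --surrogate AP     # train on session 1
surromod evaluate --outdir study/ --surrogate AP     # validate on sessions 2-3
surromod compare  --outdir study/                    # part 1: all surrogates
surromod sweep    --outdir study/ --seed 1           # part 2: training sizes
surromod report   --outdir study/                    # figures + tables
```

All commands accept `--config FILE` (validated YAML; every key optional,
see `surromod/config.py` for the schema) and `--log-level`.  A
`manifest.json` with the seed, config hash and library versions is
written next to the data.  All data files are plain CSV/JSON.

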