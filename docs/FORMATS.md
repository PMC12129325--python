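# File formats

All files are plain text, UTF-8, "." decimal separator, angles in degrees.

## Trials CSV

One row per trial; `NA` for missing values.

| column        | type                | meaning                                      |
|---------------|---------------------|----------------------------------------------|
| session_id    | string              | session identifier                           |
| t             | int, 1-based        | trial index, strictly increasing per session |
| condition     | `L` / `N` / `R`     | contextual condition                         |
| omega_deg     | float               | stimulus direction (positive = rightward)    |
| choice        | `left` / `right`    | the subject's report                         |
| reward        | `0` / `1` / `NA`    | reward delivered                             |
| boundary_deg  | float / `NA`        | reward boundary in effect for this trial     |

A rewarded trial must carry the boundary that produced the decision.

## Sessions manifest CSV (multi-session fitting)

Columns: `session_id, trials_csv, heading_deg, eccentricity_deg` — one row
per session, pointing at that session's trials CSV.

## Config YAML

Priors (`PriorSpec`) and sampler settings (`SamplerConfig`) load from YAML
or JSON with explicit keys, e.g.

```yaml
# priors.yaml
P_L: {mean: -10.0, sd: 7.0}
P_R: {mean: 10.0, sd: 7.0}
D:   {mean: 0.0, sd: 10.0}
S_shape: 8.0      # Gamma shape; scalar or [L, N, R]
S_rate: 0.5       # Gamma RATE (mean S = shape/rate = 16 deg)
lapse_a: 1.0      # Beta(a, b) on every lapse rate
lapse_b: 10.0
flat: false       # true: Uniform(-180, 180) on all three biases
```

```yaml
# sampler.yaml
n_draws: 5000
burn_in: 2500
n_chains: 1
refit_cadence: 1
```

## Outputs

- Posterior fits: JSON with means, SDs, central 68%/95% intervals,
  diagnostics (split-Rhat, ESS), trial count, seed, convergence flag.
- Online traces: JSON array of per-trial records (t, boundaries, refit flag,
  current bias estimates, refit wall time).
- RL experiments: tidy CSV (`rep, session, condition, psi_end, psi_mean,
  B_hat, S_hat`).
- Every output file gets a sidecar `*.manifest.json` (package version, seed,
  full config) from which it can be reproduced exactly.

Proprietary formats (e.g. `.mat` archives of recorded sessions) are not
read; convert recorded data to the trials CSV externally and use
`perceptbias replay`.
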