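# scdeconv

Model-based deconvolution of skin conductance signals into sudomotor
neural inputs.

Sudomotor nerve activity is parameterised as Gaussian bursts in four input
classes — anticipatory (within CS–US windows), evoked (event-locked),
spontaneous (inter-trial) and slow level drifts. A deterministic forward
model maps these inputs through causal response kernels (anticipatory and
evoked inputs share one kernel; spontaneous fluctuations use their own;
drifts are integrated) to a conductance trace. Inverting the forward
model under design-derived priors yields trial-by-trial estimates of the
underlying neural activity, which can be compared against conventional
peak-scoring and convolution-GLM estimators through a BIC / log-Bayes
factor statistics layer, including Rescorla–Wagner learning-model fits.

## Layout

| module | role |
|---|---|
| `scdeconv.model_core` | domain types, response kernels, forward model, noisy observation simulator |
| `scdeconv.design` | trial structure (CS/US timing, anticipation and inter-trial windows) |
| `scdeconv.preprocess` | band-pass filter → downsample → z-transform conditioning chain |
| `scdeconv.rf_estimation` | response-kernel and latency estimation via PCA of event-locked epochs |
| `scdeconv.inversion` | MAP inversion: trial-wise anticipatory timing/dispersion/amplitude, evoked amplitudes, spontaneous and drift events |
| `scdeconv.benchmarks` | peak scoring (EIR/FIR/SIR) and the convolution GLM (conditions / trials / derivative basis with reconstruction) |
| `scdeconv.stats` | BIC, log-Bayes factors, condition-prediction GLM, CS main-effect test, Rescorla–Wagner fitting |
| `scdeconv.synthetic_experiment` | ground-truthed conditioning-session simulator with named presets |
| `scdeconv.io` / `scdeconv.cli` / `scdeconv.pipeline` | file formats, command line, end-to-end runner |

## Command line

```sh
# generate a ground-truthed synthetic cohort (writes trace CSVs, events
# TSVs, ground-truth bump tables and a manifest)
scdeconv simulate --preset exp2 --subjects 20 --seed 42 --outdir sim/

# condition a raw trace: band-pass (5 Hz / 10 s time constant),
# downsample to 10 Hz, z-transform
scdeconv preprocess --in sim/subject00_trace.csv --out pre.csv

# fit the response kernel + latency from event-locked epochs
scdeconv estimate-rf --in pre.csv --events sim/subject00_events.tsv --out rf.json

# invert: trial-by-trial neural-input estimates (JSON + flat CSV)
scdeconv invert --in pre.csv --events sim/subject00_events.tsv --rf rf.json --out result.json

# benchmark estimators
scdeconv score-peak --in pre.csv --events sim/subject00_events.tsv --mode EIR --out peaks.csv
scdeconv glm --in pre.csv --events sim/subject00_events.tsv --mode trials --basis derivs --out glm.csv

# statistics over a measures table (subject, trial, condition, method, estimate)
scdeconv stats compare --measures measures.csv --out comparison.json
scdeconv stats rw --measures measures.csv --events sim/subject00_events.tsv --out rw.csv

# or the whole pipeline in one go
scdeconv run --in sim/subject00_trace.csv --events sim/subject00_events.tsv --outdir out/
```

Exit codes: 0 success, 2 validation error, 3 convergence error.

## File formats

* **Traces** — CSV, header `time,conductance` (seconds, microsiemens), or a
  single column plus an explicit sampling rate.
* **Events** — tab-separated `onset  duration  trial_type  reinforced
  trial_index`, with `trial_type` one of `CS-`, `CS+`, `US`; CS rows carry
  the CS–US interval in `duration`.
* **Kernels** — JSON holding the family parameters, normalisation constant
  and fitted latency.
* **Ground truth** — tab-separated bump table (class, amplitude, center,
  dispersion).

All amplitudes are in "sudomotor units": kernels are normalised so a
reference burst of unit amplitude (0.3 s dispersion) produces a response
peaking at exactly 1.
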