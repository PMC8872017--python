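# nasga

Genetic-algorithm neural architecture search (NAS) over recurrent-cell
topologies for early sepsis-onset prediction from ICU time series, together
with the full data pipeline — onset labeling from inflammatory-response
criteria plus infection evidence, sliding-window episode extraction,
Gaussian-process imputation, autoencoder denoising, evaluation — and a
synthetic MIMIC-like event-table generator so the whole method runs end to
end without restricted clinical data.

## What it does

- **`nasga.synthdata`** generates `chartevents` / `labevents` /
  `prescriptions` CSV tables and a demographics table for a configurable
  cohort, with irregular timestamps, mixed units, duplicate source feature
  ids, missingness, antibiotic prescriptions as infection evidence, and a
  planted pre-sepsis precursor whose strength decays with lead time.
- **`nasga.cohort`** harmonizes event tables onto a 40-feature catalog
  (id merging, majority-unit election, lab-over-chart conflict resolution,
  hourly resampling), detects the two-of-four inflammatory-response
  criteria per hour, labels sepsis onset as the start of the earliest ≥5 h
  continuous run given infection evidence, extracts 5 h sliding windows
  labeled at a 0–12 h prediction horizon, filters sparse episodes, balances
  classes, and splits 5:3:2.
- **`nasga.preprocess`** imputes missing hourly values with a
  Gaussian-process posterior mean (fixed squared-exponential kernel),
  z-scores per feature on training statistics, and denoises with a trained
  two-layer denoising autoencoder.
- **`nasga.cellspace`** encodes an N-node recurrent cell as a genotype
  (per-node activations from {tanh, relu, identity, sigmoid}, one
  predecessor per node, weight genes for all possible edges), converts
  genotype ↔ adjacency matrix ↔ DAG, and counts/enumerates the
  `4^N × (N−1)!` search space exactly.
- **`nasga.childmodel`** materializes a genotype into a trainable
  recurrent classifier (terminal-node outputs averaged into the cell
  output), trains it with Adam + cross-entropy and early stopping, and
  shares learned weights across children through a versioned store.
- **`nasga.ga_engine`** evolves the population: top-10% elitism, roulette
  selection with the wheel compressed so max/min area ≤ 3, per-property
  single-point crossover, single-gene mutation.
- **`nasga.evaluation`** computes confusion metrics, rank-based AUROC with
  percentile-bootstrap confidence intervals, a gated-recurrent baseline,
  and the 0–12 h horizon sweep.

All neural components run on a small numpy reverse-mode autodiff engine
(`nasga.nn`), so the package has no deep-learning framework dependency.

## CLI

```bash
nasga simulate --config cfg.yaml --out data/            # synthetic tables
nasga cohort --in data/ --horizon 3 --seed 1 --out eps/ # episodes + splits
nasga preprocess --episodes eps/ --out proc/            # impute+normalize+denoise
nasga search --episodes proc/ --config cfg.yaml --out run/
nasga evaluate --model run/best_chromosome.json --store run/store.npz \
               --episodes proc/ --out report.json
nasga sweep --horizons 1,4,8 --config cfg.yaml --seed 1 --out sweep/
```

`cfg.yaml` sections map onto the config dataclasses, e.g.

```yaml
synth: {n_patients: 400, sepsis_prevalence: 0.2, seed: 1}
ga:    {population_size: 12, max_generations: 5, n_nodes: 5, seed: 1}
train: {hidden: 16, max_epochs: 10, patience: 4, seed: 1}
dae:   {epochs: 15}
```

## Notes on scale

The original study searches 12-node cells with population 100 on GPU over
a credentialed clinical database; its headline numbers are not reproducible
at desk scale. The defaults here (5-node cells, small populations, a
synthetic cohort of 400 patients) exercise every mechanism end to end on
one CPU in minutes while preserving the qualitative behavior — including
the decline of AUROC with growing prediction horizon.
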