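# strandex

Simulation and analysis of single-molecule FRET strand-transfer and
protein-exchange kinetics.

`strandex` pairs a generative simulator of protein–nucleic-acid exchange
mechanisms (direct strand transfer through a ternary intermediate,
facilitated homo/hetero protein exchange, DNA/RNA competition) with the
full smFRET analysis pipeline those mechanisms are measured with.  Every
analysis stage is exercised end to end on synthetic data: schemes are
simulated as continuous-time Markov chains, rendered into camera-frame
donor/acceptor traces (or field-of-view image series) with realistic
optical artifacts, and then analyzed back to the kinetic constants the
simulation was seeded with.

## Components

| module | what it does |
| --- | --- |
| `strandex.kinetics` | labeled CTMC schemes, exact Gillespie sampling (single-path and vectorized ensemble), matrix-exponential occupancies, effective-rate formulas |
| `strandex.synth` | state path → two-channel intensity traces: 50 ms frames, ALEX blocks (10 green / 1 dark / 10 red), donor leakage, shot/read noise, per-dye photobleaching, flow background step, time-weighted mid-frame state changes, short-movie snapshot sampling |
| `strandex.fov` | synthetic field-of-view image series with Gaussian-PSF spots and exponential spot survival |
| `strandex.fret` | E_FRET with leakage correction, donor-only exclusion via red frames, pooled unit-area histograms, multi-Gaussian decomposition, bound fractions |
| `strandex.infer` | single-exponential decay fits, bimolecular (k_obs vs concentration) fits, censoring-aware first-passage estimation (Kaplan–Meier), transfer-event detection with failed-attempt counting, dwell-time Gaussian summaries, event-synchronized averaging, spot-count decay, hetero-exchange completion analysis |
| `strandex.spots` | spot detection (top-hat background subtraction, matched filter, robust thresholding) and counting |
| `strandex.presets` / `strandex.pipeline` | per-assay presets with ground-truth constants and the closed-loop simulate→analyze recovery drivers |
| `strandex.cli` / `config` / `io` | YAML-configured CLI, validated schemas, CSV/JSON/TIFF file formats |

## CLI

```sh
strandex list-presets
# simulate an ensemble of snapshot movies
strandex simulate -c config.yml -o data/
# analyze trace directories back to k_obs / k_bi / dwell times
strandex analyze -i data/ -o results/
# closed-loop recovery of a preset's ground-truth constant
strandex recover --preset ssb_dT70_dT60 --seed 1
strandex recover --preset ssb_realtime_dT40 --seed 5
# small example dataset + config
strandex make-fixtures -o fixtures/
```

A minimal simulate config:

```yaml
preset: ssb_dT70_dT60
concentrations_nM: [10, 30, 50, 75, 100]
n_molecules: 1000
seed: 1
movie_times_s: [0, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600, 660]
```

Concentrations are given in nM and converted to molar internally; all
rates are reported in SI units (M⁻¹ s⁻¹, s⁻¹).

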