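# dynconn

Dynamic EEG network reconfiguration analysis: windowed phase-lag (wPLI)
connectivity, multilayer community detection, temporal network metrics, and
bootstrap group comparisons — exercised end to end on synthetic data with
planted dynamic community structure.

## What it does

Given multichannel EEG (EDF or delimited text) the pipeline:

1. **connectivity** — band-pass filters the signal (order-3 zero-phase
   Butterworth; delta 1–3, theta 3–7, alpha 8–13, beta 21–30, gamma
   25–40 Hz), cuts it into non-overlapping 10-s windows, and computes the
   weighted phase lag index `|E{Im X}| / E{|Im X|}` of every channel pair in
   every window, plus the per-edge temporal coefficient of variation.
2. **communities** — maximizes multilayer modularity over the resulting
   layer stack (Louvain-style greedy optimization on the supra-modularity
   matrix, resolution γ, ordinal inter-layer coupling ω), with a shuffled
   null for (γ, ω) selection and a seeded 100-run detection ensemble.
   The reference operating point (γ = 1.1364, ω = 0.5) ships as
   `communities.REFERENCE_PRESET`.
3. **metrics** — from the N×L community labels: per-node **flexibility**
   ξᵢ = gᵢ/(L−1), per-pair **allegiance** (fraction of layers spent in the
   same community), and per-pair **intermittence** (fraction of layer
   boundaries at which the pair's co-membership flips — distinguishes bursty
   from block-like co-affiliation at equal allegiance), with ensemble
   averaging and allegiance-thresholded selection.
4. **behavior** — codes opinion change from three-scenario questionnaires
   (travel / murder trial / vaccination, three timepoints), assigns
   change/no-change groups per interval, and computes transition
   percentages.
5. **stats** — bootstrap machinery: per-sensor flexibility group
   comparisons (10,000 draws), allegiance-thresholded intermittence
   difference curves with significant-range fractions, and replica-based
   (1,000 × 30) CoV comparisons across groups and contexts.
6. **synth** — generators for everything above with known ground truth:
   Markov label schedules with a controlled switch rate, phase-coupled
   multichannel signals with planted time-switching communities, and
   questionnaire records that reproduce requested marginal counts exactly.

## CLI

```sh
# full synthetic end-to-end run
dynconn all --seed 1 --out runs/demo

# individual stages
dynconn simulate --seed 1 --out runs/sim
dynconn connect runs/sim/sessions/NC_social_media_001.edf \
    --band alpha --window-seconds 10 --out runs/conn
dynconn detect runs/conn/NC_social_media_001_alpha_wpli.npy \
    --gamma 1.1364 --omega 0.5 --iterations 100 --out runs/det
dynconn metrics runs/det/*_labels_*.tsv --out runs/met
dynconn validate runs/sim/sessions/*.edf
dynconn report runs/demo
```

All settings can come from a YAML config (`--config`); CLI flags override.
A run directory contains TSV metric tables, comparison results, a JSON
summary, and a manifest with the config echo, seeds and stage timings.
Re-running with the same seed reproduces every output byte-identically.

## Layout

```
src/dynconn/
  behavior.py       questionnaire coding, transition statistics, chi-square utility
  communities.py    multilayer modularity, Louvain, shuffled null, sweep, ensemble
  connectivity.py   bands, filtering, windowing, wPLI, temporal CoV
  edf.py            minimal EDF reader/writer + delimited-text fallback
  metrics.py        flexibility / allegiance / intermittence / thresholding
  pipeline.py       RunConfig, run_pipeline, input validation
  stats.py          bootstrap comparisons (sensors, threshold curves, CoV)
  synth.py          synthetic schedules, EEG, questionnaires, cohorts
  cli.py            click CLI (simulate / connect / detect / metrics / all / ...)
tests/              pytest suite; test_acceptance.py holds the acceptance criteria
scripts/acceptance.py
```
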