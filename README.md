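# neurosurv

Longitudinal single-neuron survival analysis for automated-microscopy
experiments — with a fully synthetic data generator, so every stage can
be validated against exact ground truth.

## The problem

In neurodegeneration models built on primary neuron cultures, the
question is not *whether* cells die but *when*, and what predicts it.
Transfected neurons expressing a fluorescently tagged construct (red
channel) and optionally a stress-pathway reporter (green channel) are
imaged at fixed stage positions every 24 h for ~5 days.  Each neuron is
followed to its death — its survival time is the last frame at which it
was observed alive — or right-censored at the end of follow-up.  Because
transfection conditions are shared within a well, and baseline toxicity
drifts between replicate plates, the resulting data are hierarchical:
neurons within wells within plates.

`neurosurv` implements the three stages of such a study:

1. **simulate** — render synthetic two-channel time-lapse stacks in which
   neuron death times follow a programmable proportional-hazards model
   and fluorescence trajectories are known exactly;
2. **track** — segment each red-channel frame, link neurons across frames
   by nearest centroid, declare death on disappearance, and measure
   background-subtracted red/green intensities on the red-channel masks;
3. **analyze** — Nelson–Aalen cumulative hazards per group, Cox
   proportional-hazards models with well-cluster-robust variance and
   plate stratification, Schoenfeld-residual diagnostics, and
   quartile-binned reporter→hazard models.

## The model

The death hazard of neuron *i* in group *g* at time *t* is

    h_i(t) = h0_p(t) · exp( β_g + γ · z_i(t) )

with a separate baseline hazard `h0_p` per plate (stratification), a
group log hazard ratio `β_g`, and optionally a log-linear effect `γ` of
the neuron's standardized reporter level `z_i(t)` (held constant between
frames).  Effects are reported as hazard ratios `HR = exp(β)` with Wald
95% CIs built from a sandwich variance that aggregates score residuals
within wells (neurons in a well are not independent).  For the
quartile analysis, reporter levels measured at a landmark time (24, 48,
72 or 96 h) are binned into quartiles Q1–Q4; follow-up is left-truncated
at the landmark, so no neuron contributes risk time before its covariate
was measured.

The simulator inverts this model: it draws continuous death times from
the programmed hazard by inverse-transform sampling, renders living
neurons as Gaussian blobs with Poisson shot noise and photobleaching,
and emits exact ground truth, so programmed parameters can be compared
with what the pipeline recovers.

## Worked example

The `analysis/` scripts run a demo experiment end to end (2 plates × 8
wells × 3 fields × 10 neurons; programmed group HR 1.6; reporter coupled
to the hazard with a programmed Q4-vs-Q1 contrast of 1.8):

```
python analysis/01_simulate.py      # truth tables, layout, TIFF movies
python analysis/02_track.py         # tracks.csv, fates.csv
python analysis/03_survival.py      # survival statistics
python analysis/04_report.py        # figures
```

`03_survival.py` prints:

```
cumulative hazard at 96 h, control: 0.73
cumulative hazard at 96 h, mutant: 1.03
group Cox model (410 neurons, 255 deaths, 16 wells, strata: plate):
  group[mutant]: HR 1.43 (95% CI 1.16-1.76), p = 0.00076
  proportional-hazards check: global p = 0.62
reporter quartiles at 24 h (n=410): Q4 vs Q1 HR 2.38 (1.67-3.38), group-adjusted
reporter quartiles at 48 h (n=334): Q4 vs Q1 HR 2.24 (1.55-3.26), group-adjusted
reporter quartiles at 72 h (n=262): Q4 vs Q1 HR 2.36 (1.09-5.15), group-adjusted
```

Reading this: the mutant construct raises the death hazard ~1.4-fold
(the programmed 1.6 attenuated by 24-h observation granularity and one
realization's sampling noise — 410 informative neurons); the
proportional-hazards assumption is not rejected; and neurons in the top
reporter quartile at 24 h die at ~2.4× the rate of the bottom quartile
even after adjusting for group, recovering the programmed
reporter–death association.  The unadjusted and group-adjusted quartile
tables for each landmark are written as `quartile_model_{t}_{crude|adj}.csv`.

The same pipeline runs from a single YAML config via the CLI:

```
neurosurv run --config config.yaml --seed 1 --out results/run1
```

with subcommands `simulate`, `track`, `analyze`, `report` for the
individual stages.

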