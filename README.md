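# pupildeconv

Online estimation of cognitive load from a continuous pupil-diameter
stream.  The pupil dilates transiently when the brain engages with a
demanding task (the task-evoked pupillary response, TEPR).  `pupildeconv`
implements a causal, frame-wise deconvolution algorithm that watches a
60-Hz diameter stream and explains it as a static baseline plus a sparse
train of latent **attentional pulses** — point events whose convolution
with a pupillary impulse response reproduces the observed dilations.  The
algorithm needs no knowledge of stimulus timing: the pulses themselves
estimate when processing started and how strong it was.

The package is aimed at psychophysiologists and HCI researchers who want
to (a) deconvolve pupil recordings into processing events, (b) validate
the result against stimulus-locked analyses (per-sample mixed-model
scans, trial classification from pupil features), and (c) test the whole
chain on synthetic data with known ground truth.

## Model

The impulse response is the Erlang/gamma-shaped kernel

    h(t) = t^n · exp(−n·t / t_max),   n = 10.1,  t_max = 0.93 s,

normalised to unit peak, so a pulse's scale s_i is millimetres of peak
dilation.  The modelled trace is

    M[t] = b + Σ_i s_i · h(t − t_i)

with static baseline b.  Online, each frame compares the observation Z[t]
with M[t]; when the residual exceeds 0.25% of a reference diameter
persistently, a pulse is inserted 500 ms before the detection time stamp
(then refined causally) and the scales of recent pulses are re-fitted by
nonnegative least squares, minimising ε = Σ (M[t] − Z[t])².

Around the deconvolver sit the standard pupillometry stages: cubic-spline
blink reconstruction, a five-point median Hampel despiker, gaze/blink
trial exclusion, event-locked epoching against a 100-ms pre-stimulus
baseline, per-sample linear mixed models with a |t| > 2 + 200-ms run-length
significance rule, per-participant logistic-regression classification of
trial condition (5-fold cross-validated accuracy, ROC AUC), and the
behavioural indices Cowan's K = N·(hit − FA) and inverse efficiency
RT / proportion-correct.

## Worked example

```python
import pupildeconv as pdv

# a 12-s, 60-Hz recording: baseline 4 mm + three pulses + 0.01-mm noise
rec = pdv.make_pulse_recording(onsets=[2.0, 4.5, 7.0],
                               scales=[0.30, 0.45, 0.20],
                               duration_s=12.0, seed=1)
res = pdv.run(rec)
for t, s in zip(res.pulses.onsets, res.pulses.scales):
    print(f"pulse at {t:.3f} s, scale {s:.3f} mm")
```

prints

```
pulse at 2.000 s, scale 0.299 mm
pulse at 4.500 s, scale 0.448 mm
pulse at 7.000 s, scale 0.202 mm
```

i.e. all three latent events are recovered on the sample grid with scales
within ~1% of truth.  `res.modeled` holds the modelled trace M[t] (which
exactly equals the offline convolution of the recovered pulses),
`res.residuals` the per-frame innovation, and `res.insertions` an audit
log of every detection.

The same object works as a scikit-learn estimator:

```python
est = pdv.OnlinePupilDeconvolver(residual_threshold_frac=0.0025).fit(rec)
est.pulses_, est.baseline_
```

A command-line surface wraps the library:

```
pupildeconv simulate --seed 7 --out cohort/
pupildeconv preprocess cohort/participant_00/recording.csv \
    cohort/participant_00/events.csv --out epochs
pupildeconv deconvolve cohort/participant_00/recording.csv --out dec/
pupildeconv analyze epochs_data.csv epochs_meta.csv \
    --factors vwm_load,vs_difficulty --out analysis/
```

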