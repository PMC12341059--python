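# patchkin

Single-channel BK (KCa1.1) current analysis for cell-attached
patch-clamp recordings, with a Markov gating simulator that provides
ground truth for every stage.

BK channels — large-conductance voltage- and Ca²⁺-activated K⁺
channels encoded by *KCNMA1* — can be recorded one channel at a time
in primary cells such as skin fibroblasts, which makes it possible to
test whether a patient's heterozygous *KCNMA1* variant changes channel
gating (gain or loss of function) directly in patient-derived tissue.
`patchkin` implements the complete analysis chain such a study needs:

- **Idealization**: all-points amplitude histogram → closed/open level
  detection → half-amplitude (50%) threshold event detection with
  dead-time merging, turning a noisy sweep into a sequence of
  (occupancy level, dwell time) events.
- **Open-probability metrics**: NPo = Σ k·t_k / T over each 15 s sweep,
  channel count N per patch from the maximum simultaneous open level,
  and Po = NPo/N; NPo–V and Po–V tables per patch.
- **Unitary conductance**: unitary current–voltage points from the
  histogram level spacing and the ohmic slope conductance γ (pS) by OLS
  over −40…+100 mV.
- **Dwell-time constants**: log-binned dwell histograms (constant bin
  width in log t, where an exponential component peaks exactly at its
  time constant) fitted with one open component (τ_open) and two closed
  components (τ_closed1 < τ_closed2).
- **Allele-specific expression**: ref/alt base counts from a read
  pileup at a heterozygous variant site, with an exact binomial test
  against the 50:50 heterozygous expectation and Clopper–Pearson
  intervals.
- **Group statistics**: Shapiro–Wilk routing into one-way ANOVA +
  Bonferroni or Kruskal–Wallis + Dunn, and per-voltage Mann–Whitney
  ladders with Holm correction.
- **Simulation**: continuous-time Markov (Gillespie) gating over a
  C2 ⇄ C1 ⇄ O scheme with exponentially voltage-dependent rates,
  rendered at 50 kHz with Gaussian noise and a zero-phase 6 kHz
  low-pass — including control-like, gain-of-function-like, and
  paxilline-blocked presets.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

Simulate a single-channel patch with the gain-of-function preset whose
closed states are destabilized, then analyze it:

```python
from patchkin import preset_scheme, preset_config, simulate_recording
from patchkin.pipeline import analyze_recording, dwell_summary

cfg = preset_config("n999s", n_channels=1, sweep_duration=5.0, seed=42)
rec = simulate_recording(preset_scheme("n999s"), cfg, patch_id="demo")
analysis = analyze_recording(rec)

print(f"channels in patch: N = {analysis.summary.n_channels}")
for v in (60.0, 100.0, 140.0):
    print(f"  {v:+6.0f} mV   NPo = {analysis.summary.npo_by_voltage[v]:.4f}")
fits = dwell_summary(analysis, voltage=140.0)
t_c = fits["closed"].taus
print(f"tau_open = {fits['open'].taus[0]*1e3:.2f} ms; "
      f"tau_closed1 = {t_c[0]*1e3:.3f} ms, tau_closed2 = {t_c[1]*1e3:.2f} ms")
```

prints

```
channels in patch: N = 1
     +60 mV   NPo = 0.0000
    +100 mV   NPo = 0.0182
    +140 mV   NPo = 0.6838
tau_open = 9.66 ms; tau_closed1 = 0.049 ms, tau_closed2 = 5.32 ms
```

The channel is silent at +60 mV, activates steeply above +80 mV
(NPo 0.018 at +100 mV, 0.68 at +140 mV), and its closed dwell
distribution resolves into a fast (~0.05 ms) and a slow (~5 ms)
component — the signature of the two closed states in the generating
scheme.

The same stages are exposed on the command line:

```sh
patchkin simulate --preset wt --n-channels 3 --seed 1 --out rec/
patchkin analyze  --in rec/ --iv-range -40:100 --out analysis/
patchkin dwell    --in events.csv --bins-per-decade 10 --out taus.json
patchkin allele   --tsv calls.tsv --ref T --alt C
patchkin report   --config pipeline.json --out report/
```

`patchkin report` runs whole simulated cohorts (multiple presets ×
patches) through idealization, metrics, dwell fits and the statistics
ladder, writing CSV tables, `summary.json`, and a run log; reruns with
the same config and seed are byte-identical.

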