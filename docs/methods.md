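# Methods

## Scope and model

`patchkin` analyzes single-channel BK (KCa1.1) currents recorded in the
cell-attached configuration, and simulates such recordings from
continuous-time Markov gating schemes so that every stage of the
analysis can be validated against ground truth. The pipeline is

1. **gating simulation** — Gillespie sampling of a kinetic scheme per
   channel, rendered into sampled, noisy, low-pass-filtered sweeps;
2. **idealization** — all-points amplitude histogram, level detection,
   half-amplitude (50%) thresholding, dead-time event merging;
3. **channel metrics** — NPo = Σ k·t_k / T, channel count N, Po = NPo/N,
   unitary i–V points and ohmic slope conductance;
4. **dwell-time fitting** — log-binned open/closed dwell histograms with
   peak-at-τ component fits;
5. **allele pileup** — ref/alt base counting at a heterozygous variant
   site with an exact binomial imbalance test;
6. **group statistics** — Shapiro–Wilk routing into ANOVA/Bonferroni or
   Kruskal–Wallis/Dunn, plus per-voltage Mann–Whitney ladders with
   family-wise correction.

## Gating model

The default scheme is the minimal linear chain **C2 ⇄ C1 ⇄ O**: one open
state gives a single-exponential open-dwell distribution, two closed
states give a two-exponential closed-dwell distribution, matching the
fit structure used for the fibroblast data (single-component open fit;
two-component closed fit). Transition rates are

    k(V) = k0 · exp(V / V_e)

with `V_e` the signed e-fold voltage (infinite = voltage-independent).
Voltage dependence is carried by the C1→O and O→C1 rates (e-fold values
+12 mV and −30 mV); the C2⇄C1 step is voltage-independent. Calcium is
not an explicit variable: recordings are made at fixed endogenous
cytosolic Ca²⁺, so its effect is folded into the effective rates.

Preset parameters (rates at +120 mV):

| preset | C2→C1 | C1→C2 | C1→O | O→C1 | mechanism emulated |
|---|---|---|---|---|---|
| `wt` | 110/s | 18 000/s | 2 000/s | 500/s | control gating |
| `n999s` | 330/s | 18 000/s | 6 000/s | 500/s | GOF: closed states destabilized (shorter closed dwells) |
| `e656a` | 110/s | 18 000/s | 2 000/s | 165/s | GOF: open state stabilized (longer open dwells), default 2 channels/patch instead of 3 |

The `wt` parameters place the stationary open probability below 10⁻⁴ at
+60 mV and above 0.1 at +140 mV, so control-like channels only activate
above roughly +80 mV, and its closed-class sub-generator has dwell
eigen-constants near 0.05 ms and 9 ms — the same order as the control
line's fitted fast/slow closed constants. `blocked` pins every channel
closed (the paxilline identity control, an acquisition condition rather
than a scheme). `conductance_assay` is a voltage-independent two-state
scheme (C ⇄ O at 200/s each, Po = 0.5, τ ≈ 5 ms): it exists because a
voltage-activated scheme produces essentially no openings over most of
the −40…+100 mV window in which the unitary i–V slope is fitted, so
conductance characterization needs a scheme with resolvable openings at
every protocol step.

## Acquisition defaults

15 s sweeps from −40 to +160 mV in 20 mV steps (11 sweeps), 50 kHz
sampling, 6 kHz low-pass, holding 0 mV, unitary conductance 165 pS,
reversal potential 0 mV (near-symmetric K⁺), Gaussian noise sd 1 pA
before filtering, 1–5 channels per patch (preset defaults 3; 2 for the
reduced-expression preset). All voltages are membrane potentials;
pipette-potential sign conversion is never applied internally. The
unitary current is ohmic, i = γ·(V − V_rev); rectification is not
modeled. The filter is a 4-pole Bessel applied forward-backward
(zero-phase), so dwell boundaries are not skewed; true online filters
are causal, which the simulator deliberately trades away to keep
idealization unbiased.

Channel paths are stationary-initialized, independent across channels
and sweeps, and seeded through `numpy` `SeedSequence` spawning, so a
(scheme, config, seed) triple reproduces a bit-identical recording.

## Idealization choices

- **Histogram bin width**: half the within-level noise sd (floored at
  0.05 pA), with the sd estimated robustly from successive sample
  differences (median absolute deviation / √2), which cancels the
  level structure. Guard bins are added on both sides so no amplitude
  peak sits on the histogram boundary.
- **Level detection**: local maxima with prominence ≥ 5% of the tallest
  peak (library default) and separation ≥ half the expected unitary
  amplitude; peak positions are refined by a count-weighted centroid to
  remove bin quantization. Baseline = lowest peak; unitary amplitude =
  median spacing of consecutive peaks (levels assumed equally spaced).
- **Baseline anchoring**: the pipeline knows the closed current level of
  a leak-free cell-attached sweep (0 pA after sign-flipping negative
  driving forces), so `analyze_recording` anchors the level lattice
  there and lowers the prominence floor to 1%. This recovers minority
  levels at low Po and — critically — prevents the open level of a
  near-saturated sweep (closed peak almost absent) from being mistaken
  for baseline. A sweep whose single peak sits a whole level above the
  anchor is classified pinned-open with an *assumed* amplitude; such
  sweeps are excluded from i–V fitting.
- **Thresholds**: threshold k = baseline + (k − ½)·Δi — the 50% rule;
  placing it midway between histogram peaks is identical for equally
  spaced peaks. No hysteresis (available as nothing; single crossing).
- **Dead time**: T_d = 0.179 / f_c (rise-time bound of a Gaussian-type
  filter; ≈ 30 µs at 6 kHz). Sub-dead-time events are merged into the
  longer adjacent event, shortest first. No missed-event correction is
  applied to fitted time constants afterwards; τ estimates near T_d are
  therefore biased long, which is documented rather than corrected.

## Channel metrics

N per patch is the maximum simultaneous open level observed at the two
highest protocol voltages (where Po is maximal); this undercounts when
Po is low, a standard and documented bias. Po = NPo/N is clipped to
[0, 1]. i–V points are emitted only where an open level resolves (never
imputed at small driving force) and carry the sign of the driving
force; slope conductance is an unweighted OLS over −40…+100 mV
(≥ 3 points required), reported in pS.

## Dwell-time fitting

Dwells from single-channel sweeps only (levels {0, 1}); the
boundary-truncated first and last events are excluded. Histograms use
constant-width bins in log₁₀ time, default 10 bins/decade, padded one
bin each side. The fitted component is the exponential density
transformed to log time,

    g(x) = A · exp((x − x_τ) − e^(x − x_τ)),  x = ln t,

whose peak falls exactly at τ — the property that motivates log
binning. (A literal log-normal peak is available as an option but lacks
the peak-at-τ property.) Fitting is unweighted least squares on counts
(lmfit Levenberg–Marquardt); open fits use one component, closed fits
two with τ₁ < τ₂ enforced via a positive log-spacing parameter.
Initialization takes the most prominent histogram maxima, ties toward
smaller τ. Component weights are the normalized component areas.
Fewer than 50 dwells attaches a warning; a vanishing or collapsed
second component is flagged "effectively single". A one-bin histogram
returns that bin center as τ directly.

## Allele-expression module

Base calls at one 1-based position are tallied strand-agnostically
after per-base quality floors (defaults Q20 for base and mapping
quality — the position-level analogue of the read-level Q20 truncation
used upstream in sequencing QC). Fractions are reported against the
retained depth; the imbalance test is an exact two-sided binomial test
of the alt count against 0.5 among ref+alt calls (the heterozygous
expectation), with a 95% Clopper–Pearson interval. No reference-bias
correction is applied. The simulator draws alt alleles binomially,
applies a uniform base-substitution error, and draws qualities around
Q30. SAM/BAM ingestion delegates to pysam; a plain TSV of
(read_id, base, baseq, mapq) is the dependency-free path.

## Statistics ladder

Shapiro–Wilk on every group (α = 0.05) routes to the parametric branch
(one-way ANOVA; Bonferroni-adjusted pairwise t, Tukey HSD optional) or
the nonparametric branch (Kruskal–Wallis; Dunn's rank z test with tie
correction, Bonferroni-adjusted by default). The named post-hoc tests
differ across published analyses of this kind; all three are provided
and the choice is logged. Groups with n < 3 or constant data route
nonparametric with a warning; fully constant comparisons are flagged
degenerate with omnibus p = 1. Voltage-resolved curves are compared
with one two-sided Mann–Whitney per shared voltage under Holm
correction across voltages (Šidák optional; Holm is uniformly more
powerful than Bonferroni at the same family-wise level); voltages with
fewer than 3 patches in either group are skipped with a warning.

## Problem sizes used in the validation assays

- Slope-conductance recovery: 20 seeded single-channel recordings per
  conductance value, 3 s sweeps at 50 kHz over −40…+100 mV, noise sd
  1 pA, 6 kHz filter; the mean recovered slope is compared to the
  generating value. 3 s sweeps give ~600 gating events per sweep at the
  assay scheme's rates, ample for amplitude estimation.
- Closed-constant recovery: 10,000 dwells per replicate from an
  equal-weight two-exponential mixture, 20 replicates, median reported.
- Family-wise error of the per-voltage ladder: 500 replicates of two
  identical 5-patch groups at 3 voltages, with per-patch NPo taken as
  the open fraction of a 0.5 s simulated gating path (the rendering and
  idealization stages are bypassed there because they are noise-neutral
  for a rank-test size property).

## What the simulator does and does not emulate

Emulated: voltage-step protocol, unitary amplitude and its noise,
online low-pass filtering, multi-channel superposition, voltage-
dependent activation with realistic dwell structure, the paxilline
zero-activity control, and heterozygous-line pileup depths and allele
ratios. Not emulated: seal/capacitive artifacts, baseline drift,
open-channel noise in excess of baseline noise, conductance substates,
Ca²⁺ as an explicit ligand, β/γ regulatory subunits, causal filter
asymmetry, and rectification of the unitary current. Passing the
recovery suites therefore demonstrates correctness of the analysis
pipeline under idealized recording physics, not robustness to every
artifact of real patches.

## Known limitations

- N estimation undercounts at low Po; Po = NPo/N inherits that bias.
- τ estimates within a few dead times of T_d are biased long (no
  missed-event correction), and the fast closed constant of the
  control-like scheme (0.05 ms) sits near the 6 kHz dead time
  (0.03 ms), so idealization-derived (as opposed to generated) closed
  histograms under-represent the fast component.
- The Dunn z test is asymptotic; for very small groups its p-values are
  approximate where the exact Mann–Whitney is not.
- Baseline anchoring assumes a leak-subtracted (zero-centred) closed
  level; recordings with an uncorrected offset must be analyzed with
  `baseline_hint=None` or pre-corrected.
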