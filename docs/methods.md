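# Methods

## Scope and units

`qlmac` models LPS-induced activation of a macrophage population in which
cells secrete and sense TNF through a shared medium, and in which the
proportion of cells licensed for high activation depends on cell-density
history through the pre-stimulus state. All concentrations are in
arbitrary units anchored to reporter fluorescence (absolute molecule
counts are out of reach of fluorescence data); time is in hours, with
stimulus at t = 0 hps and pretreatments at negative times (IL-10 at
−12 h, sTNFR at −1 h). The package simulates deterministic ODEs per cell;
all cell-to-cell variability is extrinsic (initial-state) noise, not
stochastic kinetics.

## Single-cell network

Per-cell state (17 species): receptor activities `a_tlr4`, `a_tnfr`,
`a_il10r` (fractions), IKK activity, the NF-κB pools (`nfkb_ikb_c`
cytoplasmic complex, `nfkb_c` free cytoplasmic, `nfkb_n` nuclear), free
IκB, *Rela*/*Tnf*/mCherry transcripts, intracellular TNF, immature and
mature mCherry, the SR and DSR post-transcriptional regulator activities,
and the running integral of secreted TNF (carried as a state so
cumulative secretion is exact, and exactly flat under BFA).

Reaction forms: receptor activation is reversible two-state binding;
transcriptional induction of IκB and of the *Tnf*/mCherry promoter are
Hill functions of nuclear NF-κB; every other step is mass action. Newly
translated RelA enters the cytoplasmic complex pool (instant IκB capture
surrogate), which keeps the resting localization cytoplasmic.

Three design choices deserve comment because the dynamics depend on them:

* **Stimulus attenuation.** The TLR4/PKC drive is a dose step multiplied
  by `exp(−k_adapt·t)`. A constant drive sends the deterministic core to
  a sustained-activation fixed point in which nuclear NF-κB never
  declines; the observed single-cell trajectories instead rise and fall
  over ~10–15 h. First-order attenuation of the incoming signal
  (receptor-level tolerance) is the minimal time-dependent process that
  produces the decline without adding species.
* **FBD as a dose-gated switch.** Above the LPS threshold (1 ng ml⁻¹;
  never for PMA, which enters through PKC), *Rela* transcription gains a
  term `m6·k_fbd·Hill(a_tlr4; K_fbd, h_fbd)` with a small `K_fbd` and
  steep Hill. Driving the switch from TLR4 activity rather than from
  nuclear NF-κB amplitude makes total NF-κB expression structurally
  insensitive to the magnitudes of the other five mechanisms (m1–m5)
  once the switch is engaged — the buffering seen in the mechanism
  sweep — and means every cell, high- or low-activating, undergoes FBD.
  With the flag off, total reporter is exactly conserved at its basal
  balance (synthesis = turnover), so the unstimulated and PMA conditions
  show a flat total NF-κB signal.
* **SR/DSR.** Both are first-order relaxation variables driven by TLR4
  activity: SR fast-on/fast-off (transient mRNA stabilization), DSR
  slow-on/slow-off. DSR both destabilizes *Tnf* mRNA (`alpha_dsr`) and
  inhibits its translation (`beta_dsr`), m4 scaling both. The
  translational arm is what terminates the TNF→TNFR intercellular
  positive feedback at late times; with destabilization alone the loop
  self-sustains. The combination yields the early (3–6 hps) intracellular
  TNF burst and its decline while the *Tnf* promoter (mCherry) is still
  active.

IL-10 acts at three points: active IL-10R divides the IKK drive
(`gamma_il10`), accelerates *Tnf* mRNA decay (`alpha_il10`), and inhibits
TNF translation (`beta_il10`).

Mechanism multipliers m1..m6 (defaults 1) scale: (1) TLR4→IKK weight,
(2) promoter transcription `k_txn`, (3) SR weight, (4) DSR weights,
(5) TNFR→IKK weight and TNFR translational enhancement, (6) FBD gain.
Zero is allowed (mechanism knock-out).

## Population coupling

Extracellular TNF obeys

    d(tnf_ext)/dt = (ρ(t)/ρ_ref)·⟨k_sec·(1−BFA)·tnf_intra⟩_cells
                    − d_ext·tnf_ext − k_bind·stnfr_free·tnf_ext
                    − k_upt·(ρ(t)/ρ_ref)·tnf_ext

with ρ_ref = 3.3×10⁵ cells ml⁻¹ (high-density plating), so density is one
dimensionless knob. The last term is density-scaled cellular uptake.
sTNFR binding conserves `stnfr_free + tnf_stnfr` exactly; the 8.3 µg ml⁻¹
experimental dose is mapped to 500 a.u., a large excess that is never
exhausted within 24 h (smaller pools saturate and let TNF leak through
late, contradicting the observed near-complete blockade). Density grows
logistically from its plating value (default doubling ~18 h, capacity 4×
plating). N simulated cells are representative: per-capita secretion is
averaged, then scaled by density.

Ensembles of N ≤ 64 cells are integrated fully coupled (one ODE system,
LSODA, rtol 1e−6 / atol 1e−9, output every 0.1 h). Larger ensembles use a
mean-field two-pass scheme: 48 cells at density quantiles of the initial
state are integrated fully coupled to obtain the medium trajectory, then
all N cells are integrated independently against that medium
(vectorized RK45 in chunks). A test compares the two paths on a 70-cell
ensemble (median discrepancy < 5%); the approximation is good because
each cell's influence on the medium is O(1/N).

## Initial-state heterogeneity and cross-density imputation

Pre-stimulus reporter distributions are bimodal in log-fluorescence. A
two-component Gaussian mixture is fitted by multi-start EM (components
ordered by mean; degenerate fits — vanishing weight, coincident means, or
Ashman's D < 2 — are flagged). The high→low density transform is a
log-additive shift δ plus reassignment of the high-mode weight w_high′
(labels from posterior responsibility, resampled to the target weight),
with (δ, w_high′) chosen to minimize the two-sample Kolmogorov–Smirnov
distance to the target distribution (Nelder–Mead from mixture-aligned
starts). Log-additive shift was chosen over linear-additive because flow
distributions are log-shaped; the transform API exposes the samples so
either convention can be tested.

Each simulated cell draws one latent log-fluorescence; `exp(latent)`,
normalized to population mean 1, multiplies the initial NF-κB·IκB
complex, the basal *Rela* transcription rate `k_rela0`, and the initial
*Rela* mRNA — full correlation through a single extrinsic-noise axis (an
independent-sampling switch exists for sensitivity checks). The
population mean complex is anchored to the equilibrated mean cell's basal
state. The default synthetic mixture (μ = 0 and 2.5 log-a.u., σ = 0.5 and
0.6, w_high = 0.75 at high density; δ = −0.5, w_high = 0.25 at low) is a
generator setting producing visibly bimodal, overlapping modes; low and
very-low density share initial values, differing only through coupling.

## Calibration

Training data are summary statistics of the mean-cell trajectory: peak
times of total/nuclear/cytoplasmic reporter and mCherry, the
cytoplasmic:nuclear peak-amplitude ratio, and mCherry rise durations
under LPS-only and IL-10 pretreatment, each with its reported SD.
Objectives are squared SD-normalized residuals (the loss the source
description leaves unstated). Fitting is on the homogeneous mean cell;
heterogeneity is added afterward.

Round 1 frees the cell-intrinsic NF-κB arm (receptor, IKK, release,
shuttling, IκB, FBD, RelA turnover — 14 parameters) against the
sTNFR + LPS condition (intercellular feedback excluded) and returns the
Pareto-nondominated family from an NSGA-II-style GA (binary tournament on
rank/crowding, SBX crossover η = 15, polynomial mutation η = 20) over
log-uniform bounds centred on sweep values. Round 2 frees the
expression/secretion/IL-10 parameters (11) plus one categorical gene
selecting a round-1 family member, across all conditions (including an
unstimulated basal anchor), and returns the member minimizing the
weighted total residual. Initial populations are seeded with the
sweep-centre vector (round 1) and with one centre row per family member
(round 2). Defaults in `ParameterSet` are the round-2 calibrated values.
Search budgets are configurable; the acceptance script uses populations
of 20 for 6/5 generations with 5× bounds, which recomputes all targets in
about two minutes on one CPU.

## Analyses

* **Nadir threshold**: Gaussian KDE (Silverman bandwidth) on log values;
  the threshold is the density minimum between the two highest local
  maxima; unimodal densities return a flagged sentinel. The licensed
  fraction is the share above threshold (invariant to monotone axis
  rescaling).
* **Activation classes**: nadir split on log cumulative mCherry, falling
  back to a deterministic two-means split when unimodal.
* **Permutation R²**: least-squares R² with a one-tailed permutation
  test; full enumeration for n ≤ 7 (exact p), otherwise B Monte-Carlo
  permutations with the add-one correction p = (1+k)/(B+1), so
  p ≥ 1/(B+1). A Gaussian-tail approximation of the permutation null is
  reported separately (clearly labeled) for tails finite B cannot
  resolve.
* **12 hps readouts**: trapezoid integrals of total reporter and mCherry
  over [0, 12] hps plus cumulative secreted TNF on that window.
* **Mechanism sweep**: one multiplier at a time over a log2 grid
  (default 1/8×–8×) at high density with LPS; readouts are the mean
  triple.
* **Robustness sweep**: all kinetic parameters drawn lognormally with
  median at the fitted value and log-SD matched to a target linear CV;
  divergence is the median (over draws) mean absolute relative deviation
  of the readout triple from base — a metric chosen for outlier
  robustness, as the source description names none.
* **Heterogeneous vs homogeneous**: {density low/high} × {initials
  low/high} scenarios; homogeneous cells carry the linear-scale mean of
  the matching heterogeneous distribution; both distributions are
  normalized against the high-density anchor so levels are comparable;
  readouts are normalized to the heterogeneous low/low scenario; total
  secretion folds in density. The coupling metric compares the
  total-TNF fold change when density and initials move together against
  the product of the single-factor fold changes.

## Synthetic data

Generators are pure functions of (config, seed) and ship truth sidecars.
Measurement noise is multiplicative lognormal (`observed =
true·exp(N(0, σ_meas))`, default σ = 0.1), the standard fluorescence
convention; the generators emulate bimodal pre-stimulus distributions
(optionally with an arbitrary unit factor to mimic non-comparable
acquisitions), 24 h trajectory tables subsampled to a microscopy-like
interval, and per-cell snapshot tables with a small uniform shift for
log-display. They do not emulate intrinsic kinetic noise, cell division
or movement, segmentation errors, or flow-cytometry gating — so passing
recovery tests shows the estimators work under the stated noise model,
not that they are robust to those real-data artifacts.

## Numerical choices and degenerate inputs

Stiff-capable LSODA at rtol 1e−6 / atol 1e−9; output grid 0.1 h; species
clipped at 0 after solves and verified non-negative to 1e−6. Basal states
are found by repeated 400 h no-stimulus integration until every species
changes < 1e−6 per hour (relative), with an analytic warm start; the
cumulative-secretion state is excluded from the criterion and reset.
Peak times use quadratic interpolation around the grid argmax; monotone
observables report the window end and are flagged. Zero mechanism
multipliers are valid knock-outs. Identical-cell inputs raise on
statistics that need dispersion (CV with one cell, classification of
identical cells, zero-variance permutation tests).

## Known limitations

The ODE core cannot reproduce the multi-peaked nuclear trajectories some
cells show, nor nuclear-reservoir variation beyond what the initial
scaling carries. The density signal is encoded only through initial-state
priming and TNF coupling; the molecular mediator of the density effect is
deliberately out of scope. The homogeneous-vs-heterogeneous contrast and
the coupling synergy are structural but modest in magnitude (~2%
super-multiplicativity under defaults), so they are reported as
directional checks, not effect-size claims. Calibration identifies
parameter combinations, not individual constants; the Pareto family is
the honest output of round 1, and the defaults are one member of it.
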