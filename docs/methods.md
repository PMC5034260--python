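# Methods

`tdlusim` simulates a cross-section of a breast terminal duct lobular unit
(TDLU) as a stochastic cellular automaton coupled to continuous chemokine
fields, over repeated menstrual cycles. This note records the model, its
assumptions, the defaults and why they were chosen, and the known limits of
what the synthetic setting can show.

## Lattice and geometry

The domain is a square lattice (one node = one cell diameter, ~10 µm, at
most one cell per node). Each acinus is a disc-shaped lumen wrapped by a
one-node luminal ring and a one-node myoepithelial ring, both built with the
4-neighbourhood so lumina are sealed: no lumen node touches stroma, and
chemokines and immune cells never enter lumina. Cell–cell contact (killing,
suppression) and immune movement use the Moore 8-neighbourhood, so
"surrounded" counts run up to 8; the diffusion stencil is the von Neumann
4-neighbourhood. Acini sit on a jittered grid; the TDLU polygon separating
intra- from interlobular stroma is the convex hull of the epithelium dilated
by a 3-node stromal margin — a parametric stand-in for the pathologist's
annotation that defines the same two stromal compartments. The default
geometry (12 acini, lumen radius 3, 80×80 grid) holds 528 epithelial nodes,
inside the 250–2500 range of epithelial cells per lobular structure observed
in tissue sections, and small enough that a calibrated 12-cycle replicate
runs in ~20 s on one CPU core.

## Hormone-modulated turnover

Epithelial turnover is driven by normalized proliferation and apoptosis
index curves f_PI, f_AI ∈ [0, 1] over one cycle (follicular 0–14 d, luteal
14–28 d by default). Division and apoptosis rates are

    rate_pro(t) = k_pro · θ · f_PI(t mod T),   k_pro = 0.03 h⁻¹
    rate_apt(t) = k_apt · θ · f_AI(t mod T),   k_apt = 0.0021 h⁻¹

with θ the hormone level (θ = 1 normal; θ multiplies the normalized curves,
i.e. the turnover rates, and nothing else — chemokine and trafficking
parameters are unaffected). The default curve shapes are PCHIP interpolants
through anchor points chosen once to realise the qualitative features the
quantified indices show: f_PI has its global maximum late in the luteal
phase and a follicular local maximum fixed at 13.45/30.46 ≈ 0.4416 of the
global one, so that the simulated proliferation index spans the measured
13.45–30.46 events per 1000 cells; f_AI is maximal at the beginning and end
of the cycle with a deep mid-cycle trough. The exact numeric shapes of the
experimental curves are not published, so the package treats the curve
table as an explicit, swappable input (CSV `day,f_pi,f_ai`); the anchor
values are a design choice made once, with the luteal/follicular contrast
of f_AI strong enough that the linear trafficking law below can reproduce
all three effector phase targets as a nonnegative least-squares fit.

Variable cycle lengths dilate or contract the follicular segment of the
time axis linearly while translating the luteal segment unchanged (the
luteal phase is physiologically fixed at ~14 d); curve values are preserved
pointwise under the time map.

## Cell states and processes

Epithelial cells (luminal/myoepithelial) are firmly placed and never move.
Each step (dt = 1 h; all rates are quoted per hour, and per-step
probabilities 1 − exp(−rate·dt) stay ≪ 1 at the parameter ranges used),
cells are visited in a fresh random permutation. Rate→probability uses the
exponential map rather than rate·dt so that proportional-hazard statements
are exact: the probability that a damaged cell with n adjacent activated
effectors is killed is 1 − exp(−k_kill·n·dt), exactly linear in n on the
hazard scale; suppression of an active effector by n adjacent activated
regulatory cells works identically with k_sup.

* **Division.** The intrinsic division clock fires with probability
  1 − exp(−rate_pro·dt). A firing is logged as a proliferation event — this
  is the Ki-67-like read-out, a cell entering the division program — and
  the daughter is placed on a uniformly chosen free epithelial neighbour
  node if one exists; with no free neighbour, no daughter appears. A
  daughter of a normal parent is aberrantly damaged with probability k_dge
  (a proxy for DNA-repair defects such as BRCA1/2 loss); damaged parents
  always breed damaged daughters.
* **Apoptosis.** Normal epithelial cells enter a DYING state with
  probability 1 − exp(−rate_apt·dt), crowded or not. Damaged cells never die
  by apoptosis; they must be killed.
* **Crowding-mediated homeostasis.** Proliferation requires a free
  neighbour node, apoptosis does not. This asymmetry is the load-bearing
  mechanism that reconciles k_pro ≫ k_apt with a stationary epithelium: the
  tissue fills to capacity, realised divisions are limited to the holes
  apoptosis opens, and the population oscillates about its carrying
  capacity over the cycle with no secular trend. The proliferation-index
  read-out meanwhile tracks 1000·k_pro·θ·f_PI(t), because clock firings are
  logged whether or not space admits the daughter.
* **Dying cells and lysis.** DYING cells block their node and emit the
  find-me chemokine until lysed, tau_lys = 12 h after death (configurable);
  lysis frees the node.
* **Immune cells.** Effectors (cytotoxic CD8-like) and regulatory cells
  (CD4/CD163-like) occupy any non-lumen node. A non-permanently-inactivated
  immune cell is ACTIVE exactly while the damaged-cell chemokine at its
  node is ≥ c_act (threshold inclusive), INACTIVE otherwise — activation is
  a deterministic read-out of the local field. Suppressed effectors become
  PERM_INACTIVE irreversibly, stop responding to chemokines, and leave via
  the ordinary efflux of inactive cells. Immune cells never proliferate.
* **Motility.** Each immune cell attempts a move with probability
  1 − exp(−m_rate·dt) (m_rate = 10 h⁻¹, i.e. essentially every step — one
  node per hour, a deliberately coarse random-walk speed matched to the
  1-h step). The target is one free non-lumen Moore neighbour drawn with
  weight exp(χ·ΔC), where ΔC is the local increase of C_dam + C_dying for
  effectors and of C_dam for regulatory cells; χ = 0 or a flat field gives
  a uniform choice. χ = 50 (per concentration unit) makes the bias strong
  inside a chemokine halo (where ΔC ~ 0.01–0.05 per node) and negligible
  outside it, so immune cells aggregate at damaged/dying sites without
  long-range guidance.

## Chemokine fields

Two nonnegative fields live on the non-lumen nodes: C_dam sourced by
damaged cells (activating, recruiting) and C_dying sourced by dying cells
(the apoptotic find-me signal, recruiting effectors only). Each obeys

    ∂C/∂t = D ∇²C − λ C + s · 1_sources

integrated by forward Euler on the 4-point stencil (assembled once as a
sparse operator) with zero-flux walls at grid edges and lumen boundaries;
substeps respect the stability bound dt ≤ 1/(4D + λ), which also preserves
nonnegativity and conserves mass exactly when λ = 0. Defaults D = 5
nodes²/h, λ = 0.5 h⁻¹, s = 1 units/h give a decay length √(D/λ) ≈ 3 nodes:
the quasi-steady halo around a handful of co-located source cells spans
~5–10 nodes, large enough to recruit nearby immune cells, small enough that
activation stays local and clusters (rather than domain-wide activation)
emerge. The activation threshold c_act = 0.02 puts the single-cell halo
radius at ~2–3 nodes and a small damaged cluster's at ~5–10. These
constants are design choices (concentration units are arbitrary); all are
configurable.

## Trafficking and calibration

Vasculature is implicit and homogeneous: immune cells enter on uniformly
chosen free stromal nodes as a domain-level Poisson process and inactive
(or permanently inactivated) cells leave at per-cell rate lam_out; active
cells never leave. Influx intensities are linear in the stromal-mean
fields,

    λ_E = lam0_E + alpha_E·⟨C_dam⟩ + beta_E·⟨C_dying⟩
    λ_R = lam0_R + alpha_R·⟨C_dam⟩,

the minimal form consistent with "rates depending on chemokine intensity",
and the reason calibration is well-posed. The dying-cell signal recruits
effectors only, which is what makes the effector pool cycle-dependent while
the regulatory pool stays flat at baseline, as observed.

Calibration targets are the quantified healthy-lobule relative numbers:
effector 0.05 ± 0.01 (days 1–11), 0.04 ± 0.01 (days 11–17), 0.07 ± 0.02
(days 17–28) and regulatory 0.055 ± 0.01 overall. Because the baseline
(k_dge = 0) epithelial and chemokine dynamics are independent of
trafficking, one probe replicate records ⟨C_dying⟩(t) and N_epi(t); the
expected inactive pool then obeys the exact linear recursion
E[N_{k+1}] = E[N_k]·e^(−lam_out·dt) + λ(t_k)·dt, so the phase means are
linear in (lam0_E, beta_E) and a nonnegative least-squares solve (over a
small lam_out grid) yields a candidate; lam0_R comes in closed form from
the discrete-map stationarity E[N] = λ·dt/(1 − e^(−lam_out·dt)). A
coordinate search scored on real 3-replicate × 12-cycle simulations with
fixed seeds then accepts or refines the candidate; in practice the
mean-field candidate already lands within the experimental tolerances. The
chemokine couplings alpha_E/alpha_R are not identifiable at baseline (C_dam
≡ 0) and keep their defaults.

Runs start from the healthy state: a full epithelium and immune pools drawn
at their zero-field stationary sizes, so the baseline has essentially no
transient. Sweeps into damaging parameter regions do have a build-up
transient, which is why regime classification (below) excludes the first
cycle.

## Spatial statistics

The pair-correlation function g(r) is estimated on the lattice with an
exact finite-domain normalisation: observed pair counts per distance bin
(Euclidean metric, 1-node bins, r_max = half the domain diagonal) divided
by the expectation for a uniform pattern of the same size on the same
admissible node set, computed from the full pair-distance census of that
set (via FFT autocorrelation; integer-exact). This removes edge effects
without any boundary approximation: a CSR pattern has g ≡ 1 in expectation
at every r. The decay is summarised by ordinary least squares of log g on
log r over the positive bins, reported as g ≈ b·r^−m together with the raw
first-bin (contact) value. Clusters are Moore-connected components of
immune-occupied nodes with at least 3 cells (scipy.ndimage labelling; the
threshold is a declared convention — the original narrative never defines
one). The contact profile counts immune cells at lattice distance 0, 1, 2
and ≥3 from the epithelium, normalised by the epithelial count.

Under this g, clustering necessarily raises b (and the contact-bin value)
and steepens the measured decay, so b is the package's primary clustering
read-out. Descriptions elsewhere of a *high* power-law slope for
well-distributed healthy infiltrates are not reproducible under a
CSR-normalised pair correlation — a uniform pattern has m ≈ 0 by
construction — and the package makes no attempt to match that sign; see
the limitation list.

## Experiments and regimes

The study protocol is 10 replicates × 12 cycles per parameter point
(counter-based seed streams: master seed plus replicate index via numpy
SeedSequence spawn keys, so sweeps are reproducible and parallelizable).
Phase means pool days 1–11 / 11–17 / 17–28 across cycles and replicates.
Sweep summaries include the mean damaged fraction, mean/max relative
infiltrate, within-cycle amplitude (max − min per cycle), the
regulatory-minus-effector difference, and cluster statistics from day-25
snapshots.

Regime classification, per sweep column at fixed (k_kill, θ, cycle
length): a point is PHYSIOLOGICAL if its mean damaged fraction lies within
10% (relative) of the straight line fitted through the three smallest
k_dge values **and** every post-burn-in cycle's minimum relative
infiltrate returns to the healthy band (baseline mean + 2 SD); CHRONIC if
the post-burn-in cycle minima all exceed the baseline's maximum infiltrate
(inflammation never resolves, even at its seasonal low); SEVERE otherwise.
The 10% linearity tolerance and the 2-SD band are declared conventions —
no numeric criterion is published. The first cycle is excluded because
every run starts healthy, so its minimum is trivially at baseline level and
would make CHRONIC unreachable by construction.

Cycle-length comparisons are made at matched total simulated duration
(as many 21-day as 35-day cycles fit the same number of days, ~one year by
default in the protocol's spirit of "12 cycles, about 1 year"). At equal
cycle counts the two arms observe very different amounts of wall-clock
time; in the strongly damaging regime, where the damaged fraction is still
ramping, sheer duration then dominates the comparison and obscures the
per-day burden that is the scientifically meaningful quantity. At matched
duration, short cycles accumulate more damage — the larger luteal share of
each day drives more turnover and hence more damaged daughters.

## Numerical choices and degenerate inputs

dt = 1 h everywhere (per-step probabilities ≤ 0.03 at default rates);
chemokine substeps are chosen automatically with a 0.9 safety factor on the
stability bound. Ties in movement weights resolve by cumulative-sum
inversion of one uniform draw; exponent arguments are clipped at 50 to
avoid overflow at extreme χ·ΔC. A division with several free neighbours
picks uniformly; with none, the daughter is discarded (the event is still
logged). Zero-target calibration returns all-zero influx exactly.
Geometry refuses infeasible layouts (overlapping acini, boundary
crossings, epithelial count outside the configured 250–2500 band) instead
of clipping. With no free stromal node, an immune entry is discarded with a
logged warning. tau_lys = 0 removes a dying cell in the step it dies.

## What the synthetic setting does and does not show

All inputs are generated: the hormone curves are a qualitative-shape
stand-in, the calibration targets are the published phase means, and the
geometry is a parametric idealisation of annotated lobules. Passing tests
therefore demonstrate internal consistency — the mechanisms produce the
calibrated levels, the documented orderings and the regime structure — not
agreement with any particular patient's tissue. Real lobules differ in
ways the model ignores: branching 3-D architecture, vessel placement,
heterogeneous immune subtypes (all regulatory agents are pooled, all
effectors identical), receptor-level chemokine kinetics, immune
proliferation, and mechanical forces. Within-run variability is purely
demographic (finite cells, Poisson trafficking); there is no between-TDLU
parameter heterogeneity unless the user varies geometry seeds, which is
how the inter-TDLU comparisons are produced.

Known limitations: the power-law-slope sign issue above; activation is a
hard threshold rather than dose-dependent; the supplement-level trafficking
and PDE constants are re-derived design choices, not published values; and
calibration fixes only four targets, leaving alpha_E/alpha_R (damage-driven
influx gain) at round defaults of the same magnitude as the fitted
dying-signal coupling.
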