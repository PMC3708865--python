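# Methods

## The biological problem and the modelling idea

In fission yeast the Septation Initiation Network (SIN) is regulated at the
two spindle pole bodies (SPBs). During metaphase SIN components load onto
both SPBs; during anaphase the network stays active only on the new SPB,
while the Cdc16-Byr4 GAP complex accumulates on the old SPB and silences
SIN there. This package implements three nested ODE models of how that
asymmetry is established, and every in-silico experiment built on them:
symmetry breaking from a tiny bias or noise, total-level and efficiency
scans with terminal-phenotype calls, named mutants and their combinations,
SPB ablation, Byr4-induction with separated or shared cytoplasm, and the
pitchfork bifurcation analysis of the symmetric system.

All three models share one mechanism: a double-negative (hence positive)
feedback between two antagonists that each remove the other from the SPBs.
With a zero-order (saturating) step in the loop, the symmetric state is
unstable — a pitchfork — so any infinitesimal asymmetry is amplified until
one antagonist owns each SPB.

## Model structure

**Compartments.** Every mobile species has four pools: old SPB, new SPB,
and two cytoplasmic half-pools coupled by a first-order exchange rate
`k_diff` (default 10 /t.u., fast compared with every binding step). This
implements "fast diffusion between the SPBs until separation" while
letting the separation event simply set `k_diff = 0` without changing the
state layout mid-run; the `cyt` accessor always reports the summed
half-pools. Concentrations are in arbitrary units (a.u.); wild-type totals
and all scan multipliers are normalised to 1.

**Minimal model** (`X`, `Y`; 8 states). X and Y bind the SPBs by mass
action and unbind basally; bound Y catalyses X removal by mass action and
bound X catalyses Y removal through a saturating (Michaelis-Menten) step
with a small constant `J_xy = 0.05`, which supplies the zero-order
nonlinearity the feedback loop needs. X carries the binding bias
`(1 + k_bias)` at the old SPB. Only the X-on-Y step is saturating; the
reverse step is linear, the simplest loop that is bistable.

**Molecular model** (SIN, Byr4 mobile; Cdc11 in two forms per SPB; 12
states). Byr4 removes SPB-bound SIN through a saturating step with rate
`k_soff` — the axis along which cdc16 temperature-sensitive alleles are
simulated. SIN does not touch Byr4 directly: it phosphorylates the
immobile scaffold Cdc11 (forms U and P, conserved per SPB), and Byr4 can
bind an SPB only in proportion to the unphosphorylated fraction there.
Phosphorylated scaffold additionally destabilises bound Byr4 (`k_boff`).
A lumped phosphatase (`e_pp`) opposes SIN. Byr4 carries the
`(1 + k_bias)` advantage at the old SPB (default 0.1 %).

**Extended model** (Cdc11 in four forms U, CP, SP, PP per SPB; 16
states). Cdc11 carries Cdk sites and SIN sites, interconverted on a
reaction square: Cdk (constant activity after anaphase onset) drives
U→CP and SP→PP, local SIN drives U→SP and CP→PP, and two hypothetical
phosphatases reverse them — ppC on Cdk sites (CP→U, PP→SP), ppS on SIN
sites (SP→U, PP→CP). Every step uses saturating kinetics; the SIN-site
cycle runs in the zero-order, switch-like regime (`J_sin = 0.15`,
`J_pps = 0.05`), the Cdk-site cycle in a graded regime (`J_cdk = 0.3`,
`J_ppc = 1.0`). Only the fully dephosphorylated form U supports Byr4
binding.

**The Goldbeter–Koshland primitive.** The steady state of each
kinase/phosphatase cycle is the classic zero-order-ultrasensitivity
function, implemented analytically as `gk_switch` and used for
initial-state construction and as an independent oracle in tests; the
ODEs themselves integrate the saturating kinetics whose fixed point it
is.

**The Byr4-binding gate.** The binding capacity of an SPB is
`g(u) = u^n_u`, optionally passed through a normalised hyperbola
`g·(1+gate_sat)/(gate_sat+g)`. With `gate_sat > 0` the gate responds
mostly to the *appearance* of U-Cdc11 rather than to its exact high-end
level. The extended model uses `gate_sat = 0.15`; this is what makes
asymmetry timing nearly independent of the Cdk efficiency (which moves
the terminal U level between ~75 % and ~92 %) while preserving the
qualitative rule that no unphosphorylated Cdc11 means no Byr4 binding.
The molecular and minimal calibrations use the pure power law
(`gate_sat = 0`, `n_u = 1`).

## Initial conditions

Simulations start at the metaphase→anaphase transition. The default
initial state is constructed, not stored:

- SIN (or X) at its binding equilibrium over the two SPBs and the
  cytoplasm — the GAP-driven removal is taken to be inactive before
  anaphase, so SIN is predominantly SPB-bound and symmetric.
- Cdc11 at the steady state of its phosphoform system under *frozen
  metaphase activities* (`mito_*` parameters): high Cdk, nascent SIN-site
  phosphorylation. The four-form metaphase state is Cdk-phosphorylated
  dominant with a small unphosphorylated fraction u0 (~4 %).
- Byr4 at the binding equilibrium allowed by that u0 — low but strictly
  nonzero at both SPBs. A completely Byr4-free metaphase SPB would make
  the subsequent takeover of the old SPB much slower.

The `mito_*` activities are deliberately decoupled from the post-anaphase
efficiency parameters: in-silico mutants and efficiency scans perturb the
anaphase dynamics but inherit the same (wild-type) metaphase history.
This is what lets total removal of Cdk efficiency leave asymmetry timing
unchanged — the Cdk-primed initial state is part of the cell's history,
not of the scanned parameter. Total-level scans do flow through the
construction, so scaled totals start from correspondingly scaled
metaphase states; that construction is also what produces the Byr4:SIN
crossover of the early-mitotic state at ~2.5× Byr4.

## Numerics

- Integrator: `scipy.integrate.solve_ivp`, default LSODA with
  `rtol = 1e-8`, `atol = 1e-10`; dense output on a uniform grid
  (≥ 1000 points) plus the event times. Conservation drift over a
  wild-type run is < 1e-6 relative.
- Events are stop–modify–restart: integration halts at the event time,
  the state/parameters are transformed discretely (ablation spill,
  cytoplasm split, induction rate, parameter scaling), and integration
  resumes. Simultaneous events are applied in order.
- Symmetry: with `k_bias = 0` all right-hand sides commute exactly (to
  the bit) with the old↔new swap. Explicit Runge–Kutta methods update
  component-wise and therefore keep a bitwise-symmetric state on the
  symmetric manifold forever; implicit methods can inject rounding-level
  asymmetry through pivoting in their linear solves, which the pitchfork
  instability then amplifies. Tests of the "symmetric configurations
  never break symmetry" property therefore use RK45; everything else
  uses the stiff-capable default.
- Steady states: multi-start `scipy.optimize.root` (hybr) on the reduced
  shared-cytoplasm system (cytoplasm eliminated by conservation and the
  fast-diffusion limit), ≥ 50 deterministic starts spanning the
  conserved-pool simplex plus handcrafted antagonistic corners, the swap
  image of every root added by equivariance, deduplication at 1e-6,
  stability from the eigenvalues of a finite-difference Jacobian
  (|Re λ| ≤ 1e-7 flagged marginal).
- Timing metric: the inflection point (maximum slope) of a sigmoid-like
  transition curve — Byr4 at the old SPB by default, SIN at the new SPB
  for the total-level scans — computed on a monotone cubic (PCHIP)
  interpolant. The search is restricted to the contiguous stretch of the
  curve containing the last crossing of the half-amplitude level, which
  rejects the fast binding re-equilibration transient just after
  anaphase onset. Flat curves and transitions that have not settled by
  `t_end` report no time; in scans those points carry the terminal
  phenotype call instead.
- Phenotype calls: `wildtype_asymmetric` requires a completed transition
  and a terminal SIN asymmetry index |(new−old)/(new+old)| ≥ 0.8;
  SIN below 10 % of its total at both SPBs, or Byr4 established above
  25 % at both, is `multinucleate_like` (division failure); Byr4 below
  10 % at both SPBs, or SIN above 25 % at both, is `multiseptate_like`
  (SIN hyperactivation). The 0.8 / 10 % / 25 % cutoffs are calibration
  choices — the experimental literature offers phenotype cartoons, not
  numeric thresholds.

## Calibration

The canonical rate constants of the original study are not available to
this implementation, so the shipped defaults are the package's frozen
calibration, chosen once so that the wild-type behaviour and the whole
perturbation panel hold simultaneously: sub-0.1 % bias sufficiency,
~75/25 U/CP at the old SPB (exactly the `e_cdk : e_ppc` balance through
their Michaelis constants), the ~2.5× Byr4 crossover, terminal-phenotype
maps of the total-level scans, Cdk-efficiency insensitivity (< 5 %
timing change for 0.25–1×), cdc16-delay and S5A-advance orderings, the
additive cdc16/SIP double mutant, ablation takeover, and the
separated-vs-shared termination asymmetry. The two-form and four-form
models are calibrated separately where they must be (`k_soff`,
`k_on_byr4`, `k_off_byr4`, `gate_sat`); the defaults live in
`sin_asym.models` as per-model overrides of one shared `ParameterSet`.

Notable emergent behaviours of this calibration, stated as such:

- In the four-form model, halving the SIN efficiency (the cdc11-S5A
  proxy) unlocks the scaffold immediately, so the Byr4(old-SPB) curve —
  the timing proxy used throughout — rises almost at once, a dramatic
  advance; the SIN asymmetry-index crossing itself moves much less. The
  mutant-ordering results use the curve-based metric.
- The cdc16-116 (k_soff × 0.2) delay is large (≈ 20× wild type): the
  deep GAP defect brings the Byr4 attack close to stalling against SIN
  rebinding. Mutant-combination runs therefore use `t_end = 3000–4000`.
- Reducing either phosphatase delays the transition and ultimately
  leaves SIN active at both SPBs (a multiseptate-like call under the
  rules above); increasing ppS hands both SPBs to Byr4
  (multinucleate-like), while increasing ppC changes no phenotype.

## Synthetic inputs

The generator perturbs the constructed metaphase state with independent
log-normal factors (log-scale σ) on every SPB-bound mobile pool,
re-balancing the cytoplasm so totals are conserved exactly; σ = 0.001
("a little noise", the stated alternative to the 0.1 % bias) is the
ensemble default, 100 replicates, seeds spawned per replicate from one
`SeedSequence`. What this emulates is cell-to-cell variability in the
loading of the two SPBs at anaphase onset; it does not emulate intrinsic
reaction noise during the transition (no stochastic integration), nor
variability in rate constants or totals. Passing ensembles therefore
show that the deterministic flow amplifies small initial asymmetries of
either sign — not that the model is robust to molecular noise en route.

## Known limitations

- Arbitrary units throughout; timings are comparable within and between
  runs but not mapped to minutes.
- The models inherit the published architecture's known failure: the
  two-form model is oversensitive to Cdc11 levels, and nothing in the
  four-form model prevents the (experimentally falsified) prediction
  that cdc11-S5A rescues cdc16 defects — reproducing that prediction is
  part of the point.
- Cdk activity after anaphase onset is a constant, not a declining
  input; SPB geometry, Clp1/Flp1, Sid4 scaffolding and the SIN
  activation-timing layer are outside scope.
- The pitchfork analysis uses brute-force grid continuation (steady
  states re-found per control value), adequate at this model size; no
  arclength continuation is attempted.
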