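# Methods

## The model

Gene levels `g = (g_1 … g_n)` evolve under external inputs `I` by

    dg_i/dt = f_i(g, I) − γ g_i

with a linear decay `γ = 1` and a bounded synthesis rate `f ∈ (0, 1)^n`.
Integration is explicit forward Euler with a deliberately coarse step
`dt = 0.2`,

    g(t + dt) = (1 − γ·dt)·g(t) + f(g(t), I(t))·dt,

so typical simulations finish in a few tens of iterations.  With `f` bounded
in `[0, 1]`, `γ·dt ≤ 1` and initial levels in `[0, 1]`, every state stays in
`[0, 1]` — divergence is impossible by construction.  The aim of the method
is qualitative (which regulatory links exist and with which sign), so the
discretization error of the coarse step is acceptable; an adaptive or
higher-order solver is deliberately out of scope.

The synthesis function is a small multilayer perceptron over the
concatenated state `(g, I)`: two equal ReLU hidden layers and a sigmoid
output layer that keeps every rate strictly inside `(0, 1)`.  Two layouts
are provided: a single `shared` network with `n` outputs (used for the
gap-gene and cellular-automata models) and a `per_gene` stack of `n`
independent single-output networks (used for the 2–3-gene design tasks,
where it makes structural link masks and their gradient behavior exact by
construction).  Only the observable gene levels cross time steps — the
network carries no hidden recurrent state.  Weights start from small
Gaussians (σ = 0.1); hidden widths default to 16 for the small design tasks
and 64 for the 10-gene lattice model (choices of this package; anything
comparable works).

Time evolution is therefore the recurrent iteration of one feed-forward
block, and fitting a task is ordinary backpropagation through the unrolled
loop.  The forward/backward passes are hand-written in NumPy: the models are
tiny, and the integrator needs reverse-mode gradients assembled around the
network's own forward/backward primitives (which are verified against
finite differences in the test suite).

## Tasks and training

A task fixes input time courses (one per condition), a sparse set of target
constraints `(condition, time, gene, value)`, a per-gene initial-state
policy, and the horizon.  The loss is the Euclidean distance pooled over all
constraints of all conditions,

    Loss = sqrt( Σ (g_model − ĝ_target)² ).

Unconstrained pre-stimulus levels are trainable parameters passed through a
sigmoid so they stay in `(0, 1)`.

Training is full-batch Adam (learning rate 1e−2, at most 3000 iterations)
over the unrolled dynamics, with run-time Langevin noise: a zero-mean
Gaussian kick (σ = 0.01 by default) added to the state after each Euler
update and clipped at zero.  The noise enters the state (not the synthesis
term); it regularizes the learned dynamics and contributes to the strong
degeneracy of repeated restarts.  Because the noise jitters the training
loss, convergence is monitored on periodic noise-free evaluations (every 10
iterations): training stops when the noise-free loss falls below
`loss_target` (0.05 by default) or fails to improve by 1e−6 over 10
consecutive evaluations, and the best noise-free parameters seen are the
ones returned.  Ensembles derive one independent (build seed, noise seed)
pair per restart from a base seed; diverged restarts are recorded and
skipped.

### Adaptation

The output gene must respond to a step input with a pulse and return to its
pre-stimulus level 0.4.  The target after onset is a difference of two
exponentials scaled so the peak deviation equals `pulse_amplitude`.
Defaults: amplitude 0.35 (peak 0.75), τ_fast = 0.6, τ_slow = 1.8 time
units, horizon N_T = 40.  These values are chosen so the target is
*dynamically trackable*: with `f ≤ 1` and `γ = 1` the fastest possible rise
from 0.4 obeys `g = 1 − 0.6·0.8^t`, so a 0.9 peak reached in under 8 steps
is infeasible, and an untrackable target leaves a large irreducible residual
that swamps every downstream loss comparison (deletion ranking, failure
detection).  The recovery constant is set so the pulse has fully returned
within the horizon.

Two features of the condition design exist to exclude degenerate solutions
rather than to shape the response:

* a **zero-input condition** with a flat target — without it, a network can
  emit the pulse unconditionally;
* **varied onset times** across the step conditions (defaults 8/12/5 for
  levels 0.4/0.6/0.8; the strongest step, whose response the phenotype
  metrics read, gets the earliest onset so the adaptation error is measured
  over the longest post-stimulus window) — with a single fixed onset, the trainable helper
  initial value can act as an autonomous timer that the input merely gates,
  and sparsification then converges on timer circuits instead of feedback
  motifs.  Varying the onset forces a causally input-triggered pulse.
  Training several step heights jointly likewise excludes solutions that
  respond non-monotonically to input strength.

### Controlled oscillation

Three conditions constrain only the output gene: no input → constant low
basal level (0.1); input 1 on (0.8) → triangular wave between 0.2 and 0.8
with a 20-step period after a 10-step transient; input 2 on (0.8) →
sustained 0.9.  The precise waveform and period do not matter for the
discovered topologies.  An optional variant pins the helper gene's
pre-stimulus value high (0.9), which biases the search toward a different
branch of the solution space; it is exposed as a flag and not exercised by
the tests.

### Gap-gene patterning

A synthetic stand-in emulates trunk patterning profiles: a strictly
decreasing exponential Bcd gradient, a terminal Tor profile high at both
poles, and four band-like gap-gene targets (hb, Kr, kni, gt) with distinct
ordered peaks and seeded jitter.  Per spatial position the task supplies the
static two-component morphogen input, zero initial state for all four
genes, and target constraints only at the final time point (N_T = 30);
positions are spatially uncoupled.  `merge_gap_gene_tasks` pools the
positions into one multi-condition task so a single shared network produces
the whole pattern, which is how the worked example and the Kr-knockout
illustration are run.  What passing these tests shows is that the
train–distill–knockout loop behaves correctly on band-forming input–output
relations; it says nothing about real embryos — the generator has smooth
noise-free profiles, no measurement error, and no spatial coupling.

## Interrogating a trained model

The knockdown score of link i→j is

    Δ_ij = f_j(…, g_i) − f_j(…, λ·g_i),     0 ≤ λ ≤ 1,

evaluated with everything else fixed and averaged over every state of the
pooled wild-type trajectories (all conditions).  λ = 0.95 is the default for
scoring: the measure weights the bare partial derivative by the regulator's
expression level, matching what a biological knockdown probes, and small
perturbations stay close to the dynamically relevant region.  λ = 0 deletes
the link entirely and is used for mutant simulation.  The perturbed
synthesis function replaces only component j; iterating it through the
integrator yields link-mutant trajectories, and clamping a gene's value to
zero everywhere (plus zeroing its own synthesis and initial level) yields
whole-gene null mutants.

Scores are normalized per target gene — each gene's column is divided by
its own maximum absolute score, so a gene's regulators are compared among
themselves and the regulation of a weakly-synthesized gene is not hidden
behind another gene's dominant link (a per-model global normalization is
available as an option).  Entries with normalized magnitude ≤ cutoff become
absent links, the rest take the sign of their score.  The default extraction cutoff is 0.1: trained responses to
inputs often saturate, which makes a 5 % knockdown underestimate input
links, and 0.2 was observed to drop functional links for that reason.  When
comparing topologies across an ensemble, the cutoff that maximizes the
number of distinct topologies can be selected from a grid (50 points on
[0, 1] by default): too low a cutoff makes sparse solutions
indistinguishable from dense ones, too high a cutoff erases real weak
links, so the distinct-topology count peaks in between.

### Sparsification

Step 0 trains with an optional initial mask.  Each iteration simulates the
λ = 0 knockout of every structurally remaining link, ranks links by how
little their knockout increases the task loss (ties break toward the lowest
regulator-then-target index), deletes the best-ranked link, and retrains
(warm start by default).  If the retrained loss exceeds the failure
threshold the deletion is rolled back and the next-ranked candidate is
tried; the search terminates when no remaining link can be deleted without
losing the function — the greedy ranking is myopic, and requiring outright
termination to mean "no link is deletable" is what lets the sequence reach
genuinely minimal motifs.  The failure threshold is
`max(2 × step-0 loss, 0.3)`; the absolute floor is derived from the task's
own scale (an adaptation error `e` sustained over the ~20-step post-pulse
plateau of the three stimulated conditions adds about `sqrt(60)·e` to the
loss, so 0.3 corresponds to `e ≈ 0.04`).  Recorded topologies use cutoff 0 —
the structure is fixed by the mask, so every surviving link keeps its sign
and recorded link counts fall by exactly one per step.

## Hill-function validation

A signed topology becomes an ODE model by giving every activating link a
term `b·g^n/(K^n + g^n)` and every repressing link a factor
`K^n/(K^n + g^n)`, with activation terms summed, repression factors
multiplied, Hill coefficient n = 2 throughout, and basal expression ignored
— a gene with no activators is never expressed, which in particular means a
high steady state is unreachable for any gene that no input or expressed
gene activates.  Parameters are drawn i.i.d. from Exp(1).  Simulation uses
the same Euler scheme (γ = 1, dt = 0.2, 200 steps, all genes starting at
0.1) as the neural model, so transfer tests compare like with like.

Success criteria (the quantitative stand-ins for a by-eye check):

* **controlled oscillation** — no-input mean of the output over steps
  101–200 below 0.3 with variance below 1e−3; under input 2, mean above 0.6
  with variance below 1e−3; under input 1, variance above 1e−3 over steps
  101–200, peak-to-peak above 0.05, and a regularity test on the trace from
  step 51 on (≥ 3 detected peaks, coefficient of variation of inter-peak
  gaps < 0.2).  The peak window is longer than the variance window so slow
  oscillators still show three cycles.
* **adaptation** — settle 200 steps with the input off, then step the input
  to 1: peak deviation (sensitivity) above 0.1 and final deviation below
  0.1 × sensitivity.

A topology is *successful* when at least 2 sampled parameter sets succeed;
the count itself is its robustness.  Screens are vectorized across
parameter sets and chunked (10,000 per chunk), with chunk c of a screen
seeded by `SeedSequence((seed, offset + c))`, so a screen split across
workers reproduces the single-run count exactly.

The two-gene enumeration assigns each of the 8 directed links (two inputs ×
two genes plus four gene-gene links) a sign in {−1, 0, +1} and keeps the
2304 of 6561 assignments in which each input regulates at least one gene
and the two genes are bidirectionally coupled.

Under these conventions the minimal two-gene negative-feedback controlled
oscillator coincides with the six-link network the trained models typically
discover: a two-gene negative-feedback loop at equal decay rates only
oscillates when the output is self-activating (the relaxation-oscillator
core `g1→g1, g1→g2, g2⊣g1`); the high state under input 2 requires a direct
`I2→g1` activation (no basal expression to bootstrap from); and sustained
high output requires `I2⊣g2` to silence the repressor.  None of the six
links is deletable.  The p53-like three-node controlled oscillator used as
a fixture is the core damage-response module (input → kinase → p53 →
phosphatase ⊣ kinase, with the second input driving p53 directly while
silencing the phosphatase), defined here as a six-link topology.

Measured under these criteria, the six-link oscillator admits roughly 3–5
successful parameter sets per 160,000 — rare enough that fixture screens
use the full 160,000-sample budget rather than a reduced one, while random
topologies are screened at 20,000 samples each.

## The cellular-automata benchmark

Ground truth: a ring of 32 identical cells, each carrying 10 gene levels,
updating by the shared Euler rule with inputs `(g_x, h_x)` where
`h_x = (g_{x−1} + g_{x+1})/2` (reflection-symmetric rules only, periodic
boundary).  The rule's 200 candidate links are drawn i.i.d. with
probabilities 0.35 / 0.30 / 0.35 for activating / absent / inhibiting and
realized with Exp(1) Hill parameters; candidates whose test run (200 steps
from a random lattice) fails to show a time-averaged spatial variance above
0.01 for at least one gene are rejected and redrawn.  Because activator
strengths are unnormalized, true synthesis rates and states exceed 1; the
observed data are divided by their pooled maximum before modeling (the
Euler update is exactly scale-covariant, turning the rate into `f/s`), which
keeps the neural model's `(0, 1)` output bound valid and leaves link signs
untouched.

Inference: the dynamics are observed every 10 raw steps (12 trajectories of
200 steps from i.i.d. uniform initial lattices by default — many short
trajectories, because the diverse early frames carry most of the
information that separates own-cell from neighbor influence).  The neural
model (shared architecture, 10 genes + 10 neighbor inputs, hidden 64 × 64)
starts at an observed state and free-runs 10 Euler steps to predict the
next observed state.  During the free run the neighbor input is an
observation, not part of the model state; by default it is linearly
interpolated between its values at the two observed frames (`h_mode =
"interp"`; "frozen" and a fully coupled lattice rollout are alternatives —
the coupled mode pays a much higher chaos-limited loss floor for little
benefit at this problem size).  Training is minibatch Adam (batch 384,
6000 iterations, learning rate 3e−3 halved at 1/2 and 3/4 of the run) with
decoupled weight decay 1e−3, which smooths the learned response surface and
measurably improves the fidelity of the sensitivities that link scoring
probes.

Every candidate link is scored by `⟨Δ⟩` with λ = 0.95 over the pooled
observed states.  For the three-way classification, the weakest 30 % of
links by |score| are called absent and the rest take their score's sign;
for ROC analysis the threshold on the score (negated score) sweeps out the
activating (inhibiting) detector curve, with trapezoidal AUC.  The baseline
is the least-squares linear auto-regressor `y = W·(g, h) + c` fitted to the
same observed pairs, its W entries serving as link scores.  Note the AUC
ceiling against the full 200-link truth is far below 1 for any method:
with dense random topologies many true links are dynamically faint (the
ground truth's own median |Δ| across existing links is ~1e−3), so ranking
them against exact zeros is noise-limited.

## Numerical choices and degenerate inputs

* Inputs are held piecewise-constant over a step (step i uses input row i).
* Langevin noise clips states at zero; the clip's gradient is zero where it
  binds.
* A loss of exactly zero short-circuits backpropagation (no gradient).
* All-zero link scores extract to the empty topology rather than erroring.
* Gradient norms are clipped at 100 before Adam updates.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` derivation; derived seeds stay below 2^31.

## Problem sizes

Test and example runs use the sizes stated above: 10-restart ensembles for
adaptation, 24 spatial positions for the gap-gene example, 4 rules ×
12 × 200-step trajectories for the lattice benchmark, 160,000-sample
fixture screens and 20,000-sample random screens for the Hill validation.
These sizes were chosen so each study completes in minutes on one CPU core
while leaving the tested claims comfortably resolved; all are configurable.

## Known limitations

* The method reports *effective* regulation near the trained trajectories;
  links that act only in unvisited regions of state space are invisible in
  principle.
* Knockdown scores underestimate saturated regulations (a 5 % knockdown of
  a saturated input barely moves the response); the extraction cutoff
  default compensates but cannot eliminate this.
* Greedy deletion with backtracking explores one path per seed; different
  seeds legitimately end in different minimal motifs.
* The Hill transfer test is one-sided: passing shows the topology is
  realizable with saturating biochemistry, failing does not prove it is
  unrealizable (the success criteria are conservative stand-ins for a
  qualitative judgment).
* The synthetic gap-gene and lattice generators produce smooth, noise-free,
  fully observed data; conclusions about robustness to measurement noise or
  missing genes are outside what the tests establish.
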