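"""Continuous-state cellular-automata benchmark for network inference.

A 1-D ring of identical cells each carries 10 gene levels.  Every time step,
each cell updates by the shared Euler rule with synthesis driven by its own
state g and the average of its two neighbors h = (g_left + g_right) / 2
(reflection-symmetric rules only; periodic boundary).  The regulation rule —
a signed topology over 20 regulators (10 own-cell genes + 10 neighbor
averages) x 10 targets, 200 candidate links in all — is drawn at random
(35% activating / 30% absent / 35% inhibiting per link), realized with
random-parameter Hill functions, and kept only if its dynamics develop
non-uniform spatio-temporal patterns.

The inference task: observe the dynamics down-sampled 10-fold in time, train
a neural synthesis model that free-runs 10 steps between observed frames, and
score every candidate link by the knockdown measure of the interrogation
module.  Link recovery (ROC/AUC for activating and inhibiting links, and a
3-way confusion matrix after discarding the weakest 30% of links) is compared
against the simplest linear auto-regressor fitted to the same observed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc, roc_curve

from netdistill.hill import HillParams, HillSynthesis, sample_hill_params
from netdistill.interrogation import LinkScores, Topology, delta_matrix
from netdistill.nn_synthesis import MLPSynthesis, build_synthesis
from netdistill.training import AdamState

__all__ = [
    "CARule",
    "CAConfig",
    "CATrainConfig",
    "LinkPredictionEval",
    "generate_ca_rule",
    "simulate_ca",
    "neighbor_average",
    "downsample_temporal",
    "CAPairs",
    "train_ca_rnn",
    "score_ca_links",
    "classify_links",
    "roc_analysis",
    "linear_autoregressor_baseline",
    "run_benchmark",
]

DT = 0.2
GAMMA = 1.0
N_GENES = 10


@dataclass
class CAConfig:
    """Ground-truth generation settings: lattice size, link-sign priors and
    the non-uniformity acceptance test (time-averaged spatial variance of at
    least one gene above ``accept_var`` over a test run)."""

    n_cells: int = 32
    link_probs: tuple[float, float, float] = (0.35, 0.30, 0.35)  # (+, 0, -)
    test_steps: int = 200
    accept_var: float = 0.01
    max_retries: int = 50


@dataclass
class CARule:
    """A ground-truth cellular-automaton rule: signed 20 x 10 topology plus
    Hill parameters, with the seed and acceptance diagnostics recorded."""

    topology: Topology
    params: HillParams
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_candidate_links(self) -> int:
        return self.topology.sign.size


class CAGenerationError(RuntimeError):
    """Raised when no accepted rule is found within the retry budget."""


def neighbor_average(g: np.ndarray) -> np.ndarray:
    """h_x = (g_{x-1} + g_{x+1}) / 2 with periodic wrap-around."""
    return 0.5 * (np.roll(g, 1, axis=0) + np.roll(g, -1, axis=0))


def _draw_rule(seed: int, cfg: CAConfig) -> CARule:
    rng = np.random.default_rng(seed)
    p_act, p_none, p_inh = cfg.link_probs
    sign = rng.choice(np.array([1, 0, -1], dtype=np.int8),
                      size=(2 * N_GENES, N_GENES),
                      p=[p_act, p_none, p_inh])
    topo = Topology(n_genes=N_GENES, n_inputs=N_GENES, sign=sign)
    params = sample_hill_params(topo, seed=rng)
    return CARule(topology=topo, params=params, seed=seed)


def generate_ca_rule(seed: int = 0, config: CAConfig | None = None) -> CARule:
    """Draw random CA rules until one develops non-uniform patterns.

    Each candidate's link signs are i.i.d. with the configured prior and its
    Hill parameters i.i.d. unit-exponential.  A test simulation from a random
    initial state must show a time-averaged spatial variance above the
    acceptance threshold for at least one gene; rejected candidates retry
    with derived seeds.
    """
    cfg = config or CAConfig()
    ss = np.random.SeedSequence(seed)
    for attempt, child in enumerate(ss.spawn(cfg.max_retries)):
        sub = int(child.generate_state(1)[0] % (2 ** 31))
        rule = _draw_rule(sub, cfg)
        init = np.random.default_rng(child).uniform(
            0.0, 1.0, (cfg.n_cells, N_GENES))
        arr = simulate_ca(rule, init, cfg.test_steps)
        spatial_var = arr.var(axis=1).mean(axis=0)  # time-mean over cells-var
        if np.isfinite(arr).all() and spatial_var.max() > cfg.accept_var:
            rule.diagnostics = {
                "attempt": attempt,
                "max_time_mean_spatial_var": float(spatial_var.max()),
            }
            return rule
    raise CAGenerationError(
        f"no patterned rule found in {cfg.max_retries} attempts (seed {seed})")


def simulate_ca(rule: CARule, initial_states: np.ndarray,
                n_steps: int) -> np.ndarray:
    """Spatio-temporal simulation: returns (n_steps + 1, n_cells, 10).

    Every cell applies the shared Euler update with inputs (g_x, h_x); the
    neighbor average uses periodic boundaries.
    """
    init = np.asarray(initial_states, dtype=float)
    if init.ndim != 2 or init.shape[1] != N_GENES:
        raise ValueError("initial states must have shape (n_cells, 10)")
    if init.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    synth = HillSynthesis(rule.topology, rule.params)
    out = np.empty((n_steps + 1, init.shape[0], N_GENES))
    out[0] = init
    g = init.copy()
    for t in range(n_steps):
        h = neighbor_average(g)
        f = synth(g, h)
        g = (1.0 - GAMMA * DT) * g + DT * f
        if not np.isfinite(g).all():
            raise RuntimeError(f"non-finite CA state at step {t + 1}")
        out[t + 1] = g
    return out


@dataclass
class CAPairs:
    """Training pairs from down-sampled observations: for each observed
    frame and cell, the own state ``g``, the neighbor average ``h``, and the
    state at the next observed frame ``y`` (all (n_pairs, 10)).

    ``scale`` records the normalization applied to the raw observations.
    Hill-rule states are not bounded by 1, while the neural synthesis rate
    is; the Euler update is scale-covariant (dividing states by s turns the
    synthesis rate into f/s), so observations are divided by their maximum
    before training and scoring.  Link signs are unaffected.
    """

    g: np.ndarray
    h: np.ndarray
    y: np.ndarray
    factor: int = 10
    scale: float = 1.0
    h_next: np.ndarray | None = None  # neighbor average at the next frame
    n_cells: int = 0  # cells per frame; rows are frame-contiguous when > 0

    @property
    def n_pairs(self) -> int:
        return self.g.shape[0]

    @property
    def n_frames(self) -> int:
        return 0 if self.n_cells == 0 else self.g.shape[0] // self.n_cells

    def normalized(self) -> "CAPairs":
        """Rescale observations into [0, 1] by their pooled maximum."""
        s = float(max(self.g.max(), self.h.max(), self.y.max()))
        if s <= 1.0:
            return self
        return CAPairs(g=self.g / s, h=self.h / s, y=self.y / s,
                       factor=self.factor, scale=self.scale * s,
                       h_next=None if self.h_next is None else self.h_next / s,
                       n_cells=self.n_cells)

    def raw_states(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed (g, h) on the original (unnormalized) scale."""
        return self.g * self.scale, self.h * self.scale


def downsample_temporal(array: np.ndarray, factor: int = 10) -> CAPairs:
    """Keep every ``factor``-th frame and form (state, next-observed-state)
    pairs, flattened over cells, recording each cell's (g, h)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(array, dtype=float)
    if arr.shape[0] < factor + 1:
        raise ValueError("need at least factor + 1 frames")
    frames = arr[::factor]
    g = frames[:-1].reshape(-1, arr.shape[2])
    y = frames[1:].reshape(-1, arr.shape[2])
    h = np.concatenate([neighbor_average(fr) for fr in frames[:-1]])
    h_next = np.concatenate([neighbor_average(fr) for fr in frames[1:]])
    return CAPairs(g=g, h=h, y=y, factor=factor, h_next=h_next,
                   n_cells=arr.shape[1])


@dataclass
class CATrainConfig:
    """Neural-model training settings for the CA benchmark.  The learning
    rate is halved twice over the run (a simple step schedule; late-stage
    fine-tuning sharpens the learned sensitivities that link scoring
    probes)."""

    hidden_sizes: tuple[int, int] = (64, 64)
    learning_rate: float = 3e-3
    iterations: int = 12000
    batch_size: int = 384
    seed: int = 0
    free_run_steps: int = 10
    grad_clip: float = 100.0
    h_mode: str = "interp"  # "interp" | "coupled" | "frozen"
    weight_decay: float = 1e-3  # decoupled L2; smooths the learned response
    # surface, sharpening the sensitivities that link scoring probes


class CATrainingError(RuntimeError):
    pass


def _free_run_loss_grads(model: MLPSynthesis, g0: np.ndarray, h: np.ndarray,
                         y: np.ndarray, steps: int,
                         h_next: np.ndarray | None = None):
    """Loss and gradients for a free run between observed frames.

    The neighbor input is an observation, not part of the per-pair state:
    it is held at its start-frame value, or linearly interpolated toward the
    next frame's value when ``h_next`` is given.  No gradient flows into it.
    """
    decay = 1.0 - GAMMA * DT
    g = g0
    caches = []
    for t in range(steps):
        ht = (h if h_next is None
              else h + (t / steps) * (h_next - h))
        x = np.concatenate([g, ht], axis=1)
        f, cache = model.forward_cached(x)
        caches.append(cache)
        g = decay * g + DT * f
    resid = g - y
    L = float(np.sqrt(np.sum(resid * resid)))
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    if L <= 0 or not np.isfinite(L):
        return L, grads
    dg = resid / L
    for cache in reversed(caches):
        df = DT * dg
        step_grads, dx = model.backward(cache, df)
        for k, v in step_grads.items():
            grads[k] += v
        dg = decay * dg + dx[:, :N_GENES]  # neighbor input h is frozen
    return L, grads


def _coupled_run_loss_grads(model: MLPSynthesis, g0: np.ndarray,
                            y: np.ndarray, steps: int):
    """Loss and gradients for a spatially coupled lattice free run.

    States have shape (frames, cells, genes); the neighbor input at every
    step is the neighbor average of the co-evolving predicted state, and the
    gradient flows back through the (self-adjoint) averaging stencil.
    """
    decay = 1.0 - GAMMA * DT
    B, C, _ = g0.shape
    g = g0
    caches = []
    for _ in range(steps):
        h = 0.5 * (np.roll(g, 1, axis=1) + np.roll(g, -1, axis=1))
        x = np.concatenate([g, h], axis=2).reshape(B * C, 2 * N_GENES)
        f, cache = model.forward_cached(x)
        caches.append(cache)
        g = decay * g + DT * f.reshape(B, C, N_GENES)
    resid = g - y
    L = float(np.sqrt(np.sum(resid * resid)))
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    if L <= 0 or not np.isfinite(L):
        return L, grads
    dg = resid / L
    for cache in reversed(caches):
        df = (DT * dg).reshape(B * C, N_GENES)
        step_grads, dx = model.backward(cache, df)
        for k, v in step_grads.items():
            grads[k] += v
        dx = dx.reshape(B, C, 2 * N_GENES)
        dh = dx[:, :, N_GENES:]
        dg = (decay * dg + dx[:, :, :N_GENES]
              + 0.5 * (np.roll(dh, 1, axis=1) + np.roll(dh, -1, axis=1)))
    return L, grads


def train_ca_rnn(pairs: CAPairs, config: CATrainConfig | None = None,
                 ) -> tuple[MLPSynthesis, np.ndarray]:
    """Fit a shared synthesis MLP (10 genes + 10 neighbor inputs) to the
    observed pairs.

    The model starts at an observed state and free-runs ``free_run_steps``
    Euler steps to predict the next observed state; during the free run the
    neighbor input is held at its observed value for the pair's start frame,
    which keeps the training pairs independent (full spatial co-simulation is
    used only at evaluation).  Minibatch Adam; returns (model, loss history).
    """
    cfg = config or CATrainConfig()
    if pairs.n_pairs == 0:
        raise ValueError("no training pairs")
    model = build_synthesis(N_GENES, N_GENES, hidden_sizes=cfg.hidden_sizes,
                            architecture="shared", seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamState(model.params, cfg.learning_rate)
    history = []
    n = pairs.n_pairs
    coupled = cfg.h_mode == "coupled" and pairs.n_cells > 0
    if coupled:
        C = pairs.n_cells
        gf = pairs.g.reshape(-1, C, N_GENES)
        yf = pairs.y.reshape(-1, C, N_GENES)
        n_frames = gf.shape[0]
        frames_per_batch = max(1, cfg.batch_size // C)
    for it in range(cfg.iterations):
        if it in (cfg.iterations // 2, (3 * cfg.iterations) // 4):
            opt.lr *= 0.5
        if coupled:
            idx = rng.integers(0, n_frames, size=frames_per_batch)
            L, grads = _coupled_run_loss_grads(model, gf[idx], yf[idx],
                                               cfg.free_run_steps)
        else:
            idx = rng.integers(0, n, size=min(cfg.batch_size, n))
            hn = None
            if cfg.h_mode == "interp" and pairs.h_next is not None:
                hn = pairs.h_next[idx]
            L, grads = _free_run_loss_grads(model, pairs.g[idx], pairs.h[idx],
                                            pairs.y[idx], cfg.free_run_steps,
                                            h_next=hn)
        if not np.isfinite(L):
            raise CATrainingError(f"non-finite loss at iteration {it}")
        gn = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        if gn > cfg.grad_clip:
            for g in grads.values():
                g *= cfg.grad_clip / gn
        opt.step(model.params, grads)
        if cfg.weight_decay > 0:
            for k in ("W1", "W2", "W3"):
                model.params[k] *= 1.0 - opt.lr * cfg.weight_decay
        history.append(L)
    return model, np.asarray(history)


def score_ca_links(model, pairs_or_states, lam: float = 0.95) -> LinkScores:
    """Knockdown link scores over pooled observed states: a 20 x 10 matrix
    treating own-cell genes and neighbor averages as independent regulators."""
    if isinstance(pairs_or_states, CAPairs):
        G, H = pairs_or_states.g, pairs_or_states.h
    else:
        G, H = pairs_or_states
    return delta_matrix(model, (G, H), lam=lam)


@dataclass
class LinkPredictionEval:
    """Link-recovery evaluation: a 3x3 confusion matrix (rows = true class,
    columns = predicted, ordered inhibiting / non-exist / activating) and
    per-class ROC curves with their AUCs."""

    confusion: np.ndarray | None = None
    roc_activating: tuple[np.ndarray, np.ndarray] | None = None
    roc_inhibiting: tuple[np.ndarray, np.ndarray] | None = None
    auc_activating: float | None = None
    auc_inhibiting: float | None = None


def classify_links(scores: LinkScores, truth: Topology,
                   discard_fraction: float = 0.30) -> LinkPredictionEval:
    """Three-way link classification: the weakest ``discard_fraction`` of
    links (by |score|) are predicted non-existent, the rest take the sign of
    their score; counts are tallied against the true topology."""
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    vals = scores.values
    if vals.shape != truth.sign.shape:
        raise ValueError("score/truth shape mismatch")
    flat = vals.ravel()
    true = truth.sign.ravel()
    n = flat.size
    n_discard = int(round(discard_fraction * n))
    order = np.argsort(np.abs(flat), kind="stable")
    pred = np.sign(flat).astype(int)
    pred[order[:n_discard]] = 0
    confusion = np.zeros((3, 3), dtype=int)
    for t, p in zip(true, pred):
        confusion[t + 1, p + 1] += 1
    return LinkPredictionEval(confusion=confusion)


def roc_analysis(scores: LinkScores, truth: Topology) -> LinkPredictionEval:
    """ROC curves for 'activating vs rest' (threshold on the score) and
    'inhibiting vs rest' (threshold on the negated score), with trapezoidal
    AUC."""
    vals = scores.values.ravel()
    true = truth.sign.ravel()
    if not (true == 1).any() or not (true == -1).any():
        raise ValueError("truth must contain at least one link of each class")
    fpr_a, tpr_a, _ = roc_curve(true == 1, vals)
    fpr_i, tpr_i, _ = roc_curve(true == -1, -vals)
    return LinkPredictionEval(
        roc_activating=(fpr_a, tpr_a),
        roc_inhibiting=(fpr_i, tpr_i),
        auc_activating=float(sk_auc(fpr_a, tpr_a)),
        auc_inhibiting=float(sk_auc(fpr_i, tpr_i)),
    )


def linear_autoregressor_baseline(pairs: CAPairs) -> LinkScores:
    """Least-squares linear auto-regressor: next observed state =
    W (g, h) + c; link scores are the entries of W."""
    X = np.column_stack([pairs.g, pairs.h, np.ones(pairs.n_pairs)])
    if X.shape[0] < X.shape[1]:
        raise ValueError("not enough pairs for a determined least-squares fit")
    coef, _, rank, _ = np.linalg.lstsq(X, pairs.y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            "more diverse training states are needed")
    return LinkScores(values=coef[:-1, :], lam=1.0,
                      provenance={"model": "linear_autoregressor"})


# ---------------------------------------------------------------------- #
# end-to-end benchmark
# ---------------------------------------------------------------------- #
def generate_training_data(rule: CARule, n_trajectories: int = 3,
                           n_steps: int = 600, n_cells: int = 32,
                           seed: int = 0, factor: int = 10) -> CAPairs:
    """Simulate training trajectories from random initial lattices and pool
    their down-sampled pairs."""
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_trajectories):
        init = rng.uniform(0.0, 1.0, (n_cells, N_GENES))
        arr = simulate_ca(rule, init, n_steps)
        parts.append(downsample_temporal(arr, factor))
    return CAPairs(
        g=np.concatenate([p.g for p in parts]),
        h=np.concatenate([p.h for p in parts]),
        y=np.concatenate([p.y for p in parts]),
        factor=factor,
        h_next=np.concatenate([p.h_next for p in parts]),
        n_cells=n_cells,
    ).normalized()


def run_benchmark(
    n_rules: int = 4,
    seed: int = 0,
    ca_config: CAConfig | None = None,
    train_config: CATrainConfig | None = None,
    n_trajectories: int = 12,
    n_steps: int = 200,
    lam: float = 0.95,
) -> pd.DataFrame:
    """Full benchmark: for each generated rule, train the neural model on
    down-sampled data, score links by knockdown, and compare AUCs against
    the linear auto-regressor.  Returns one row per rule."""
    cfg = ca_config or CAConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    for ri, child in enumerate(ss.spawn(n_rules)):
        s_rule, s_data, s_train = (int(x) for x in
                                   child.generate_state(3) % (2 ** 31))
        rule = generate_ca_rule(s_rule, cfg)
        pairs = generate_training_data(rule, n_trajectories, n_steps,
                                       cfg.n_cells, seed=s_data)
        tc = train_config or CATrainConfig()
        tc = CATrainConfig(**{**tc.__dict__, "seed": s_train})
        model, history = train_ca_rnn(pairs, tc)
        rnn_eval = roc_analysis(score_ca_links(model, pairs, lam=lam),
                                rule.topology)
        lin_eval = roc_analysis(linear_autoregressor_baseline(pairs),
                                rule.topology)
        rows.append({
            "rule": ri,
            "rule_seed": rule.seed,
            "train_loss_first": float(history[0]),
            "train_loss_last": float(history[-1]),
            "auc_rnn_activating": rnn_eval.auc_activating,
            "auc_rnn_inhibiting": rnn_eval.auc_inhibiting,
            "auc_linear_activating": lin_eval.auc_activating,
            "auc_linear_inhibiting": lin_eval.auc_inhibiting,
        })
    return pd.DataFrame(rows)
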