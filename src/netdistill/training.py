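"""Gradient-based fitting of the synthesis function to a task.

Time evolution of the regulatory system is the recurrent iteration of the
synthesis MLP through the forward-Euler update, so fitting is ordinary
backpropagation through the unrolled computation graph (all conditions are
batched and trained full-batch; the optimizer is Adam).  Trainable
pre-stimulus initial values receive gradients through the same unroll.

Run-time Langevin noise (a small zero-mean Gaussian kick to the state after
each Euler update, clipped at zero) is applied during training; it
regularizes the learned dynamics and is part of what makes repeated restarts
collapse onto a limited set of effective regulation networks.  Convergence is
monitored on periodic noise-free evaluations of the loss, and the best
noise-free parameters seen are the ones returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from netdistill.dynamics import Trajectory, simulate
from netdistill.nn_synthesis import MLPSynthesis, build_synthesis
from netdistill.tasks import TaskSpec, loss as task_loss_fn

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TrainingError",
    "EnsembleError",
    "train",
    "train_ensemble",
    "resolve_initial_state",
    "simulate_task",
]


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


class EnsembleError(RuntimeError):
    """Raised when every restart of an ensemble fails."""


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``loss_target`` stops training once the noise-free loss drops below it
    (the tasks posed here are fit essentially perfectly well before the
    iteration budget runs out); ``tol``/``patience_evals`` implement a
    plateau stop on the noise-free evaluation sequence.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-2
    max_iterations: int = 3000
    noise_sd: float = 0.01
    seed: int = 0
    loss_target: float = 0.05
    tol: float = 1e-6
    eval_every: int = 10
    patience_evals: int = 30
    grad_clip: float = 100.0


@dataclass
class TrainResult:
    model: MLPSynthesis
    loss_history: np.ndarray  # noise-free evaluations, one per eval point
    best_loss: float
    n_iterations: int
    converged: bool
    seed: int = 0
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #
# task helpers
# ---------------------------------------------------------------------- #
def resolve_initial_state(synth, task: TaskSpec) -> np.ndarray:
    """Initial gene levels for simulating ``task`` with ``synth``.

    A trained MLP carries its own (possibly trained) initial values; any
    other synthesis function falls back to the policy values of the task.
    """
    if isinstance(synth, MLPSynthesis):
        return synth.initial_state()
    return np.array([v for _, v in task.initial_policy], dtype=float)


def simulate_task(synth, task: TaskSpec, noise_sd: float = 0.0,
                  seed: int | None = None) -> list[Trajectory]:
    """Simulate every condition of a task (noise-free by default)."""
    g0 = resolve_initial_state(synth, task)
    out = []
    for ci, course in enumerate(task.conditions):
        s = None if seed is None else seed + ci
        out.append(simulate(synth, g0, course, n_steps=task.N_T,
                            dt=task.dt, noise_sd=noise_sd, seed=s))
    return out


def task_loss(synth, task: TaskSpec) -> float:
    """Noise-free task loss of a synthesis function."""
    return task_loss_fn(simulate_task(synth, task), task)


# ---------------------------------------------------------------------- #
# batched unroll with gradients
# ---------------------------------------------------------------------- #
def _target_tensors(task: TaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dense (N_T+1, B, n_genes) masks/values for the sparse constraints."""
    shape = (task.N_T + 1, task.n_conditions, task.n_genes)
    mask = np.zeros(shape)
    values = np.zeros(shape)
    for c, t, g, v in task.targets:
        mask[int(t), int(c), int(g)] = 1.0
        values[int(t), int(c), int(g)] = v
    return mask, values


def _forward_backward(
    model: MLPSynthesis,
    task: TaskSpec,
    inputs: np.ndarray,  # (B, N_T+1, m)
    tmask: np.ndarray,
    tvalues: np.ndarray,
    gamma: float,
    noise: np.ndarray | None,  # (B, N_T, n) or None
) -> tuple[float, dict[str, np.ndarray]]:
    """One pass of BPTT: returns (loss, parameter gradients)."""
    B = task.n_conditions
    n, dt = task.n_genes, task.dt
    decay = 1.0 - gamma * dt
    g0 = model.initial_state()
    g = np.broadcast_to(g0, (B, n)).copy()
    states = np.empty((task.N_T + 1, B, n))
    states[0] = g
    caches = []
    clip_masks = []
    for t in range(task.N_T):
        x = np.concatenate([g, inputs[:, t, :]], axis=1) if model.n_inputs else g
        f, cache = model.forward_cached(x)
        caches.append(cache)
        g = decay * g + dt * f
        if noise is not None:
            raw = g + noise[:, t, :]
            clip_masks.append(raw > 0.0)
            g = np.maximum(raw, 0.0)
        else:
            clip_masks.append(None)
        states[t + 1] = g

    resid = (states - tvalues) * tmask
    sq = float(np.sum(resid * resid))
    L = float(np.sqrt(sq))
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    if L <= 0.0 or not np.isfinite(L):
        return L, grads
    dstates = resid / L  # dL/dg at every (t, cond, gene)

    dg = dstates[task.N_T].copy()
    for t in range(task.N_T - 1, -1, -1):
        if clip_masks[t] is not None:
            dg = dg * clip_masks[t]
        df = dt * dg
        step_grads, dx = model.backward(caches[t], df)
        for k, v in step_grads.items():
            grads[k] += v
        dg = decay * dg + dx[:, :n]
        dg += dstates[t]
    # gradient into trainable initial logits through g0 = sigmoid(logit)
    tr = model.init_trainable
    if tr.any():
        dg0 = dg.sum(axis=0)
        s = model.initial_state()
        grads["init_logits"][tr] = dg0[tr] * s[tr] * (1.0 - s[tr])
    return L, grads


class AdamState:
    """Minimal Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * gk * gk
            p -= self.lr * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + self.eps)


def train(
    synth: MLPSynthesis,
    task: TaskSpec,
    config: TrainConfig | None = None,
    reset_init: bool = True,
) -> TrainResult:
    """Fit a synthesis MLP (and its trainable initial values) to a task.

    The model is trained full-batch over all conditions by backpropagation
    through the unrolled Euler dynamics.  The returned model carries the
    parameters of the best noise-free loss evaluation.  Deterministic given
    the config seed (and the model's build seed).  ``reset_init=False``
    keeps an already-configured model's initial-condition state (used when
    continuing training after a structural change).
    """
    config = config or TrainConfig()
    if config.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")
    model = synth.copy()
    if reset_init:
        model.set_initial_policy(task.initial_policy)
    if model.n_genes != task.n_genes or model.n_inputs != task.n_inputs:
        raise ValueError("synthesis dimensions do not match the task")
    inputs = np.stack(task.conditions)  # (B, N_T+1, m)
    tmask, tvalues = _target_tensors(task)
    rng = np.random.default_rng(config.seed)
    opt = AdamState(model.params, config.learning_rate)

    history: list[float] = []
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    evals_since_improve = 0
    n_iter = 0
    converged = False
    for it in range(config.max_iterations):
        n_iter = it + 1
        noise = None
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd,
                               (task.n_conditions, task.N_T, task.n_genes))
        L, grads = _forward_backward(model, task, inputs, tmask, tvalues,
                                     gamma=1.0, noise=noise)
        if not np.isfinite(L):
            raise TrainingError(
                f"non-finite loss at iteration {it} (seed {config.seed})")
        gn = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        if gn > config.grad_clip:
            for g in grads.values():
                g *= config.grad_clip / gn
        opt.step(model.params, grads)
        if (it + 1) % config.eval_every == 0 or it == config.max_iterations - 1:
            clean = task_loss(model, task)
            if not np.isfinite(clean):
                raise TrainingError(
                    f"non-finite evaluation loss at iteration {it}")
            history.append(clean)
            if clean < best_loss - config.tol:
                best_loss = clean
                best_params = {k: v.copy() for k, v in model.params.items()}
                evals_since_improve = 0
            else:
                evals_since_improve += 1
            if best_loss < config.loss_target:
                converged = True
                break
            if evals_since_improve >= config.patience_evals:
                converged = True
                break
    model.params = best_params
    if not history:
        history = [task_loss(model, task)]
        best_loss = history[0]
    return TrainResult(
        model=model,
        loss_history=np.asarray(history),
        best_loss=float(best_loss),
        n_iterations=n_iter,
        converged=converged,
        seed=config.seed,
    )


def train_ensemble(
    task: TaskSpec,
    n_restarts: int,
    base_seed: int = 0,
    config: TrainConfig | None = None,
    hidden_sizes: tuple[int, int] = (16, 16),
    architecture: str = "per_gene",
    mask: list[tuple[int | str, int | str]] | None = None,
) -> list[TrainResult]:
    """Repeated training with different weight initialization and noise.

    Each restart derives an independent seed pair (build seed, training seed)
    from ``base_seed``.  Restarts whose loss diverges are recorded and
    skipped; if every restart fails an :class:`EnsembleError` is raised.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    from netdistill.nn_synthesis import apply_structural_mask

    config = config or TrainConfig()
    ss = np.random.SeedSequence(base_seed)
    results: list[TrainResult] = []
    failures: list[tuple[int, str]] = []
    for child in ss.spawn(n_restarts):
        s_build, s_train = (int(x) for x in child.generate_state(2) % (2 ** 31))
        synth = build_synthesis(task.n_genes, task.n_inputs,
                                hidden_sizes=hidden_sizes,
                                architecture=architecture, seed=s_build)
        if mask:
            synth = apply_structural_mask(synth, mask)
        cfg = TrainConfig(**{**config.__dict__, "seed": s_train})
        try:
            results.append(train(synth, task, cfg))
        except TrainingError as exc:
            failures.append((s_train, str(exc)))
    if not results:
        raise EnsembleError(
            f"all {n_restarts} restarts failed: {failures}")
    return results
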