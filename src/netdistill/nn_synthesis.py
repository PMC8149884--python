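"""Trainable bounded synthesis function f(g, I) as a small multilayer perceptron.

Two architectures are supported:

``shared``
    A single MLP maps the full state (all gene levels plus all external
    inputs) to all synthesis rates at once.
``per_gene``
    Each gene owns a private MLP mapping the full state to its single
    synthesis rate.  Weights are stored stacked along a leading gene axis so
    all subnetworks evaluate in one batched pass.

Hidden layers use ReLU; the output layer uses a sigmoid so every synthesis
rate stays strictly inside (0, 1), which together with linear decay keeps the
gene dynamics bounded.

Structural link masks implement permanent link knockouts: a forbidden
(regulator, target) pair zeroes the regulator's value at the input of the
target's synthesis computation, so the target's rate is exactly invariant to
that regulator and no gradient ever flows through the severed connection.

The forward/backward passes are written directly in NumPy: the model is tiny
(tens of hidden units) and the surrounding integrator needs reverse-mode
gradients through an unrolled time loop, which the training module assembles
from the ``forward_cached`` / ``backward`` primitives defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MLPSynthesis",
    "build_synthesis",
    "apply_structural_mask",
    "save_checkpoint",
    "load_checkpoint",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPSynthesis:
    """Bounded synthesis-rate map realised by a small MLP.

    Parameters live in ``params`` (a flat name -> array dict) so a generic
    optimizer can update them in place.  ``mask`` is an (n_regulators,
    n_genes) 0/1 matrix with genes first, then inputs, along the regulator
    axis; 0 marks a forbidden link.

    Pre-stimulus initial gene levels may be trainable: for genes flagged in
    ``init_trainable`` the initial value is ``sigmoid(params["init_logits"])``
    (kept in (0, 1) by construction); other genes use ``init_fixed``.
    """

    n_genes: int
    n_inputs: int
    hidden_sizes: tuple[int, int]
    architecture: str  # "shared" | "per_gene"
    params: dict[str, np.ndarray]
    mask: np.ndarray  # (n_genes + n_inputs, n_genes), 1 = allowed
    init_trainable: np.ndarray = field(default=None)  # bool (n_genes,)
    init_fixed: np.ndarray = field(default=None)  # float (n_genes,)

    def __post_init__(self) -> None:
        if self.init_trainable is None:
            self.init_trainable = np.ones(self.n_genes, dtype=bool)
        if self.init_fixed is None:
            self.init_fixed = np.full(self.n_genes, 0.5)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != (self.n_regulators, self.n_genes):
            raise ValueError(
                f"mask shape {self.mask.shape} != "
                f"({self.n_regulators}, {self.n_genes})"
            )

    # ------------------------------------------------------------------ #
    # naming / indexing
    # ------------------------------------------------------------------ #
    @property
    def n_regulators(self) -> int:
        return self.n_genes + self.n_inputs

    @property
    def regulator_names(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genes)] + [
            f"I{i + 1}" for i in range(self.n_inputs)
        ]

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genes)]

    def regulator_index(self, node: int | str) -> int:
        if isinstance(node, (int, np.integer)):
            if not 0 <= node < self.n_regulators:
                raise KeyError(f"regulator index {node} out of range")
            return int(node)
        try:
            return self.regulator_names.index(node)
        except ValueError:
            raise KeyError(f"unknown regulator {node!r}") from None

    def gene_index(self, node: int | str) -> int:
        if isinstance(node, (int, np.integer)):
            if not 0 <= node < self.n_genes:
                raise KeyError(f"gene index {node} out of range")
            return int(node)
        try:
            return self.gene_names.index(node)
        except ValueError:
            raise KeyError(f"unknown gene {node!r}") from None

    @property
    def has_mask(self) -> bool:
        return bool((self.mask == 0.0).any())

    @property
    def forbidden_links(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask == 0.0)
        return {(int(r), int(c)) for r, c in zip(rows, cols)}

    # ------------------------------------------------------------------ #
    # evaluation
    # ------------------------------------------------------------------ #
    def __call__(self, g: np.ndarray, inputs: np.ndarray | None = None) -> np.ndarray:
        """Evaluate f(g, I).  Accepts 1-D vectors or batched 2-D arrays."""
        g = np.asarray(g, dtype=float)
        single = g.ndim == 1
        G = np.atleast_2d(g)
        if self.n_inputs:
            if inputs is None:
                raise ValueError("synthesis function requires an input vector")
            I = np.atleast_2d(np.asarray(inputs, dtype=float))
            if I.shape[0] == 1 and G.shape[0] > 1:
                I = np.broadcast_to(I, (G.shape[0], self.n_inputs))
            x = np.concatenate([G, I], axis=1)
        else:
            x = G
        f, _ = self.forward_cached(x)
        return f[0] if single else f

    def forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Forward pass on a batch of concatenated states x = [g, I].

        Returns (f, cache) with f of shape (batch, n_genes).
        """
        if x.shape[1] != self.n_regulators:
            raise ValueError(
                f"state width {x.shape[1]} != n_genes + n_inputs "
                f"({self.n_regulators})"
            )
        p = self.params
        if self.architecture == "shared" and not self.has_mask:
            z1 = x @ p["W1"].T + p["b1"]
            h1 = np.maximum(z1, 0.0)
            z2 = h1 @ p["W2"].T + p["b2"]
            h2 = np.maximum(z2, 0.0)
            z3 = h2 @ p["W3"].T + p["b3"]
            f = _sigmoid(z3)
            return f, {"mode": "plain", "x": x, "z1": z1, "h1": h1,
                       "z2": z2, "h2": h2, "f": f}
        # gated path: one (possibly weight-shared) pass per target gene,
        # batched over the gene axis, with the input vector masked per gene
        X = x[:, None, :] * self.mask.T[None, :, :]  # (B, G, d)
        if self.architecture == "shared":
            z1 = np.einsum("bgd,hd->bgh", X, p["W1"]) + p["b1"]
            h1 = np.maximum(z1, 0.0)
            z2 = np.einsum("bgh,kh->bgk", h1, p["W2"]) + p["b2"]
            h2 = np.maximum(z2, 0.0)
            z3 = np.einsum("bgk,gk->bg", h2, p["W3"]) + p["b3"]
        else:  # per_gene
            z1 = np.einsum("bgd,ghd->bgh", X, p["W1"]) + p["b1"]
            h1 = np.maximum(z1, 0.0)
            z2 = np.einsum("bgh,gkh->bgk", h1, p["W2"]) + p["b2"]
            h2 = np.maximum(z2, 0.0)
            z3 = np.einsum("bgk,gk->bg", h2, p["W3"]) + p["b3"]
        f = _sigmoid(z3)
        return f, {"mode": "gated", "x": x, "X": X, "z1": z1, "h1": h1,
                   "z2": z2, "h2": h2, "f": f}

    def backward(self, cache: dict, df: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Reverse-mode pass: upstream gradient on f -> (param grads, dx).

        dx is the gradient with respect to the concatenated state [g, I].
        """
        p = self.params
        f = cache["f"]
        dz3 = df * f * (1.0 - f)
        if cache["mode"] == "plain":
            h2, h1, x = cache["h2"], cache["h1"], cache["x"]
            grads = {
                "W3": dz3.T @ h2,
                "b3": dz3.sum(0),
            }
            dh2 = dz3 @ p["W3"]
            dz2 = dh2 * (cache["z2"] > 0)
            grads["W2"] = dz2.T @ h1
            grads["b2"] = dz2.sum(0)
            dh1 = dz2 @ p["W2"]
            dz1 = dh1 * (cache["z1"] > 0)
            grads["W1"] = dz1.T @ x
            grads["b1"] = dz1.sum(0)
            dx = dz1 @ p["W1"]
            return grads, dx
        X, h1, h2 = cache["X"], cache["h1"], cache["h2"]
        if self.architecture == "shared":
            grads = {
                "W3": np.einsum("bg,bgk->gk", dz3, h2),
                "b3": dz3.sum(0),
            }
            dh2 = dz3[:, :, None] * p["W3"][None, :, :]
            dz2 = dh2 * (cache["z2"] > 0)
            grads["W2"] = np.einsum("bgk,bgh->kh", dz2, h1)
            grads["b2"] = dz2.sum((0, 1))
            dh1 = np.einsum("bgk,kh->bgh", dz2, p["W2"])
            dz1 = dh1 * (cache["z1"] > 0)
            grads["W1"] = np.einsum("bgh,bgd->hd", dz1, X)
            grads["b1"] = dz1.sum((0, 1))
            dX = np.einsum("bgh,hd->bgd", dz1, p["W1"])
        else:
            grads = {
                "W3": np.einsum("bg,bgk->gk", dz3, h2),
                "b3": dz3.sum(0),
            }
            dh2 = dz3[:, :, None] * p["W3"][None, :, :]
            dz2 = dh2 * (cache["z2"] > 0)
            grads["W2"] = np.einsum("bgk,bgh->gkh", dz2, h1)
            grads["b2"] = dz2.sum(0)
            dh1 = np.einsum("bgk,gkh->bgh", dz2, p["W2"])
            dz1 = dh1 * (cache["z1"] > 0)
            grads["W1"] = np.einsum("bgh,bgd->ghd", dz1, X)
            grads["b1"] = dz1.sum(0)
            dX = np.einsum("bgh,ghd->bgd", dz1, p["W1"])
        dx = (dX * self.mask.T[None, :, :]).sum(axis=1)
        return grads, dx

    # ------------------------------------------------------------------ #
    # initial conditions
    # ------------------------------------------------------------------ #
    def initial_state(self) -> np.ndarray:
        """Resolve the pre-stimulus gene levels (trainable via sigmoid)."""
        g0 = self.init_fixed.astype(float).copy()
        if self.init_trainable.any():
            g0[self.init_trainable] = _sigmoid(
                self.params["init_logits"][self.init_trainable]
            )
        return g0

    def set_initial_policy(self, policy: Iterable[tuple[str, float]]) -> None:
        """Configure per-gene initial conditions.

        ``policy`` yields (kind, value) per gene; kind ``"fixed"`` pins the
        initial level at value, kind ``"trainable"`` makes it a trainable
        logit initialised so that sigmoid(logit) = value.
        """
        policy = list(policy)
        if len(policy) != self.n_genes:
            raise ValueError("one (kind, value) entry per gene required")
        trainable = np.zeros(self.n_genes, dtype=bool)
        fixed = np.zeros(self.n_genes)
        logits = self.params["init_logits"]
        for i, (kind, value) in enumerate(policy):
            if kind == "fixed":
                fixed[i] = float(value)
            elif kind == "trainable":
                trainable[i] = True
                v = min(max(float(value), 1e-6), 1.0 - 1e-6)
                logits[i] = np.log(v / (1.0 - v))
            else:
                raise ValueError(f"unknown initial-policy kind {kind!r}")
        self.init_trainable = trainable
        self.init_fixed = fixed

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    def copy(self) -> "MLPSynthesis":
        return MLPSynthesis(
            n_genes=self.n_genes,
            n_inputs=self.n_inputs,
            hidden_sizes=self.hidden_sizes,
            architecture=self.architecture,
            params={k: v.copy() for k, v in self.params.items()},
            mask=self.mask.copy(),
            init_trainable=self.init_trainable.copy(),
            init_fixed=self.init_fixed.copy(),
        )


def build_synthesis(
    n_genes: int,
    n_inputs: int,
    hidden_sizes: tuple[int, int] = (16, 16),
    architecture: str = "per_gene",
    seed: int | None = 0,
) -> MLPSynthesis:
    """Construct a synthesis MLP with near-zero Gaussian weights (sigma=0.1).

    ``shared`` builds one network with input width ``n_genes + n_inputs`` and
    output width ``n_genes``; ``per_gene`` builds ``n_genes`` independent
    single-output networks (stored stacked).  Small-scale initialization
    keeps early dynamics gentle and avoids exploding gradients through the
    unrolled integrator.
    """
    if n_genes < 1 or n_inputs < 0:
        raise ValueError("n_genes must be >= 1 and n_inputs >= 0")
    h1, h2 = hidden_sizes
    if h1 < 1 or h2 < 1:
        raise ValueError("hidden sizes must be >= 1")
    if architecture not in ("shared", "per_gene"):
        raise ValueError(f"unknown architecture {architecture!r}")
    rng = np.random.default_rng(seed)
    d = n_genes + n_inputs
    sigma = 0.1
    if architecture == "shared":
        params = {
            "W1": rng.normal(0.0, sigma, (h1, d)),
            "b1": np.zeros(h1),
            "W2": rng.normal(0.0, sigma, (h2, h1)),
            "b2": np.zeros(h2),
            "W3": rng.normal(0.0, sigma, (n_genes, h2)),
            "b3": np.zeros(n_genes),
        }
    else:
        params = {
            "W1": rng.normal(0.0, sigma, (n_genes, h1, d)),
            "b1": np.zeros((n_genes, h1)),
            "W2": rng.normal(0.0, sigma, (n_genes, h2, h1)),
            "b2": np.zeros((n_genes, h2)),
            "W3": rng.normal(0.0, sigma, (n_genes, h2)),
            "b3": np.zeros(n_genes),
        }
    params["init_logits"] = np.zeros(n_genes)
    return MLPSynthesis(
        n_genes=n_genes,
        n_inputs=n_inputs,
        hidden_sizes=(h1, h2),
        architecture=architecture,
        params=params,
        mask=np.ones((d, n_genes)),
    )


def apply_structural_mask(
    synth: MLPSynthesis,
    forbidden_links: Iterable[tuple[int | str, int | str]],
) -> MLPSynthesis:
    """Return a copy of ``synth`` with the given (regulator, target) links cut.

    The masked regulator's value is replaced by 0 whenever the target's
    synthesis component is evaluated (a permanent lambda = 0 perturbation);
    the mask persists through training and is additive with any mask already
    present.
    """
    out = synth.copy()
    for reg, tgt in forbidden_links:
        i = out.regulator_index(reg)
        j = out.gene_index(tgt)
        out.mask[i, j] = 0.0
    return out


# ---------------------------------------------------------------------- #
# checkpoints
# ---------------------------------------------------------------------- #
def save_checkpoint(synth: MLPSynthesis, path: str | Path) -> None:
    """Save weights to ``<path>.npz`` with architecture metadata in
    ``<path>.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **synth.params,
             __mask__=synth.mask,
             __init_trainable__=synth.init_trainable.astype(int),
             __init_fixed__=synth.init_fixed)
    meta = {
        "n_genes": synth.n_genes,
        "n_inputs": synth.n_inputs,
        "hidden_sizes": list(synth.hidden_sizes),
        "architecture": synth.architecture,
        "forbidden_links": sorted(synth.forbidden_links),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> MLPSynthesis:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        arrays: Mapping[str, np.ndarray] = {k: data[k] for k in data.files}
    mask = arrays.pop("__mask__")
    init_trainable = arrays.pop("__init_trainable__").astype(bool)
    init_fixed = arrays.pop("__init_fixed__")
    return MLPSynthesis(
        n_genes=int(meta["n_genes"]),
        n_inputs=int(meta["n_inputs"]),
        hidden_sizes=tuple(meta["hidden_sizes"]),
        architecture=meta["architecture"],
        params=dict(arrays),
        mask=mask,
        init_trainable=init_trainable,
        init_fixed=init_fixed,
    )
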