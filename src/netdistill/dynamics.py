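"""Discrete-time integration of gene dynamics dg/dt = f(g, I) - gamma*g.

The integrator is a plain forward-Euler scheme with a relatively large step
(dt = 0.2 by default, decay rate gamma = 1), so typical simulations complete
within a few tens of iterations:

    g(i+1) = (1 - gamma*dt) * g(i) + f(g(i), I(i)) * dt

Because the synthesis rate f is bounded in [0, 1] and degradation is linear,
states started in [0, 1] never leave it (for gamma*dt <= 1 and zero noise).
Optional run-time Langevin noise adds a zero-mean Gaussian perturbation to the
state after each update, clipped at zero to keep levels non-negative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "euler_step", "simulate"]

DEFAULT_GAMMA = 1.0
DEFAULT_DT = 0.2


@dataclass
class Trajectory:
    """A simulated time course: gene levels plus the input course that drove it.

    ``values`` has shape (n_steps + 1, n_genes); row 0 is the initial
    condition.  ``inputs`` has the same number of rows.
    """

    dt: float
    values: np.ndarray
    inputs: np.ndarray
    gamma: float = DEFAULT_GAMMA
    seed: int | None = None
    noise_sd: float = 0.0

    @property
    def n_steps(self) -> int:
        return self.values.shape[0] - 1

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.dt

    def to_frame(self) -> pd.DataFrame:
        cols = {f"g_{i + 1}": self.values[:, i] for i in range(self.n_genes)}
        cols.update({f"I_{i + 1}": self.inputs[:, i] for i in range(self.n_inputs)})
        df = pd.DataFrame(cols)
        df.insert(0, "time", self.times)
        df.insert(0, "step", np.arange(self.values.shape[0]))
        return df

    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase, dt: float | None = None,
                 gamma: float = DEFAULT_GAMMA) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        g_cols = [c for c in df.columns if c.startswith("g_")]
        i_cols = [c for c in df.columns if c.startswith("I_")]
        if dt is None:
            dt = float(df["time"].iloc[1] - df["time"].iloc[0]) if len(df) > 1 else DEFAULT_DT
        return cls(
            dt=dt,
            values=df[g_cols].to_numpy(float),
            inputs=df[i_cols].to_numpy(float) if i_cols else np.zeros((len(df), 0)),
            gamma=gamma,
        )

    def to_npz(self, path: str | Path) -> None:
        np.savez(path, values=self.values, inputs=self.inputs,
                 dt=self.dt, gamma=self.gamma, noise_sd=self.noise_sd)

    @classmethod
    def from_npz(cls, path: str | Path) -> "Trajectory":
        with np.load(path) as data:
            return cls(
                dt=float(data["dt"]),
                values=data["values"],
                inputs=data["inputs"],
                gamma=float(data["gamma"]),
                noise_sd=float(data["noise_sd"]),
            )


def euler_step(
    g: np.ndarray,
    f_value: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """One forward-Euler update: (1 - gamma*dt) * g + f_value * dt."""
    g = np.asarray(g, dtype=float)
    f_value = np.asarray(f_value, dtype=float)
    if g.shape != f_value.shape:
        raise ValueError(f"shape mismatch: g {g.shape} vs f {f_value.shape}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return (1.0 - gamma * dt) * g + f_value * dt


def _expand_inputs(input_course: np.ndarray | None, n_steps: int,
                   n_inputs: int) -> np.ndarray:
    """Broadcast a constant input vector to a full (n_steps+1, m) course."""
    if n_inputs == 0:
        return np.zeros((n_steps + 1, 0))
    inputs = np.asarray(input_course, dtype=float)
    if inputs.ndim == 1:
        inputs = np.broadcast_to(inputs, (n_steps + 1, inputs.shape[0])).copy()
    if inputs.shape != (n_steps + 1, n_inputs):
        raise ValueError(
            f"input course shape {inputs.shape} != ({n_steps + 1}, {n_inputs})"
        )
    return inputs


def simulate(
    synth,
    g0: np.ndarray,
    input_course: np.ndarray | None = None,
    n_steps: int = 40,
    gamma: float = DEFAULT_GAMMA,
    dt: float = DEFAULT_DT,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trajectory:
    """Integrate the gene dynamics under a pluggable synthesis function.

    ``synth`` is any callable (g, I) -> f with f of the same length as g
    (an :class:`~netdistill.nn_synthesis.MLPSynthesis`, a Hill-function
    model, or a plain function).  Inputs are held piecewise-constant across a
    step (forward-Euler convention): step i uses the input row i.

    With ``noise_sd > 0`` a zero-mean Gaussian perturbation is added to the
    state after each update and the state is clipped at zero (Langevin-style
    run-time noise).  Identical seed and inputs give identical output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    g0 = np.asarray(g0, dtype=float)
    n_genes = g0.shape[0]
    n_inputs = getattr(synth, "n_inputs", None)
    if n_inputs is None:
        n_inputs = 0 if input_course is None else np.atleast_2d(np.asarray(input_course)).shape[-1]
    inputs = _expand_inputs(input_course, n_steps, n_inputs)
    values = np.empty((n_steps + 1, n_genes))
    values[0] = g0
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    g = g0.copy()
    for i in range(n_steps):
        f = np.asarray(synth(g, inputs[i]) if n_inputs else synth(g, None), dtype=float)
        g = euler_step(g, f, gamma=gamma, dt=dt)
        if rng is not None:
            g = np.maximum(g + rng.normal(0.0, noise_sd, n_genes), 0.0)
        values[i + 1] = g
    return Trajectory(dt=dt, values=values, inputs=inputs, gamma=gamma,
                      seed=seed, noise_sd=noise_sd)
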