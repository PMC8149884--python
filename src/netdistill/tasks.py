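"""Task definitions: target curves, input conditions, loss, phenotype metrics.

A :class:`TaskSpec` fixes everything needed to pose a training problem for the
recurrent gene-dynamics model: the input time courses (one per condition), a
sparse set of target constraints (condition, time index, gene, value), the
per-gene initial-state policy, and the horizon.  The training loss is the
Euclidean distance between model trajectories and the target values, pooled
over all constraints of all conditions.

Built-in generators cover the benchmark functions studied with this method:

* **adaptation** — the output gene must respond to a step input with a pulse
  (sum of two exponentials) and return to its pre-stimulus level even though
  the stimulus persists;
* **controlled oscillation** — the output must stay at a low basal level with
  no stimulus, oscillate (triangular target waveform) under input 1, and hold
  a sustained high level under input 2;
* **gap-gene patterning** — four trunk gap genes (hb, Kr, kni, gt) driven by
  two static maternal morphogen gradients (Bcd, Tor) must reach a band-like
  target expression profile at the final time point, independently at each
  position along the anterior-posterior axis (no spatial coupling).

Real FlyEX data is out of scope; :func:`synth_gap_gene_profiles` generates a
synthetic stand-in with the same qualitative structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import find_peaks

from netdistill.dynamics import DEFAULT_DT, Trajectory

__all__ = [
    "TaskSpec",
    "PhenotypeMetrics",
    "make_adaptation_task",
    "make_controlled_oscillation_task",
    "synth_gap_gene_profiles",
    "make_gap_gene_task",
    "merge_gap_gene_tasks",
    "loss",
    "phenotype_metrics",
]


@dataclass
class TaskSpec:
    """A training problem for the recurrent gene-dynamics model.

    ``targets`` is an (n_constraints, 4) float array with columns
    (condition index, time index, gene index, target value); index columns
    are integral-valued.  ``initial_policy`` lists one ("fixed"|"trainable",
    value) pair per gene.
    """

    n_genes: int
    n_inputs: int
    conditions: list[np.ndarray]  # each (N_T + 1, n_inputs)
    targets: np.ndarray
    initial_policy: list[tuple[str, float]]
    N_T: int
    dt: float = DEFAULT_DT
    kind: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float).reshape(-1, 4)
        if self.targets.shape[0] < 1:
            raise ValueError("at least one target constraint is required")
        c, t, g, v = self.targets.T
        if (v < 0).any() or (v > 1).any():
            raise ValueError("target values must lie in [0, 1]")
        if (c < 0).any() or (c >= len(self.conditions)).any():
            raise ValueError("target condition index out of bounds")
        if (t < 0).any() or (t > self.N_T).any():
            raise ValueError("target time index out of bounds")
        if (g < 0).any() or (g >= self.n_genes).any():
            raise ValueError("target gene index out of bounds")
        for i, cond in enumerate(self.conditions):
            cond = np.asarray(cond, dtype=float)
            if cond.shape != (self.N_T + 1, self.n_inputs):
                raise ValueError(
                    f"condition {i} shape {cond.shape} != "
                    f"({self.N_T + 1}, {self.n_inputs})"
                )
            self.conditions[i] = cond
        if len(self.initial_policy) != self.n_genes:
            raise ValueError("one initial-policy entry per gene required")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_inputs": self.n_inputs,
            "N_T": self.N_T,
            "dt": self.dt,
            "kind": self.kind,
            "meta": dict(self.meta),
            "conditions": [c.tolist() for c in self.conditions],
            "targets": [
                {"condition": int(c), "time": int(t), "gene": int(g),
                 "value": float(v)}
                for c, t, g, v in self.targets
            ],
            "initial_policy": [
                {"kind": k, "value": float(v)} for k, v in self.initial_policy
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        return cls(
            n_genes=int(d["n_genes"]),
            n_inputs=int(d["n_inputs"]),
            conditions=[np.asarray(c, dtype=float) for c in d["conditions"]],
            targets=np.array(
                [[t["condition"], t["time"], t["gene"], t["value"]]
                 for t in d["targets"]], dtype=float,
            ),
            initial_policy=[(p["kind"], float(p["value"]))
                            for p in d["initial_policy"]],
            N_T=int(d["N_T"]),
            dt=float(d.get("dt", DEFAULT_DT)),
            kind=d.get("kind", "custom"),
            meta=dict(d.get("meta", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PhenotypeMetrics:
    """Scalar summaries of a response trajectory.

    ``sensitivity`` is the peak deviation of the output from its pre-stimulus
    level after stimulus onset; ``adaptation_error`` the absolute deviation of
    the final level from the pre-stimulus level.  Oscillation metrics are
    derived from peak detection on the post-transient window and are zero for
    non-oscillatory traces.
    """

    sensitivity: float
    adaptation_error: float
    oscillation_amplitude: float = 0.0
    oscillation_period: float = 0.0
    steady_level: float = 0.0


# ---------------------------------------------------------------------- #
# adaptation
# ---------------------------------------------------------------------- #
def adaptation_target_curve(
    times: np.ndarray,
    t0: float,
    pre_level: float,
    amplitude: float,
    tau_fast: float,
    tau_slow: float,
) -> np.ndarray:
    """Pulse-shaped target: pre-stimulus level plus a difference of two
    exponentials after onset, scaled so the peak deviation equals
    ``amplitude``."""
    s = np.maximum(times - t0, 0.0)
    raw = np.exp(-s / tau_slow) - np.exp(-s / tau_fast)
    # analytic peak of exp(-s/ts) - exp(-s/tf) at s* = ln(ts/tf)/(1/tf - 1/ts)
    s_star = np.log(tau_slow / tau_fast) / (1.0 / tau_fast - 1.0 / tau_slow)
    peak = np.exp(-s_star / tau_slow) - np.exp(-s_star / tau_fast)
    curve = pre_level + amplitude * raw / peak
    curve[times < t0] = pre_level
    return curve


def make_adaptation_task(
    pre_level: float = 0.4,
    input_levels: tuple[float, ...] = (0.0, 0.4, 0.6, 0.8),
    pulse_amplitude: float = 0.35,
    tau_fast: float = 0.6,
    tau_slow: float = 1.8,
    N_T: int = 40,
    dt: float = DEFAULT_DT,
    onset_steps: tuple[int, ...] | int = (5, 8, 12, 5),
) -> TaskSpec:
    """Adaptation task: a step input must elicit a pulse that returns to the
    pre-stimulus level.

    The target time course of the output gene g1 is ``pre_level`` before the
    step and pre_level + A*(exp(-(t-t0)/tau_slow) - exp(-(t-t0)/tau_fast))
    after, with A scaled so the peak deviation is ``pulse_amplitude``.  One
    condition is generated per entry of ``input_levels``; training against
    several step heights jointly excludes solutions that respond
    non-monotonically to the input strength, and a zero level (included by
    default) demands a flat response with no stimulus.  Onset times differ
    across conditions (``onset_steps``, one per level): together with the
    zero-level condition this excludes degenerate solutions that produce the
    pulse as an autonomous timer started at t = 0 (via the trainable helper
    initial value) rather than as a causally input-triggered response.  The
    helper gene g2 is unconstrained with a trainable initial value; g1
    starts pinned at ``pre_level``.
    """
    if not 0 < tau_fast < tau_slow:
        raise ValueError("need 0 < tau_fast < tau_slow")
    if pre_level + pulse_amplitude > 1.0 or pre_level < 0:
        raise ValueError("target curve must stay inside [0, 1]")
    if isinstance(onset_steps, (int, np.integer)):
        onset_steps = (int(onset_steps),) * len(input_levels)
    if len(onset_steps) != len(input_levels):
        raise ValueError("one onset step per input level required")
    times = np.arange(N_T + 1) * dt
    conditions = []
    targets = []
    for ci, (level, onset) in enumerate(zip(input_levels, onset_steps)):
        course = np.zeros((N_T + 1, 1))
        course[onset:, 0] = level
        conditions.append(course)
        if level > 0:
            cond_curve = adaptation_target_curve(
                times, onset * dt, pre_level, pulse_amplitude,
                tau_fast, tau_slow)
        else:
            cond_curve = np.full(N_T + 1, pre_level)
        for ti in range(N_T + 1):
            targets.append([ci, ti, 0, cond_curve[ti]])
    metrics_condition = int(np.argmax(input_levels))
    return TaskSpec(
        n_genes=2,
        n_inputs=1,
        conditions=conditions,
        targets=np.array(targets),
        initial_policy=[("fixed", pre_level), ("trainable", 0.5)],
        N_T=N_T,
        dt=dt,
        kind="adaptation",
        meta={"pre_level": pre_level,
              "onset_step": int(onset_steps[metrics_condition]),
              "pulse_amplitude": pulse_amplitude,
              "tau_fast": tau_fast, "tau_slow": tau_slow,
              "metrics_condition": metrics_condition},
    )


# ---------------------------------------------------------------------- #
# controlled oscillation
# ---------------------------------------------------------------------- #
def triangular_wave(steps: np.ndarray, period: int, low: float,
                    high: float) -> np.ndarray:
    """Triangular waveform starting at ``low``, rising first."""
    phase = (steps % period) / period
    up = phase < 0.5
    w = np.where(up, 2.0 * phase, 2.0 - 2.0 * phase)
    return low + (high - low) * w


def make_controlled_oscillation_task(
    low_level: float = 0.1,
    high_level: float = 0.9,
    osc_min: float = 0.2,
    osc_max: float = 0.8,
    period: int = 20,
    N_T: int = 60,
    dt: float = DEFAULT_DT,
    n_genes: int = 2,
    input_strength: float = 0.8,
    transient_steps: int = 10,
    fixed_helper_init: float | None = None,
) -> TaskSpec:
    """Controlled oscillation: oscillate under input 1, hold high under input 2.

    Three conditions are posed, all constraining only the output gene g1:
    no input (constant low basal target), I1 = 0.8 (triangular-wave target
    between ``osc_min`` and ``osc_max`` after a short transient), and
    I2 = 0.8 (sustained ``high_level`` target after the transient).  g1
    starts pinned at ``low_level``; other genes have trainable initial
    values, unless ``fixed_helper_init`` pins them (an optional curriculum
    variant that biases the search toward a different solution branch).
    """
    if not 0 <= low_level < high_level <= 1:
        raise ValueError("need 0 <= low_level < high_level <= 1")
    if period < 2:
        raise ValueError("oscillation period must span at least 2 steps")
    steps = np.arange(N_T + 1)
    conditions = []
    targets = []
    # condition 0: no stimulus, rest at the basal level
    conditions.append(np.zeros((N_T + 1, 2)))
    for ti in steps:
        targets.append([0, ti, 0, low_level])
    # condition 1: I1 on, triangular oscillation target
    course = np.zeros((N_T + 1, 2))
    course[:, 0] = input_strength
    conditions.append(course)
    wave = triangular_wave(steps[transient_steps:] - transient_steps,
                           period, osc_min, osc_max)
    for ti, v in zip(steps[transient_steps:], wave):
        targets.append([1, ti, 0, v])
    # condition 2: I2 on, sustained high expression
    course = np.zeros((N_T + 1, 2))
    course[:, 1] = input_strength
    conditions.append(course)
    for ti in steps[transient_steps:]:
        targets.append([2, ti, 0, high_level])
    policy: list[tuple[str, float]] = [("fixed", low_level)]
    for _ in range(n_genes - 1):
        if fixed_helper_init is None:
            policy.append(("trainable", 0.5))
        else:
            policy.append(("fixed", fixed_helper_init))
    return TaskSpec(
        n_genes=n_genes,
        n_inputs=2,
        conditions=conditions,
        targets=np.array(targets),
        initial_policy=policy,
        N_T=N_T,
        dt=dt,
        kind="oscillation",
        meta={"low_level": low_level, "high_level": high_level,
              "osc_min": osc_min, "osc_max": osc_max, "period": period,
              "transient_steps": transient_steps, "metrics_condition": 1},
    )


# ---------------------------------------------------------------------- #
# gap-gene patterning (synthetic profiles)
# ---------------------------------------------------------------------- #
def synth_gap_gene_profiles(
    n_positions: int = 50,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic stand-in for experimentally measured trunk patterning profiles.

    Returns ``(morphogens, targets)``: ``morphogens`` is (n_positions, 2)
    with a strictly decreasing exponential-like Bcd gradient and a terminal
    (both-ends-high) Tor profile; ``targets`` is (n_positions, 4) with four
    band-like gap-gene profiles (hb, Kr, kni, gt) whose peaks are pairwise
    distinct and ordered along the anterior-posterior axis.  All values lie
    in [0, 1]; the small seeded jitter on band positions and widths makes the
    profiles reproducible but not perfectly stereotyped.
    """
    if n_positions < 10:
        raise ValueError("need at least 10 spatial positions")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_positions)
    bcd = np.exp(-x / 0.25)
    tor = np.exp(-x / 0.05) + np.exp(-(1.0 - x) / 0.05)
    tor = np.clip(tor, 0.0, 1.0)
    centers = np.array([0.22, 0.45, 0.63, 0.82])
    widths = np.array([0.13, 0.09, 0.08, 0.08])
    centers = centers + rng.normal(0.0, 0.01, 4)
    widths = widths * rng.uniform(0.9, 1.1, 4)
    heights = rng.uniform(0.8, 0.95, 4)
    targets = np.empty((n_positions, 4))
    for k in range(4):
        targets[:, k] = heights[k] * np.exp(-((x - centers[k]) ** 2)
                                            / (2.0 * widths[k] ** 2))
    # anterior hb shoulder: hb stays high toward the anterior pole
    targets[:, 0] = np.maximum(targets[:, 0],
                               heights[0] * (x < centers[0]))
    targets = np.clip(targets, 0.0, 1.0)
    morphogens = np.column_stack([bcd, tor])
    return morphogens, targets


def merge_gap_gene_tasks(tasks: list["TaskSpec"]) -> "TaskSpec":
    """Pool per-position gap-gene tasks into one multi-condition task.

    One shared synthesis network is trained against every spatial position at
    once: each position becomes a condition (its static morphogen inputs)
    whose four final-time targets constrain the same network.
    """
    if not tasks:
        raise ValueError("no tasks to merge")
    first = tasks[0]
    conditions = []
    targets = []
    for ci, t in enumerate(tasks):
        conditions.append(t.conditions[0])
        for _, ti, gi, v in t.targets:
            targets.append([ci, ti, gi, v])
    return TaskSpec(
        n_genes=first.n_genes,
        n_inputs=first.n_inputs,
        conditions=conditions,
        targets=np.array(targets, dtype=float),
        initial_policy=list(first.initial_policy),
        N_T=first.N_T,
        dt=first.dt,
        kind="gap_gene",
        meta={"n_positions": len(tasks)},
    )


def make_gap_gene_task(
    profiles: tuple[np.ndarray, np.ndarray],
    N_T: int = 30,
    dt: float = DEFAULT_DT,
) -> list[TaskSpec]:
    """One task per spatial position: static morphogen inputs, zero initial
    state for all four gap genes, target constraints only at the final time
    point.  Positions are independent (the model is not spatially coupled)."""
    morphogens, targets = profiles
    morphogens = np.asarray(morphogens, dtype=float)
    targets = np.asarray(targets, dtype=float)
    tasks = []
    for pos in range(morphogens.shape[0]):
        course = np.broadcast_to(morphogens[pos], (N_T + 1, 2)).copy()
        t = [[0, N_T, gi, targets[pos, gi]] for gi in range(4)]
        tasks.append(TaskSpec(
            n_genes=4,
            n_inputs=2,
            conditions=[course],
            targets=np.array(t, dtype=float),
            initial_policy=[("fixed", 0.0)] * 4,
            N_T=N_T,
            dt=dt,
            kind="gap_gene",
            meta={"position": pos},
        ))
    return tasks


# ---------------------------------------------------------------------- #
# loss and phenotype metrics
# ---------------------------------------------------------------------- #
def loss(trajectories: list[Trajectory] | list[np.ndarray], task: TaskSpec) -> float:
    """Euclidean training loss: sqrt of the summed squared deviations over all
    target constraints, pooled across conditions."""
    if len(trajectories) != task.n_conditions:
        raise ValueError(
            f"need {task.n_conditions} trajectories, got {len(trajectories)}"
        )
    values = [t.values if isinstance(t, Trajectory) else np.asarray(t, dtype=float)
              for t in trajectories]
    for v in values:
        if v.shape[0] != task.N_T + 1:
            raise ValueError("trajectory horizon does not match task N_T")
    sq = 0.0
    for c, t, g, v in task.targets:
        resid = values[int(c)][int(t), int(g)] - v
        sq += resid * resid
    return float(np.sqrt(sq))


def phenotype_metrics(traj: Trajectory, task: TaskSpec,
                      output_gene: int = 0) -> PhenotypeMetrics:
    """Summarize an output trajectory against the task's pre-stimulus level.

    For adaptation-style tasks the pre-stimulus level and stimulus onset come
    from the task metadata; otherwise the initial output value serves as the
    reference and onset defaults to step 0.  Oscillation amplitude/period are
    computed from peak detection on the second half of the trace.
    """
    g = traj.values[:, output_gene]
    pre = float(task.meta.get("pre_level", task.meta.get("low_level", g[0])))
    onset = int(task.meta.get("onset_step", 0))
    post = g[onset:] if onset < len(g) else g[-1:]
    if len(post) == 0:
        raise ValueError("no post-stimulus samples")
    sensitivity = float(np.max(np.abs(post - pre)))
    adaptation_error = float(abs(g[-1] - pre))
    half = g[len(g) // 2:]
    peaks, _ = find_peaks(half)
    amp = float((half.max() - half.min()) / 2.0) if len(peaks) >= 2 else 0.0
    period = float(np.mean(np.diff(peaks)) * traj.dt) if len(peaks) >= 2 else 0.0
    return PhenotypeMetrics(
        sensitivity=sensitivity,
        adaptation_error=adaptation_error,
        oscillation_amplitude=amp,
        oscillation_period=period,
        steady_level=float(g[-1]),
    )
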