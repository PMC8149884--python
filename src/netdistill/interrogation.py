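"""Distill a trained synthesis function into a signed regulation network.

The central primitive is the in-silico link mutation: to probe the regulatory
effect of regulator i on gene j, evaluate the synthesis function twice — once
unperturbed and once with regulator i's value scaled by a discount factor
lambda — and keep the perturbed value only for component j.  lambda = 0 is a
link knockout (deleting the regulator's binding sites for that one target);
lambda close to 1 yields a knockdown derivative

    Delta_ij = f_j(..., g_i) - f_j(..., lambda * g_i)

which, averaged along a wild-type trajectory, quantifies the effective
regulation from g_i to g_j: positive means activation, negative inhibition.
This measure is preferred over the bare partial derivative because it weights
the sensitivity by the regulator's actual expression level (fold-change
semantics, like a biological knockdown).

Iterating the perturbed synthesis function simulates link-mutant dynamics;
deleting, one at a time, the link whose knockout least perturbs the phenotype
and retraining yields a sequence of ever-sparser networks ending in a minimal
functional motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from netdistill.dynamics import Trajectory, simulate
from netdistill.nn_synthesis import MLPSynthesis, apply_structural_mask, build_synthesis
from netdistill.tasks import PhenotypeMetrics, TaskSpec, loss as task_loss_fn, phenotype_metrics
from netdistill.training import (
    TrainConfig,
    TrainResult,
    resolve_initial_state,
    simulate_task,
    train,
)

__all__ = [
    "Topology",
    "LinkScores",
    "PerturbedSynthesis",
    "perturbed_f",
    "delta_matrix",
    "mutant_trajectory",
    "gene_knockout_trajectory",
    "extract_topology",
    "optimal_cutoff",
    "SparsifyConfig",
    "SparsifyStep",
    "sparsify",
    "topology_distance",
    "topology_neighbor_graph",
    "contains_incoherent_feedforward",
    "contains_negative_feedback",
    "distill_topology",
]


def _node_names(n_genes: int, n_inputs: int) -> list[str]:
    return [f"g{i + 1}" for i in range(n_genes)] + [
        f"I{i + 1}" for i in range(n_inputs)]


@dataclass(frozen=True)
class Topology:
    """Signed regulation network over (genes + inputs) regulators x genes.

    ``sign`` rows are regulators (genes first, then inputs), columns are
    target genes; entries are -1 (inhibition), 0 (absent) or +1 (activation).
    Inputs appear only as regulators, never as targets.
    """

    n_genes: int
    n_inputs: int
    sign: np.ndarray

    def __post_init__(self) -> None:
        sign = np.asarray(self.sign, dtype=np.int8)
        if sign.shape != (self.n_genes + self.n_inputs, self.n_genes):
            raise ValueError(
                f"sign shape {sign.shape} != "
                f"({self.n_genes + self.n_inputs}, {self.n_genes})")
        if not np.isin(sign, (-1, 0, 1)).all():
            raise ValueError("sign entries must be in {-1, 0, +1}")
        object.__setattr__(self, "sign", sign)

    @property
    def n_regulators(self) -> int:
        return self.n_genes + self.n_inputs

    @property
    def node_names(self) -> list[str]:
        return _node_names(self.n_genes, self.n_inputs)

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.sign))

    def links(self) -> list[tuple[int, int, int]]:
        """Nonzero links as (regulator index, target gene index, sign)."""
        rows, cols = np.nonzero(self.sign)
        return [(int(r), int(c), int(self.sign[r, c]))
                for r, c in zip(rows, cols)]

    def key(self) -> bytes:
        return self.sign.tobytes()

    def __eq__(self, other) -> bool:
        return (isinstance(other, Topology)
                and self.n_genes == other.n_genes
                and self.n_inputs == other.n_inputs
                and np.array_equal(self.sign, other.sign))

    def __hash__(self) -> int:
        return hash((self.n_genes, self.n_inputs, self.key()))

    @classmethod
    def from_links(
        cls,
        n_genes: int,
        n_inputs: int,
        links: Iterable[tuple[int | str, int | str, int]],
    ) -> "Topology":
        """Build from (regulator, target, sign) triples; nodes may be named
        ("g1", "I2", ...) or indexed."""
        names = _node_names(n_genes, n_inputs)
        sign = np.zeros((n_genes + n_inputs, n_genes), dtype=np.int8)
        for reg, tgt, s in links:
            i = names.index(reg) if isinstance(reg, str) else int(reg)
            j = (names.index(tgt) if isinstance(tgt, str) else int(tgt))
            sign[i, j] = int(s)
        return cls(n_genes=n_genes, n_inputs=n_inputs, sign=sign)


@dataclass
class LinkScores:
    """Real-valued link-mutation scores Delta_ij with provenance metadata."""

    values: np.ndarray  # (n_regulators, n_genes)
    lam: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("link scores must be finite")

    def normalized(self, mode: str = "per_target") -> np.ndarray:
        """Scores on a comparable scale (zeros where all scores vanish).

        ``per_target`` (default) divides each target gene's column by its own
        maximum absolute score: a gene's regulators are compared among
        themselves, so regulation of a weakly-synthesized gene is not hidden
        behind another gene's dominant link.  ``per_model`` divides by the
        global maximum instead.
        """
        if mode == "per_model":
            m = np.max(np.abs(self.values))
            return self.values / m if m > 0 else np.zeros_like(self.values)
        if mode != "per_target":
            raise ValueError(f"unknown normalization mode {mode!r}")
        m = np.max(np.abs(self.values), axis=0, keepdims=True)
        safe = np.where(m > 0, m, 1.0)
        return self.values / safe


# ---------------------------------------------------------------------- #
# link mutation primitives
# ---------------------------------------------------------------------- #
class PerturbedSynthesis:
    """Synthesis function with one regulatory link knocked down.

    Wraps any synthesis callable; regulator i's value is scaled by ``lam``
    when and only when computing target j's synthesis component.
    """

    def __init__(self, synth, link: tuple[int | str, int | str], lam: float):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.base = synth
        self.n_genes = synth.n_genes
        self.n_inputs = synth.n_inputs
        names = _node_names(self.n_genes, self.n_inputs)
        reg, tgt = link
        try:
            self.reg = names.index(reg) if isinstance(reg, str) else int(reg)
            self.tgt = names.index(tgt) if isinstance(tgt, str) else int(tgt)
        except ValueError:
            raise KeyError(f"unknown node in link {link!r}") from None
        if not 0 <= self.reg < self.n_genes + self.n_inputs:
            raise KeyError(f"unknown regulator {link[0]!r}")
        if not 0 <= self.tgt < self.n_genes:
            raise KeyError(f"unknown target {link[1]!r}")
        self.lam = float(lam)

    def __call__(self, g, inputs=None):
        g = np.asarray(g, dtype=float)
        f = np.asarray(self.base(g, inputs), dtype=float)
        if self.lam == 1.0:
            return f
        gp = g.copy()
        ip = None if inputs is None else np.asarray(inputs, dtype=float).copy()
        if self.reg < self.n_genes:
            gp[..., self.reg] *= self.lam
        else:
            ip[..., self.reg - self.n_genes] *= self.lam
        fp = np.asarray(self.base(gp, ip), dtype=float)
        out = f.copy()
        out[..., self.tgt] = fp[..., self.tgt]
        return out


def perturbed_f(synth, link: tuple[int | str, int | str], lam: float,
                state: tuple[np.ndarray, np.ndarray | None]) -> np.ndarray:
    """Evaluate the link-perturbed synthesis vector at one state (g, I)."""
    g, inputs = state
    return PerturbedSynthesis(synth, link, lam)(g, inputs)


def delta_matrix(
    synth,
    trajectory: Trajectory | tuple[np.ndarray, np.ndarray],
    lam: float = 0.95,
) -> LinkScores:
    """Knockdown scores Delta_ij averaged along a wild-type trajectory.

    Entry (i, j) is the mean over trajectory states of
    f_j(..., g_i) - f_j(..., lam * g_i).  Positive entries indicate
    activation, negative inhibition.  ``trajectory`` may also be a raw
    (states, inputs) pair of arrays to score over pooled states.
    """
    if isinstance(trajectory, Trajectory):
        G, I = trajectory.values, trajectory.inputs
    else:
        G, I = trajectory
        G = np.asarray(G, dtype=float)
        I = np.asarray(I, dtype=float)
    if G.shape[0] == 0:
        raise ValueError("empty trajectory")
    n_genes, n_inputs = synth.n_genes, synth.n_inputs
    F = np.asarray(synth(G, I if n_inputs else None), dtype=float)
    values = np.zeros((n_genes + n_inputs, n_genes))
    if lam != 1.0:
        for i in range(n_genes + n_inputs):
            if i < n_genes:
                Gp, Ip = G.copy(), I
                Gp[:, i] *= lam
            else:
                Gp, Ip = G, I.copy()
                Ip[:, i - n_genes] *= lam
            Fp = np.asarray(synth(Gp, Ip if n_inputs else None), dtype=float)
            values[i] = (F - Fp).mean(axis=0)
    return LinkScores(values=values, lam=lam,
                      provenance={"n_states": int(G.shape[0])})


def _pooled_states(synth, task: TaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Wild-type states pooled over all conditions of a task."""
    trajs = simulate_task(synth, task)
    G = np.concatenate([t.values for t in trajs])
    I = np.concatenate([t.inputs for t in trajs])
    return G, I


def distill_topology(
    synth,
    task: TaskSpec,
    lam: float = 0.95,
    cutoff: float = 0.1,
) -> tuple[Topology, LinkScores]:
    """Score every link along the pooled wild-type trajectories and extract
    the signed topology at the given normalized cutoff."""
    scores = delta_matrix(synth, _pooled_states(synth, task), lam=lam)
    return extract_topology(scores, cutoff), scores


def mutant_trajectory(
    synth,
    link: tuple[int | str, int | str],
    lam: float,
    condition: int | np.ndarray,
    task: TaskSpec,
    **sim_kwargs,
) -> Trajectory:
    """Simulate the dynamics of the link-knockdown mutant (lam = 0: knockout).

    ``condition`` is either an index into the task's conditions or an
    explicit input course.
    """
    course = (task.conditions[condition]
              if isinstance(condition, (int, np.integer)) else condition)
    mutant = PerturbedSynthesis(synth, link, lam)
    g0 = resolve_initial_state(synth, task)
    return simulate(mutant, g0, course, n_steps=task.N_T, dt=task.dt,
                    **sim_kwargs)


class _GeneKnockout:
    """Synthesis wrapper with one gene's value clamped to 0 everywhere and its
    own synthesis zeroed."""

    def __init__(self, synth, gene: int):
        self.base = synth
        self.n_genes = synth.n_genes
        self.n_inputs = synth.n_inputs
        self.gene = int(gene)

    def __call__(self, g, inputs=None):
        g = np.asarray(g, dtype=float).copy()
        g[..., self.gene] = 0.0
        f = np.asarray(self.base(g, inputs), dtype=float).copy()
        f[..., self.gene] = 0.0
        return f


def gene_knockout_trajectory(
    synth,
    gene: int | str,
    condition: int | np.ndarray,
    task: TaskSpec,
    **sim_kwargs,
) -> Trajectory:
    """Simulate a whole-gene null mutant (all outgoing links cut, no
    synthesis, zero initial level)."""
    names = _node_names(synth.n_genes, synth.n_inputs)
    gi = names.index(gene) if isinstance(gene, str) else int(gene)
    if not 0 <= gi < synth.n_genes:
        raise KeyError(f"unknown gene {gene!r}")
    course = (task.conditions[condition]
              if isinstance(condition, (int, np.integer)) else condition)
    g0 = resolve_initial_state(synth, task).copy()
    g0[gi] = 0.0
    return simulate(_GeneKnockout(synth, gi), g0, course, n_steps=task.N_T,
                    dt=task.dt, **sim_kwargs)


# ---------------------------------------------------------------------- #
# topology extraction
# ---------------------------------------------------------------------- #
def extract_topology(scores: LinkScores, cutoff: float) -> Topology:
    """Threshold normalized scores into a signed topology.

    Scores are first normalized per target gene (each column by its own
    maximum absolute score); entries with normalized magnitude <= cutoff
    become 0, the rest take the sign of the score.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    norm = scores.normalized()
    sign = np.where(np.abs(norm) > cutoff, np.sign(norm), 0).astype(np.int8)
    n_reg, n_genes = sign.shape
    return Topology(n_genes=n_genes, n_inputs=n_reg - n_genes, sign=sign)


def optimal_cutoff(
    score_list: Sequence[LinkScores],
    grid: Sequence[float] | None = None,
) -> tuple[float, int]:
    """Cutoff maximizing the number of distinct extracted topologies.

    Too low a cutoff makes sparse topologies indistinguishable from denser
    ones (every tiny score becomes a link); too high a cutoff erases real
    weak links.  Ties break toward the smallest cutoff.
    """
    if not score_list:
        raise ValueError("score_list must be non-empty")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 50)
    if len(grid) == 0:
        raise ValueError("cutoff grid must be non-empty")
    best_cut, best_count = None, -1
    for cut in grid:
        distinct = {extract_topology(s, cut).key() for s in score_list}
        if len(distinct) > best_count:
            best_cut, best_count = float(cut), len(distinct)
    return best_cut, best_count


# ---------------------------------------------------------------------- #
# sparsification by iterative link deletion
# ---------------------------------------------------------------------- #
@dataclass
class SparsifyConfig:
    """Configuration for the iterative link-deletion search.

    A deletion is deemed successful while the retrained loss stays below
    max(fail_ratio * initial loss, fail_abs).  If the best-ranked deletion
    fails to retrain, the next-ranked candidates are tried (up to
    ``max_attempts`` per iteration) before the search terminates; the last
    failed attempt is recorded with ``success=False``.  ``cutoff=0`` records
    the effective sign of every structurally remaining link, so recorded
    link counts decrease by exactly one per step.
    """

    train_config: TrainConfig = field(default_factory=TrainConfig)
    hidden_sizes: tuple[int, int] = (16, 16)
    architecture: str = "per_gene"
    cutoff: float = 0.0
    lam_score: float = 0.95
    fail_ratio: float = 2.0
    fail_abs: float = 0.3
    seed: int = 0
    warm_start: bool = True
    max_attempts: int | None = None


@dataclass
class SparsifyStep:
    mask: frozenset
    topology: Topology
    metrics: PhenotypeMetrics
    loss: float
    success: bool
    deleted_link: tuple[int, int] | None = None


class SparsifyError(RuntimeError):
    """Raised when the initial (step-0) training fails outright."""


def _knockout_loss(model, task: TaskSpec, link: tuple[int, int]) -> float:
    mutant = PerturbedSynthesis(model, link, 0.0)
    g0 = resolve_initial_state(model, task)
    trajs = [simulate(mutant, g0, c, n_steps=task.N_T, dt=task.dt)
             for c in task.conditions]
    return task_loss_fn(trajs, task)


def sparsify(
    task: TaskSpec,
    config: SparsifyConfig | None = None,
    initial_mask: Iterable[tuple[int | str, int | str]] | None = None,
) -> list[SparsifyStep]:
    """Search for minimal functional networks by iterative link deletion.

    Step 0 trains a model with ``initial_mask`` applied.  Each iteration then
    simulates the link-knockout mutant for every remaining link and ranks
    links by how little their knockout increases the task loss (the minimal
    phenotype change; ties break toward the lowest regulator-then-target
    index).  The best-ranked link is deleted and the model retrained with
    the enlarged mask; if the retrained loss exceeds the failure threshold
    the deletion is rolled back and the next-ranked link tried, so the
    search terminates only when no remaining link can be deleted without
    losing the function.  Successful steps are recorded in order (link count
    decreasing by one per step), followed by the final failing attempt.
    """
    config = config or SparsifyConfig()
    ss = np.random.SeedSequence(config.seed)
    s_build, s_train = (int(x) for x in ss.generate_state(2) % (2 ** 31))
    synth = build_synthesis(task.n_genes, task.n_inputs,
                            hidden_sizes=config.hidden_sizes,
                            architecture=config.architecture, seed=s_build)
    if initial_mask:
        synth = apply_structural_mask(synth, initial_mask)
    cfg0 = TrainConfig(**{**config.train_config.__dict__, "seed": s_train})
    try:
        result = train(synth, task, cfg0)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise SparsifyError(f"initial training failed: {exc}") from exc
    model = result.model
    loss0 = result.best_loss
    threshold = max(config.fail_ratio * loss0, config.fail_abs)

    def record(deleted: tuple[int, int] | None, loss_value: float) -> SparsifyStep:
        topo, _ = distill_topology(model, task, lam=config.lam_score,
                                   cutoff=config.cutoff)
        ci = int(task.meta.get("metrics_condition", 0))
        traj0 = simulate_task(model, task)[ci]
        return SparsifyStep(
            mask=frozenset(model.forbidden_links),
            topology=topo,
            metrics=phenotype_metrics(traj0, task),
            loss=loss_value,
            success=loss_value <= threshold,
            deleted_link=deleted,
        )

    steps = [record(None, loss0)]
    retrain_seeds = iter(int(x) for x in
                         np.random.SeedSequence((config.seed, 1)).generate_state(
                             4 * model.n_regulators * model.n_genes) % (2 ** 31))
    while True:
        forbidden = model.forbidden_links
        remaining = [(i, j) for i in range(model.n_regulators)
                     for j in range(model.n_genes) if (i, j) not in forbidden]
        if len(remaining) <= 1:
            break
        ko_losses = sorted(
            ((_knockout_loss(model, task, link), link) for link in remaining),
            key=lambda t: (t[0], t[1]))
        deleted = False
        failed_step: SparsifyStep | None = None
        n_try = (len(ko_losses) if config.max_attempts is None
                 else config.max_attempts)
        for _, link in ko_losses[:n_try]:
            masked = apply_structural_mask(model, [link])
            cfg = TrainConfig(**{**config.train_config.__dict__,
                                 "seed": next(retrain_seeds)})
            if not config.warm_start:
                masked = apply_structural_mask(
                    build_synthesis(task.n_genes, task.n_inputs,
                                    hidden_sizes=config.hidden_sizes,
                                    architecture=config.architecture,
                                    seed=next(retrain_seeds)),
                    masked.forbidden_links)
            try:
                result = train(masked, task, cfg,
                               reset_init=not config.warm_start)
                attempt_loss = result.best_loss
                attempt_model = result.model
            except Exception:  # noqa: BLE001 - divergence counts as failure
                attempt_loss = float("inf")
                attempt_model = masked
            if attempt_loss <= threshold:
                model = attempt_model
                steps.append(record(link, attempt_loss))
                deleted = True
                break
            if failed_step is None:
                keep = model
                model = attempt_model
                failed_step = record(link, attempt_loss)
                model = keep
        if not deleted:
            if failed_step is not None:
                steps.append(failed_step)
            break
    return steps


# ---------------------------------------------------------------------- #
# topology utilities
# ---------------------------------------------------------------------- #
def topology_distance(a: Topology, b: Topology) -> int:
    """Number of (regulator, target) positions with unequal sign entries."""
    if a.sign.shape != b.sign.shape:
        raise ValueError("topology shape mismatch")
    return int(np.count_nonzero(a.sign != b.sign))


def topology_neighbor_graph(topologies: Iterable[Topology]) -> nx.Graph:
    """Graph with one node per distinct topology and an edge where two
    topologies differ by exactly one regulatory link."""
    distinct: list[Topology] = []
    seen = set()
    for t in topologies:
        if t.key() not in seen:
            seen.add(t.key())
            distinct.append(t)
    graph = nx.Graph()
    for idx, t in enumerate(distinct):
        graph.add_node(idx, topology=t, n_links=t.n_links)
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            if topology_distance(distinct[i], distinct[j]) == 1:
                graph.add_edge(i, j)
    return graph


# ---------------------------------------------------------------------- #
# motif detection
# ---------------------------------------------------------------------- #
def contains_incoherent_feedforward(
    topo: Topology, input_index: int = 0, output_gene: int = 0
) -> bool:
    """True if the input reaches the output both directly and through one
    intermediate gene, with opposite net signs on the two paths."""
    row = topo.n_genes + input_index
    direct = int(topo.sign[row, output_gene])
    if direct == 0:
        return False
    for k in range(topo.n_genes):
        if k == output_gene:
            continue
        indirect = int(topo.sign[row, k]) * int(topo.sign[k, output_gene])
        if indirect != 0 and indirect == -direct:
            return True
    return False


def contains_negative_feedback(topo: Topology,
                               output_gene: int | None = 0) -> bool:
    """True if a two-gene cycle with negative sign product exists (through
    the output gene by default; any pair if ``output_gene`` is None)."""
    genes = range(topo.n_genes)
    pairs = ([(output_gene, k) for k in genes if k != output_gene]
             if output_gene is not None
             else [(i, k) for i in genes for k in genes if i < k])
    for i, k in pairs:
        if int(topo.sign[i, k]) * int(topo.sign[k, i]) == -1:
            return True
    return False
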