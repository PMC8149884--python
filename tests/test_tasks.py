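"""Task generators, loss, phenotype metrics, synthetic gap-gene profiles."""

import numpy as np
import pytest

from netdistill.dynamics import Trajectory
from netdistill.tasks import (
    PhenotypeMetrics,
    TaskSpec,
    adaptation_target_curve,
    loss,
    make_adaptation_task,
    make_controlled_oscillation_task,
    make_gap_gene_task,
    phenotype_metrics,
    synth_gap_gene_profiles,
    triangular_wave,
)


# ---------------------------------------------------------------------- #
# adaptation target
# ---------------------------------------------------------------------- #
def test_adaptation_target_boundary_values():
    times = np.linspace(0, 50, 2001)
    curve = adaptation_target_curve(times, t0=1.0, pre_level=0.4,
                                    amplitude=0.35, tau_fast=0.6,
                                    tau_slow=1.8)
    # at onset the difference of exponentials vanishes
    assert curve[times.searchsorted(1.0)] == pytest.approx(0.4, abs=1e-9)
    # long after onset both exponentials vanish
    assert curve[-1] == pytest.approx(0.4, abs=1e-6)
    assert curve.max() == pytest.approx(0.75, abs=1e-4)


def test_adaptation_target_peak_time_matches_calculus():
    # argmax of exp(-s/ts) - exp(-s/tf) is s* = ln(ts/tf) / (1/tf - 1/ts)
    tf, ts, t0 = 0.5, 2.5, 2.0
    times = np.linspace(0, 30, 300001)
    curve = adaptation_target_curve(times, t0, 0.3, 0.4, tf, ts)
    s_star = np.log(ts / tf) / (1.0 / tf - 1.0 / ts)
    assert times[np.argmax(curve)] == pytest.approx(t0 + s_star, abs=1e-3)


def test_adaptation_task_structure():
    task = make_adaptation_task()
    assert task.n_genes == 2 and task.n_inputs == 1
    assert task.n_conditions == 4  # zero level + three step heights
    # zero-input condition demands a flat response
    flat = task.targets[task.targets[:, 0] == 0][:, 3]
    assert np.allclose(flat, 0.4)
    # g1 pinned at the pre-stimulus level, g2 trainable
    assert task.initial_policy[0] == ("fixed", 0.4)
    assert task.initial_policy[1][0] == "trainable"


def test_adaptation_task_rejects_bad_arguments():
    with pytest.raises(ValueError):
        make_adaptation_task(pre_level=0.8, pulse_amplitude=0.5)
    with pytest.raises(ValueError):
        make_adaptation_task(tau_fast=2.0, tau_slow=1.0)


# ---------------------------------------------------------------------- #
# controlled oscillation
# ---------------------------------------------------------------------- #
def test_oscillation_task_three_conditions():
    task = make_controlled_oscillation_task()
    assert task.n_conditions == 3
    assert task.N_T == 60
    # condition 0: no stimulus, constant low target
    t0 = task.targets[task.targets[:, 0] == 0]
    assert np.allclose(t0[:, 3], 0.1)
    # condition 1 targets span exactly [osc_min, osc_max]
    t1 = task.targets[task.targets[:, 0] == 1][:, 3]
    assert t1.min() == pytest.approx(0.2)
    assert t1.max() == pytest.approx(0.8)
    # targets constrain only the output gene
    assert (task.targets[:, 2] == 0).all()


def test_triangular_wave_extremes():
    w = triangular_wave(np.arange(40), period=20, low=0.2, high=0.8)
    assert w.min() == pytest.approx(0.2)
    assert w.max() == pytest.approx(0.8)
    assert w[0] == pytest.approx(0.2)  # starts low, rising


def test_oscillation_task_rejects_degenerate_period():
    with pytest.raises(ValueError):
        make_controlled_oscillation_task(period=1)


# ---------------------------------------------------------------------- #
# gap-gene profiles and tasks
# ---------------------------------------------------------------------- #
def test_gap_gene_profiles_contract():
    morphogens, targets = synth_gap_gene_profiles(60, seed=3)
    bcd, tor = morphogens[:, 0], morphogens[:, 1]
    assert (np.diff(bcd) < 0).all()  # anterior-posterior decay
    # terminal system input: high at both poles, low in the middle
    assert tor[0] > tor[30] and tor[-1] > tor[30]
    assert morphogens.min() >= 0 and morphogens.max() <= 1
    assert targets.min() >= 0 and targets.max() <= 1
    peaks = targets.argmax(axis=0)
    assert len(set(peaks)) == 4  # four distinct band positions
    assert (np.diff(sorted(peaks)) > 0).all()


def test_gap_gene_profiles_reproducible():
    a = synth_gap_gene_profiles(40, seed=9)
    b = synth_gap_gene_profiles(40, seed=9)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = synth_gap_gene_profiles(40, seed=10)
    assert not np.array_equal(a[1], c[1])


def test_gap_gene_task_list():
    profiles = synth_gap_gene_profiles(20, seed=0)
    tasks = make_gap_gene_task(profiles, N_T=30)
    assert len(tasks) == 20
    for task in tasks:
        assert task.n_genes == 4 and task.n_inputs == 2
        assert (task.targets[:, 1] == 30).all()  # final time point only
        assert all(p == ("fixed", 0.0) for p in task.initial_policy)
        # static morphogen input
        assert np.ptp(task.conditions[0], axis=0).max() == 0.0


# ---------------------------------------------------------------------- #
# loss
# ---------------------------------------------------------------------- #
def _flat_task(value=0.5):
    return TaskSpec(
        n_genes=1, n_inputs=0, conditions=[np.zeros((4, 0)), np.zeros((4, 0))],
        targets=np.array([[0, 1, 0, value], [0, 3, 0, value],
                          [1, 2, 0, value]]),
        initial_policy=[("fixed", value)], N_T=3)


def test_loss_zero_iff_all_constraints_met():
    task = _flat_task()
    exact = [np.full((4, 1), 0.5), np.full((4, 1), 0.5)]
    assert loss(exact, task) == 0.0
    off = [v.copy() for v in exact]
    off[1][2, 0] = 1.0  # single constraint off by 0.5
    assert loss(off, task) == pytest.approx(0.5)


def test_loss_matches_brute_force_enumeration():
    rng = np.random.default_rng(4)
    task = make_adaptation_task()
    trajs = [rng.uniform(0, 1, (task.N_T + 1, 2))
             for _ in range(task.n_conditions)]
    sq = sum((trajs[int(c)][int(t), int(g)] - v) ** 2
             for c, t, g, v in task.targets)
    assert loss(trajs, task) == pytest.approx(np.sqrt(sq), abs=1e-12)


def test_loss_rejects_wrong_condition_count():
    task = _flat_task()
    with pytest.raises(ValueError):
        loss([np.full((4, 1), 0.5)], task)


def test_taskspec_requires_targets_in_bounds():
    with pytest.raises(ValueError):
        TaskSpec(n_genes=1, n_inputs=0, conditions=[np.zeros((3, 0))],
                 targets=np.array([[0, 1, 0, 1.4]]),
                 initial_policy=[("fixed", 0.0)], N_T=2)
    with pytest.raises(ValueError):
        TaskSpec(n_genes=1, n_inputs=0, conditions=[np.zeros((3, 0))],
                 targets=np.array([[0, 5, 0, 0.5]]),
                 initial_policy=[("fixed", 0.0)], N_T=2)


def test_taskspec_yaml_round_trip(tmp_path):
    task = make_adaptation_task()
    path = tmp_path / "task.yaml"
    task.to_yaml(path)
    back = TaskSpec.from_yaml(path)
    assert back.n_genes == task.n_genes
    assert back.kind == task.kind
    assert np.allclose(back.targets, task.targets)
    for a, b in zip(back.conditions, task.conditions):
        assert np.allclose(a, b)
    assert back.initial_policy == task.initial_policy


# ---------------------------------------------------------------------- #
# phenotype metrics
# ---------------------------------------------------------------------- #
def _traj_from(values):
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    return Trajectory(dt=0.2, values=values,
                      inputs=np.zeros((values.shape[0], 0)))


def test_metrics_constant_trajectory():
    task = make_adaptation_task()
    m = phenotype_metrics(_traj_from(np.full(41, 0.4)), task)
    assert m.sensitivity == 0.0 and m.adaptation_error == 0.0


def test_metrics_pulse_and_decay():
    task = make_adaptation_task()
    g = np.full(41, 0.4)
    g[15] = 0.9  # pulse peak, then returns
    m = phenotype_metrics(_traj_from(g), task)
    assert m.sensitivity == pytest.approx(0.5)
    assert m.adaptation_error == pytest.approx(0.0)
    decay = 0.4 + 0.3 * 0.9 ** np.arange(41)  # settles at a new level
    m = phenotype_metrics(_traj_from(decay), task)
    assert m.adaptation_error == pytest.approx(abs(decay[-1] - 0.4))


def test_metrics_are_non_negative_dataclass():
    m = PhenotypeMetrics(sensitivity=0.1, adaptation_error=0.0)
    assert m.oscillation_amplitude == 0.0
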