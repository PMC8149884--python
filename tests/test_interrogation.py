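"""Link mutation, topology extraction, mutant simulation, motifs."""

import numpy as np
import pytest

from netdistill.dynamics import simulate
from netdistill.hill import HillSynthesis, sample_hill_params
from netdistill.interrogation import (
    LinkScores,
    PerturbedSynthesis,
    Topology,
    contains_incoherent_feedforward,
    contains_negative_feedback,
    delta_matrix,
    extract_topology,
    gene_knockout_trajectory,
    mutant_trajectory,
    optimal_cutoff,
    perturbed_f,
    topology_distance,
    topology_neighbor_graph,
)
from netdistill.nn_synthesis import apply_structural_mask, build_synthesis
from netdistill.training import simulate_task

from conftest import random_hill_system


@pytest.fixture(scope="module")
def probe_model():
    return build_synthesis(2, 1, (8, 8), "per_gene", seed=13)


# ---------------------------------------------------------------------- #
# perturbed_f
# ---------------------------------------------------------------------- #
def test_lambda_one_is_identity(probe_model):
    g, i = np.array([0.4, 0.6]), np.array([0.5])
    assert np.array_equal(perturbed_f(probe_model, ("g1", "g2"), 1.0, (g, i)),
                          probe_model(g, i))


def test_only_target_component_changes(probe_model):
    g, i = np.array([0.4, 0.6]), np.array([0.5])
    base = probe_model(g, i)
    pert = perturbed_f(probe_model, ("g1", "g2"), 0.3, (g, i))
    assert pert[0] == base[0]  # bitwise equality away from the target
    assert pert[1] != base[1]


def test_lambda_zero_equals_structural_mask(probe_model):
    masked = apply_structural_mask(probe_model, [("g1", "g2")])
    rng = np.random.default_rng(0)
    for _ in range(20):
        g, i = rng.uniform(0, 1, 2), rng.uniform(0, 1, 1)
        assert perturbed_f(probe_model, ("g1", "g2"), 0.0, (g, i))[1] == \
            pytest.approx(masked(g, i)[1], abs=1e-12)


def test_invalid_link_raises(probe_model):
    with pytest.raises(KeyError):
        PerturbedSynthesis(probe_model, ("g9", "g1"), 0.5)
    with pytest.raises(ValueError):
        PerturbedSynthesis(probe_model, ("g1", "g2"), 1.5)


# ---------------------------------------------------------------------- #
# delta_matrix
# ---------------------------------------------------------------------- #
def _random_trajectory(synth, seed=0, n_steps=30):
    rng = np.random.default_rng(seed)
    g0 = rng.uniform(0.1, 0.9, synth.n_genes)
    course = rng.uniform(0.2, 0.8, (n_steps + 1, synth.n_inputs))
    return simulate(synth, g0, course, n_steps)


def test_masked_link_scores_exactly_zero():
    m = apply_structural_mask(
        build_synthesis(3, 1, (8, 8), "per_gene", seed=2), [("g2", "g1")])
    scores = delta_matrix(m, _random_trajectory(m), lam=0.95)
    assert scores.values[1, 0] == 0.0


def test_lambda_one_gives_all_zero_scores(probe_model):
    scores = delta_matrix(probe_model, _random_trajectory(probe_model), 1.0)
    assert np.all(scores.values == 0.0)


def test_empty_trajectory_rejected(probe_model):
    with pytest.raises(ValueError):
        delta_matrix(probe_model, (np.empty((0, 2)), np.empty((0, 1))), 0.95)


def test_delta_signs_match_finite_difference_partials():
    # on a monotone Hill ground truth the knockdown score and the bare
    # partial derivative agree in sign at every trajectory state
    synth = random_hill_system(3, seed=5)
    traj = _random_trajectory(synth, seed=1)
    scores = delta_matrix(synth, traj, lam=0.95)
    eps = 1e-6
    G, I = traj.values, traj.inputs
    X = np.concatenate([G, I], axis=1)
    F = synth(G, I)
    for i in range(4):
        for j in range(3):
            true_sign = int(synth.topology.sign[i, j])
            if true_sign == 0:
                assert scores.values[i, j] == 0.0
                continue
            Xp = X.copy()
            Xp[:, i] += eps
            Fp = synth(Xp[:, :3], Xp[:, 3:])
            fd = (Fp[:, j] - F[:, j]) / eps
            # finite-difference partial has the link's sign wherever the
            # regulator is expressed
            active = X[:, i] > 1e-6
            assert (np.sign(fd[active]) == true_sign).all()
            assert np.sign(scores.values[i, j]) == true_sign


def test_delta_over_one_minus_lambda_converges_to_derivative():
    # as lam -> 1, Delta / (1 - lam) approaches g_i * df_j/dg_i averaged
    # along the trajectory
    synth = random_hill_system(2, seed=8)
    traj = _random_trajectory(synth, seed=2)
    G, I = traj.values, traj.inputs
    X = np.concatenate([G, I], axis=1)
    F = synth(G, I)
    eps = 1e-7
    ref = np.zeros((3, 2))
    for i in range(3):
        Xp = X.copy()
        Xp[:, i] += eps
        Fp = synth(Xp[:, :2], Xp[:, 2:])
        for j in range(2):
            ref[i, j] = np.mean((Fp[:, j] - F[:, j]) / eps * X[:, i])
    prev_err = np.inf
    for lam in (0.99, 0.999):
        sc = delta_matrix(synth, traj, lam=lam).values / (1.0 - lam)
        err = np.abs(sc - ref).max()
        assert err < prev_err or err < 1e-3
        prev_err = err
    assert prev_err < 5e-3


# ---------------------------------------------------------------------- #
# mutant trajectories
# ---------------------------------------------------------------------- #
def test_mutant_with_lambda_one_is_wild_type(trained_adaptation,
                                             adaptation_task):
    model = trained_adaptation.model
    wt = simulate_task(model, adaptation_task)[1]
    mut = mutant_trajectory(model, ("g1", "g2"), 1.0, 1, adaptation_task)
    assert np.array_equal(wt.values, mut.values)


def test_knockout_direction_matches_ground_truth_sign():
    # on an HF ground truth, knocking out an activating link lowers the
    # target's level; knocking out a repressing link raises it
    for seed in range(4):
        synth = random_hill_system(3, seed=100 + seed)
        rng = np.random.default_rng(seed)
        g0 = rng.uniform(0.2, 0.8, 3)
        course = np.full((41, 1), 0.6)
        wt = simulate(synth, g0, course, 40)
        for i, j, s in synth.topology.links():
            if i >= 3 or i == j:
                continue  # gene-gene cross links only
            mut = simulate(PerturbedSynthesis(synth, (i, j), 0.0),
                           g0, course, 40)
            diff = mut.values[-1, j] - wt.values[-1, j]
            if abs(diff) < 1e-9:
                continue  # dynamically silent link
            assert np.sign(diff) == -s


def test_null_link_knockout_changes_nothing():
    synth = random_hill_system(3, seed=42)
    absent = [(i, j) for i in range(4) for j in range(3)
              if synth.topology.sign[i, j] == 0]
    rng = np.random.default_rng(0)
    g0 = rng.uniform(0.2, 0.8, 3)
    course = np.full((31, 1), 0.5)
    wt = simulate(synth, g0, course, 30)
    for link in absent[:3]:
        mut = simulate(PerturbedSynthesis(synth, link, 0.0), g0, course, 30)
        assert np.allclose(mut.values, wt.values, atol=1e-12)


def test_gene_knockout_equals_masking_all_outgoing_links(
        trained_adaptation, adaptation_task):
    model = trained_adaptation.model
    ko = gene_knockout_trajectory(model, "g2", 1, adaptation_task)
    assert np.allclose(ko.values[:, 1], 0.0, atol=1e-12)
    # knocked-out gene contributes nothing: equivalent to lam=0 on every
    # outgoing link plus zeroed own synthesis
    masked = apply_structural_mask(model, [("g2", "g1"), ("g2", "g2")])
    g0 = model.initial_state().copy()
    g0[1] = 0.0

    def silenced(g, i):
        f = masked(g, i)
        f[..., 1] = 0.0
        return f

    silenced.n_genes, silenced.n_inputs = 2, 1
    ref = simulate(silenced, g0, adaptation_task.conditions[1], 40)
    assert np.allclose(ko.values[:, 0], ref.values[:, 0], atol=1e-12)


# ---------------------------------------------------------------------- #
# extraction and cutoff
# ---------------------------------------------------------------------- #
def _scores(values, lam=0.95):
    return LinkScores(values=np.asarray(values, dtype=float), lam=lam)


def test_extract_topology_thresholds_normalized_scores():
    sc = _scores([[1.0], [-0.4], [0.1]])
    topo = extract_topology(sc, cutoff=0.2)
    assert topo.sign[:, 0].tolist() == [1, -1, 0]
    assert extract_topology(sc, cutoff=1.0).n_links == 0
    assert extract_topology(sc, cutoff=0.0).n_links == 3


def test_all_zero_scores_give_empty_topology():
    topo = extract_topology(_scores([[0.0], [0.0]]), cutoff=0.0)
    assert topo.n_links == 0


def test_optimal_cutoff_tie_breaks_to_smallest():
    sc = _scores([[1.0], [0.5]])
    cut, count = optimal_cutoff([sc], grid=[0.1, 0.3, 0.7])
    assert count == 1 and cut == 0.1


def test_optimal_cutoff_separates_weak_extra_link():
    a = _scores([[1.0], [0.0]])
    b = _scores([[1.0], [0.15]])
    cut, count = optimal_cutoff([a, b], grid=[0.05, 0.5])
    assert cut == 0.05 and count == 2
    # a high cutoff collapses them
    _, high_count = optimal_cutoff([a, b], grid=[0.5])
    assert high_count == 1


# ---------------------------------------------------------------------- #
# topology utilities and motifs
# ---------------------------------------------------------------------- #
def test_topology_distance_counts_differing_positions():
    a = Topology.from_links(2, 1, [("I1", "g1", +1)])
    b = Topology.from_links(2, 1, [("I1", "g1", +1), ("g1", "g2", +1)])
    assert topology_distance(a, a) == 0
    assert topology_distance(a, b) == 1
    c = Topology.from_links(2, 1, [("I1", "g1", -1)])
    assert topology_distance(a, c) == 1  # sign flip counts once


def test_topology_distance_requires_matching_shapes():
    a = Topology.from_links(2, 1, [("I1", "g1", +1)])
    b = Topology.from_links(3, 1, [("I1", "g1", +1)])
    with pytest.raises(ValueError):
        topology_distance(a, b)


def test_neighbor_graph_edges_at_distance_one():
    base = Topology.from_links(2, 1, [("I1", "g1", +1), ("g1", "g2", +1)])
    plus = Topology.from_links(2, 1, [("I1", "g1", +1), ("g1", "g2", +1),
                                      ("g2", "g1", -1)])
    graph = topology_neighbor_graph([base, plus, base])
    assert graph.number_of_nodes() == 2  # duplicates collapse
    assert graph.number_of_edges() == 1
    # three mutually distance-2 topologies: no edges
    t1 = Topology.from_links(2, 1, [("I1", "g1", +1), ("g1", "g2", +1)])
    t2 = Topology.from_links(2, 1, [("I1", "g1", -1), ("g1", "g2", -1)])
    t3 = Topology.from_links(2, 1, [("I1", "g2", +1), ("g2", "g1", +1)])
    g = topology_neighbor_graph([t1, t2, t3])
    assert g.number_of_edges() == 0


def test_incoherent_feedforward_detection():
    iff = Topology.from_links(2, 1, [("I1", "g1", +1), ("I1", "g2", +1),
                                     ("g2", "g1", -1)])
    assert contains_incoherent_feedforward(iff)
    coherent = Topology.from_links(2, 1, [("I1", "g1", +1), ("I1", "g2", +1),
                                          ("g2", "g1", +1)])
    assert not contains_incoherent_feedforward(coherent)
    no_direct = Topology.from_links(2, 1, [("I1", "g2", +1),
                                           ("g2", "g1", -1)])
    assert not contains_incoherent_feedforward(no_direct)


def test_negative_feedback_detection():
    nfb = Topology.from_links(2, 1, [("I1", "g1", +1), ("g1", "g2", +1),
                                     ("g2", "g1", -1)])
    assert contains_negative_feedback(nfb)
    flipped = Topology.from_links(2, 1, [("I1", "g1", +1), ("g1", "g2", -1),
                                         ("g2", "g1", +1)])
    assert contains_negative_feedback(flipped)
    positive = Topology.from_links(2, 1, [("g1", "g2", +1), ("g2", "g1", +1)])
    assert not contains_negative_feedback(positive)
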