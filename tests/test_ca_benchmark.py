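"""Cellular-automata benchmark: symmetries, data prep, link evaluation."""

import numpy as np
import pytest

from netdistill.ca_benchmark import (
    CAConfig,
    CAPairs,
    classify_links,
    downsample_temporal,
    generate_ca_rule,
    linear_autoregressor_baseline,
    neighbor_average,
    roc_analysis,
    score_ca_links,
    simulate_ca,
    train_ca_rnn,
    CATrainConfig,
    _draw_rule,
)
from netdistill.hill import HillSynthesis
from netdistill.interrogation import LinkScores, Topology


@pytest.fixture(scope="module")
def rule():
    return generate_ca_rule(seed=0)


# ---------------------------------------------------------------------- #
# ground-truth generation
# ---------------------------------------------------------------------- #
def test_rule_exposes_200_candidate_links(rule):
    assert rule.n_candidate_links == 200
    assert rule.topology.sign.shape == (20, 10)


def test_link_sign_prior_matches_binomial():
    # over many pre-rejection draws, existing links ~ Binomial(200, 0.7)
    counts = [np.count_nonzero(_draw_rule(s, CAConfig()).topology.sign)
              for s in range(1000)]
    mean = np.mean(counts)
    # 99.7% CI for the mean of 1000 draws: 140 +- 3 * sqrt(200*0.7*0.3/1000)
    assert abs(mean - 140.0) < 3 * np.sqrt(200 * 0.7 * 0.3 / 1000)


def test_accepted_rule_is_patterned(rule):
    assert rule.diagnostics["max_time_mean_spatial_var"] > 0.01


# ---------------------------------------------------------------------- #
# lattice symmetries
# ---------------------------------------------------------------------- #
def test_uniform_state_stays_uniform(rule):
    init = np.tile(np.linspace(0.1, 0.9, 10), (8, 1))
    arr = simulate_ca(rule, init, 50)
    assert np.abs(arr - arr[:, :1, :]).max() < 1e-12


def test_translation_equivariance(rule):
    rng = np.random.default_rng(1)
    init = rng.uniform(0, 1, (16, 10))
    a = simulate_ca(rule, init, 30)
    b = simulate_ca(rule, np.roll(init, 3, axis=0), 30)
    assert np.abs(np.roll(a, 3, axis=1) - b).max() < 1e-12


def test_reflection_equivariance(rule):
    rng = np.random.default_rng(2)
    init = rng.uniform(0, 1, (16, 10))
    a = simulate_ca(rule, init, 30)
    b = simulate_ca(rule, init[::-1], 30)
    assert np.abs(a[:, ::-1, :] - b).max() < 1e-12


def test_simulate_requires_three_cells(rule):
    with pytest.raises(ValueError):
        simulate_ca(rule, np.zeros((2, 10)), 5)


def test_neighbor_average_periodic():
    g = np.arange(12.0).reshape(4, 3)
    h = neighbor_average(g)
    assert np.allclose(h[0], (g[3] + g[1]) / 2)
    assert np.allclose(h[-1], (g[2] + g[0]) / 2)


# ---------------------------------------------------------------------- #
# down-sampling
# ---------------------------------------------------------------------- #
def test_downsample_pair_counts(rule):
    rng = np.random.default_rng(3)
    arr = simulate_ca(rule, rng.uniform(0, 1, (8, 10)), 100)  # 101 frames
    pairs = downsample_temporal(arr, factor=10)
    assert pairs.n_pairs == 10 * 8  # 10 pairs per cell
    assert pairs.factor == 10
    # pair spacing is exactly 10 raw steps
    assert np.allclose(pairs.g[:8] * pairs.scale, arr[0])
    assert np.allclose(pairs.y[:8] * pairs.scale, arr[10])


def test_downsample_factor_one_gives_consecutive_frames(rule):
    rng = np.random.default_rng(4)
    arr = simulate_ca(rule, rng.uniform(0, 1, (5, 10)), 6)
    pairs = downsample_temporal(arr, factor=1)
    assert pairs.n_pairs == 6 * 5
    assert np.allclose(pairs.y[:5] * pairs.scale, arr[1])


def test_downsample_needs_enough_frames(rule):
    rng = np.random.default_rng(5)
    arr = simulate_ca(rule, rng.uniform(0, 1, (4, 10)), 5)
    with pytest.raises(ValueError):
        downsample_temporal(arr, factor=10)


# ---------------------------------------------------------------------- #
# link scoring and evaluation
# ---------------------------------------------------------------------- #
def test_truth_model_scores_recover_every_existing_link_sign(rule):
    rng = np.random.default_rng(6)
    arr = simulate_ca(rule, rng.uniform(0, 1, (16, 10)), 200)
    pairs = downsample_temporal(arr, factor=10)
    truth = HillSynthesis(rule.topology, rule.params)
    scores = score_ca_links(truth, pairs.raw_states(), lam=0.95)
    assert scores.values.shape == (20, 10)
    sign = rule.topology.sign
    nz = sign != 0
    assert (np.sign(scores.values[nz]) == sign[nz]).all()
    assert (scores.values[~nz] == 0.0).all()
    # lam = 1 scores vanish identically
    z = score_ca_links(truth, pairs.raw_states(), lam=1.0)
    assert np.all(z.values == 0.0)


def test_classifier_discards_exactly_thirty_percent(rule):
    rng = np.random.default_rng(7)
    scores = LinkScores(values=rng.normal(size=(20, 10)), lam=0.95)
    ev = classify_links(scores, rule.topology, discard_fraction=0.30)
    assert ev.confusion.sum() == 200
    assert ev.confusion[:, 1].sum() == 60  # predicted non-exist column


def test_perfect_scores_give_diagonal_confusion(rule):
    # scores equal to the truth signs: the confusion matrix is diagonal
    # (absent links all score 0, so they are discarded or predicted 0)
    scores = LinkScores(values=rule.topology.sign.astype(float), lam=0.95)
    ev = classify_links(scores, rule.topology, discard_fraction=0.30)
    conf = ev.confusion
    assert np.trace(conf) == conf.sum() == 200
    assert conf[1, 1] == int((rule.topology.sign == 0).sum())


def test_random_scores_give_chance_level_auc(rule):
    rng = np.random.default_rng(8)
    aucs = []
    for _ in range(30):
        ev = roc_analysis(LinkScores(rng.normal(size=(20, 10)), 0.95),
                          rule.topology)
        aucs.append((ev.auc_activating + ev.auc_inhibiting) / 2)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def test_roc_endpoints(rule):
    rng = np.random.default_rng(9)
    ev = roc_analysis(LinkScores(rng.normal(size=(20, 10)), 0.95),
                      rule.topology)
    fpr, tpr = ev.roc_activating
    assert fpr[0] == 0 and tpr[0] == 0
    assert fpr[-1] == 1 and tpr[-1] == 1
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


def test_roc_requires_both_classes():
    empty = Topology(n_genes=10, n_inputs=10, sign=np.zeros((20, 10)))
    with pytest.raises(ValueError):
        roc_analysis(LinkScores(np.ones((20, 10)), 0.95), empty)


# ---------------------------------------------------------------------- #
# linear baseline
# ---------------------------------------------------------------------- #
def test_linear_baseline_recovers_exactly_linear_rule():
    rng = np.random.default_rng(10)
    W = rng.normal(scale=0.3, size=(20, 10))
    c = rng.normal(scale=0.1, size=10)
    g = rng.uniform(0, 1, (400, 10))
    h = rng.uniform(0, 1, (400, 10))
    y = np.column_stack([g, h]) @ W + c
    pairs = CAPairs(g=g, h=h, y=y)
    scores = linear_autoregressor_baseline(pairs)
    assert np.abs(scores.values - W).max() < 1e-8


def test_linear_baseline_rejects_underdetermined_fit():
    rng = np.random.default_rng(11)
    pairs = CAPairs(g=rng.uniform(size=(5, 10)), h=rng.uniform(size=(5, 10)),
                    y=rng.uniform(size=(5, 10)))
    with pytest.raises(ValueError):
        linear_autoregressor_baseline(pairs)


def test_linear_baseline_is_deterministic():
    rng = np.random.default_rng(12)
    g = rng.uniform(0, 1, (100, 10))
    h = rng.uniform(0, 1, (100, 10))
    y = rng.uniform(0, 1, (100, 10))
    pairs = CAPairs(g=g, h=h, y=y)
    a = linear_autoregressor_baseline(pairs)
    b = linear_autoregressor_baseline(pairs)
    assert np.array_equal(a.values, b.values)


# ---------------------------------------------------------------------- #
# neural-model training (small smoke run; the full comparison lives in the
# acceptance suite)
# ---------------------------------------------------------------------- #
def test_ca_training_learns_the_synthesis_function(rule):
    # ten-step prediction of a chaotic lattice has an irreducible error
    # floor, so convergence is judged by the loss dropping toward it and by
    # the learned synthesis rates matching the ground truth on the data
    from netdistill.ca_benchmark import generate_training_data

    pairs = generate_training_data(rule, n_trajectories=6, n_steps=200,
                                   n_cells=16, seed=13)
    model, hist = train_ca_rnn(pairs, CATrainConfig(iterations=4000, seed=3,
                                                    batch_size=256))
    assert hist[-20:].mean() < hist[:5].mean() / 3
    scores = score_ca_links(model, pairs)
    assert scores.values.shape == (20, 10)
    truth = HillSynthesis(rule.topology, rule.params)
    fm = model(pairs.g, pairs.h)
    ft = truth(*pairs.raw_states()) / pairs.scale
    r = np.corrcoef(fm.ravel(), ft.ravel())[0, 1]
    assert r > 0.8
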