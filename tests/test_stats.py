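"""t-tests, BH-FDR, the evaluation grid, and relevance group statistics."""

import numpy as np
import pytest

from eeglrp import ClassEffect, CohortSpec, NetSpec, RunConfig, generate_cohort
from eeglrp.stats import (
    GridResult,
    benjamini_hochberg,
    compare_grid_cells,
    grid_cells,
    relevance_group_stats,
    run_grid,
    topography_frame,
    ttest_independent,
)


# -- t-test ------------------------------------------------------------------


def test_ttest_identical_samples_null():
    t, p = ttest_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0
    assert p == pytest.approx(1.0)


def test_ttest_antisymmetric_in_sample_order():
    a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
    t1, p1 = ttest_independent(a, b)
    t2, p2 = ttest_independent(b, a)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_ttest_matches_closed_form():
    """{1,2,3} vs {4,5,6}: pooled-variance textbook formula."""
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([4.0, 5.0, 6.0])
    t, p = ttest_independent(a, b)
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert t == pytest.approx(expected_t, rel=1e-12)
    from scipy.stats import t as tdist

    assert p == pytest.approx(2 * tdist.sf(abs(expected_t), df=4), rel=1e-12)


def test_ttest_degenerate_variance_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        ttest_independent([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError, match="2 observations"):
        ttest_independent([1.0], [2.0, 3.0])


# -- Benjamini-Hochberg ------------------------------------------------------


def test_bh_single_p_is_identity():
    np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])


def test_bh_flat_p_stays_flat():
    np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)


def test_bh_step_up_hand_example():
    """p = {.01,.02,.03,.04}: q_i = min over j>=i of p_j * 4 / j = .04 each."""
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
    )


def test_bh_permutation_equivariant():
    rng = np.random.default_rng(0)
    p = rng.random(15)
    perm = rng.permutation(15)
    q = benjamini_hochberg(p)
    q_perm = benjamini_hochberg(p[perm])
    np.testing.assert_allclose(q_perm, q[perm])


def test_bh_properties_and_validation():
    rng = np.random.default_rng(1)
    p = rng.random(30)
    q = benjamini_hochberg(p)
    assert np.all(q >= p - 1e-12)
    assert np.all(q <= 1.0)
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])
    with pytest.raises(ValueError):
        benjamini_hochberg([-0.1])


# -- evaluation grid ---------------------------------------------------------


def test_default_grid_is_80_cells():
    cells = grid_cells(RunConfig())
    assert len(cells) == 80
    ks = sorted({k for k, _ in cells})
    lengths = sorted({l for _, l in cells})
    assert ks == [1, 2, 3, 4, 5, 10, 15, 20, 25, 62]
    assert lengths == [10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0]


@pytest.fixture(scope="module")
def tiny_grid(small_montage, tiny_cohort, tiny_net):
    _, recs = tiny_cohort
    config = RunConfig(
        epochs=4,
        net=tiny_net,
        seed=3,
        channel_counts=(2, 8),
        data_lengths_s=(10.0,),
    )
    return run_grid(recs, config), config, recs


def test_grid_cell_count_conservation(tiny_grid):
    grid, config, _ = tiny_grid
    assert len(grid) == len(config.channel_counts) * len(config.data_lengths_s)


def test_grid_accuracy_recomputable_from_indicators(tiny_grid):
    grid, _, recs = tiny_grid
    for cell in grid:
        correct = [c for _, c in cell.correct]
        assert len(correct) == len(recs)
        assert cell.accuracy == pytest.approx(100.0 * np.mean(correct))


def test_grid_cell_matches_independent_loocv_rerun(tiny_grid, small_montage, tiny_net):
    """A full-montage cell equals a direct LOOCV at the same setting."""
    from eeglrp.net import loocv
    from eeglrp.preprocessing import segment

    grid, config, recs = tiny_grid
    cell = next(g for g in grid if g.n_channels == 8)
    sets = [segment(r, 10.0) for r in recs]
    _, metrics = loocv(sets, small_montage, config, net_spec=tiny_net)
    assert cell.accuracy == pytest.approx(metrics.accuracy)


def test_grid_rejects_overlong_data_length(small_montage, tiny_cohort, tiny_net):
    _, recs = tiny_cohort
    config = RunConfig(
        epochs=1, net=tiny_net, channel_counts=(8,), data_lengths_s=(60.0,)
    )
    with pytest.raises(ValueError, match="exceeds"):
        run_grid(recs, config)


# -- between-cell comparisons ------------------------------------------------


def cell(k, length, correct):
    correct = [(f"s{i}", c) for i, c in enumerate(correct)]
    acc = 100.0 * np.mean([c for _, c in correct])
    return GridResult(k, length, acc, acc, acc, tuple(correct))


def test_compare_cell_with_itself_flagged_not_different():
    g = cell(5, 60.0, [1, 0, 1, 1])
    df = compare_grid_cells([g, g])
    assert len(df) == 1
    assert df.loc[0, "t"] == 0.0
    assert df.loc[0, "p"] == pytest.approx(1.0)
    assert bool(df.loc[0, "not_different"])


def test_compare_three_cells_matches_bruteforce_bh():
    a = cell(1, 10.0, [1, 0, 0, 1, 0, 1])
    b = cell(2, 10.0, [1, 1, 1, 1, 0, 1])
    c = cell(3, 10.0, [0, 0, 1, 0, 0, 0])
    df = compare_grid_cells([a, b, c])
    assert len(df) == 3
    ps = df["p"].to_numpy()
    np.testing.assert_allclose(df["q"], benjamini_hochberg(ps))


def test_compare_requires_indicators():
    g = GridResult(1, 10.0, 50.0, 50.0, 50.0, ())
    with pytest.raises(ValueError, match="indicators"):
        compare_grid_cells([g, g])


# -- relevance group statistics ----------------------------------------------


def test_group_stats_identical_subjects_are_null():
    vec = np.array([0.5, 1.5, 2.0])
    rel = {f"s{i}": vec for i in range(6)}
    labels = {f"s{i}": i % 2 for i in range(6)}
    stats = relevance_group_stats(rel, labels, ("a", "b", "c"))
    assert all(s.t == 0.0 and s.p == pytest.approx(1.0) for s in stats)


def test_group_stats_normalisation_and_exclusion(caplog):
    rng = np.random.default_rng(0)
    rel = {f"s{i}": rng.random(4) for i in range(6)}
    rel["zero"] = np.zeros(4)
    labels = {sid: i % 2 for i, sid in enumerate(rel)}
    import logging

    with caplog.at_level(logging.WARNING):
        stats = relevance_group_stats(rel, labels, ("a", "b", "c", "d"))
    assert "zero" in caplog.text
    means = np.array([[s.mean_control, s.mean_patient] for s in stats])
    np.testing.assert_allclose(means.sum(axis=0), 1.0)  # columns are L1-normalised


def test_group_stats_localise_planted_effect(small_montage):
    """Oz band power (relevance proxy) gives Oz the smallest p in most seeds."""
    from scipy.signal import welch

    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        spec = CohortSpec(
            n_per_class=12,
            montage=small_montage,
            fs=100.0,
            duration=8.0,
            effects=(ClassEffect(band=(8, 12), channels=("Oz",), power_scale=3.0),),
            seed=300 + seed,
        )
        recs = generate_cohort(spec)
        rel, labels = {}, {}
        for r in recs:
            f, psd = welch(r.signal, fs=r.fs, nperseg=256)
            sel = (f >= 8) & (f <= 12)
            rel[r.subject_id] = psd[:, sel].mean(axis=1)
            labels[r.subject_id] = r.label
        stats = relevance_group_stats(rel, labels, small_montage.channel_names)
        smallest = min(stats, key=lambda s: s.p)
        hits += smallest.channel == "Oz"
    assert hits >= 8


def test_topography_frame_shape(small_montage):
    df = topography_frame(small_montage, np.arange(8.0))
    assert list(df.columns) == ["channel", "x", "y", "value"]
    assert len(df) == 8
    with pytest.raises(ValueError):
        topography_frame(small_montage, np.arange(7.0))
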