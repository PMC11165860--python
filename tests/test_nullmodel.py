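"""Richness/range-preserving randomization, accumulators, SES and p-values."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_instance
from phylohex.hexgrid import PresenceMatrix
from phylohex.nullmodel import (
    InfeasibleConstraintError,
    NullAccumulator,
    chunk_rng,
    rand_structured,
    run_nullmodel,
    significance,
    two_tailed_flags,
)


def _matrix(A, records=None):
    A = np.asarray(A, dtype=bool)
    n_cells, n_species = A.shape
    return PresenceMatrix(
        3,
        np.arange(1, n_cells + 1, dtype=np.uint64),
        np.arange(1, n_species + 1, dtype=np.int64),
        A,
        records if records is not None else A.sum(axis=1),
    )


def test_single_cell_matrix_randomization_is_identity():
    m = _matrix([[True, True, True]])
    out = rand_structured(m, np.random.default_rng(0))
    assert (out.A == m.A).all()


def test_ubiquitous_species_stays_everywhere():
    rng = np.random.default_rng(0)
    A = rng.random((6, 5)) < 0.4
    A[:, 0] = True  # species 1 occupies every cell
    A[0, :] = True  # and no species has an empty range
    m = _matrix(A)
    for seed in range(20):
        out = rand_structured(m, np.random.default_rng(seed))
        assert out.A[:, 0].all()


def test_marginals_preserved_over_many_draws():
    rng = np.random.default_rng(5)
    A = rng.random((10, 20)) < 0.3
    A |= ~A.any(axis=1)[:, None]
    keep = A.any(axis=0)
    m = _matrix(A[:, keep])
    richness = m.A.sum(axis=1)
    ranges = m.A.sum(axis=0)
    gen = np.random.default_rng(123)
    for _ in range(300):
        out = rand_structured(m, gen)
        assert (out.A.sum(axis=1) == richness).all()
        assert (out.A.sum(axis=0) == ranges).all()


def test_two_by_two_exhaustive_enumeration():
    """Cells with richness {2,1} and species ranges {2,1}: the only valid
    arrangement keeps the range-2 species in both cells and the range-1
    species in the richness-2 cell — every seed must reproduce it."""
    A = np.array([[True, True], [True, False]])
    m = _matrix(A)
    seen = set()
    for seed in range(500):
        out = rand_structured(m, np.random.default_rng(seed))
        seen.add(out.A.tobytes())
        assert (out.A.sum(axis=1) == [2, 1]).all()
        assert (out.A.sum(axis=0) == [2, 1]).all()
    assert seen == {A.tobytes()}


def test_constraint_groups_confine_species():
    # two groups of cells; species 1-3 live in group 0, species 4-6 in group 1
    A = np.zeros((6, 6), dtype=bool)
    A[:3, :3] = np.random.default_rng(1).random((3, 3)) < 0.7
    A[3:, 3:] = np.random.default_rng(2).random((3, 3)) < 0.7
    A |= ~A.any(axis=1)[:, None]
    m = _matrix(A)
    groups = np.array([0, 0, 0, 1, 1, 1])
    for seed in range(10):
        out = rand_structured(m, np.random.default_rng(seed), constraints=groups)
        assert not out.A[3:, :3].any() or not A[:3, :3].any()
        assert (out.A.sum(axis=0) == A.sum(axis=0)).all()
        assert (out.A.sum(axis=1) == A.sum(axis=1)).all()


def test_bad_constraint_shape_rejected():
    m = _matrix([[True, False], [True, True]])
    with pytest.raises(InfeasibleConstraintError):
        rand_structured(m, np.random.default_rng(0), constraints=np.array([0]))


def test_run_nullmodel_reproducible_and_chunk_merge():
    tree, matrix, tip_to_key, _ = random_instance(4)
    a1 = run_nullmodel(matrix, tree, 40, base_seed=9, chunks=1, tip_to_key=tip_to_key)
    a2 = run_nullmodel(matrix, tree, 40, base_seed=9, chunks=1, tip_to_key=tip_to_key)
    assert a1.n == a2.n == 40
    assert (a1.sum == a2.sum).all() and (a1.count_ge == a2.count_ge).all()
    s1 = significance(a1)
    s2 = significance(a2)
    pd.testing.assert_frame_equal(s1, s2)

    a4 = run_nullmodel(matrix, tree, 40, base_seed=9, chunks=4, tip_to_key=tip_to_key)
    assert a4.n == 40
    # different substreams, same distribution: means within Monte-Carlo noise
    m1 = a1.sum / a1.n
    m4 = a4.sum / a4.n
    sd = np.sqrt(np.maximum(a1.sumsq / a1.n - m1**2, 1e-12))
    assert (np.abs(m1 - m4) <= 5 * sd / np.sqrt(40) + 1e-9).mean() > 0.95


def test_richness_null_is_degenerate():
    """Richness is preserved by construction: zero variance, SES undefined."""
    tree, matrix, tip_to_key, _ = random_instance(6)
    acc = run_nullmodel(matrix, tree, 20, base_seed=1, tip_to_key=tip_to_key)
    sig = significance(acc)
    assert sig["richness_ses"].isna().all()
    assert (sig["richness_p_high"] == 1.0).all()
    assert (sig["richness_p_low"] == 1.0).all()


def _scalar_acc(obs, nulls):
    acc = NullAccumulator(
        metric_names=("x",),
        cells=np.array([1], dtype=np.uint64),
        observed=np.array([[obs]], dtype=float),
    )
    for v in nulls:
        acc.update(np.array([[v]], dtype=float))
    return acc


def test_add_one_rank_p_values():
    acc = _scalar_acc(5.0, [1.0, 2.0, 3.0, 4.0])
    sig = significance(acc)
    assert sig["x_p_high"].iloc[0] == pytest.approx(1 / 5)
    assert sig["x_p_low"].iloc[0] == pytest.approx(1.0)


def test_all_ties_give_unit_p_both_tails():
    acc = _scalar_acc(2.0, [2.0] * 10)
    sig = significance(acc)
    assert sig["x_p_high"].iloc[0] == 1.0
    assert sig["x_p_low"].iloc[0] == 1.0
    assert np.isnan(sig["x_ses"].iloc[0])


def test_p_value_bounds():
    acc = _scalar_acc(100.0, list(range(9)))
    sig = significance(acc)
    assert sig["x_p_high"].iloc[0] == pytest.approx(1 / 10)  # floor 1/(n+1)
    assert sig["x_p_low"].iloc[0] == 1.0


def test_chunk_rng_streams_differ():
    a = chunk_rng(7, 0).random(5)
    b = chunk_rng(7, 1).random(5)
    c = chunk_rng(7, 0).random(5)
    assert (a == c).all() and not (a == b).all()


def test_two_tailed_flags():
    sig = pd.DataFrame({"pd_p_p_high": [0.01, 0.5], "pd_p_p_low": [1.0, 0.5]})
    flags = two_tailed_flags(sig, "pd_p", alpha=0.05)
    assert flags.tolist() == [True, False]
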