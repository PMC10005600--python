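"""Chunked construction, single-step correction, and parallel dispatch."""

import numpy as np
import pytest

from chunkpbwt import (
    build_approx_state,
    build_state_at,
    check_state,
    correct_group,
    correct_state,
    initial_state,
    invert_prefix_array,
    long_matches,
    parallel_build_states,
    parallel_run,
    plan_chunks,
    sentinel_groups,
    set_maximal_matches,
)
from chunkpbwt.core import sequential_states
from chunkpbwt.parallel import _scan_sentinel_groups
from chunkpbwt.synthetic import generate_panel, random_panel

from conftest import panel_from_rows


# ---------------------------------------------------------------------------
# chunk planning and permutation inversion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "N,T,expected",
    [
        (100, 4, [0, 25, 50, 75, 100]),
        (10, 3, [0, 4, 7, 10]),  # remainder spread over leading chunks
        (7, 1, [0, 7]),
    ],
)
def test_plan_chunks_partitions_near_equally(N, T, expected):
    plan = plan_chunks(N, T)
    assert list(plan.boundaries) == expected
    sizes = [e - s for s, e in plan.ranges()]
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == N


@pytest.mark.parametrize("N,T", [(5, 6), (5, 0), (0, 1)])
def test_plan_chunks_rejects_bad_counts(N, T):
    with pytest.raises(ValueError):
        plan_chunks(N, T)


@pytest.mark.parametrize(
    "a,expected",
    [([0, 1, 2], [0, 1, 2]), ([2, 0, 1], [1, 2, 0]), ([1, 0], [1, 0])],
)
def test_invert_prefix_array(a, expected):
    inv = invert_prefix_array(np.array(a))
    assert inv.tolist() == expected
    assert inv[np.array(a)].tolist() == list(range(len(a)))


def test_invert_prefix_array_rejects_non_permutations():
    for bad in ([0, 0, 2], [0, 3, 1]):
        with pytest.raises(ValueError):
            invert_prefix_array(np.array(bad))


# ---------------------------------------------------------------------------
# approximate builds and sentinel groups
# ---------------------------------------------------------------------------


def test_first_chunk_build_is_exact():
    panel = random_panel(11, M=16, N=48, dup_rate=0.4)
    approx = build_approx_state(panel, 0, 30)
    assert approx.corrected  # sentinel array coincides with d_0
    assert build_state_at(panel, 30).a.tolist() == approx.a.tolist()
    assert build_state_at(panel, 30).d.tolist() == approx.d.tolist()


def test_identical_chunk_is_one_full_sentinel_group():
    panel = panel_from_rows([[0, 1, 1, 0]] * 5)
    approx = build_approx_state(panel, 1, 4)
    assert (approx.d[1:] == 1).all()
    assert sentinel_groups(approx) == [(0, 5)]


def test_distinct_chunk_has_no_sentinel_groups():
    panel = panel_from_rows([[0, 0], [0, 1], [1, 0], [1, 1]])
    approx = build_approx_state(panel, 0, 2)
    assert sentinel_groups(approx) == []


def test_planted_duplicate_pair_yields_sentinel_group():
    # group identical over [8, 24) straddles the boundary at 16, so the
    # chunk [16, 24) cannot distinguish its members
    panel = generate_panel(8, 32, dup_groups=[(2, 8, 24)],
                           mutation_rate_within_group=0.5, seed=5)
    approx = build_approx_state(panel, 16, 24)
    groups = sentinel_groups(approx)
    assert any(stop - start >= 2 for start, stop in groups)
    flagged = {int(approx.a[i]) for s, e in groups for i in range(s, e)}
    assert {0, 1} <= flagged


def test_build_approx_state_rejects_bad_ranges():
    panel = random_panel(0, M=4, N=10)
    for cs, ce in ((3, 3), (5, 2), (-1, 4), (0, 11)):
        with pytest.raises(ValueError):
            build_approx_state(panel, cs, ce)


# ---------------------------------------------------------------------------
# correction
# ---------------------------------------------------------------------------


def test_correct_group_hand_trace():
    # previous positions of the group members are looked up, sorted, and the
    # divergence window maxima replace the sentinels
    a_k = np.array([0, 2, 1], dtype=np.int64)
    d_k = np.array([9, 3, 9], dtype=np.int64)
    a_prev = np.array([2, 0, 1], dtype=np.int64)
    d_prev = np.array([3, 1, 2], dtype=np.int64)
    correct_group(a_k, d_k, 0, 2, a_prev, d_prev, invert_prefix_array(a_prev))
    assert a_k.tolist() == [2, 0, 1]  # group reordered to a_prev order
    assert d_k.tolist() == [9, 1, 9]  # d[start] untouched, d[1] = max(d_prev[1:2])


def test_correct_group_rejects_trivial_groups():
    arrs = [np.array([0, 1], dtype=np.int64) for _ in range(2)]
    prev = np.array([0, 1], dtype=np.int64)
    with pytest.raises(ValueError):
        correct_group(arrs[0], arrs[1], 0, 1, prev, prev, invert_prefix_array(prev))


def test_correct_state_validates_and_is_idempotent_on_chunk_zero():
    panel = random_panel(21, M=12, N=40, dup_rate=0.5)
    approx = build_approx_state(panel, 0, 20)
    before = (approx.a.copy(), approx.d.copy())
    stats = correct_state(approx, initial_state(panel.n_haplotypes))
    assert stats.groups == 0
    assert approx.a.tolist() == before[0].tolist()
    assert approx.d.tolist() == before[1].tolist()

    later = build_approx_state(panel, 20, 40)
    with pytest.raises(ValueError):
        correct_state(later, build_state_at(panel, 10))  # wrong anchor
    with pytest.raises(ValueError):
        correct_state(later, build_approx_state(panel, 10, 20))  # uncorrected prev


@pytest.mark.parametrize("seed", range(30))
def test_corrected_chunk_equals_sequential_build(seed):
    dup = [0.0, 0.4, 0.8][seed % 3]
    panel = random_panel(seed + 50, max_M=32, max_N=96, dup_rate=dup)
    N = panel.n_sites
    cs, ce = N // 3, N
    approx = build_approx_state(panel, cs, ce)
    correct_state(approx, build_state_at(panel, cs))
    assert approx.as_state() == build_state_at(panel, ce)
    assert check_state(panel, approx.as_state())


@pytest.mark.parametrize("seed", range(10))
def test_error_is_local_to_sentinel_groups(seed):
    """Before correction, divergences that escaped the sentinel are true,
    and indices outside the candidate groups carry true a and d values."""
    panel = random_panel(seed + 200, max_M=32, max_N=96, dup_rate=0.5)
    N, M = panel.n_sites, panel.n_haplotypes
    cs = N // 2
    approx = build_approx_state(panel, cs, N)
    truth = build_state_at(panel, N)
    free = approx.d > cs
    assert (approx.d[free] == truth.d[free]).all()
    outside = np.ones(M, dtype=bool)
    for s, e in _scan_sentinel_groups(approx.d, cs):
        outside[s:e] = False
    assert (approx.a[outside] == truth.a[outside]).all()
    assert (approx.d[outside] == truth.d[outside]).all()


@pytest.mark.parametrize("seed", range(10))
def test_correction_work_is_linear_in_M(seed):
    """Summed sorted-group sizes <= M; per-group window scans <= M."""
    panel = random_panel(seed + 300, max_M=48, max_N=64, dup_rate=0.8)
    N, M = panel.n_sites, panel.n_haplotypes
    cs = N // 2
    approx = build_approx_state(panel, cs, N)
    stats = correct_state(approx, build_state_at(panel, cs))
    assert stats.sorted_elements <= M
    assert stats.max_group_scan <= M
    assert sum(stats.group_sizes) == stats.sorted_elements
    assert sum(stats.group_scans) == stats.scan_lookups


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def test_parallel_build_states_matches_sequential_boundaries():
    panel = random_panel(77, M=24, N=90, dup_rate=0.5)
    for T in (1, 2, 3, 5, 8):
        states = parallel_build_states(panel, T)
        bounds = plan_chunks(panel.n_sites, T).boundaries[1:]
        truth = sequential_states(panel, bounds)
        assert len(states) == T
        for got, want in zip(states, truth):
            assert got == want
            assert check_state(panel, got)


def test_parallel_build_identical_panel_divergences_are_zero():
    panel = panel_from_rows([[0, 1, 0, 1, 1, 0, 1, 0]] * 6)
    for state in parallel_build_states(panel, 4):
        assert (state.d[1:] == 0).all()


def test_worker_count_does_not_change_results():
    panel = random_panel(88, M=20, N=64, dup_rate=0.4)
    serial = parallel_build_states(panel, 4, workers=1)
    pooled = parallel_build_states(panel, 4, workers=3)
    assert all(a == b for a, b in zip(serial, pooled))
    assert parallel_run(panel, 4, "long", workers=3, L=2) == parallel_run(
        panel, 4, "long", workers=1, L=2
    )


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("T", [2, 3, 4, 8])
def test_parallel_run_equals_sequential_run(seed, T):
    panel = random_panel(seed + 400, max_M=24, max_N=80, dup_rate=0.4)
    if T > panel.n_sites:
        pytest.skip("more chunks than loci")
    assert parallel_run(panel, T, "long", L=2) == long_matches(panel, 2)
    assert parallel_run(panel, T, "setmax") == set_maximal_matches(panel)


def test_parallel_run_validates_mode_and_length():
    panel = random_panel(1, M=8, N=20)
    with pytest.raises(ValueError):
        parallel_run(panel, 2, "frequent")
    with pytest.raises(ValueError):
        parallel_run(panel, 2, "long")  # L missing
    assert parallel_run(panel, 2, "long", L=panel.n_sites + 1) == set()
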