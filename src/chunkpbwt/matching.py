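"""Haplotype match reporting over PBWT sweeps.

Two report modes are supported, both running inside a single left-to-right
sweep that maintains ``a_k``/``d_k`` via the radix-sort step:

* **long matches** — every maximal pairwise match of length >= L;
* **set-maximal matches** — for every haplotype h, the matches to h whose
  locus interval is not strictly contained in any other match involving h.

A match is *reported at the locus where it terminates*: the first locus at
which the two haplotypes disagree, or the end of the panel.  Because each
match terminates exactly once, splitting ``[0, N]`` into consecutive locus
ranges (each seeded with the correct boundary state) partitions the output
— the property the chunk-parallel driver in :mod:`chunkpbwt.parallel`
relies on.  Matches still open at ``k = N`` are flushed by the range whose
end is ``N``.

Quadratic all-versus-all oracles (:func:`brute_force_long_matches`,
:func:`brute_force_set_maximal`) implement the same contracts by direct
enumeration and serve as the independent ground truth in the test-suite.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Optional

import numpy as np

from .core import HaplotypePanel, PBWTState, _advance_arrays, initial_state

__all__ = [
    "MatchRecord",
    "long_matches",
    "set_maximal_matches",
    "brute_force_long_matches",
    "brute_force_set_maximal",
]


class MatchRecord(NamedTuple):
    """A maximal haplotype match over the half-open locus interval [start, end)."""

    hap_i: int
    hap_j: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _rec(h1: int, h2: int, start: int, end: int) -> MatchRecord:
    if h1 > h2:
        h1, h2 = h2, h1
    return MatchRecord(int(h1), int(h2), int(start), int(end))


# ---------------------------------------------------------------------------
# per-locus reporters (operate on the state a_k, d_k and the alleles at k,
# given in sorted order; vals is None at the end-of-panel flush, where every
# still-open match terminates)
# ---------------------------------------------------------------------------


def _report_long_at(
    k: int,
    a: np.ndarray,
    d: np.ndarray,
    vals: Optional[np.ndarray],
    L: int,
    sink: set,
) -> None:
    """Report matches of length >= L ending at locus k.

    Positions with ``d > k - L`` break the sorted order into blocks; inside
    a block every adjacent divergence is <= k - L, so every pair matches
    over at least L loci ending at k.  A pair terminates at k when its two
    alleles differ there (or unconditionally at the flush).  The match start
    of a pair at sorted positions p < q is ``max(d[p+1..q])``, accumulated
    with a running maximum while p walks down.
    """
    M = a.shape[0]
    thresh = k - L
    inside = d <= thresh  # True where the match with the predecessor is long enough
    if not inside.any():
        return
    breaks = np.flatnonzero(~inside)  # includes 0: d[0] = k > k - L for L >= 1
    bounds = np.append(breaks, M)
    for bstart, bend in zip(bounds[:-1], bounds[1:]):
        if bend - bstart < 2:
            continue
        if vals is not None:
            nz = int(vals[bstart:bend].sum())
            if nz == 0 or nz == bend - bstart:
                continue  # no pair terminates here
        for q in range(bstart + 1, bend):
            run = int(d[q])
            vq = None if vals is None else vals[q]
            for p in range(q - 1, bstart - 1, -1):
                if vals is None or vals[p] != vq:
                    sink.add(_rec(a[p], a[q], run, k))
                if p > bstart:
                    run = max(run, int(d[p]))


def _report_setmax_at(
    k: int,
    a: np.ndarray,
    d: np.ndarray,
    vals: Optional[np.ndarray],
    sink: set,
) -> None:
    """Report set-maximal matches ending at locus k.

    For the haplotype at sorted position i the longest current matches start
    at ``min(d[i], d[i+1])`` and lie among its sorted neighbours.  Scanning
    outward over every neighbour matching from that locus: if any of them
    carries the same allele at k the match extends past k and nothing is
    set-maximal for i here; otherwise all neighbour matches on the winning
    side(s) terminate at k and are reported.
    """
    M = a.shape[0]
    for i in range(M):
        dn_p = int(d[i])  # divergence to the predecessor (d[0] == k: none)
        dn_s = int(d[i + 1]) if i + 1 < M else k
        if min(dn_p, dn_s) >= k:
            continue  # no nonempty neighbour match
        m = i - 1
        n = i + 1
        extended = False
        if dn_p <= dn_s:
            while m >= 0 and d[m + 1] <= dn_p:
                if vals is not None and vals[m] == vals[i]:
                    extended = True
                    break
                m -= 1
        if not extended and dn_s <= dn_p:
            while n < M and d[n] <= dn_s:
                if vals is not None and vals[n] == vals[i]:
                    extended = True
                    break
                n += 1
        if extended:
            continue
        if dn_p <= dn_s:
            for j in range(m + 1, i):
                sink.add(_rec(a[j], a[i], dn_p, k))
        if dn_s <= dn_p:
            for j in range(i + 1, n):
                sink.add(_rec(a[i], a[j], dn_s, k))


# ---------------------------------------------------------------------------
# sweep driver
# ---------------------------------------------------------------------------


def _match_sweep(
    alleles: np.ndarray,
    col0: int,
    ks: int,
    ke: int,
    N: int,
    a: np.ndarray,
    d: np.ndarray,
    reporter: Callable[..., None],
) -> set:
    """Run a reporter over loci [ks, ke), flushing at N when ke == N.

    ``alleles`` may be a column slice of the full panel; ``col0`` is the
    absolute locus of its first column.  ``a``/``d`` must be the correct
    global state at ``ks``.
    """
    sink: set = set()
    a = a.copy()
    d = d.copy()
    for k in range(ks, ke):
        column = alleles[:, k - col0]
        reporter(k, a, d, column[a], sink)
        a, d = _advance_arrays(k, a, d, column)
    if ke == N:
        reporter(N, a, d, None, sink)
    return sink


def _check_sweep_args(
    panel: HaplotypePanel, k_range: tuple[int, int], start_state: Optional[PBWTState]
) -> tuple[int, int, PBWTState]:
    ks, ke = int(k_range[0]), int(k_range[1])
    if not 0 <= ks <= ke <= panel.n_sites:
        raise ValueError(f"k_range {k_range} outside [0, {panel.n_sites}]")
    if start_state is None:
        if ks != 0:
            raise ValueError("start_state required when the range does not start at 0")
        start_state = initial_state(panel.n_haplotypes)
    if start_state.k != ks:
        raise ValueError(f"start_state.k={start_state.k} != range start {ks}")
    if start_state.n_haplotypes != panel.n_haplotypes:
        raise ValueError("start_state size does not match the panel")
    return ks, ke, start_state


def long_matches(
    panel: HaplotypePanel,
    L: int,
    k_range: Optional[tuple[int, int]] = None,
    start_state: Optional[PBWTState] = None,
) -> set[MatchRecord]:
    """All maximal matches of length >= L whose end locus lies in ``k_range``.

    ``k_range`` defaults to the whole panel ``(0, N)``; a match still open at
    the end of the panel is owned by the range whose end equals N.  The
    minimum length bound is inclusive (a match of exactly L loci is
    reported).
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if k_range is None:
        k_range = (0, panel.n_sites)
    ks, ke, state = _check_sweep_args(panel, k_range, start_state)

    def reporter(k, a, d, vals, sink):
        _report_long_at(k, a, d, vals, L, sink)

    return _match_sweep(panel.alleles, 0, ks, ke, panel.n_sites, state.a, state.d, reporter)


def set_maximal_matches(
    panel: HaplotypePanel,
    k_range: Optional[tuple[int, int]] = None,
    start_state: Optional[PBWTState] = None,
) -> set[MatchRecord]:
    """Set-maximal matches whose end locus lies in ``k_range``.

    A match (h, j, s, e) is set-maximal for h when no other match involving
    h covers a strictly larger interval containing [s, e).  Ties — several
    partners j over the same maximal interval — are all reported.
    """
    if k_range is None:
        k_range = (0, panel.n_sites)
    ks, ke, state = _check_sweep_args(panel, k_range, start_state)
    return _match_sweep(
        panel.alleles, 0, ks, ke, panel.n_sites, state.a, state.d, _report_setmax_at
    )


# ---------------------------------------------------------------------------
# quadratic oracles
# ---------------------------------------------------------------------------


def _maximal_runs(x: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open intervals over which the two allele rows agree."""
    eq = (x == y).astype(np.int8)
    padded = np.concatenate(([0], eq, [0]))
    step = np.diff(padded)
    starts = np.flatnonzero(step == 1)
    ends = np.flatnonzero(step == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def brute_force_long_matches(panel: HaplotypePanel, L: int) -> set[MatchRecord]:
    """All-pairs O(M^2 N) scan for maximal shared runs of length >= L."""
    out: set[MatchRecord] = set()
    X = panel.alleles
    M = panel.n_haplotypes
    for i in range(M):
        for j in range(i + 1, M):
            for s, e in _maximal_runs(X[i], X[j]):
                if e - s >= L:
                    out.add(_rec(i, j, s, e))
    return out


def brute_force_set_maximal(panel: HaplotypePanel) -> set[MatchRecord]:
    """Direct application of the set-maximal definition per haplotype."""
    out: set[MatchRecord] = set()
    X = panel.alleles
    M = panel.n_haplotypes
    runs = {}
    for i in range(M):
        for j in range(i + 1, M):
            runs[(i, j)] = _maximal_runs(X[i], X[j])
    for h in range(M):
        cands: list[tuple[int, int, int]] = []
        for j in range(M):
            if j == h:
                continue
            key = (h, j) if h < j else (j, h)
            cands.extend((s, e, j) for s, e in runs[key])
        for s, e, j in cands:
            contained = any(
                s2 <= s and e <= e2 and (s2, e2) != (s, e) for s2, e2, _ in cands
            )
            if not contained:
                out.add(_rec(h, j, s, e))
    return out
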