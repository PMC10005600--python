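"""Sequential positional Burrows-Wheeler transform (PBWT) construction.

The PBWT reorders the M haplotypes of a phased, biallelic panel at every
locus k so that haplotypes with identical reverse prefixes (the alleles at
loci 0..k-1, compared right-to-left) become adjacent.  Two arrays carry the
whole structure:

* the positional prefix array ``a_k`` — the permutation listing haplotype
  ids in non-decreasing colexicographic order of their reverse prefixes;
  equivalently, the order produced by a column-wise stable radix sort of
  the first k panel columns;
* the divergence array ``d_k`` — ``d_k[i]`` is the smallest locus j such
  that the haplotypes at sorted positions i and i-1 agree on every locus in
  [j, k); i.e. the start of their current match.  ``d_k[0] = k`` by
  convention (no predecessor, empty match).

Advancing from locus k to k+1 is a stable two-way partition of ``a_k`` by
the allele at locus k, with the new divergences obtained from two running
maxima (one per allele class) that reset after each emitted entry.  This
module provides that step, the fold that builds the state at any locus, and
a quadratic brute-force validity oracle used throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HaplotypePanel",
    "PBWTState",
    "initial_state",
    "advance",
    "build_state_at",
    "check_state",
]


@dataclass
class HaplotypePanel:
    """A phased, biallelic haplotype panel.

    Parameters
    ----------
    alleles
        ``(M, N)`` matrix of 0/1 alleles; rows are haplotypes, columns are
        loci.  Stored as a C-contiguous ``uint8`` array.
    site_ids
        Optional per-locus metadata (e.g. :class:`~chunkpbwt.panel_io.SiteRecord`).
    sample_ids
        Optional sample labels; haplotypes ``2s`` and ``2s + 1`` are the two
        phased alleles of sample ``s``.
    """

    alleles: np.ndarray
    site_ids: Optional[list] = None
    sample_ids: Optional[list] = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles)
        if arr.ndim != 2:
            raise ValueError(f"alleles must be 2-D (M x N), got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("panel needs at least one haplotype (M >= 1)")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("alleles must be 0 or 1 (biallelic, no missing data)")
        self.alleles = np.ascontiguousarray(arr, dtype=np.uint8)
        if self.site_ids is not None and len(self.site_ids) != self.n_sites:
            raise ValueError("site_ids length must equal the number of loci")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass
class PBWTState:
    """PBWT state at locus ``k``: prefix array ``a`` and divergence array ``d``."""

    k: int
    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        if self.a.shape != self.d.shape or self.a.ndim != 1:
            raise ValueError("a and d must be 1-D arrays of equal length")

    @property
    def n_haplotypes(self) -> int:
        return self.a.shape[0]

    def copy(self) -> "PBWTState":
        return PBWTState(self.k, self.a.copy(), self.d.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PBWTState):
            return NotImplemented
        return (
            self.k == other.k
            and np.array_equal(self.a, other.a)
            and np.array_equal(self.d, other.d)
        )


def initial_state(M: int) -> PBWTState:
    """State before any locus: ``a_0 = [0..M-1]``, ``d_0 = [0]*M``."""
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    return PBWTState(0, np.arange(M, dtype=np.int64), np.zeros(M, dtype=np.int64))


def _advance_arrays(
    k: int, a: np.ndarray, d: np.ndarray, column: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One radix-sort step: stable 0/1 partition of ``a`` with new divergences.

    ``column`` is indexed by haplotype id.  The two per-class running maxima
    start at ``k + 1`` and reset to 0 after each emitted entry, so the new
    divergence of each entry is the maximum of ``d`` over the gap since the
    previous same-class entry (or ``k + 1`` for the class head).  Computed
    with segmented maxima (``np.maximum.reduceat``) instead of a scalar scan.
    """
    vals = column[a]
    idx0 = np.flatnonzero(vals == 0)
    idx1 = np.flatnonzero(vals)
    new_a = np.concatenate((a[idx0], a[idx1]))
    new_d = np.empty_like(d)
    pos = 0
    for idx in (idx0, idx1):
        n = idx.size
        if n == 0:
            continue
        seg = new_d[pos : pos + n]
        seg[0] = k + 1  # running maximum starts above every d value (d <= k)
        if n > 1:
            starts = idx[:-1] + 1
            seg[1:] = np.maximum.reduceat(d[: idx[-1] + 1], starts)
        pos += n
    return new_a, new_d


def _check_column(column: np.ndarray, M: int) -> np.ndarray:
    col = np.asarray(column)
    if col.shape != (M,):
        raise ValueError(f"column has length {col.shape}, expected ({M},)")
    if col.size and not np.isin(col, (0, 1)).all():
        raise ValueError("column contains non-binary alleles")
    return np.ascontiguousarray(col, dtype=np.uint8)


def advance(state: PBWTState, column: Sequence[int]) -> PBWTState:
    """Return the state at ``k + 1`` given the alleles at locus ``k``.

    Pure: the input state is not modified.  ``column[h]`` is the allele of
    haplotype ``h`` (indexed by haplotype id, not by sorted position); the
    gather into ``a_k`` order happens internally.
    """
    col = _check_column(column, state.n_haplotypes)
    new_a, new_d = _advance_arrays(state.k, state.a, state.d, col)
    return PBWTState(state.k + 1, new_a, new_d)


def build_state_at(panel: HaplotypePanel, k: int) -> PBWTState:
    """Sequential ground truth: fold :func:`advance` over columns ``0..k-1``."""
    if not 0 <= k <= panel.n_sites:
        raise ValueError(f"k={k} outside [0, {panel.n_sites}]")
    state = initial_state(panel.n_haplotypes)
    a, d = state.a, state.d
    alleles = panel.alleles
    for j in range(k):
        a, d = _advance_arrays(j, a, d, alleles[:, j])
    return PBWTState(k, a, d)


def sequential_states(panel: HaplotypePanel, at: Sequence[int]) -> list[PBWTState]:
    """States at each locus in the ascending list ``at``, from one sweep."""
    ks = list(at)
    if any(k2 < k1 for k1, k2 in zip(ks, ks[1:])):
        raise ValueError("loci must be ascending")
    if ks and not (0 <= ks[0] and ks[-1] <= panel.n_sites):
        raise ValueError("locus outside [0, N]")
    out: list[PBWTState] = []
    state = initial_state(panel.n_haplotypes)
    a, d = state.a, state.d
    pos = 0
    for k in ks:
        while pos < k:
            a, d = _advance_arrays(pos, a, d, panel.alleles[:, pos])
            pos += 1
        out.append(PBWTState(k, a.copy(), d.copy()))
    return out


def check_state(panel: HaplotypePanel, state: PBWTState) -> bool:
    """Brute-force validity oracle (quadratic; tests only).

    Verifies, by direct string comparison of reverse prefixes, that ``a`` is
    a permutation in non-decreasing colexicographic order and that every
    ``d[i]`` equals the true divergence of the haplotypes at sorted
    positions i and i-1 (with ``d[0] == k``).
    """
    k, M = state.k, panel.n_haplotypes
    if not 0 <= k <= panel.n_sites:
        return False
    if sorted(state.a.tolist()) != list(range(M)):
        return False
    prefix = panel.alleles[:, :k]
    rev = [tuple(prefix[h][::-1]) for h in range(M)]
    order = state.a.tolist()
    for i in range(1, M):
        if rev[order[i]] < rev[order[i - 1]]:
            return False
    if state.d[0] != k:
        return False
    for i in range(1, M):
        x, y = prefix[order[i]], prefix[order[i - 1]]
        j = k
        while j > 0 and x[j - 1] == y[j - 1]:
            j -= 1
        if state.d[i] != j:
            return False
    return True
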