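"""Seeded haplotype-panel generator with planted duplicate structure.

The correction path of the chunk-parallel build only fires where haplotypes
are identical over an entire chunk, so the generator's central knob is a
list of *duplicate groups*: blocks of haplotypes forced identical over a
chosen locus span (optionally perturbed outside it).  Background haplotypes
are i.i.d. Bernoulli per site with frequencies drawn uniformly from
[0.05, 0.5] by default — low enough diversity to produce realistic short
shared runs without monomorphic columns dominating.

These panels emulate allele-frequency structure and planted identity, not
linkage disequilibrium or genealogy; they exercise every code path of the
construction and correction algorithms, which are combinatorial and make no
distributional assumptions about the panel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .core import HaplotypePanel

__all__ = ["generate_panel", "random_panel", "generate_vcf_fixture"]

FreqSpec = Union[float, tuple[float, float], Sequence[float]]


def _site_frequencies(rng: np.random.Generator, N: int, spec: FreqSpec) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 2:
        lo, hi = spec
        return rng.uniform(lo, hi, size=N)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        arr = np.full(N, float(arr))
    if arr.shape != (N,):
        raise ValueError("allele_freq must be a scalar, a (lo, hi) pair, or length-N")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return arr


def generate_panel(
    M: int,
    N: int,
    allele_freq: FreqSpec = (0.05, 0.5),
    dup_groups: Sequence[tuple[int, int, int]] = (),
    mutation_rate_within_group: float = 0.0,
    seed: int = 0,
) -> HaplotypePanel:
    """Generate an M x N binary panel, deterministic for a given seed.

    ``dup_groups`` is a list of ``(group_size, span_start, span_end)``
    triples; each group occupies the next ``group_size`` rows, copies one
    template haplotype, and is left exactly identical over
    ``[span_start, span_end)``.  Outside the span each member is perturbed
    by flipping alleles independently at ``mutation_rate_within_group``.
    Rows not claimed by a group are i.i.d. Bernoulli per site.
    """
    if M < 1 or N < 0:
        raise ValueError("need M >= 1 and N >= 0")
    if not 0.0 <= mutation_rate_within_group <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    total = sum(g[0] for g in dup_groups)
    if total > M:
        raise ValueError(f"duplicate groups need {total} haplotypes, panel has {M}")
    for size, s, e in dup_groups:
        if size < 1:
            raise ValueError(f"group size must be >= 1, got {size}")
        if not 0 <= s <= e <= N:
            raise ValueError(f"group span [{s}, {e}) outside [0, {N})")
    rng = np.random.default_rng(seed)
    freqs = _site_frequencies(rng, N, allele_freq)
    alleles = (rng.random((M, N)) < freqs).astype(np.uint8)
    row = 0
    for size, s, e in dup_groups:
        template = alleles[row].copy()
        for r in range(row, row + size):
            alleles[r] = template
            if mutation_rate_within_group > 0.0:
                flips = rng.random(N) < mutation_rate_within_group
                flips[s:e] = False
                alleles[r] ^= flips.astype(np.uint8)
        row += size
    return HaplotypePanel(alleles)


def random_panel(
    seed: int,
    M: int | None = None,
    N: int | None = None,
    dup_rate: float = 0.0,
    max_M: int = 64,
    max_N: int = 256,
) -> HaplotypePanel:
    """Random test panel with ~``dup_rate`` of haplotypes in duplicate groups.

    Sizes are sampled from the seed when not given (M in [2, max_M], N in
    [8, max_N]).  Groups mix full-length and partial spans so that planted
    identity both crosses and stays inside chunk boundaries.
    """
    rng = np.random.default_rng(seed)
    if M is None:
        M = int(rng.integers(2, max_M + 1))
    if N is None:
        N = int(rng.integers(8, max_N + 1))
    groups: list[tuple[int, int, int]] = []
    budget = int(round(dup_rate * M))
    while budget >= 2:
        size = int(rng.integers(2, min(5, budget) + 1))
        if rng.random() < 0.5 or N < 2:
            span = (0, N)
        else:
            s = int(rng.integers(0, N - 1))
            e = int(rng.integers(s + 1, N + 1))
            span = (s, e)
        groups.append((size, span[0], span[1]))
        budget -= size
    return generate_panel(
        M,
        N,
        dup_groups=groups,
        mutation_rate_within_group=0.1 if groups else 0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_vcf_fixture(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a minimal phased VCF realizing the panel exactly.

    Consecutive haplotype pairs become one diploid sample, so M must be
    even.  Synthetic CHROM/POS/REF/ALT metadata is used unless the panel
    carries site records.  ``read_vcf`` inverts the file exactly.
    """
    M, N = panel.n_haplotypes, panel.n_sites
    if M % 2:
        raise ValueError("VCF output needs an even number of haplotypes (diploid)")
    n_samples = M // 2
    samples = panel.sample_ids or [f"S{i}" for i in range(n_samples)]
    if len(samples) != n_samples:
        raise ValueError("sample_ids length must be M/2")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={max(N, 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(N):
            if panel.site_ids:
                site = panel.site_ids[j]
                meta = (site.chrom, site.pos, site.id, site.ref, site.alt)
            else:
                meta = ("1", j + 1, f"site{j}", "A", "G")
            gts = "\t".join(
                f"{panel.alleles[2 * s, j]}|{panel.alleles[2 * s + 1, j]}"
                for s in range(n_samples)
            )
            fh.write(f"{meta[0]}\t{meta[1]}\t{meta[2]}\t{meta[3]}\t{meta[4]}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
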