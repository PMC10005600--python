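"""Readers and writers: phased VCF, 0/1 matrix text, match TSV, checkpoints.

Coordinate conventions: internal loci are 0-based column indices; the VCF
POS field is carried only as metadata.  Match TSVs are 0-based, half-open.
All formats hold integers only, so every round-trip is exact.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .core import HaplotypePanel, PBWTState
from .matching import MatchRecord

__all__ = [
    "SiteRecord",
    "PanelFormatError",
    "EmptyPanelError",
    "read_vcf",
    "read_matrix",
    "write_matrix",
    "write_matches",
    "read_matches",
    "save_state",
    "load_state",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class PanelFormatError(ValueError):
    """Malformed or unsupported input file."""


class EmptyPanelError(PanelFormatError):
    """No usable haplotype data in the input."""


@dataclass(frozen=True)
class SiteRecord:
    """Metadata for one biallelic site."""

    chrom: str
    pos: int  # 1-based VCF coordinate
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: PathLike, strict: bool = True) -> HaplotypePanel:
    """Load a phased, biallelic VCF/VCF.gz into a haplotype panel.

    Haplotypes ``2s`` and ``2s+1`` are sample ``s``'s two alleles in VCF
    order, so M = 2 x sample count.  Sites with more than one ALT allele, a
    missing allele, or an unphased separator are rejected in strict mode
    and skipped (with a logged count) in lenient mode.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise EmptyPanelError(f"{path}: VCF has no samples")
    columns: list[list[int]] = []
    sites: list[SiteRecord] = []
    skipped = 0
    for variant in vcf:
        reason = None
        if len(variant.ALT) != 1:
            reason = "multiallelic or ALT-less site"
        column: list[int] = []
        if reason is None:
            for g in variant.genotypes:
                if len(g) != 3:
                    reason = "non-diploid genotype"
                    break
                h1, h2, phased = g[0], g[1], g[2]
                if h1 < 0 or h2 < 0:
                    reason = "missing allele"
                    break
                if not phased:
                    reason = "unphased genotype"
                    break
                column.append(int(h1))
                column.append(int(h2))
        if reason is not None:
            if strict:
                raise PanelFormatError(
                    f"{path}: {reason} at {variant.CHROM}:{variant.POS}"
                )
            skipped += 1
            continue
        columns.append(column)
        sites.append(
            SiteRecord(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                id=str(variant.ID) if variant.ID else ".",
                ref=str(variant.REF),
                alt=str(variant.ALT[0]),
            )
        )
    if skipped:
        logger.info("read_vcf: skipped %d unusable site(s) in %s", skipped, path)
    if not columns:
        raise EmptyPanelError(f"{path}: no usable biallelic phased sites")
    alleles = np.array(columns, dtype=np.uint8).T  # sites x haps -> haps x sites
    return HaplotypePanel(alleles, site_ids=sites, sample_ids=samples)


# ---------------------------------------------------------------------------
# matrix text
# ---------------------------------------------------------------------------


def read_matrix(path: PathLike) -> HaplotypePanel:
    """Read a plain-text panel: one haplotype per line, characters 0/1."""
    lines = Path(path).read_text().splitlines()
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise EmptyPanelError(f"{path}: empty matrix file")
    width = len(lines[0])
    rows = []
    for ln, line in enumerate(lines, start=1):
        if len(line) != width:
            raise PanelFormatError(f"{path}:{ln}: ragged line")
        if line.strip("01"):
            raise PanelFormatError(f"{path}:{ln}: characters other than 0/1")
        rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    return HaplotypePanel(np.array(rows, dtype=np.uint8))


def write_matrix(panel: HaplotypePanel, path: PathLike) -> None:
    with open(path, "w") as fh:
        for row in panel.alleles:
            fh.write("".join("1" if x else "0" for x in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# match TSV
# ---------------------------------------------------------------------------

_MATCH_COLUMNS = ["hap_i", "hap_j", "start", "end", "length"]


def write_matches(records: Iterable[MatchRecord], path: PathLike) -> None:
    """Write matches as TSV, canonically sorted by (start, hap_i, hap_j).

    The sort makes the file identical regardless of chunk count or worker
    scheduling.
    """
    rows = sorted(records, key=lambda r: (r.start, r.hap_i, r.hap_j))
    with open(path, "w") as fh:
        fh.write("# haplotype match report; loci are 0-based, intervals half-open [start, end)\n")
        fh.write("\t".join(_MATCH_COLUMNS) + "\n")
        for r in rows:
            fh.write(f"{r.hap_i}\t{r.hap_j}\t{r.start}\t{r.end}\t{r.end - r.start}\n")


def read_matches(path: PathLike) -> set[MatchRecord]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype="int64")
    except (ValueError, pd.errors.ParserError) as exc:
        raise PanelFormatError(f"{path}: malformed match TSV ({exc})") from exc
    if list(df.columns) != _MATCH_COLUMNS:
        raise PanelFormatError(f"{path}: unexpected columns {list(df.columns)}")
    if ((df["end"] - df["start"]) != df["length"]).any():
        raise PanelFormatError(f"{path}: inconsistent length column")
    return {
        MatchRecord(int(r.hap_i), int(r.hap_j), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# state checkpoints
# ---------------------------------------------------------------------------

_MAGIC = b"PBWTCKP1"
_VERSION = 1
_HEADER = struct.Struct("<8sIQQQ")  # magic, version, M, N, k


def save_state(state: PBWTState, path: PathLike, n_sites: int = 0) -> None:
    """Serialize a state as a little-endian binary checkpoint.

    Layout: header ``{magic, version, M, N, k}`` followed by the ``a`` then
    ``d`` arrays as 64-bit little-endian integers.  ``n_sites`` (N) is
    panel metadata; pass 0 when unknown.
    """
    M = state.n_haplotypes
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, M, n_sites, state.k))
        fh.write(np.ascontiguousarray(state.a, dtype="<i8").tobytes())
        fh.write(np.ascontiguousarray(state.d, dtype="<i8").tobytes())


def load_state(path: PathLike) -> PBWTState:
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER.size:
        raise PanelFormatError(f"{path}: truncated checkpoint header")
    magic, version, M, _n_sites, k = _HEADER.unpack_from(blob)
    if magic != _MAGIC:
        raise PanelFormatError(f"{path}: bad magic {magic!r}")
    if version != _VERSION:
        raise PanelFormatError(f"{path}: unsupported version {version}")
    expected = _HEADER.size + 2 * 8 * M
    if len(blob) != expected:
        raise PanelFormatError(
            f"{path}: truncated checkpoint ({len(blob)} bytes, expected {expected})"
        )
    a = np.frombuffer(blob, dtype="<i8", count=M, offset=_HEADER.size).astype(np.int64)
    d = np.frombuffer(blob, dtype="<i8", count=M, offset=_HEADER.size + 8 * M).astype(
        np.int64
    )
    return PBWTState(int(k), a, d)
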