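"""Pairwise alignment helpers shared across the pipeline.

Two engines compute the same quantities:

* ``edlib`` — unit-cost global alignment (Levenshtein path).  Fast enough to
  build distance matrices over thousands of amplicon fragments; the default.
* ``blosum`` — Biopython global alignment with BLOSUM62 scoring and affine
  gaps, for users who prefer similarity-scored alignment.

Both report the fraction of differing aligned columns (p-distance) and the
fraction of identical columns (identity), counted over aligned columns with
terminal gap columns excluded.  Internal gap columns count as differences.
"""

from __future__ import annotations

import functools
import re

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _column_counts(ops: list[tuple[int, str]]) -> tuple[int, int]:
    """(aligned columns, differing columns), terminal indel runs excluded."""
    # trim leading/trailing runs of pure insertion/deletion (terminal gaps)
    start, end = 0, len(ops)
    while start < end and ops[start][1] in "ID":
        start += 1
    while end > start and ops[end - 1][1] in "ID":
        end -= 1
    cols = diffs = 0
    for n, op in ops[start:end]:
        cols += n
        if op != "=":
            diffs += n
    return cols, diffs


@functools.lru_cache(maxsize=200_000)
def _edlib_path(a: str, b: str) -> tuple[int, int]:
    res = edlib.align(a, b, mode="NW", task="path")
    return _column_counts(_cigar_ops(res["cigar"]))


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (no path; cheapest comparison)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@functools.lru_cache(maxsize=8)
def _blosum_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # terminal gaps are free so the trimmed-column convention is respected
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def _blosum_columns(a: str, b: str) -> tuple[int, int]:
    aln = _blosum_aligner().align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    both = [i for i, (x, y) in enumerate(zip(ga, gb)) if x != "-" and y != "-"]
    if not both:
        return 0, 0
    lo, hi = both[0], both[-1] + 1  # trim terminal gap runs
    cols = hi - lo
    diffs = sum(1 for x, y in zip(ga[lo:hi], gb[lo:hi]) if x != y or x == "-")
    return cols, diffs


def aligned_columns(a: str, b: str, engine: str = "edlib") -> tuple[int, int]:
    """Return (aligned columns, differing columns) for a global alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a > b:  # canonical order: co-optimal paths would otherwise break symmetry
        a, b = b, a
    if engine == "edlib":
        return _edlib_path(a, b)
    if engine == "blosum":
        return _blosum_columns(a, b)
    raise ValueError(f"unknown alignment engine: {engine!r}")


def p_distance(a: str, b: str, engine: str = "edlib") -> float:
    """Fraction of differing aligned columns (terminal gaps excluded)."""
    cols, diffs = aligned_columns(a, b, engine=engine)
    if cols == 0:
        raise ValueError("alignment has no comparable columns")
    return diffs / cols

def identity(a: str, b: str, engine: str = "edlib") -> float:
    """Fraction of identical aligned columns (terminal gaps excluded)."""
    return 1.0 - p_distance(a, b, engine=engine)
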