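"""Thin pairwise-alignment layer shared by the pipeline stages.

All identity/coverage numbers in the package funnel through the two
functions here so that every stage (contig de-redundancy, orthologue and
expression screens, distance matrices) uses one identity definition:

* ``semi_global`` — end-gap-free alignment of the shorter sequence into
  the longer one (cd-hit-like).  Identity is computed over the alignment
  columns only, i.e. terminal overhangs of the longer sequence do not
  count against it.  This matches how capture-assembly contigs differ:
  mostly by end truncation.
* ``global_pairwise`` — Needleman-Wunsch over the full length of both
  sequences; used for p-distances and private-indel detection.

Both are backed by edlib (unit-cost edit distance with extended CIGAR),
which is exact and fast enough that no heuristic pre-filter is needed at
the scales this package runs at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIG = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of a pairwise alignment.

    identity / coverage are percentages in [0, 100].  ``coverage`` is the
    aligned fraction of the *shorter* sequence for semi-global mode, and
    of the first sequence for global mode.  ``cigar`` is edlib's extended
    CIGAR (=/X/I/D) with the shorter (or first) sequence as query.
    """

    identity: float
    coverage: float
    cigar: str
    query_is_first: bool
    target_span: tuple[int, int]  # half-open slice of the longer/second seq


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (matches, columns) of an extended CIGAR string."""
    matches = 0
    columns = 0
    for n, op in _CIG.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def semi_global(a: str, b: str, max_distance: int | None = None) -> AlignmentResult | None:
    """End-gap-free alignment of the shorter of ``a``/``b`` into the longer.

    Returns ``None`` when ``max_distance`` is given and no alignment at or
    below that edit distance exists (cheap early-out for clearly unrelated
    pairs).  Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    a_u, b_u = a.upper(), b.upper()
    query_is_first = len(a_u) <= len(b_u)
    query, target = (a_u, b_u) if query_is_first else (b_u, a_u)
    k = -1 if max_distance is None else max_distance
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    matches, columns = _cigar_stats(res["cigar"])
    identity = 100.0 * matches / columns if columns else 0.0
    # The whole query is consumed in HW mode, so the shorter sequence is
    # fully covered by construction.
    start, end = res["locations"][0]
    return AlignmentResult(
        identity=identity,
        coverage=100.0,
        cigar=res["cigar"],
        query_is_first=query_is_first,
        target_span=(start, end + 1),
    )


def global_pairwise(a: str, b: str) -> AlignmentResult:
    """Needleman-Wunsch alignment of ``a`` (query) against ``b`` (target)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches, columns = _cigar_stats(res["cigar"])
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentResult(
        identity=identity,
        coverage=100.0,
        cigar=res["cigar"],
        query_is_first=True,
        target_span=(0, len(b)),
    )


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching columns among aligned (non-gap) columns."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    matches = mismatches = 0
    for n, op in _CIG.findall(res["cigar"]):
        if op == "=":
            matches += int(n)
        elif op == "X":
            mismatches += int(n)
    aligned = matches + mismatches
    return mismatches / aligned if aligned else 0.0


def cigar_walk(cigar: str):
    """Yield (op, length, query_pos, target_pos) for each CIGAR run."""
    q = t = 0
    for n, op in _CIG.findall(cigar):
        n = int(n)
        yield op, n, q, t
        if op in "=XM":
            q += n
            t += n
        elif op == "I":  # insertion relative to target: consumes query
            q += n
        elif op == "D":  # deletion: consumes target
            t += n


def affine_indels(query: str, target: str,
                  min_len: int = 1) -> list[tuple[int, int, str]]:
    """Indels of an affine-gap global alignment of query vs target.

    Unit-cost edit distance fragments long gaps whenever a few deleted
    bases happen to match nearby sequence, so indel calling uses an
    affine-gap alignment instead.  Returns (query_position, length,
    'ins'|'del') with 'del' meaning bases present in the target but
    absent from the query.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-10, extend_gap_score=-0.5)
    aln = aligner.align(target.upper(), query.upper())[0]
    t_blocks, q_blocks = aln.aligned
    out = []
    for k in range(1, len(t_blocks)):
        t_gap = int(t_blocks[k][0]) - int(t_blocks[k - 1][1])
        q_gap = int(q_blocks[k][0]) - int(q_blocks[k - 1][1])
        q_pos = int(q_blocks[k - 1][1])
        if t_gap >= min_len:
            out.append((q_pos, t_gap, "del"))
        if q_gap >= min_len:
            out.append((q_pos, q_gap, "ins"))
    return sorted(out)


def indels_from_cigar(cigar: str, min_len: int = 1) -> list[tuple[int, int, str]]:
    """Extract indels as (query_position, length, 'ins'|'del') tuples.

    Positions are on the query; a deletion (bases present in the target
    but absent from the query) is anchored at the query position where
    the gap opens.
    """
    out = []
    for op, n, q, _t in cigar_walk(cigar):
        if n < min_len:
            continue
        if op == "I":
            out.append((q, n, "ins"))
        elif op == "D":
            out.append((q, n, "del"))
    return out
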