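"""Contig post-processing ahead of NLR annotation.

Three steps are applied to a raw enrichment assembly before motif
scanning:

1. **De-redundancy** — greedy longest-first clustering at a percent
   identity threshold (default 95), the cd-hit strategy.  Identity is
   semi-global (end-gap-free) alignment identity, because capture-derived
   contigs differ mainly by end truncation; a contig fully contained in a
   longer one at high identity is therefore redundant.
2. **Rescue of removed contigs** — a removed contig can hide a genuinely
   distinct gene copy (recent duplication, residual heterozygosity).
   Each removed contig is re-annotated: if it carries no complete NLR it
   stays dropped; if its complete NLR is >99% identical to an
   already-catalogued NLR it stays dropped; if the identity is 95–99% the
   contig is rescued and its complete NLRs join the catalog.
3. **Low-complexity soft-masking** — DUST-style triplet-entropy masking
   to lowercase.  Masking is soft so coordinates are preserved; the motif
   scanner treats case as insignificant but masked tracts can be skipped
   by repeat-aware consumers.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import alignment
from .errors import NlrkitError


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    n_reads: int | None = None
    coverage: float | None = None

    def __post_init__(self):
        if not self.sequence:
            raise NlrkitError(f"contig {self.id}: empty sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise NlrkitError(f"contig {self.id}: non-ACGTN characters")


DECISION_COLUMNS = ["contig_id", "status", "matched_id", "identity", "reason"]


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Percent identity and coverage of a semi-global alignment.

    Identity is matches over alignment columns, terminal-gap columns
    excluded; coverage is the aligned fraction of the shorter sequence.
    Symmetric in its arguments.
    """
    res = alignment.semi_global(a, b)
    return res.identity, res.coverage


def _max_distance_for(threshold: float, query_len: int) -> int:
    # identity > t implies edit distance d < L * (1 - t) / t (columns are
    # at most query length plus deletions, each of which costs one edit).
    t = threshold / 100.0
    return int(query_len * (1.0 - t) / t) + 2


def remove_redundant(contigs: dict[str, str],
                     threshold: float = 95.0) -> pd.DataFrame:
    """Greedy longest-first clustering.

    Contigs are sorted by length (descending, ties by id) and compared to
    the retained representatives; a contig whose identity to any
    representative exceeds ``threshold`` is removed and points at the
    representative that claimed it.
    """
    if not 50.0 < threshold <= 100.0:
        raise NlrkitError("identity threshold must be in (50, 100]")
    ids = list(contigs)
    if len(set(ids)) != len(ids):
        raise NlrkitError("duplicate contig ids")
    order = sorted(ids, key=lambda i: (-len(contigs[i]), i))
    retained: list[str] = []
    rows = []
    for cid in order:
        seq = contigs[cid]
        hit_id, hit_identity = None, 0.0
        for rid in retained:
            res = alignment.semi_global(
                seq, contigs[rid],
                max_distance=_max_distance_for(threshold, len(seq)))
            if res is not None and res.identity > threshold:
                hit_id, hit_identity = rid, res.identity
                break
        if hit_id is None:
            retained.append(cid)
            rows.append({"contig_id": cid, "status": "retained",
                         "matched_id": "", "identity": 100.0,
                         "reason": "unique"})
        else:
            rows.append({"contig_id": cid, "status": "removed",
                         "matched_id": hit_id,
                         "identity": round(hit_identity, 2),
                         "reason": "duplicate_gt_threshold"})
    df = pd.DataFrame(rows, columns=DECISION_COLUMNS)
    # report in input order
    return df.set_index("contig_id").loc[ids].reset_index()


def rescue_removed(removed: dict[str, str], catalog_nlrs: dict[str, str],
                   annotate_fn) -> pd.DataFrame:
    """Re-examine removed contigs for distinct complete NLRs.

    ``annotate_fn(contig_id, sequence)`` must yield ``(locus_id,
    completeness, locus_sequence)`` tuples.  A removed contig whose best
    complete-NLR identity against the catalog is >99% stays dropped; at
    or below 99% (including novel, sub-95% loci) it is rescued; with no
    complete NLR at all it stays dropped.
    """
    rows = []
    for cid, seq in removed.items():
        loci = list(annotate_fn(cid, seq))
        complete = [(lid, ls) for lid, comp, ls in loci if comp == "complete"]
        if not complete:
            rows.append({"contig_id": cid, "status": "removed",
                         "matched_id": "", "identity": 0.0,
                         "reason": "drop_no_or_partial_nlr"})
            continue
        best_id, best_identity = "", 0.0
        for _lid, lseq in complete:
            for nid, nseq in catalog_nlrs.items():
                res = alignment.semi_global(lseq, nseq)
                if res.identity > best_identity:
                    best_id, best_identity = nid, res.identity
        if best_identity > 99.0:
            rows.append({"contig_id": cid, "status": "removed",
                         "matched_id": best_id,
                         "identity": round(best_identity, 2),
                         "reason": "drop_complete_gt99"})
        else:
            rows.append({"contig_id": cid, "status": "rescued",
                         "matched_id": best_id,
                         "identity": round(best_identity, 2),
                         "reason": "rescue_complete_95_99"})
    return pd.DataFrame(rows, columns=DECISION_COLUMNS)


def dust_score(window: str) -> float:
    """DUST score of one window: sum over triplet counts c of c(c-1)/2,
    normalized by (number of triplets - 1)."""
    w = window.upper()
    n_triplets = len(w) - 2
    if n_triplets < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(n_triplets):
        t = w[i:i + 3]
        counts[t] = counts.get(t, 0) + 1
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return s / (n_triplets - 1)


def mask_low_complexity(seq: str, window: int = 64,
                        threshold: float = 2.0) -> str:
    """Soft-mask (lowercase) low-complexity tracts, DUST style.

    Every ``window``-length window whose triplet score exceeds
    ``threshold`` is masked in full.  Length-preserving and idempotent
    (scoring is case-insensitive).
    """
    if window < 3:
        raise NlrkitError("window must be >= 3")
    n = len(seq)
    if n < 3:
        return seq
    mask = [False] * n
    step = max(window // 2, 1)
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] != max(n - window, 0):
        starts.append(max(n - window, 0))
    for s in starts:
        e = min(s + window, n)
        if dust_score(seq[s:e]) > threshold:
            for i in range(s, e):
                mask[i] = True
    return "".join(c.lower() if m else c.upper()
                   for c, m in zip(seq, mask))
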