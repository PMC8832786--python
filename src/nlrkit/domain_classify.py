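"""Domain merging, Type I–V classification and integrated-domain calls.

NLR proteins are classified from their merged domain annotations.  Two
annotation sources (a plant R-gene domain scan and a superfamily scan,
or the package's own coarse motif-based caller) are integrated after an
e-value gate (default 1e-3); only proteins carrying an NB-ARC domain
count as NLRs at all.  Domain composition then partitions the catalog:

========  =========================  ==================
Type      domains beside NB-ARC      class label
========  =========================  ==================
I         CC and LRR                 CNL
II        LRR only                   NL
III       CC only                    CN
IV        none                       N
V         any atypical domain        NLR-ID
========  =========================  ==================

Anything outside the canonical set {CC, NB-ARC, LRR} — kinases, WRKY,
zf-BED, Kelch, B3, PP2C, ... — is an integrated (decoy) domain, and its
position relative to the NB-ARC span assigns it to the N (CC-side) or C
(LRR-side) terminal.  Because the two annotation sources use different
vocabularies, names pass through a configurable alias map first.

Coordinates here are 1-based inclusive amino-acid positions, the common
convention of domain-annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import NlrkitError
from .nlr_annotate import NlrLocus
from .synthetic_data import MotifLibrary

CANONICAL_DOMAINS = frozenset({"CC", "NB-ARC", "LRR"})

#: Default vocabulary normalization across annotation sources.
DEFAULT_ALIASES = {
    "Rx_N": "CC",
    "NB-ARC": "NB-ARC",
    "NBARC": "NB-ARC",
    "NB_ARC": "NB-ARC",
    "NBS": "NB-ARC",
    "LRR": "LRR",
}

CLASS_ORDER = ["CNL", "NL", "CN", "N", "NLR-ID"]


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domain_name: str
    start: int  # 1-based inclusive aa
    end: int
    source: str  # rgene_scan | superfamily_scan | builtin
    evalue: float

    def __post_init__(self):
        if self.end < self.start:
            raise NlrkitError(
                f"{self.protein_id}/{self.domain_name}: end < start")
        if self.evalue < 0:
            raise NlrkitError("negative e-value")


@dataclass
class NlrRecord:
    protein_id: str
    locus_id: str
    domains: list[DomainAnnotation]
    nlr_class: str
    ids: list[tuple[str, str]] = field(default_factory=list)  # (name, terminal)


def normalize_domain_name(name: str,
                          aliases: dict[str, str] | None = None) -> str:
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    if name in aliases:
        return aliases[name]
    if name.upper().startswith("LRR"):  # superfamily LRR naming variants
        return "LRR"
    return name


def merge_domain_sources(a: list[DomainAnnotation],
                         b: list[DomainAnnotation],
                         evalue_max: float = 1e-3,
                         aliases: dict[str, str] | None = None
                         ) -> dict[str, list[DomainAnnotation]]:
    """Integrate two annotation sources per protein.

    Rows above the e-value gate are dropped; same-name overlapping (or
    touching) intervals are merged to their union; disjoint rows are
    concatenated.  Output per protein is sorted by start.
    """
    per_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in list(a) + list(b):
        if ann.evalue > evalue_max:
            continue
        name = normalize_domain_name(ann.domain_name, aliases)
        per_protein.setdefault(ann.protein_id, []).append(
            DomainAnnotation(ann.protein_id, name, ann.start, ann.end,
                             ann.source, ann.evalue))
    merged: dict[str, list[DomainAnnotation]] = {}
    for pid, anns in per_protein.items():
        by_name: dict[str, list[DomainAnnotation]] = {}
        for ann in anns:
            by_name.setdefault(ann.domain_name, []).append(ann)
        out: list[DomainAnnotation] = []
        for name, rows in by_name.items():
            rows.sort(key=lambda r: (r.start, r.end))
            cur_start, cur_end = rows[0].start, rows[0].end
            cur_ev = rows[0].evalue
            cur_src = rows[0].source
            for r in rows[1:]:
                if r.start <= cur_end + 1:  # overlap or adjacency: union
                    cur_end = max(cur_end, r.end)
                    cur_ev = min(cur_ev, r.evalue)
                    if r.source != cur_src:
                        cur_src = "merged"
                else:
                    out.append(DomainAnnotation(pid, name, cur_start,
                                                cur_end, cur_src, cur_ev))
                    cur_start, cur_end = r.start, r.end
                    cur_ev, cur_src = r.evalue, r.source
            out.append(DomainAnnotation(pid, name, cur_start, cur_end,
                                        cur_src, cur_ev))
        out.sort(key=lambda r: (r.start, r.end, r.domain_name))
        merged[pid] = out
    return merged


def classify_nlr(domains: list[DomainAnnotation]) -> str | None:
    """Class from merged domains; ``None`` (rejected) without NB-ARC."""
    names = {d.domain_name for d in domains}
    if "NB-ARC" not in names:
        return None
    atypical = names - CANONICAL_DOMAINS
    if atypical:
        return "NLR-ID"
    has_cc = "CC" in names
    has_lrr = "LRR" in names
    if has_cc and has_lrr:
        return "CNL"
    if has_lrr:
        return "NL"
    if has_cc:
        return "CN"
    return "N"


def assign_id_terminal(domains: list[DomainAnnotation]
                       ) -> list[tuple[str, str]]:
    """Place each integrated domain relative to the NB-ARC span.

    Wholly before NB-ARC → ``N``; wholly after → ``C``; overlapping →
    ``ambiguous``.  Raises when the record has no NB-ARC domain.
    """
    nb = [d for d in domains if d.domain_name == "NB-ARC"]
    if not nb:
        raise NlrkitError("record without NB-ARC domain")
    nb_start = min(d.start for d in nb)
    nb_end = max(d.end for d in nb)
    out = []
    for d in domains:
        if d.domain_name in CANONICAL_DOMAINS:
            continue
        if d.end < nb_start:
            out.append((d.domain_name, "N"))
        elif d.start > nb_end:
            out.append((d.domain_name, "C"))
        else:
            out.append((d.domain_name, "ambiguous"))
    return out


def build_records(proteins: dict[str, str],
                  merged: dict[str, list[DomainAnnotation]],
                  locus_of: dict[str, str] | None = None
                  ) -> tuple[list[NlrRecord], list[str]]:
    """Classify every protein; returns (records, rejected protein ids)."""
    records, rejected = [], []
    for pid in proteins:
        domains = merged.get(pid, [])
        cls = classify_nlr(domains)
        if cls is None:
            rejected.append(pid)
            continue
        ids = assign_id_terminal(domains) if cls == "NLR-ID" else []
        records.append(NlrRecord(
            protein_id=pid,
            locus_id=(locus_of or {}).get(pid, pid),
            domains=domains, nlr_class=cls, ids=ids))
    return records, rejected


# ---------------------------------------------------------------------------
# Coarse builtin domain calls from the motif library
# ---------------------------------------------------------------------------

_CATEGORY_TO_DOMAIN = {"CC": "CC", "NB": "NB-ARC", "LRR": "LRR"}


def annotate_domains_builtin(protein_id: str, protein: str,
                             library: MotifLibrary,
                             source: str = "builtin",
                             merge_gap_aa: int = 40
                             ) -> list[DomainAnnotation]:
    """Direct motif-consensus scan of a protein.

    Motif hits of the same domain name within ``merge_gap_aa`` residues
    are merged into one span, so a run of NB motifs reports as a single
    NB-ARC domain — the coarse stand-in for an HMM-based domain search
    on synthetic runs.
    """
    import numpy as np

    arr = np.frombuffer(protein.upper().encode("ascii"), dtype=np.uint8)
    raw: dict[str, list[tuple[int, int]]] = {}
    for motif in library.motifs:
        m = motif.consensus.encode("ascii")
        w = len(m)
        L = len(arr) - w + 1
        if L <= 0:
            continue
        counts = np.zeros(L, dtype=np.int32)
        for j, ch in enumerate(m):
            counts += arr[j:j + L] == ch
        name = (motif.domain_name if motif.category == "ID"
                else _CATEGORY_TO_DOMAIN[motif.category])
        for pos in np.nonzero(counts >= w - motif.max_mismatches)[0]:
            pos = int(pos)
            raw.setdefault(name, []).append((pos + 1, pos + w))
    out = []
    for name, spans in raw.items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e + merge_gap_aa:
                cur_e = max(cur_e, e)
            else:
                out.append(DomainAnnotation(protein_id, name, cur_s, cur_e,
                                            source, 1e-10))
                cur_s, cur_e = s, e
        out.append(DomainAnnotation(protein_id, name, cur_s, cur_e,
                                    source, 1e-10))
    out.sort(key=lambda d: (d.start, d.end, d.domain_name))
    return out


# ---------------------------------------------------------------------------
# Linked pairs and class summary
# ---------------------------------------------------------------------------

def find_paired_nlrs(loci: list[NlrLocus],
                     max_separation_bp: int = 10000) -> pd.DataFrame:
    """Adjacent locus pairs per contig with their relative orientation.

    Opposite strands with 5' ends facing → ``head_to_head``; opposite
    strands with 3' ends facing → ``tail_to_tail``; same strand →
    ``tandem``.
    """
    rows = []
    by_contig: dict[str, list[NlrLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig_id, []).append(locus)
    for contig_id in sorted(by_contig):
        ordered = sorted(by_contig[contig_id], key=lambda l: (l.start, l.end))
        for left, right in zip(ordered, ordered[1:]):
            sep = right.start - left.end
            if sep > max_separation_bp:
                continue
            if left.strand == right.strand:
                orientation = "tandem"
            elif left.strand == "-" and right.strand == "+":
                orientation = "head_to_head"  # 5' ends face each other
            else:
                orientation = "tail_to_tail"
            rows.append({"contig_id": contig_id,
                         "left_locus": left.locus_id,
                         "right_locus": right.locus_id,
                         "separation_bp": sep,
                         "orientation": orientation})
    return pd.DataFrame(rows, columns=["contig_id", "left_locus",
                                       "right_locus", "separation_bp",
                                       "orientation"])


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(Decimal(100.0 * count / total).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_classes(class_counts: dict[str, int]) -> pd.DataFrame:
    """Per-class counts and half-up one-decimal percentages, plus a total
    row.  Accepts either a counts dict or is fed from records upstream."""
    total = sum(class_counts.values())
    rows = [{"nlr_class": c, "count": class_counts.get(c, 0),
             "percent": _pct(class_counts.get(c, 0), total)}
            for c in CLASS_ORDER]
    rows.append({"nlr_class": "total", "count": total,
                 "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows, columns=["nlr_class", "count", "percent"])


def summarize_records(records: list[NlrRecord]) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.nlr_class] = counts.get(r.nlr_class, 0) + 1
    return summarize_classes(counts)
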