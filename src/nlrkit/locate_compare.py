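"""Chromosome assignment, congruence, screens and cross-species comparison.

In the Triticeae, chromosomes fall into seven homoeologous groups shared
across the A, B, D, H and V genomes.  An NLR assembled without a
reference genome is therefore located *in silico* by its best hit per
related genome: the majority of the hit chromosome numbers (ignoring
"Un") is its homoeologous group.  Physical locations from wheat
translocation lines provide the independent check: an arm whose modal
in-silico group differs from its own number is flagged discordant — the
signature of an ancestral rearrangement such as the 4L/7S translocation,
which *H. villosa* (4VL vs group 7) did not share.

The module also implements the catalog screens:

* orthologue screen against cloned R genes (> 80% identity, > 60%
  coverage, same homoeologous group);
* expression screen against a full-length transcriptome (> 95% identity,
  > 90% coverage) with exon-chain (splice-pattern) comparison;
* private-indel detection for marker design;
* integrated-domain membership comparison across species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import alignment
from .errors import NlrkitError

SPECIES_ORDER = ["VV", "AABBDD", "AA", "DD", "HH", "Bd", "Os"]

_CHROM_NUM = re.compile(r"^(\d+)")


@dataclass(frozen=True)
class ScreenThresholds:
    """Percent thresholds for the orthologue and expression screens."""

    ortho_identity: float = 80.0
    ortho_coverage: float = 60.0
    expr_identity: float = 95.0
    expr_coverage: float = 90.0

    def __post_init__(self):
        for f in ("ortho_identity", "ortho_coverage",
                  "expr_identity", "expr_coverage"):
            v = getattr(self, f)
            if not 0.0 < v <= 100.0:
                raise NlrkitError(f"{f}={v} outside (0, 100]")


# ---------------------------------------------------------------------------
# Homoeologous-group assignment
# ---------------------------------------------------------------------------

def chromosome_number(chromosome: str) -> int | None:
    """Leading chromosome number, or None for 'Un'/unparseable labels."""
    m = _CHROM_NUM.match(str(chromosome).strip())
    return int(m.group(1)) if m else None


def _majority_group(numbers: list[int]) -> int | None:
    if not numbers:
        return None
    counts: dict[int, int] = {}
    for x in numbers:
        counts[x] = counts.get(x, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None  # tie
    return ranked[0][0]


def assign_homoeologous_group(hits: pd.DataFrame) -> dict:
    """Group assignment for one query from its hit rows.

    Per genome the best hit wins (highest bitscore, ties by identity,
    then lexicographic chromosome); the group is the majority chromosome
    number across genomes, with "Un" excluded from the vote; a tie means
    unassigned.
    """
    if hits.empty:
        return {"per_genome_chromosome": {}, "group": None}
    per_genome: dict[str, str] = {}
    for genome, sub in hits.groupby("genome"):
        sub = sub.sort_values(["bitscore", "identity", "chromosome"],
                              ascending=[False, False, True],
                              kind="mergesort")
        per_genome[genome] = str(sub.iloc[0]["chromosome"])
    numbers = [n for n in (chromosome_number(c) for c in per_genome.values())
               if n is not None]
    return {"per_genome_chromosome": per_genome,
            "group": _majority_group(numbers)}


def assign_groups(hits: pd.DataFrame) -> pd.DataFrame:
    """Vectorized wrapper: one assignment row per query id."""
    rows = []
    for qid, sub in hits.groupby("query_id", sort=True):
        a = assign_homoeologous_group(sub)
        row = {"query_id": qid, "group": a["group"]}
        row.update({f"chr_{g}": c
                    for g, c in a["per_genome_chromosome"].items()})
        rows.append(row)
    return pd.DataFrame(rows)


def marker_table_assignments(markers: pd.DataFrame) -> pd.DataFrame:
    """In-silico assignment of a physically mapped marker table.

    Expects columns ``nlr_id``, ``status``, per-genome chromosome columns
    (everything between ``status`` and ``physical arm``), and the arm
    column ending in ``_arm``.
    """
    columns = ["nlr_id", "status", "physical_arm", "group"]
    if markers.empty:
        return pd.DataFrame(columns=columns)
    arm_col = [c for c in markers.columns if c.endswith("_arm")][-1]
    genome_cols = [c for c in markers.columns
                   if c not in ("nlr_id", "status", arm_col)]
    rows = []
    for _, r in markers.iterrows():
        numbers = [n for n in (chromosome_number(r[c]) for c in genome_cols)
                   if n is not None]
        rows.append({"nlr_id": r["nlr_id"], "status": r["status"],
                     "physical_arm": r[arm_col],
                     "group": _majority_group(numbers)})
    return pd.DataFrame(rows)


def congruence_report(assignments: pd.DataFrame,
                      markers: pd.DataFrame) -> dict:
    """Physical-vs-in-silico congruence per chromosome arm.

    ``assignments`` carries ``nlr_id``/``query_id``, ``group``;
    ``markers`` carries ``nlr_id``, ``status`` and a physical-arm column.
    Returns a per-arm table (modal in-silico group, discordance flag,
    complete/partial counts), per-locus discordance flags, status counts
    and any marker ids missing from the assignments (listed, not fatal).
    """
    arm_columns = ["physical_arm", "n_markers", "n_complete", "n_partial",
                   "modal_group", "discordant"]
    locus_columns = ["nlr_id", "status", "physical_arm", "group",
                     "discordant"]
    if markers.empty:
        return {"per_arm": pd.DataFrame(columns=arm_columns),
                "per_locus": pd.DataFrame(columns=locus_columns),
                "status_counts": {}, "unknown_markers": [],
                "duplicated_markers": []}
    key = "nlr_id" if "nlr_id" in assignments.columns else "query_id"
    group_of = dict(zip(assignments.get(key, []), assignments.get("group", [])))
    arm_col = [c for c in markers.columns if c.endswith("_arm")]
    arm_col = arm_col[-1] if arm_col else "physical_arm"

    unknown = [i for i in markers["nlr_id"] if i not in group_of]
    per_locus = []
    for _, r in markers.iterrows():
        arm = str(r[arm_col])
        arm_num = chromosome_number(arm)
        grp = group_of.get(r["nlr_id"])
        per_locus.append({
            "nlr_id": r["nlr_id"], "status": r["status"],
            "physical_arm": arm, "group": grp,
            "discordant": (grp is not None and arm_num is not None
                           and grp != arm_num)})
    per_locus = pd.DataFrame(per_locus)

    arm_rows = []
    for arm, sub in per_locus.groupby("physical_arm", sort=True):
        groups = [g for g in sub["group"] if g is not None]
        modal = _majority_group(groups)
        if modal is None and groups:  # tie: smallest most-common group
            counts: dict[int, int] = {}
            for g in groups:
                counts[g] = counts.get(g, 0) + 1
            modal = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        arm_num = chromosome_number(arm)
        arm_rows.append({
            "physical_arm": arm,
            "n_markers": len(sub),
            "n_complete": int((sub["status"] == "Complete NLR").sum()),
            "n_partial": int((sub["status"] != "Complete NLR").sum()),
            "modal_group": modal,
            "discordant": modal is not None and modal != arm_num})
    duplicated = sorted(markers.loc[markers["nlr_id"].duplicated(), "nlr_id"])
    return {
        "per_arm": pd.DataFrame(arm_rows),
        "per_locus": per_locus,
        "status_counts": markers["status"].value_counts().to_dict(),
        "unknown_markers": unknown,
        "duplicated_markers": duplicated,
    }


def marker_polymorphism_rate(n_polymorphic: int, n_total: int) -> int:
    """Percent of primer pairs that are polymorphic, rounded half-up to
    the nearest integer."""
    if n_total <= 0:
        return 0
    return int(Decimal(100.0 * n_polymorphic / n_total).quantize(
        Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Orthologue screen
# ---------------------------------------------------------------------------

def screen_orthologues(candidates: pd.DataFrame,
                       thresholds: ScreenThresholds = ScreenThresholds()
                       ) -> pd.DataFrame:
    """Filter candidate orthologues of cloned R genes.

    ``candidates`` rows carry ``identity``, ``coverage`` (percent vs the
    R gene) and, when available, ``query_group`` and ``group`` for the
    same-homoeologous-locus requirement; rows missing either group pass
    that part vacuously.
    """
    df = candidates.copy()
    ok = ((df["identity"] > thresholds.ortho_identity)
          & (df["coverage"] > thresholds.ortho_coverage))
    if "query_group" in df.columns and "group" in df.columns:
        both = df["query_group"].notna() & df["group"].notna()
        ok &= ~both | (df["query_group"] == df["group"])
    return df[ok].reset_index(drop=True)


def locus_paralogue_count(hits: pd.DataFrame, anchor_mb: float,
                          window_mb: float = 1.0) -> int:
    """Count rows whose best-hit subject position falls at an anchor
    locus (e.g. the barley *Mla* cluster on 1H)."""
    pos = pd.to_numeric(hits["subject_mb"], errors="coerce")
    return int(((pos - anchor_mb).abs() <= window_mb).sum())


# ---------------------------------------------------------------------------
# Expression screen with splice comparison
# ---------------------------------------------------------------------------

def _identity_coverage(seq: str, reference: str) -> tuple[float, float]:
    """Identity of the semi-global alignment and coverage of ``reference``."""
    res = alignment.semi_global(seq, reference)
    if len(seq) >= len(reference):
        coverage = 100.0  # reference fully aligned as the query
    else:
        a, b = res.target_span
        coverage = 100.0 * (b - a) / len(reference)
    return res.identity, coverage


def infer_exon_junctions(transcript: str, genomic: str,
                         min_intron: int = 30) -> list[tuple[int, int]]:
    """Intron intervals (genomic coordinates) implied by aligning a
    transcript to its genomic locus.

    Uses an affine-gap global alignment (a unit-cost edit distance would
    scatter an intron into fragments); introns are genomic gaps of at
    least ``min_intron`` between consecutive aligned blocks.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-10, extend_gap_score=-0.5)
    # genomic flanks are free (attribute renamed across Biopython versions)
    try:
        aligner.end_insertion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
    aln = aligner.align(genomic.upper(), transcript.upper())[0]
    t_blocks, q_blocks = aln.aligned
    introns = []
    for k in range(1, len(t_blocks)):
        t_gap = int(t_blocks[k][0]) - int(t_blocks[k - 1][1])
        if t_gap >= min_intron:
            introns.append((int(t_blocks[k - 1][1]), int(t_blocks[k][0])))
    return introns


def compare_splice(predicted_exons: list[tuple[int, int]],
                   transcript: str, genomic_span: str,
                   span_offset: int, strand: str,
                   min_intron: int = 30, tolerance: int = 0) -> str:
    """Compare a predicted exon chain with the chain a transcript implies.

    Returns ``"match"`` or ``"mismatch_at_junction_k"`` (1-based, first
    disagreeing junction).  ``genomic_span`` must cover the predicted
    exons; for minus-strand loci both are re-oriented to the coding
    strand before comparison.
    """
    from .synthetic_data import revcomp

    span_len = len(genomic_span)
    pred = []
    for a, b in sorted(predicted_exons):
        if strand == "+":
            pred.append((a - span_offset, b - span_offset))
        else:
            pred.append((span_offset + span_len - b,
                         span_offset + span_len - a))
    pred.sort()
    pred_introns = [(pred[i][1], pred[i + 1][0])
                    for i in range(len(pred) - 1)]
    oriented = genomic_span if strand == "+" else revcomp(genomic_span)
    obs_introns = infer_exon_junctions(transcript, oriented,
                                       min_intron=min_intron)
    for k in range(max(len(pred_introns), len(obs_introns))):
        if k >= len(pred_introns) or k >= len(obs_introns):
            return f"mismatch_at_junction_{k + 1}"
        (pa, pb), (oa, ob) = pred_introns[k], obs_introns[k]
        if abs(pa - oa) > tolerance or abs(pb - ob) > tolerance:
            return f"mismatch_at_junction_{k + 1}"
    return "match"


def match_expression(cds_by_locus: dict[str, str],
                     transcripts: dict[str, str],
                     thresholds: ScreenThresholds = ScreenThresholds()
                     ) -> pd.DataFrame:
    """Expression screen: a locus is expressed when some transcript
    exceeds the identity/coverage thresholds against its CDS.

    Returns one row per locus with the best transcript and its metrics;
    splice comparison is done separately (:func:`compare_splice`) where
    genomic context is available.
    """
    rows = []
    for locus_id in sorted(cds_by_locus):
        cds = cds_by_locus[locus_id]
        best = (None, 0.0, 0.0)
        for tx_id in sorted(transcripts):
            tx = transcripts[tx_id]
            if min(len(tx), len(cds)) < 0.5 * max(len(tx), len(cds)):
                continue
            identity, coverage = _identity_coverage(tx, cds)
            if (identity, coverage) > (best[1], best[2]):
                best = (tx_id, identity, coverage)
        expressed = (best[0] is not None
                     and best[1] > thresholds.expr_identity
                     and best[2] > thresholds.expr_coverage)
        rows.append({"locus_id": locus_id, "expressed": expressed,
                     "transcript": best[0] or "",
                     "identity": round(best[1], 2),
                     "coverage": round(best[2], 2)})
    return pd.DataFrame(rows, columns=["locus_id", "expressed",
                                       "transcript", "identity", "coverage"])


# ---------------------------------------------------------------------------
# Private indels
# ---------------------------------------------------------------------------

def find_private_indels(query: str, orthologues: dict[str, str],
                        min_len: int = 3) -> list[tuple[int, int, str]]:
    """Indels present in the query versus EVERY orthologue.

    Each indel is (query position, length, 'ins'|'del'); shared indels —
    those absent from even one comparison — are excluded, because a
    marker must distinguish the query species from all of its
    orthologues.
    """
    if not orthologues:
        raise NlrkitError("need at least one orthologue")
    common: set[tuple[int, int, str]] | None = None
    for oid in sorted(orthologues):
        found = set(alignment.affine_indels(query, orthologues[oid],
                                            min_len=min_len))
        common = found if common is None else common & found
        if not common:
            return []
    return sorted(common)


# ---------------------------------------------------------------------------
# Integrated-domain membership comparison
# ---------------------------------------------------------------------------

def shared_unique_ids(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-species (total, shared, unique) integrated-domain counts.

    ``table`` rows carry ``id_name`` and ``genomes`` (comma-separated
    membership set).  total = rows containing the species; unique = rows
    whose whole set is just that species; shared = total − unique.
    Returns the per-species table and the grand total row count.
    """
    if table.empty:
        empty = pd.DataFrame(columns=["species", "total", "shared", "unique"])
        return empty, 0
    if table["id_name"].duplicated().any():
        raise NlrkitError("duplicate integrated-domain names")
    sets = [frozenset(s.strip() for s in str(g).split(","))
            for g in table["genomes"]]
    species = [s for s in SPECIES_ORDER
               if any(s in st for st in sets)]
    species += sorted({s for st in sets for s in st} - set(species))
    rows = []
    for sp in species:
        total = sum(1 for st in sets if sp in st)
        unique = sum(1 for st in sets if st == frozenset({sp}))
        rows.append({"species": sp, "total": total,
                     "shared": total - unique, "unique": unique})
    return pd.DataFrame(rows), len(sets)
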