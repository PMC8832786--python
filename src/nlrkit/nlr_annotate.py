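"""Motif-based NLR locus annotation.

The annotation model follows the motif-grammar approach used for
high-throughput NLR discovery: short conserved amino-acid motifs
(coiled-coil, nucleotide-binding including the Walker-A P-loop and the
NB-ARC start, and LRR motifs) are scanned for in all six reading frames,
then same-strand hits are chained into loci.  A chain is split before a
fresh P-loop hit that occurs after the running chain already contains an
LRR hit — the minimal grammar that separates tandem NLR copies sharing a
long contig.

A locus is *complete* when its chain contains the P-loop motif, the
NB-ARC start motif and at least one LRR motif, and *partial* otherwise.
Either kind is additionally flagged as a pseudogene when the motif span
contains an in-frame stop codon or a frame inconsistency between
adjacent same-strand hits (the footprint of a frameshift).

Protein inference is homology-guided: the locus is extended by a flank
(default 3000 bp) on both sides, the best homolog is chosen from a
protein database (highest identity, ties by longer coverage), and the
ORF — with at most one spliceable GT..AG intron — whose translation best
matches that homolog becomes the predicted coding sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from . import alignment
from .errors import NlrkitError
from .synthetic_data import MotifLibrary, revcomp

MIN_ORF_CODONS = 50


@dataclass(frozen=True)
class MotifHit:
    contig_id: str
    motif_id: str
    frame: int           # 0..2 on the scanned strand
    strand: str          # '+' | '-'
    start: int           # forward-strand bp, 0-based half-open
    end: int
    aa_start: int        # position in the frame translation
    score: int           # number of matching consensus positions


@dataclass
class NlrLocus:
    locus_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    motif_chain: list[str]
    completeness: str = ""
    hits: list[MotifHit] = field(default_factory=list)


@dataclass
class PredictedProtein:
    locus_id: str
    cds: str
    protein: str
    homolog_id: str | None
    homolog_identity: float
    homolog_coverage: float
    exons: list[tuple[int, int]] = field(default_factory=list)
    predicted: bool = True


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def _frame_translations(seq: str):
    """Yield (strand, frame, translation) over all six frames."""
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            sub = s[frame:frame + 3 * ((len(s) - frame) // 3)]
            if len(sub) >= 3:
                yield strand, frame, str(Seq(sub).translate())


def scan_motifs(contig_id: str, sequence: str,
                library: MotifLibrary) -> list[MotifHit]:
    """Scan all six reading frames for motif-consensus matches.

    Case-insensitive (soft-masked sequence scans like unmasked); every
    window with at most the motif's mismatch budget is reported with
    forward-strand coordinates.  Contigs shorter than the shortest motif
    yield an empty list.
    """
    import numpy as np

    seq = sequence.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for strand, frame, aa in _frame_translations(seq):
        arr = np.frombuffer(aa.encode("ascii"), dtype=np.uint8)
        for motif in library.motifs:
            m = motif.consensus.encode("ascii")
            w = len(m)
            L = len(arr) - w + 1
            if L <= 0:
                continue
            counts = np.zeros(L, dtype=np.int32)
            for j, ch in enumerate(m):
                counts += arr[j:j + L] == ch
            for aa_pos in np.nonzero(counts >= w - motif.max_mismatches)[0]:
                aa_pos = int(aa_pos)
                if strand == "+":
                    start = frame + 3 * aa_pos
                    end = start + 3 * w
                else:
                    rc_start = frame + 3 * aa_pos
                    end = n - rc_start
                    start = end - 3 * w
                hits.append(MotifHit(
                    contig_id=contig_id, motif_id=motif.motif_id,
                    frame=frame, strand=strand, start=start, end=end,
                    aa_start=aa_pos, score=int(counts[aa_pos])))
    hits.sort(key=lambda h: (h.start, h.end, h.motif_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Chaining hits into loci
# ---------------------------------------------------------------------------

def chain_loci(hits: list[MotifHit], library: MotifLibrary,
               max_gap_bp: int = 3000) -> list[NlrLocus]:
    """Chain same-strand hits within ``max_gap_bp`` into loci.

    Chains are walked in transcription order; a chain is split before a
    new P-loop hit once the running chain already holds an LRR-category
    hit, which is what separates tandem copies.  Locus ids are numbered
    5'→3' on the forward strand.  Invariant to hit input order.
    """
    if not hits:
        return []
    contig_ids = {h.contig_id for h in hits}
    if len(contig_ids) > 1:
        raise NlrkitError(f"hits from multiple contigs: {sorted(contig_ids)}")
    contig_id = contig_ids.pop()
    lrr_ids = {m.motif_id for m in library.by_category("LRR")}
    p_loop = library.p_loop_id

    loci: list[NlrLocus] = []
    for strand in ("+", "-"):
        strand_hits = [h for h in hits if h.strand == strand]
        if not strand_hits:
            continue
        # transcription order: ascending on '+', descending on '-'
        strand_hits.sort(key=lambda h: (h.start, h.end, h.motif_id))
        if strand == "-":
            strand_hits.reverse()
        chain: list[MotifHit] = []
        has_lrr = False

        def flush():
            if chain:
                loci.append(NlrLocus(
                    locus_id="", contig_id=contig_id,
                    start=min(h.start for h in chain),
                    end=max(h.end for h in chain),
                    strand=strand,
                    motif_chain=[h.motif_id for h in chain],
                    hits=list(chain)))

        for h in strand_hits:
            if chain:
                if strand == "+":
                    gap = h.start - max(x.end for x in chain)
                else:
                    gap = min(x.start for x in chain) - h.end
                split = gap > max_gap_bp or (h.motif_id == p_loop and has_lrr)
            else:
                split = False
            if split:
                flush()
                chain, has_lrr = [], False
            chain.append(h)
            if h.motif_id in lrr_ids:
                has_lrr = True
        flush()

    loci.sort(key=lambda l: (l.start, l.end))
    for k, locus in enumerate(loci, start=1):
        locus.locus_id = f"{contig_id}_nlr_{k}"
    return loci


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

def _hit_frame_key(h: MotifHit, contig_len: int) -> int:
    """Codon phase of a hit on the forward strand of its own reading
    direction; constant across a phase-preserving intron."""
    if h.strand == "+":
        return h.start % 3
    return (contig_len - h.end) % 3


def classify_completeness(locus: NlrLocus, contig_sequence: str,
                          library: MotifLibrary) -> str:
    """Apply the completeness definition and the pseudogene evidence.

    Complete = chain holds the P-loop, the NB-ARC start and at least one
    LRR motif.  Pseudogene = an in-frame stop codon inside the motif
    span, or adjacent same-strand hits in incompatible frames.
    """
    seq = contig_sequence.upper()
    chain = set(locus.motif_chain)
    lrr_ids = {m.motif_id for m in library.by_category("LRR")}
    complete = (library.p_loop_id in chain and library.nb_start_id in chain
                and bool(chain & lrr_ids))
    label = "complete" if complete else "partial"

    frames = {_hit_frame_key(h, len(seq)) for h in locus.hits}
    pseudo = len(frames) > 1
    if not pseudo and locus.hits:
        # translate the motif span in the frame of the first hit
        if locus.strand == "+":
            span = seq[locus.start:locus.end]
        else:
            span = revcomp(seq[locus.start:locus.end])
        span = span[:3 * (len(span) // 3)]
        if span and "*" in str(Seq(span).translate()):
            pseudo = True
    return label + ("_pseudogene" if pseudo else "")


def annotate_contig(contig_id: str, sequence: str, library: MotifLibrary,
                    max_gap_bp: int = 3000) -> list[NlrLocus]:
    """Scan, chain and classify one contig in a single call."""
    hits = scan_motifs(contig_id, sequence, library)
    loci = chain_loci(hits, library, max_gap_bp=max_gap_bp) if hits else []
    for locus in loci:
        locus.completeness = classify_completeness(locus, sequence, library)
    return loci


# ---------------------------------------------------------------------------
# Homology-guided protein prediction
# ---------------------------------------------------------------------------

def _orfs(seq: str):
    """Yield (start, end) of ATG..stop ORFs (end past the stop codon) in
    all three frames of ``seq``."""
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in stops:
                yield start, i + 3
                start = None


def _identity_to(protein: str, homolog: str) -> float:
    if not protein:
        return 0.0
    return alignment.semi_global(protein, homolog).identity


def _best_homolog(region: str, homolog_db: dict[str, str]
                  ) -> tuple[str | None, float]:
    """Best homolog by translated identity: highest identity, ties by
    longer coverage of the homolog, then lexicographic id."""
    translations = [aa for strand, _f, aa in _frame_translations(region)
                    if strand == "+"]
    best = (None, 0.0, 0.0)
    for hid in sorted(homolog_db):
        hseq = homolog_db[hid]
        identity = max((_identity_to(t, hseq) for t in translations if t),
                       default=0.0)
        coverage = min(100.0, 100.0 * min(len(t) for t in translations)
                       / max(len(hseq), 1))
        if (identity, coverage) > (best[1], best[2]):
            best = (hid, identity, coverage)
    return best[0], best[1]


def _splice_candidates(orf_seq: str, min_intron: int = 40,
                       max_intron: int = 400):
    """Yield (donor, acceptor_end) GT..AG intron candidates inside an ORF."""
    donors = [i for i in range(len(orf_seq) - 1) if orf_seq[i:i + 2] == "GT"]
    for d in donors:
        lo, hi = d + min_intron, d + max_intron
        a = orf_seq.find("AG", max(lo - 2, d + 2))
        while a != -1 and a + 2 <= min(hi, len(orf_seq)):
            yield d, a + 2
            a = orf_seq.find("AG", a + 1)


def _translate_cds(cds: str) -> str:
    cds = cds[:3 * (len(cds) // 3)]
    aa = str(Seq(cds).translate()) if cds else ""
    stop = aa.find("*")
    return aa if stop == -1 else aa[:stop]


def predict_protein(locus: NlrLocus, contig_sequence: str,
                    homolog_db: dict[str, str], flank: int = 3000,
                    min_identity: float = 40.0) -> PredictedProtein:
    """Infer the coding sequence of a locus from its best homolog.

    The locus is extended by ``flank`` bp each side (clipped to the
    contig); the ORF — allowing at most one GT..AG intron — whose
    translation has the highest identity to the best homolog becomes the
    CDS.  When no homolog reaches ``min_identity`` the locus is returned
    flagged unpredicted rather than raising.
    """
    if not homolog_db:
        raise NlrkitError("homolog database is empty")
    seq = contig_sequence.upper()
    ext_start = max(locus.start - flank, 0)
    ext_end = min(locus.end + flank, len(seq))
    region = seq[ext_start:ext_end]
    oriented = region if locus.strand == "+" else revcomp(region)

    homolog_id, _ = _best_homolog(oriented, homolog_db)
    if homolog_id is None:
        return PredictedProtein(locus.locus_id, "", "", None, 0.0, 0.0,
                                predicted=False)
    homolog = homolog_db[homolog_id]

    # locus motif span in oriented coordinates, to require overlap
    if locus.strand == "+":
        span = (locus.start - ext_start, locus.end - ext_start)
    else:
        span = (ext_end - locus.end, ext_end - locus.start)

    best = None  # (identity, cds, orf_start, intron or None)
    for o_start, o_end in _orfs(oriented):
        if o_end - o_start < 3 * MIN_ORF_CODONS:
            continue
        if o_end <= span[0] or o_start >= span[1]:
            continue
        cds = oriented[o_start:o_end]
        ident = _identity_to(_translate_cds(cds), homolog)
        if best is None or ident > best[0]:
            best = (ident, cds, o_start, None)
    if best is None:
        return PredictedProtein(locus.locus_id, "", "", homolog_id, 0.0, 0.0,
                                predicted=False)

    # single-intron refinement when the intronless reading falls short
    if best[0] < 99.0:
        ident0, cds0, o_start, _ = best
        best = (ident0, cds0, o_start, None)
        for d, a in _splice_candidates(cds0):
            spliced = cds0[:d] + cds0[a:]
            prot = _translate_cds(spliced)
            if len(prot) < MIN_ORF_CODONS:
                continue
            ident = _identity_to(prot, homolog)
            if ident > best[0]:
                best = (ident, spliced, o_start, (d, a))

    identity, cds, o_start, intron = best
    if identity < min_identity:
        return PredictedProtein(locus.locus_id, "", "", homolog_id,
                                round(identity, 2), 0.0, predicted=False)

    # Start-codon refinement: semi-global identity is blind to N-terminal
    # overhangs, so an upstream in-frame ATG can masquerade as the start.
    # Re-score candidate in-frame ATGs with a global alignment, which
    # penalizes both overhang and truncation relative to the homolog.
    # (With an intron, ``cds`` is the spliced sequence; positions before
    # the donor are shared with the unspliced ORF, and the start must lie
    # in the first exon.)
    d_a = intron
    start_limit = (d_a[0] if d_a is not None
                   else max(len(cds) - 3 * MIN_ORF_CODONS, 0))
    atgs = [p for p in range(0, min(start_limit, len(cds)), 3)
            if cds[p:p + 3] == "ATG"]
    best_start, best_global = 0, -1.0
    for p in atgs[:40]:
        prot = _translate_cds(cds[p:])
        if len(prot) < MIN_ORF_CODONS:
            continue
        g = alignment.global_pairwise(prot, homolog).identity
        if g > best_global + 1e-9:
            best_start, best_global = p, g
    p = best_start
    cds = cds[p:]
    protein = _translate_cds(cds)
    cds = cds[:3 * (len(protein) + 1)]  # trim at the stop codon

    # exon intervals in oriented, then contig forward coordinates
    if d_a is None:
        o_exons = [(o_start + p, o_start + p + len(cds))]
    else:
        d, a = d_a
        first = (o_start + p, o_start + d)
        rest = len(cds) - (d - p)
        o_exons = [first, (o_start + a, o_start + a + rest)]
    if locus.strand == "+":
        exons = [(ext_start + a, ext_start + b) for a, b in o_exons]
    else:
        rlen = len(region)
        exons = sorted((ext_start + rlen - b, ext_start + rlen - a)
                       for a, b in o_exons)

    res = alignment.global_pairwise(protein, homolog)
    matches_cols = sum(int(n) for n, op in
                       re.findall(r"(\d+)([=XIDM])", res.cigar)
                       if op in "=X")
    coverage = 100.0 * min(matches_cols, len(homolog)) / len(homolog)
    return PredictedProtein(
        locus_id=locus.locus_id, cds=cds, protein=protein,
        homolog_id=homolog_id,
        homolog_identity=round(res.identity, 2),
        homolog_coverage=round(coverage, 2),
        exons=exons)


# ---------------------------------------------------------------------------
# GFF3 output
# ---------------------------------------------------------------------------

def write_gff3(loci: list[NlrLocus], path) -> None:
    """Write loci as GFF3 ``NLR_locus`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            attrs = (f"ID={locus.locus_id};completeness={locus.completeness};"
                     f"motif_chain={','.join(locus.motif_chain)}")
            fh.write("\t".join([
                locus.contig_id, "nlrkit", "NLR_locus",
                str(locus.start + 1), str(locus.end), ".",
                locus.strand, ".", attrs]) + "\n")
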