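"""Synthetic enrichment-assembly generator with planted NLR ground truth.

This module fabricates every input the annotation pipeline consumes —
contigs carrying planted NLR motif chains, homolog proteins, reference
best-hit tables with homoeologous-group structure, and noisy transcripts
— together with a truth table, so that locus recovery, classification,
chromosome assignment and expression screening can all be scored exactly.

The model of an NLR locus is a motif grammar: an open reading frame whose
translation contains, in order, coiled-coil (CC) motifs, nucleotide-binding
(NB) motifs — the first two of which are the designated P-loop and NB-ARC
start motifs — and a block of LRR motifs.  Variants planted on top of the
canonical chain:

* ``partial``            — the LRR block, or the whole CC/NB head, is omitted;
* ``*_pseudogene``       — an in-frame TAA stop or a 1-bp frameshift is
                           introduced inside the motif span;
* ``NLR-ID``             — a motif from an "integrated domain" category
                           (WRKY, Kelch, zf-BED, ...) is fused at the N or
                           C terminus;
* tandem loci            — two chains on one contig, separated by a spacer
                           longer than the locus-chaining gap;
* near-duplicate contigs — mutated copies at a configured percent identity,
                           for exercising de-redundancy.

Motifs are planted as exact amino-acid substrings; detection difficulty is
injected only through the configured mutations, which keeps the planted
truth unambiguous.  Background sequence is i.i.d. with 45% GC.  All
randomness flows from a single seed, and identical configurations produce
byte-identical outputs.

Coordinates are 0-based half-open throughout and converted only at I/O
boundaries (GFF3 is 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Standard-code codons per amino acid (stop codons excluded).
_CODONS: dict[str, list[str]] = {}
for _aa, _codons in {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}.items():
    _CODONS[_aa] = _codons

_COMP = str.maketrans("ACGTN", "TGCAN")

# Field-standard integrated-domain names given to the generated ID motifs,
# in a fixed order so that libraries are deterministic per seed.
ID_DOMAIN_NAMES = ("WRKY", "Kelch_1", "zf-BED", "Pkinase", "PP2C", "B3",
                   "Thioredoxin", "DDE_Tnp_4")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Motif library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifDef:
    """One motif: a consensus peptide with a mismatch budget for scanning."""

    motif_id: str
    category: str  # CC | NB | LRR | ID
    consensus: str
    max_mismatches: int
    p_loop: bool = False
    nb_start: bool = False
    domain_name: str | None = None  # integrated-domain name for ID motifs


@dataclass(frozen=True)
class MotifLibrary:
    """Ordered motif set with designated P-loop and NB-ARC-start motifs."""

    motifs: tuple[MotifDef, ...]

    def __post_init__(self):
        if sum(m.p_loop for m in self.motifs) != 1:
            raise ConfigurationError("library must flag exactly one p_loop motif")
        if sum(m.nb_start for m in self.motifs) != 1:
            raise ConfigurationError("library must flag exactly one nb_start motif")

    @property
    def p_loop_id(self) -> str:
        return next(m.motif_id for m in self.motifs if m.p_loop)

    @property
    def nb_start_id(self) -> str:
        return next(m.motif_id for m in self.motifs if m.nb_start)

    def by_category(self, category: str) -> list[MotifDef]:
        return [m for m in self.motifs if m.category == category]

    def get(self, motif_id: str) -> MotifDef:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def generate_motif_library(seed: int, n_cc: int = 3, n_nb: int = 8,
                           n_lrr: int = 4, n_id: int = 0) -> MotifLibrary:
    """Generate a deterministic motif library.

    Consensus peptides are random 12–18-mers over the 20-letter alphabet;
    the mismatch budget for scanning is length // 6, so a planted (exact)
    motif is always detected while random background essentially never is.
    The first NB motif is flagged as the P-loop and, to keep it visually
    recognizable, starts with a Walker-A-like ``GxxGxGKTT`` core; the
    second NB motif (or the same one when ``n_nb == 1``) is the NB-ARC
    start.
    """
    if n_cc < 1 or n_nb < 1 or n_lrr < 1 or n_id < 0:
        raise ConfigurationError("motif counts must be >= 1 (n_id >= 0)")
    rng = np.random.default_rng(seed)
    motifs: list[MotifDef] = []
    seen: set[str] = set()

    def fresh(length: int, prefix: str = "") -> str:
        while True:
            pep = prefix + _random_peptide(rng, length - len(prefix))
            if pep not in seen:
                seen.add(pep)
                return pep

    for i in range(n_cc):
        cons = fresh(int(rng.integers(12, 19)))
        motifs.append(MotifDef(f"CC{i + 1}", "CC", cons, len(cons) // 6))
    for i in range(n_nb):
        if i == 0:
            cons = fresh(int(rng.integers(14, 19)), prefix="GMGGLGKTT")
        else:
            cons = fresh(int(rng.integers(12, 19)))
        motifs.append(MotifDef(
            f"NB{i + 1}", "NB", cons, len(cons) // 6,
            p_loop=(i == 0),
            nb_start=(i == 1 or (n_nb == 1 and i == 0)),
        ))
    for i in range(n_lrr):
        cons = fresh(int(rng.integers(12, 19)))
        motifs.append(MotifDef(f"LRR{i + 1}", "LRR", cons, len(cons) // 6))
    for i in range(n_id):
        cons = fresh(int(rng.integers(14, 20)))
        name = ID_DOMAIN_NAMES[i % len(ID_DOMAIN_NAMES)]
        motifs.append(MotifDef(f"ID_{name}", "ID", cons, len(cons) // 6,
                               domain_name=name))
    return MotifLibrary(tuple(motifs))


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic assembly.

    Rates are fractions in [0, 1].  ``duplicate_identity`` is the percent
    identity of near-duplicate contig copies.  ``contig_length_range``
    must leave room for the longest planted locus plus flanks on both
    sides.
    """

    seed: int = 42
    n_contigs: int = 60
    contig_length_range: tuple[int, int] = (6000, 14000)
    n_loci: int = 50
    pseudogene_rate: float = 0.0
    partial_rate: float = 0.0
    id_fusion_rate: float = 0.0
    tandem_rate: float = 0.0
    near_duplicate_rate: float = 0.0
    duplicate_identity: float = 97.0
    discordant_group_fraction: float = 0.0
    transcript_rate: float = 1.0
    transcript_error_rate: float = 0.0
    intron_rate: float = 0.25
    intron_length_range: tuple[int, int] = (60, 120)
    min_flank: int = 300

    def __post_init__(self):
        for name in ("pseudogene_rate", "partial_rate", "id_fusion_rate",
                     "tandem_rate", "near_duplicate_rate",
                     "discordant_group_fraction", "transcript_rate",
                     "transcript_error_rate", "intron_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.contig_length_range
        if lo < 1000 or hi < lo:
            raise ConfigurationError("invalid contig_length_range")
        if not 50.0 < self.duplicate_identity <= 100.0:
            raise ConfigurationError("duplicate_identity must be in (50, 100]")
        if self.n_contigs < 1 or self.n_loci < 0:
            raise ConfigurationError("n_contigs >= 1 and n_loci >= 0 required")


TRUTH_COLUMNS = ["locus_id", "contig_id", "start", "end", "strand",
                 "true_completeness", "true_class", "id_domain",
                 "id_terminal", "true_group", "physical_arm"]


@dataclass
class LocusDetail:
    """Per-locus generation detail not part of the public truth table."""

    cds: str                       # spliced coding sequence (ATG..stop)
    protein: str                   # translation of cds (no stop)
    exons: list[tuple[int, int]]   # genomic exon intervals, contig coords
    strand: str
    motif_chain: list[str]


@dataclass
class GeneratedData:
    """Everything one synthetic run produces."""

    contigs: dict[str, str]
    truth: pd.DataFrame
    details: dict[str, LocusDetail] = field(default_factory=dict)
    library: MotifLibrary | None = None


# ---------------------------------------------------------------------------
# Contig/locus construction
# ---------------------------------------------------------------------------

def _encode(rng: np.random.Generator, peptide: str) -> str:
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
                   for aa in peptide)


def _background(rng: np.random.Generator, length: int) -> str:
    # i.i.d. background at 45% GC
    return "".join(rng.choice(list("ACGT"), size=length,
                              p=[0.275, 0.225, 0.225, 0.275]))


def _random_intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    """GT..AG intron, length a multiple of 3, no stop codon in the reading
    frame it interrupts (so unspliced translations stay open)."""
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    first = "GT" + str(rng.choice(list("ACGT")))
    last = str(rng.choice(list("ACG"))) + "AG"
    middle = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
              for aa in rng.choice(list(AA_ALPHABET), size=max(n_codons - 2, 0))]
    return first + "".join(middle) + last


@dataclass
class _LocusPlan:
    completeness: str
    nlr_class: str
    id_domain: str | None
    id_terminal: str | None
    group: int
    arm: str
    strand: str
    has_intron: bool
    pseudo_mode: str | None  # 'stop' | 'frameshift' | None


def _plan_locus(rng: np.random.Generator, cfg: SyntheticConfig,
                have_ids: bool) -> _LocusPlan:
    partial = rng.random() < cfg.partial_rate
    pseudo = rng.random() < cfg.pseudogene_rate
    fuse = (not partial) and have_ids and rng.random() < cfg.id_fusion_rate
    if partial:
        variant = rng.choice(["no_lrr", "no_head"])
        nlr_class = "CN" if variant == "no_lrr" else "NL"
        completeness = "partial"
    else:
        nlr_class = "NLR-ID" if fuse else "CNL"
        completeness = "complete"
    if pseudo:
        completeness += "_pseudogene"
    id_terminal = str(rng.choice(["N", "C"])) if fuse else None
    group = int(rng.integers(1, 8))
    arm = f"{group}V{rng.choice(['S', 'L'])}"
    return _LocusPlan(
        completeness=completeness,
        nlr_class=nlr_class,
        id_domain=None,  # filled in during build
        id_terminal=id_terminal,
        group=group,
        arm=arm,
        strand=str(rng.choice(["+", "-"])),
        has_intron=rng.random() < cfg.intron_rate,
        pseudo_mode=(str(rng.choice(["stop", "frameshift"])) if pseudo else None),
    )


@dataclass
class _BuiltLocus:
    genomic: str                      # locus insert, forward (pre-strand) orientation
    chain_start: int                  # motif-chain span within genomic
    chain_end: int
    exons: list[tuple[int, int]]      # within genomic
    cds: str
    protein: str
    motif_chain: list[str]
    plan: _LocusPlan


def _build_locus(rng: np.random.Generator, cfg: SyntheticConfig,
                 library: MotifLibrary, plan: _LocusPlan) -> _BuiltLocus:
    cc = library.by_category("CC")
    nb = library.by_category("NB")
    lrr = library.by_category("LRR")
    ids = library.by_category("ID")

    chain: list[MotifDef] = []
    if plan.nlr_class == "CN":           # partial: LRR block omitted
        chain = cc + nb
    elif plan.nlr_class == "NL":         # partial: CC/NB head omitted
        chain = [m for m in nb if not (m.p_loop or m.nb_start)] + \
            list(rng.choice(lrr, size=min(3, len(lrr)), replace=False))
        if not chain:
            chain = lrr[:1]
    else:
        n_lrr_use = int(rng.integers(2, len(lrr) + 1)) if len(lrr) > 1 else 1
        chain = cc + nb + [lrr[i % len(lrr)] for i in range(n_lrr_use)]
    id_motif: MotifDef | None = None
    if plan.nlr_class == "NLR-ID":
        id_motif = ids[int(rng.integers(len(ids)))]
        if plan.id_terminal == "N":
            chain = [id_motif] + chain
        else:
            chain = chain + [id_motif]
    plan.id_domain = id_motif.domain_name if id_motif else None

    # Peptide: M + spacers between motifs; record aa span of each motif.
    segments: list[str] = ["M" + _random_peptide(rng, int(rng.integers(4, 10)))]
    motif_aa_spans: list[tuple[int, int]] = []
    pos = len(segments[0])
    for m in chain:
        motif_aa_spans.append((pos, pos + len(m.consensus)))
        segments.append(m.consensus)
        pos += len(m.consensus)
        spacer = _random_peptide(rng, int(rng.integers(5, 14)))
        segments.append(spacer)
        pos += len(spacer)
    peptide = "".join(segments)
    cds = _encode(rng, peptide) + "TAA"
    protein = peptide

    chain_start_cds = motif_aa_spans[0][0] * 3
    chain_end_cds = motif_aa_spans[-1][1] * 3

    # Pseudogene lesion inside the motif span, placed in a spacer between
    # two motifs so planted motifs stay findable.
    if plan.pseudo_mode is not None and len(motif_aa_spans) >= 2:
        k = len(motif_aa_spans) // 2
        gap_lo = motif_aa_spans[k - 1][1]
        gap_hi = motif_aa_spans[k][0]
        aa_pos = int(rng.integers(gap_lo, gap_hi))
        bp = aa_pos * 3
        if plan.pseudo_mode == "stop":
            cds = cds[:bp] + "TAA" + cds[bp + 3:]
        else:
            ndel = int(rng.integers(1, 3))  # 1-2 bp frameshift
            cds = cds[:bp] + cds[bp + ndel:]
            chain_end_cds -= ndel

    # Optional single intron in the spacer after the first motif.
    exon_break = None
    if plan.has_intron and len(motif_aa_spans) >= 2:
        gap_lo = motif_aa_spans[0][1]
        gap_hi = motif_aa_spans[1][0]
        exon_break = int(rng.integers(gap_lo, gap_hi)) * 3
    if exon_break is not None:
        lo, hi = cfg.intron_length_range
        intron = _random_intron(rng, lo, hi)
        genomic = cds[:exon_break] + intron + cds[exon_break:]
        exons = [(0, exon_break), (exon_break + len(intron), len(genomic))]
        if chain_start_cds >= exon_break:
            chain_start = chain_start_cds + len(intron)
        else:
            chain_start = chain_start_cds
        chain_end = chain_end_cds + (len(intron) if chain_end_cds > exon_break else 0)
        spliced = cds
    else:
        genomic = cds
        exons = [(0, len(genomic))]
        chain_start, chain_end = chain_start_cds, chain_end_cds
        spliced = cds

    return _BuiltLocus(
        genomic=genomic,
        chain_start=chain_start,
        chain_end=chain_end,
        exons=exons,
        cds=spliced,
        protein=protein,
        motif_chain=[m.motif_id for m in chain],
        plan=plan,
    )


def _mutate_copy(rng: np.random.Generator, seq: str, identity: float) -> str:
    n_mut = int(round(len(seq) * (100.0 - identity) / 100.0))
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    bases = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != bases[p]]
        bases[p] = alternatives[int(rng.integers(3))]
    return "".join(bases)


def generate_contig_set(config: SyntheticConfig,
                        library: MotifLibrary) -> GeneratedData:
    """Plant ``config.n_loci`` NLR loci on contigs and return contigs,
    a truth table, and per-locus details (CDS, protein, exon chain).

    Raises :class:`ConfigurationError` when a planted locus cannot fit in
    ``contig_length_range`` with ``min_flank`` of background either side.
    """
    rng = np.random.default_rng(config.seed)
    have_ids = bool(library.by_category("ID"))
    lo_len, hi_len = config.contig_length_range
    flank = config.min_flank
    chain_gap = 3000  # locus-chaining gap the tandem spacer must exceed

    plans = [_plan_locus(rng, config, have_ids) for _ in range(config.n_loci)]
    built = [_build_locus(rng, config, library, p) for p in plans]

    # Group loci onto contigs: a tandem draw puts the next locus on the
    # same contig, separated by a spacer longer than the chaining gap.
    groups: list[list[_BuiltLocus]] = []
    i = 0
    while i < len(built):
        if i + 1 < len(built) and rng.random() < config.tandem_rate:
            groups.append([built[i], built[i + 1]])
            i += 2
        else:
            groups.append([built[i]])
            i += 1
    if len(groups) > config.n_contigs:
        raise ConfigurationError(
            f"n_contigs={config.n_contigs} too small for {len(groups)} "
            f"locus-bearing contigs")

    contigs: dict[str, str] = {}
    truth_rows: list[dict] = []
    details: dict[str, LocusDetail] = {}

    for gi, group in enumerate(groups, start=1):
        contig_id = f"Hv_Contig_{gi}"
        inserts = []
        spacers = []
        total_insert = 0
        for j, bl in enumerate(group):
            inserts.append(bl)
            total_insert += len(bl.genomic)
            if j + 1 < len(group):
                spacer = chain_gap + 500 + int(rng.integers(0, 1000))
                spacers.append(spacer)
                total_insert += spacer
        required = total_insert + 2 * flank
        if required > hi_len:
            raise ConfigurationError(
                f"locus group of {total_insert} bp does not fit in "
                f"contig_length_range={config.contig_length_range}")
        length = int(rng.integers(max(lo_len, required), hi_len + 1))
        offset = int(rng.integers(flank, length - total_insert - flank + 1))

        parts = [_background(rng, offset)]
        cursor = offset
        placed: list[tuple[_BuiltLocus, int]] = []
        for j, bl in enumerate(inserts):
            seq = bl.genomic if bl.plan.strand == "+" else revcomp(bl.genomic)
            parts.append(seq)
            placed.append((bl, cursor))
            cursor += len(seq)
            if j < len(spacers):
                parts.append(_background(rng, spacers[j]))
                cursor += spacers[j]
        parts.append(_background(rng, length - cursor))
        contigs[contig_id] = "".join(parts)

        # Number loci 5'->3' on the forward strand.
        placed.sort(key=lambda t: t[1])
        for k, (bl, off) in enumerate(placed, start=1):
            locus_id = f"{contig_id}_nlr_{k}"
            glen = len(bl.genomic)
            if bl.plan.strand == "+":
                start = off + bl.chain_start
                end = off + bl.chain_end
                exons = [(off + a, off + b) for a, b in bl.exons]
            else:
                start = off + glen - bl.chain_end
                end = off + glen - bl.chain_start
                exons = [(off + glen - b, off + glen - a)
                         for a, b in reversed(bl.exons)]
            truth_rows.append({
                "locus_id": locus_id, "contig_id": contig_id,
                "start": start, "end": end, "strand": bl.plan.strand,
                "true_completeness": bl.plan.completeness,
                "true_class": bl.plan.nlr_class,
                "id_domain": bl.plan.id_domain or "",
                "id_terminal": bl.plan.id_terminal or "",
                "true_group": bl.plan.group,
                "physical_arm": bl.plan.arm,
            })
            details[locus_id] = LocusDetail(
                cds=bl.cds, protein=bl.protein, exons=exons,
                strand=bl.plan.strand, motif_chain=list(bl.motif_chain))

    # Background-only contigs (no planted loci) for false-positive testing.
    for gi in range(len(groups) + 1, config.n_contigs + 1):
        length = int(rng.integers(lo_len, hi_len + 1))
        contigs[f"Hv_Contig_{gi}"] = _background(rng, length)

    # Near-duplicate copies of locus-bearing contigs.
    bearing = [f"Hv_Contig_{gi}" for gi in range(1, len(groups) + 1)]
    for cid in bearing:
        if rng.random() < config.near_duplicate_rate:
            contigs[f"{cid}_dup"] = _mutate_copy(
                rng, contigs[cid], config.duplicate_identity)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return GeneratedData(contigs=contigs, truth=truth, details=details,
                         library=library)


# ---------------------------------------------------------------------------
# Reference hits and transcripts
# ---------------------------------------------------------------------------

GENOME_LETTERS = {"AABBDD": "ABD", "HH": "H", "DD": "D", "AA": "A"}


def generate_reference_hits(truth: pd.DataFrame,
                            genomes: tuple[str, ...] = ("AABBDD", "HH", "DD"),
                            discordant_group_fraction: float = 0.0,
                            seed: int = 0) -> pd.DataFrame:
    """Emit one best hit per (locus, genome) on chromosome
    ``<group><letter>``.

    A ``discordant_group_fraction`` of loci whose physical arm is 4VL get
    group-7 chromosomes in every genome, emulating an ancestral 4L/7S
    translocation that the query species did not undergo.
    """
    if truth.empty:
        raise ConfigurationError("truth table is empty")
    for g in genomes:
        if g not in GENOME_LETTERS:
            raise ConfigurationError(f"unknown genome label {g!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, t in truth.iterrows():
        group = int(t.true_group)
        discordant = (t.physical_arm == "4VL"
                      and rng.random() < discordant_group_fraction)
        shown_group = 7 if discordant else group
        for g in genomes:
            letters = GENOME_LETTERS[g]
            letter = letters[int(rng.integers(len(letters)))]
            identity = round(float(rng.uniform(80, 99)), 1)
            coverage = round(float(rng.uniform(60, 100)), 1)
            rows.append({
                "query_id": t.locus_id,
                "genome": g,
                "chromosome": f"{shown_group}{letter}",
                "identity": identity,
                "coverage": coverage,
                "bitscore": round(identity * coverage / 10.0, 1),
            })
    return pd.DataFrame(rows)


def generate_transcripts(truth: pd.DataFrame, details: dict[str, LocusDetail],
                         transcript_rate: float = 1.0,
                         transcript_error_rate: float = 0.0,
                         seed: int = 0) -> dict[str, str]:
    """Spliced coding sequences of a sample of complete loci, with i.i.d.
    per-base substitution errors.  Headers record the source locus."""
    for name, v in (("transcript_rate", transcript_rate),
                    ("transcript_error_rate", transcript_error_rate)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    k = 0
    for _, t in truth.iterrows():
        if t.true_completeness != "complete":
            continue
        if rng.random() >= transcript_rate:
            continue
        cds = details[t.locus_id].cds
        bases = list(cds)
        errs = np.nonzero(rng.random(len(bases)) < transcript_error_rate)[0]
        for p in errs:
            alternatives = [b for b in "ACGT" if b != bases[p]]
            bases[p] = alternatives[int(rng.integers(3))]
        k += 1
        out[f"tx_{k} source={t.locus_id}"] = "".join(bases)
    return out


def transcript_source(header: str) -> str | None:
    """Parse the source locus id out of a synthetic transcript header."""
    for token in header.split():
        if token.startswith("source="):
            return token[len("source="):]
    return None
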