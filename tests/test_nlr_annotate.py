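"""Motif scanning, locus chaining, completeness and protein prediction."""

import numpy as np
import pytest

from nlrkit import nlr_annotate as na
from nlrkit.errors import NlrkitError
from nlrkit.synthetic_data import (SyntheticConfig, generate_contig_set,
                                   generate_motif_library, revcomp)
from nlrkit.pipeline import score_recovery


def _encode_peptide(peptide):
    """Deterministic single-codon encoding for hand-built fixtures."""
    table = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
             "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
             "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
             "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
    return "".join(table[aa] for aa in peptide)


@pytest.fixture(scope="module")
def background():
    rng = np.random.default_rng(11)
    return lambda n: "".join(rng.choice(list("ACGT"),
                                        p=[0.275, 0.225, 0.225, 0.275],
                                        size=n))


class TestScanMotifs:
    def test_planted_motif_found_at_exact_coordinates(self, library,
                                                      background):
        motif = library.get(library.p_loop_id)
        insert = _encode_peptide(motif.consensus)
        contig = background(300) + insert + background(300)
        hits = na.scan_motifs("c", contig, library)
        mine = [h for h in hits if h.motif_id == motif.motif_id]
        assert len(mine) == 1
        assert (mine[0].start, mine[0].end) == (300, 300 + len(insert))
        assert mine[0].strand == "+"

    def test_minus_strand_mirrored_interval(self, library, background):
        motif = library.get(library.p_loop_id)
        insert = _encode_peptide(motif.consensus)
        forward = background(240) + insert + background(60)
        contig = revcomp(forward)
        hits = [h for h in na.scan_motifs("c", contig, library)
                if h.motif_id == motif.motif_id]
        assert len(hits) == 1
        n = len(contig)
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (n - 240 - len(insert),
                                                n - 240)

    def test_case_insensitive(self, library, background):
        motif = library.get(library.p_loop_id)
        contig = background(90) + _encode_peptide(motif.consensus).lower()
        upper_hits = na.scan_motifs("c", contig.upper(), library)
        soft_hits = na.scan_motifs("c", contig, library)
        assert [(h.motif_id, h.start) for h in upper_hits] == \
            [(h.motif_id, h.start) for h in soft_hits]

    def test_short_contig_empty(self, library):
        assert na.scan_motifs("c", "ACGTACG", library) == []

    def test_random_background_has_no_hits(self, library, background):
        assert na.scan_motifs("c", background(20000), library) == []


class TestChainLoci:
    def test_single_chain_single_locus(self, clean_data, library):
        truth = clean_data.truth
        single = truth[~truth.contig_id.duplicated(keep=False)].iloc[0]
        hits = na.scan_motifs(single.contig_id,
                              clean_data.contigs[single.contig_id], library)
        loci = na.chain_loci(hits, library)
        assert len(loci) == 1
        assert loci[0].locus_id == f"{single.contig_id}_nlr_1"

    def test_distant_chains_split_by_gap(self, variant_data, library):
        tandem = variant_data.truth.groupby("contig_id").size()
        two = tandem[tandem == 2].index
        assert len(two) > 0
        for cid in two:
            hits = na.scan_motifs(cid, variant_data.contigs[cid], library)
            loci = na.chain_loci(hits, library)
            assert len(loci) == 2

    def test_fresh_ploop_after_lrr_splits_contiguous_chain(self, library,
                                                           background):
        """Two back-to-back chains closer than the gap still split at the
        second P-loop."""
        p = library.get(library.p_loop_id).consensus
        s = library.get(library.nb_start_id).consensus
        lrr = library.by_category("LRR")[0].consensus
        spacer = "GSTAK"
        chain = p + spacer + s + spacer + lrr + spacer
        contig = background(200) + _encode_peptide(chain * 2) + background(200)
        hits = na.scan_motifs("c", contig, library)
        loci = na.chain_loci(hits, library)
        assert len(loci) == 2

    def test_chain_invariant_to_hit_order(self, clean_data, library):
        cid = clean_data.truth.iloc[0].contig_id
        hits = na.scan_motifs(cid, clean_data.contigs[cid], library)
        loci_a = na.chain_loci(hits, library)
        loci_b = na.chain_loci(list(reversed(hits)), library)
        assert [(l.start, l.end, l.motif_chain) for l in loci_a] == \
            [(l.start, l.end, l.motif_chain) for l in loci_b]

    def test_mixed_contig_rejected(self, library):
        h1 = na.MotifHit("a", "NB1", 0, "+", 0, 30, 0, 10)
        h2 = na.MotifHit("b", "NB1", 0, "+", 0, 30, 0, 10)
        with pytest.raises(NlrkitError):
            na.chain_loci([h1, h2], library)


class TestCompleteness:
    def test_definition_on_planted_loci(self, variant_data, library):
        loci = []
        for cid, seq in variant_data.contigs.items():
            if cid.endswith("_dup"):
                continue
            loci.extend(na.annotate_contig(cid, seq, library))
        r = score_recovery(variant_data.truth, loci)
        assert r["recall"] == 1.0
        assert r["label_accuracy"] == 1.0

    def test_no_lrr_is_partial(self, library, background):
        p = library.get(library.p_loop_id).consensus
        s = library.get(library.nb_start_id).consensus
        contig = background(150) + _encode_peptide(
            "M" + p + "GSTAK" + s) + background(150)
        loci = na.annotate_contig("c", contig, library)
        assert len(loci) == 1
        assert loci[0].completeness == "partial"

    def test_internal_stop_marks_pseudogene(self, library, background):
        p = library.get(library.p_loop_id).consensus
        s = library.get(library.nb_start_id).consensus
        lrr = library.by_category("LRR")[0].consensus
        cds = _encode_peptide(p + "GSTAK") + "TAA" + _encode_peptide(
            "AKGST" + s + "GSTAK" + lrr)
        contig = background(150) + cds + background(150)
        loci = na.annotate_contig("c", contig, library)
        assert len(loci) == 1
        assert loci[0].completeness == "complete_pseudogene"

    def test_strand_symmetry(self, clean_data, library):
        cid = clean_data.truth.iloc[0].contig_id
        seq = clean_data.contigs[cid]
        fwd = na.annotate_contig(cid, seq, library)
        rev = na.annotate_contig(cid, revcomp(seq), library)
        n = len(seq)
        mirrored = sorted((n - l.end, n - l.start, l.completeness)
                          for l in rev)
        original = sorted((l.start, l.end, l.completeness) for l in fwd)
        assert mirrored == original


class TestPredictProtein:
    def test_exact_cds_recovery(self, clean_data, library):
        homologs = {f"hom_{k}": d.protein
                    for k, d in clean_data.details.items()}
        n_checked = 0
        for cid, seq in clean_data.contigs.items():
            for locus in na.annotate_contig(cid, seq, library):
                if locus.completeness != "complete":
                    continue
                pp = na.predict_protein(locus, seq, homologs)
                det = clean_data.details[locus.locus_id]
                assert pp.predicted
                assert pp.cds == det.cds, locus.locus_id
                assert pp.protein == det.protein
                n_checked += 1
        assert n_checked == len(clean_data.details)

    def test_flank_clipped_at_contig_bounds(self, library, background):
        p = library.get(library.p_loop_id).consensus
        contig = background(100) + _encode_peptide(p) + background(100)
        hits = na.scan_motifs("c", contig, library)
        locus = na.chain_loci(hits, library)[0]
        # should not raise despite flank exceeding the contig
        pp = na.predict_protein(locus, contig, {"h": p}, flank=3000,
                                min_identity=1.0)
        assert pp is not None

    def test_best_homolog_wins(self, clean_data, library):
        lid, det = next(iter(clean_data.details.items()))
        truth = clean_data.truth.set_index("locus_id").loc[lid]
        seq = clean_data.contigs[truth.contig_id]
        locus = [l for l in na.annotate_contig(truth.contig_id, seq, library)
                 if l.locus_id == lid][0]
        rng = np.random.default_rng(0)
        worse = list(det.protein)
        for pos in rng.choice(len(worse), size=len(worse) // 10,
                              replace=False):
            worse[pos] = "A" if worse[pos] != "A" else "G"
        pp = na.predict_protein(locus, seq,
                                {"good": det.protein,
                                 "worse": "".join(worse)})
        assert pp.homolog_id == "good"

    def test_no_homolog_flagged_unpredicted(self, clean_data, library):
        lid, det = next(iter(clean_data.details.items()))
        truth = clean_data.truth.set_index("locus_id").loc[lid]
        seq = clean_data.contigs[truth.contig_id]
        locus = [l for l in na.annotate_contig(truth.contig_id, seq, library)
                 if l.locus_id == lid][0]
        pp = na.predict_protein(locus, seq, {"junk": "WYWYWYWYWY" * 30})
        assert not pp.predicted


def test_gff3_roundtrip(tmp_path, clean_data, library):
    loci = []
    for cid, seq in clean_data.contigs.items():
        loci.extend(na.annotate_contig(cid, seq, library))
    path = tmp_path / "loci.gff3"
    na.write_gff3(loci, path)
    lines = [l for l in path.read_text().splitlines()
             if not l.startswith("#")]
    assert len(lines) == len(loci)
    first = lines[0].split("\t")
    assert first[2] == "NLR_locus"
    assert int(first[3]) == loci[0].start + 1  # 1-based conversion
    assert int(first[4]) == loci[0].end
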