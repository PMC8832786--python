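"""Group assignment, congruence, screens, indels and ID comparison."""

import numpy as np
import pandas as pd
import pytest

from nlrkit import datasets, locate_compare as lc
from nlrkit.errors import NlrkitError
from nlrkit.synthetic_data import (SyntheticConfig, generate_contig_set,
                                   generate_motif_library,
                                   generate_reference_hits, revcomp)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["query_id", "genome", "chromosome",
                                       "identity", "coverage", "bitscore"])


class TestGroupAssignment:
    def test_unanimous_group(self):
        hits = hits_frame([("q", "AABBDD", "1A", 95, 90, 800),
                           ("q", "HH", "1H", 94, 90, 790),
                           ("q", "DD", "1D", 96, 90, 810)])
        a = lc.assign_homoeologous_group(hits)
        assert a["group"] == 1

    def test_majority_rule(self):
        hits = hits_frame([("q", "AABBDD", "7D", 95, 90, 800),
                           ("q", "HH", "5H", 94, 90, 790),
                           ("q", "DD", "7D", 96, 90, 810)])
        assert lc.assign_homoeologous_group(hits)["group"] == 7

    def test_three_way_tie_unassigned(self):
        hits = hits_frame([("q", "AABBDD", "1A", 95, 90, 800),
                           ("q", "HH", "2H", 94, 90, 790),
                           ("q", "DD", "3D", 96, 90, 810)])
        assert lc.assign_homoeologous_group(hits)["group"] is None

    def test_un_excluded_from_vote(self):
        hits = hits_frame([("q", "AABBDD", "Un", 95, 90, 800),
                           ("q", "HH", "4H", 94, 90, 790),
                           ("q", "DD", "4D", 96, 90, 810)])
        assert lc.assign_homoeologous_group(hits)["group"] == 4

    def test_best_hit_by_bitscore(self):
        hits = hits_frame([("q", "HH", "2H", 90, 90, 500),
                           ("q", "HH", "6H", 99, 99, 900),
                           ("q", "AABBDD", "6A", 95, 90, 800),
                           ("q", "DD", "6D", 96, 90, 810)])
        a = lc.assign_homoeologous_group(hits)
        assert a["per_genome_chromosome"]["HH"] == "6H"
        assert a["group"] == 6

    def test_no_hits_unassigned(self):
        a = lc.assign_homoeologous_group(hits_frame([]))
        assert a == {"per_genome_chromosome": {}, "group": None}


class TestCongruence:
    def test_published_table_counts_and_4vl_flag(self):
        markers = datasets.load_chromosome_locations()
        assignments = lc.marker_table_assignments(markers)
        report = lc.congruence_report(assignments, markers)
        assert report["status_counts"]["Complete NLR"] == 61
        assert report["status_counts"]["Partial or pseudogene"] == 26
        per_arm = report["per_arm"].set_index("physical_arm")
        assert bool(per_arm.loc["4VL", "discordant"])
        assert per_arm.loc["4VL", "modal_group"] == 7
        concordant = [a for a in per_arm.index if not a.startswith("4")]
        assert not per_arm.loc[concordant, "discordant"].any()

    def test_duplicate_marker_surfaced(self):
        markers = datasets.load_chromosome_locations()
        assignments = lc.marker_table_assignments(markers)
        report = lc.congruence_report(assignments, markers)
        assert "Hv_Contig_55_nlr_1" in report["duplicated_markers"]

    def test_all_concordant_no_flags(self):
        markers = pd.DataFrame({
            "nlr_id": ["m1", "m2"], "status": ["Complete NLR"] * 2,
            "g1": ["3A", "5A"], "g2": ["3H", "5H"], "g3": ["3D", "5D"],
            "physical_arm": ["3VL", "5VS"]})
        assignments = lc.marker_table_assignments(markers)
        report = lc.congruence_report(assignments, markers)
        assert not report["per_arm"]["discordant"].any()

    def test_unknown_marker_listed_not_fatal(self):
        assignments = pd.DataFrame({"nlr_id": ["m1"], "group": [3]})
        markers = pd.DataFrame({
            "nlr_id": ["m1", "ghost"], "status": ["Complete NLR"] * 2,
            "physical_arm": ["3VL", "3VL"]})
        report = lc.congruence_report(assignments, markers)
        assert report["unknown_markers"] == ["ghost"]

    def test_discordance_fraction_converges(self):
        lib = generate_motif_library(42, 3, 8, 4)
        cfg = SyntheticConfig(seed=13, n_loci=400, n_contigs=440)
        data = generate_contig_set(cfg, lib)
        frac = 0.5
        hits = generate_reference_hits(data.truth,
                                       discordant_group_fraction=frac,
                                       seed=3)
        assignments = lc.assign_groups(hits).rename(
            columns={"query_id": "nlr_id"})
        markers = data.truth.rename(columns={"locus_id": "nlr_id"})[
            ["nlr_id", "physical_arm"]]
        markers["status"] = "Complete NLR"
        report = lc.congruence_report(assignments, markers)
        sub = report["per_locus"]
        sub = sub[sub.physical_arm == "4VL"]
        n = len(sub)
        assert n >= 20
        realized = sub.discordant.sum()
        sigma = np.sqrt(frac * (1 - frac) * n)
        assert abs(realized - frac * n) <= 3 * sigma

    def test_polymorphism_rate_rounding(self):
        assert lc.marker_polymorphism_rate(105, 757) == 14
        assert lc.marker_polymorphism_rate(0, 0) == 0


class TestOrthologueScreen:
    def test_published_mla_counts(self):
        table = datasets.load_r_gene_orthologues()
        passed = lc.screen_orthologues(table)
        assert lc.locus_paralogue_count(passed, 30.2) == 18
        assert lc.locus_paralogue_count(passed, 8.6) == 15
        assert lc.locus_paralogue_count(passed, 500.0) == 0

    @pytest.mark.parametrize("identity,coverage,passes", [
        (91.5, 93.4, True), (79.9, 93.4, False), (91.5, 59.0, False),
        (80.0, 93.4, False),  # thresholds are strict inequalities
    ])
    def test_threshold_edges(self, identity, coverage, passes):
        df = pd.DataFrame({"identity": [identity], "coverage": [coverage]})
        assert (len(lc.screen_orthologues(df)) == 1) is passes

    def test_group_match_required(self):
        df = pd.DataFrame({"identity": [95.0, 95.0],
                           "coverage": [95.0, 95.0],
                           "query_group": [1, 1], "group": [1, 3]})
        passed = lc.screen_orthologues(df)
        assert len(passed) == 1 and passed.iloc[0].group == 1

    def test_threshold_monotonicity(self):
        table = datasets.load_r_gene_orthologues()
        sizes = []
        for ident in (70, 80, 85, 90):
            th = lc.ScreenThresholds(ortho_identity=ident)
            sizes.append(len(lc.screen_orthologues(table, th)))
        assert sizes == sorted(sizes, reverse=True)


class TestExpression:
    def test_perfect_transcript_expressed(self):
        cds = "ATG" + "GCTAAAGTT" * 40 + "TAA"
        table = lc.match_expression({"l1": cds}, {"t1": cds})
        row = table.iloc[0]
        assert row.expressed and row.identity == 100.0

    def test_identity_threshold_strict(self):
        rng = np.random.default_rng(7)
        cds = "".join(rng.choice(list("ACGT"), size=900))
        tx = list(cds)
        for p in rng.choice(900, size=54, replace=False):  # 94% identity
            tx[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tx[p]]
        table = lc.match_expression({"l1": cds}, {"t1": "".join(tx)})
        assert not table.iloc[0].expressed

    def test_coverage_threshold(self):
        rng = np.random.default_rng(8)
        cds = "".join(rng.choice(list("ACGT"), size=1000))
        table = lc.match_expression({"l1": cds}, {"t1": cds[:800]})
        row = table.iloc[0]
        assert row.coverage == pytest.approx(80.0, abs=1.0)
        assert not row.expressed

    def test_splice_match_on_planted_intron(self, clean_data):
        intron_loci = {lid: det for lid, det in clean_data.details.items()
                       if len(det.exons) == 2}
        assert intron_loci
        lid, det = next(iter(intron_loci.items()))
        contig = clean_data.contigs[
            clean_data.truth.set_index("locus_id").loc[lid, "contig_id"]]
        a = min(s for s, _ in det.exons)
        b = max(e for _, e in det.exons)
        verdict = lc.compare_splice(det.exons, det.cds, contig[a:b], a,
                                    det.strand)
        assert verdict == "match"

    def test_shifted_donor_reported_at_junction_one(self, clean_data):
        intron_loci = {lid: det for lid, det in clean_data.details.items()
                       if len(det.exons) == 2}
        lid, det = next(iter(intron_loci.items()))
        contig = clean_data.contigs[
            clean_data.truth.set_index("locus_id").loc[lid, "contig_id"]]
        a = min(s for s, _ in det.exons)
        b = max(e for _, e in det.exons)
        # simulate a transcript spliced 30 bp downstream of the true donor
        exon1_len = det.exons[0][1] - det.exons[0][0]
        if det.strand == "-":
            exon1_len = det.exons[1][1] - det.exons[1][0]
        span = contig[a:b]
        oriented = span if det.strand == "+" else revcomp(span)
        intron_len = len(span) - len(det.cds)
        shifted = (oriented[:exon1_len + 30]
                   + oriented[exon1_len + 30 + intron_len:])
        verdict = lc.compare_splice(det.exons, shifted, span, a, det.strand)
        assert verdict == "mismatch_at_junction_1"


class TestPrivateIndels:
    def test_private_deletion_reported(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=600))
        query = base[:300] + base[306:]  # 6 bp deletion
        orths = {f"o{i}": base for i in range(3)}
        indels = lc.find_private_indels(query, orths)
        # gap placement is ambiguous within flanking repeats: accept the
        # planted deletion anywhere in its equivalence window
        assert any(length == 6 and kind == "del" and abs(pos - 300) <= 6
                   for pos, length, kind in indels)

    def test_shared_indel_excluded(self):
        rng = np.random.default_rng(10)
        base = "".join(rng.choice(list("ACGT"), size=600))
        query = base[:300] + base[306:]
        orths = {"o1": base, "o2": query}  # o2 shares the deletion
        assert lc.find_private_indels(query, orths) == []

    def test_identical_sequences_empty(self):
        seq = "ACGT" * 100
        assert lc.find_private_indels(seq, {"o1": seq}) == []

    def test_no_orthologues_rejected(self):
        with pytest.raises(NlrkitError):
            lc.find_private_indels("ACGT", {})


class TestIdMembership:
    def test_published_membership_counts(self):
        table = datasets.load_integrated_domains()
        summary, total = lc.shared_unique_ids(table)
        assert total == 65
        by = summary.set_index("species")
        assert tuple(by.loc["VV", ["total", "shared", "unique"]]) == \
            (15, 12, 3)
        assert by.loc["AA", "unique"] == 19
        assert by.loc["HH", "unique"] == 6
        assert by.loc["Bd", "unique"] == 0

    def test_partition_shared_plus_unique(self):
        table = datasets.load_integrated_domains()
        summary, _ = lc.shared_unique_ids(table)
        assert (summary["shared"] + summary["unique"]
                == summary["total"]).all()

    def test_single_row_single_species(self):
        table = pd.DataFrame({"id_name": ["X"], "description": ["x"],
                              "genomes": ["VV"]})
        summary, total = lc.shared_unique_ids(table)
        assert total == 1
        row = summary.set_index("species").loc["VV"]
        assert tuple(row[["total", "shared", "unique"]]) == (1, 0, 1)

    def test_empty_table_zeros(self):
        summary, total = lc.shared_unique_ids(
            pd.DataFrame(columns=["id_name", "genomes"]))
        assert total == 0 and summary.empty
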