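"""End-to-end pipeline: simulate → dedup → annotate → rescue → predict →
classify → tree → locate → screens → compare.

The pipeline is deterministic given (config, inputs): every stochastic
stage draws from the configured seed, so re-running writes byte-identical
outputs.  A manifest records per-stage input/output counts and the
parameter values in force.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import contig_prep, datasets, domain_classify, locate_compare, \
    nlr_annotate, phylo
from .errors import NlrkitError
from .fileio import write_fasta, write_tsv
from .locate_compare import ScreenThresholds
from .synthetic_data import (GeneratedData, SyntheticConfig,
                             generate_contig_set, generate_motif_library,
                             generate_reference_hits, generate_transcripts,
                             transcript_source)


@dataclass
class PipelineConfig:
    """One key per stage parameter; defaults are the published run's
    values (dedup 95, e-value 1e-3, flank 3000, screens 80/60 and 95/90,
    1000 bootstrap replicates)."""

    seed: int = 42
    out_dir: str = "nlrkit_out"
    dedup_identity: float = 95.0
    evalue_max: float = 1e-3
    flank: int = 3000
    max_gap_bp: int = 3000
    bootstrap_replicates: int = 1000
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    synthetic: SyntheticConfig = field(default_factory=lambda: SyntheticConfig(
        n_contigs=40, n_loci=30, pseudogene_rate=0.15, partial_rate=0.15,
        id_fusion_rate=0.1, tandem_rate=0.1, near_duplicate_rate=0.1,
        discordant_group_fraction=0.5, transcript_rate=0.8,
        transcript_error_rate=0.005))
    library_counts: tuple[int, int, int, int] = (3, 8, 4, 4)


def simulate_inputs(config: PipelineConfig):
    """Generate the full synthetic input bundle for one pipeline run."""
    n_cc, n_nb, n_lrr, n_id = config.library_counts
    syn = config.synthetic
    if syn.seed != config.seed:
        syn = SyntheticConfig(**{**asdict(syn), "seed": config.seed})
    library = generate_motif_library(config.seed, n_cc, n_nb, n_lrr, n_id)
    data = generate_contig_set(syn, library)
    hits = generate_reference_hits(
        data.truth, discordant_group_fraction=syn.discordant_group_fraction,
        seed=config.seed + 1)
    transcripts = generate_transcripts(
        data.truth, data.details, syn.transcript_rate,
        syn.transcript_error_rate, seed=config.seed + 2)
    homologs = {f"hom_{lid}": d.protein for lid, d in data.details.items()}
    return data, hits, transcripts, homologs


def run_pipeline(config: PipelineConfig,
                 data: GeneratedData | None = None,
                 ref_hits: pd.DataFrame | None = None,
                 transcripts: dict[str, str] | None = None,
                 homolog_db: dict[str, str] | None = None) -> dict:
    """Execute all stages; write reports under ``config.out_dir`` and
    return the manifest.

    Without explicit inputs a synthetic bundle is generated from the
    configured study conditions.  Any stage error halts the run with the
    stage name attached.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"parameters": {
        "seed": config.seed,
        "dedup_identity": config.dedup_identity,
        "evalue_max": config.evalue_max,
        "flank": config.flank,
        "max_gap_bp": config.max_gap_bp,
        "bootstrap_replicates": config.bootstrap_replicates,
        "thresholds": asdict(config.thresholds),
    }}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage
                raise NlrkitError(f"stage {name}: {exc}") from exc
        return wrap

    if data is None:
        data, ref_hits, transcripts, homolog_db = simulate_inputs(config)
    library = data.library
    contigs = data.contigs
    manifest["simulate"] = {"n_contigs": len(contigs),
                            "n_planted_loci": len(data.truth)}

    # -- dedup ------------------------------------------------------------
    decisions = stage("dedup")(lambda: contig_prep.remove_redundant(
        contigs, threshold=config.dedup_identity))
    retained_ids = list(decisions.loc[decisions.status == "retained",
                                      "contig_id"])
    removed_ids = list(decisions.loc[decisions.status == "removed",
                                     "contig_id"])
    manifest["dedup"] = {"input": len(contigs), "retained": len(retained_ids),
                         "removed": len(removed_ids)}

    # -- mask + annotate --------------------------------------------------
    def annotate_all():
        loci = []
        for cid in retained_ids:
            masked = contig_prep.mask_low_complexity(contigs[cid])
            loci.extend(nlr_annotate.annotate_contig(
                cid, masked, library, max_gap_bp=config.max_gap_bp))
        return loci
    loci = stage("annotate")(annotate_all)
    completeness_counts = pd.Series(
        [l.completeness for l in loci]).value_counts().to_dict()
    manifest["annotate"] = {"n_loci": len(loci),
                            "completeness": completeness_counts}

    # -- rescue removed contigs -------------------------------------------
    def rescue():
        catalog_nlrs = {l.locus_id: contigs[l.contig_id][l.start:l.end]
                        for l in loci if l.completeness == "complete"}
        removed = {cid: contigs[cid] for cid in removed_ids}

        def annotate_fn(cid, seq):
            for l in nlr_annotate.annotate_contig(cid, seq, library,
                                                  max_gap_bp=config.max_gap_bp):
                yield l.locus_id, l.completeness, seq[l.start:l.end]
        return contig_prep.rescue_removed(removed, catalog_nlrs, annotate_fn)
    rescue_decisions = stage("rescue")(rescue)
    rescued_ids = list(rescue_decisions.loc[
        rescue_decisions.status == "rescued", "contig_id"])
    for cid in rescued_ids:
        loci.extend(nlr_annotate.annotate_contig(
            cid, contig_prep.mask_low_complexity(contigs[cid]), library,
            max_gap_bp=config.max_gap_bp))
    manifest["rescue"] = {"removed_checked": len(removed_ids),
                          "rescued": len(rescued_ids)}

    # -- protein prediction ------------------------------------------------
    def predict():
        out = {}
        for l in loci:
            if l.completeness != "complete":
                continue
            pp = nlr_annotate.predict_protein(
                l, contigs[l.contig_id], homolog_db, flank=config.flank)
            if pp.predicted:
                out[l.locus_id] = pp
        return out
    proteins = stage("predict")(predict) if homolog_db else {}
    manifest["predict"] = {"complete_loci": sum(
        l.completeness == "complete" for l in loci),
        "predicted": len(proteins)}

    # -- domain classification --------------------------------------------
    def classify():
        anns = []
        for lid, pp in proteins.items():
            anns.extend(domain_classify.annotate_domains_builtin(
                lid, pp.protein, library))
        merged = domain_classify.merge_domain_sources(
            anns, [], evalue_max=config.evalue_max)
        records, rejected = domain_classify.build_records(
            {lid: proteins[lid].protein for lid in proteins}, merged)
        return records, rejected
    records, rejected = stage("classify")(classify)
    summary = domain_classify.summarize_records(records)
    loci_by_id = {l.locus_id: l for l in loci}
    pairs = domain_classify.find_paired_nlrs(loci)
    manifest["classify"] = {
        "records": len(records), "rejected": len(rejected),
        "classes": {r.nlr_class: 0 for r in records} | pd.Series(
            [r.nlr_class for r in records]).value_counts().to_dict(),
        "paired": len(pairs)}

    # -- NB-ARC tree -------------------------------------------------------
    tree = None
    profiles = None
    def build_tree():
        nbarc = {}
        for rec in records:
            spans = [d for d in rec.domains if d.domain_name == "NB-ARC"]
            if len(spans) != 1:
                continue
            nbarc[rec.protein_id] = phylo.extract_nbarc(
                proteins[rec.protein_id].protein, spans)
        if len(nbarc) < 4:
            return None, None
        t = phylo.bootstrap_support(
            nbarc, n_replicates=config.bootstrap_replicates,
            seed=config.seed + 3)
        prof = phylo.attach_motif_profiles(
            t, {lid: loci_by_id[lid] for lid in nbarc})
        return t, prof
    tree, profiles = stage("tree")(build_tree)
    manifest["tree"] = {"leaves": len(tree.labels) if tree else 0,
                        "bootstrap": config.bootstrap_replicates}

    # -- chromosome location ----------------------------------------------
    assignments = (locate_compare.assign_groups(ref_hits)
                   if ref_hits is not None and not ref_hits.empty
                   else pd.DataFrame(columns=["query_id", "group"]))
    markers = data.truth.rename(columns={"locus_id": "nlr_id"})[
        ["nlr_id", "physical_arm"]].copy()
    markers["status"] = [
        "Complete NLR" if c == "complete" else "Partial or pseudogene"
        for c in data.truth["true_completeness"]]
    congruence = stage("locate")(lambda: locate_compare.congruence_report(
        assignments.rename(columns={"query_id": "nlr_id"}), markers))
    manifest["locate"] = {
        "assigned": int(assignments["group"].notna().sum())
        if not assignments.empty else 0,
        "arms_flagged": int(congruence["per_arm"]["discordant"].sum())
        if len(congruence["per_arm"]) else 0}

    # -- expression screen --------------------------------------------------
    def expression():
        cds = {lid: pp.cds for lid, pp in proteins.items()}
        table = locate_compare.match_expression(
            cds, transcripts or {}, thresholds=config.thresholds)
        splices = []
        for _, row in table[table.expressed].iterrows():
            pp = proteins[row.locus_id]
            locus = loci_by_id[row.locus_id]
            a = min(s for s, _ in pp.exons)
            b = max(e for _, e in pp.exons)
            span = contigs[locus.contig_id][a:b]
            verdict = locate_compare.compare_splice(
                pp.exons, transcripts[row.transcript], span, a, locus.strand,
                tolerance=3)
            splices.append({"locus_id": row.locus_id, "splice": verdict})
        return table, pd.DataFrame(splices, columns=["locus_id", "splice"])
    expr_table, splice_table = stage("expression")(expression)
    manifest["expression"] = {
        "expressed": int(expr_table["expressed"].sum())
        if len(expr_table) else 0,
        "splice_match": int((splice_table["splice"] == "match").sum())
        if len(splice_table) else 0}

    # -- integrated-domain comparison ---------------------------------------
    id_table = datasets.load_integrated_domains()
    id_summary, id_total = locate_compare.shared_unique_ids(id_table)
    manifest["compare_ids"] = {"id_types": id_total}

    # -- reports -------------------------------------------------------------
    out = config.out_dir
    write_tsv(decisions, os.path.join(out, "dedup_decisions.tsv"))
    write_tsv(rescue_decisions, os.path.join(out, "rescue_decisions.tsv"))
    nlr_annotate.write_gff3(loci, os.path.join(out, "nlr_loci.gff3"))
    write_fasta({lid: pp.protein for lid, pp in proteins.items()},
                os.path.join(out, "nlr_proteins.faa"))
    write_tsv(summary, os.path.join(out, "class_summary.tsv"))
    write_tsv(pairs, os.path.join(out, "paired_nlrs.tsv"))
    if tree is not None:
        with open(os.path.join(out, "nbarc_tree.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        write_tsv(profiles, os.path.join(out, "motif_profiles.tsv"))
    write_tsv(assignments, os.path.join(out, "group_assignments.tsv"))
    write_tsv(congruence["per_arm"], os.path.join(out, "congruence_arms.tsv"))
    write_tsv(expr_table, os.path.join(out, "expression.tsv"))
    write_tsv(splice_table, os.path.join(out, "splice_comparison.tsv"))
    write_tsv(id_summary, os.path.join(out, "id_shared_unique.tsv"))
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# Locus-recovery scoring against planted truth
# ---------------------------------------------------------------------------

def score_recovery(truth: pd.DataFrame,
                   loci: list[nlr_annotate.NlrLocus]) -> dict:
    """Precision/recall of locus recovery against a planted truth table.

    A prediction matches a truth row when it lies on the same contig and
    strand and the intervals overlap.  Label accuracy is the fraction of
    matched pairs whose completeness labels agree exactly.
    """
    pred_by_contig: dict[str, list] = {}
    for l in loci:
        pred_by_contig.setdefault(l.contig_id, []).append(l)
    matched_pred = set()
    n_matched = 0
    n_label_ok = 0
    for _, t in truth.iterrows():
        found = None
        for l in pred_by_contig.get(t.contig_id, []):
            if (l.strand == t.strand and l.start < t.end
                    and t.start < l.end):
                found = l
                break
        if found is not None:
            n_matched += 1
            matched_pred.add(id(found))
            if found.completeness == t.true_completeness:
                n_label_ok += 1
    n_pred = len(loci)
    n_truth = len(truth)
    return {
        "precision": (sum(1 for l in loci if id(l) in matched_pred) / n_pred
                      if n_pred else 1.0),
        "recall": n_matched / n_truth if n_truth else 1.0,
        "label_accuracy": n_label_ok / n_matched if n_matched else 1.0,
        "n_truth": n_truth,
        "n_predicted": n_pred,
    }
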