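"""End-to-end orchestration: digestion -> quantification -> consistency
filter -> regulation -> isoforms -> phospho -> RNA -> enrichment.

``run_analysis`` operates on in-memory tables (what the tests and the
acceptance script use); ``run_pipeline`` adds file I/O, report writing and
a provenance record around it.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import consistency, enrichment, isoforms, phospho, quantification, regulation, rna_protein
from .config import FRACTIONS, FractionMeta, PipelineConfig
from .io import (
    read_annotations,
    read_evidence,
    read_fasta,
    read_fpkm,
    read_fractions,
    write_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    groups: list
    intensities: pd.DataFrame           # normalized, all groups
    cleaned: pd.DataFrame               # after the cleaning rules
    consistency: consistency.ConsistencyResult
    filtered: pd.DataFrame              # per-cell intensities, passed groups
    detection: pd.DataFrame
    clusters: regulation.ClusterResult | None
    regulation_summary: dict
    ibaq: pd.DataFrame
    abundance: quantification.AbundanceSummary
    isoform_profiles: pd.DataFrame
    isoform_concordance: pd.DataFrame
    phospho_sites: pd.DataFrame
    phospho_summary: dict
    gene_table: pd.DataFrame
    correlations: pd.DataFrame
    profile_classes: pd.DataFrame
    coordinated: pd.DataFrame
    degron_summary: pd.DataFrame
    term_enrichment: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_analysis(
    evidence: pd.DataFrame,
    fasta: dict[str, str],
    fractions: Sequence[FractionMeta],
    rna: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    cfg = config or PipelineConfig()

    # --- quantification ---------------------------------------------------
    groups = quantification.group_proteins(evidence)
    flags = quantification.group_flags(evidence, groups)
    raw, norm = quantification.aggregate_and_normalize(evidence, groups)

    # --- cleaning + self-consistency -------------------------------------
    kept_groups, cleaned = consistency.clean_evidence(
        groups, norm, flags["is_contaminant"], flags["is_reverse"],
        min_peptides=cfg.min_peptides,
    )
    cons = consistency.consistency_filter(cleaned, fractions,
                                          tau=cfg.tau, rho_max=cfg.rho_max)
    passed = cons.passed
    filtered = consistency.load_normalized(cleaned.loc[passed], fractions)

    # --- regulation -------------------------------------------------------
    detection = regulation.detect_regulated(filtered, cutoff=cfg.fold_cutoff)
    reg_profiles = filtered.loc[detection.index[detection["regulated"]],
                                list(FRACTIONS)]
    clusters = None
    if len(reg_profiles) >= cfg.n_clusters + 1:
        clusters = regulation.cluster_profiles(reg_profiles,
                                               n_clusters=cfg.n_clusters,
                                               cutoff=cfg.fold_cutoff)
        assignments = clusters.assignments
    else:
        logger.info("too few regulated profiles (%d) for clustering; "
                    "assigning by peak fraction only", len(reg_profiles))
        det = detection.loc[detection["regulated"]]
        assignments = pd.DataFrame({
            "cluster": det["argmax_fraction"].map(regulation.FRACTION_CLUSTER),
            "broad_class": det["argmax_fraction"].map(
                lambda f: regulation.CLUSTER_BROAD_CLASS[
                    regulation.FRACTION_CLUSTER[f]]),
            "argmax_fraction": det["argmax_fraction"],
            "fold": det["fold"],
        })
    reg_summary = regulation.summarize_regulation(assignments, len(filtered))

    # --- iBAQ and cumulative abundance ------------------------------------
    two_pep = [g.group_id for g in groups
               if g.peptide_count >= cfg.min_peptides
               and not flags.loc[g.group_id].any()]
    ibaq = quantification.compute_ibaq(norm.loc[norm.index.isin(two_pep)],
                                       [g for g in groups if g.group_id in set(two_pep)],
                                       fasta)
    abundance = quantification.cumulative_abundance(ibaq["ASYNC"])

    # --- isoforms ---------------------------------------------------------
    iso_prof = isoforms.isoform_profiles(evidence)
    iso_conc = isoforms.concordance_table(iso_prof, r0=cfg.concordance_r0)

    # --- phospho ----------------------------------------------------------
    sites = phospho.extract_phospho_sites(evidence)
    regulated_genes = sorted({
        g.gene_id for g in kept_groups
        if g.group_id in set(assignments.index)
    })
    if len(sites):
        testable, ph_summary = phospho.detect_regulated_phospho(
            sites, cutoff=cfg.phospho_cutoff)
        ph_summary.update(
            {k: v for k, v in phospho.residue_breakdown_and_overlap(
                sites, testable, set(regulated_genes)).items()
             if not isinstance(v, pd.DataFrame)})
        ph_sites = testable
    else:
        ph_sites, ph_summary = sites, {"n_testable": 0, "n_regulated": 0,
                                       "regulated_percent": 0}

    # --- RNA --------------------------------------------------------------
    gene_table = pd.DataFrame()
    correlations = pd.DataFrame(columns=["scope", "n", "rho"])
    profile_classes = pd.DataFrame()
    coordinated = pd.DataFrame()
    if rna is not None:
        fpkm = rna_protein.summarize_fpkm(rna)
        gene_groups = pd.Series({g.group_id: g.gene_id for g in kept_groups})
        prot_gene = cleaned.groupby(gene_groups.reindex(cleaned.index)).sum()
        prot_gene.index.name = "gene_id"
        # gene_table: protein F1..F6 + ASYNC, RNA G1/S/G2M + ASYNC_rna
        gene_table = rna_protein.merge_gene_level(prot_gene, fpkm)
        pooled = rna_protein.pool_protein_phases(gene_table, fractions)
        rna_phases = gene_table[["G1", "S", "G2M"]]
        corr_rows = []
        scopes = [("async", gene_table["ASYNC"], gene_table["ASYNC_rna"])]
        scopes += [(ph, pooled[ph], rna_phases[ph]) for ph in ("G1", "S", "G2M")]
        for scope, prot_col, rna_col in scopes:
            frame = pd.DataFrame({"prot": prot_col, "rna": rna_col})
            try:
                rho, n = rna_protein.correlate_abundances(frame, "prot", "rna")
                corr_rows.append((scope, n, rho))
            except ValueError:
                logger.info("scope %s: too few records for correlation", scope)
        correlations = pd.DataFrame(corr_rows, columns=["scope", "n", "rho"])
        profile_classes = rna_protein.classify_profile_correlation(
            pooled, rna_phases, r0=cfg.profile_r0)
        coordinated = rna_protein.coordinated_subset(
            regulated_genes, rna_phases, pooled, rna_cutoff=cfg.rna_fold_cutoff)

    # --- enrichment -------------------------------------------------------
    degron_summary = pd.DataFrame()
    term_enrichment = pd.DataFrame()
    if fasta:
        coord_genes = list(coordinated.index) if len(coordinated) else regulated_genes
        _, degron_summary = enrichment.scan_degrons(fasta, coord_genes)
    if annotations is not None and len(regulated_genes):
        background = sorted({g.gene_id for g in kept_groups})
        in_bg = [g for g in regulated_genes if g in set(background)]
        if in_bg:
            term_enrichment = enrichment.enrich_terms(in_bg, annotations,
                                                      background)

    summary = {
        "n_groups": len(groups),
        "n_cleaned": int(len(cleaned)),
        "n_filtered": int(len(filtered)),
        "n_regulated": int(len(assignments)),
        "regulated_percent": reg_summary["regulated_percent"],
        "broad_class_counts": reg_summary["broad_class_counts"],
        "k50": abundance.k50,
        "k90": abundance.k90,
        "n_phospho_testable": ph_summary.get("n_testable", 0),
        "n_phospho_regulated": ph_summary.get("n_regulated", 0),
        "phospho_regulated_percent": ph_summary.get("regulated_percent", 0),
        "n_coordinated": int(len(coordinated)),
        "n_gene_records": int(len(gene_table)),
    }
    return AnalysisResult(
        groups=groups, intensities=norm, cleaned=cleaned, consistency=cons,
        filtered=filtered, detection=detection, clusters=clusters,
        regulation_summary=reg_summary, ibaq=ibaq, abundance=abundance,
        isoform_profiles=iso_prof, isoform_concordance=iso_conc,
        phospho_sites=ph_sites, phospho_summary=ph_summary,
        gene_table=gene_table, correlations=correlations,
        profile_classes=profile_classes, coordinated=coordinated,
        degron_summary=degron_summary, term_enrichment=term_enrichment,
        summary=summary,
    )


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> AnalysisResult:
    """File-based entry point: read the inputs named in the config, run the
    analysis, write every module report plus a JSON summary with a
    provenance record."""
    base = Path(base_dir)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    def _resolve(name: str) -> Path:
        p = Path(name)
        return p if p.is_absolute() else base / p

    evidence_path = _resolve(config.evidence)
    if not evidence_path.exists():
        raise FileNotFoundError(f"stage quantify: evidence table {evidence_path} missing")
    evidence = read_evidence(evidence_path)
    fasta_path = _resolve(config.fasta)
    fasta = read_fasta(fasta_path) if fasta_path.exists() else {}
    fractions = read_fractions(_resolve(config.fractions))
    rna = None
    fpkm_path = _resolve(config.fpkm)
    if fpkm_path.exists():
        rna = read_fpkm(fpkm_path)
    annotations = None
    ann_path = _resolve(config.annotations)
    if ann_path.exists():
        annotations = read_annotations(ann_path)

    result = run_analysis(evidence, fasta, fractions, rna, annotations, config)

    out = _resolve(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(result.intensities, out / "protein_intensities.tsv", index=True)
    write_tsv(result.consistency.table, out / "consistency_filter.tsv", index=True)
    write_tsv(result.detection, out / "regulation_detection.tsv", index=True)
    if result.clusters is not None:
        write_tsv(result.clusters.assignments, out / "clusters.tsv", index=True)
    write_tsv(result.ibaq, out / "ibaq.tsv", index=True)
    write_tsv(result.isoform_profiles, out / "isoform_profiles.tsv", index=True)
    write_tsv(result.isoform_concordance, out / "isoform_concordance.tsv", index=True)
    write_tsv(result.phospho_sites, out / "phospho_sites.tsv")
    if len(result.gene_table):
        write_tsv(result.gene_table, out / "gene_table.tsv", index=True)
        write_tsv(result.correlations, out / "rna_protein_correlations.tsv")
        write_tsv(result.profile_classes, out / "profile_concordance.tsv", index=True)
        write_tsv(result.coordinated, out / "coordinated_subset.tsv", index=True)
    if len(result.degron_summary):
        write_tsv(result.degron_summary, out / "degron_summary.tsv", index=True)
    if len(result.term_enrichment):
        write_tsv(result.term_enrichment, out / "term_enrichment.tsv")

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stage_rows": {
            "evidence": int(len(evidence)),
            "groups": len(result.groups),
            "cleaned": int(len(result.cleaned)),
            "filtered": int(len(result.filtered)),
            "regulated": result.summary["n_regulated"],
            "gene_records": result.summary["n_gene_records"],
        },
    }
    (out / "summary.json").write_text(
        json.dumps({"summary": result.summary, "provenance": provenance},
                   indent=2, sort_keys=True))
    return result
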