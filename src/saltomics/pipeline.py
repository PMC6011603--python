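"""Workflow orchestration: DEG -> DAP -> concordance -> AS -> miRNA ->
screening -> network, with every intermediate table written and a run
report of all set sizes."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import concordance, diffexpr, io, mirna, network, proteomics, screening, splicing
from .config import COMPARISONS, PipelineConfig, Thresholds

log = logging.getLogger("saltomics")

__all__ = ["PipelineResult", "run_all", "run_from_files"]


@dataclass
class PipelineResult:
    deg_results: pd.DataFrame
    dap_results: pd.DataFrame
    tallies: dict
    pairs: pd.DataFrame
    correlations: pd.DataFrame
    as_counts: pd.DataFrame
    as_degs: pd.DataFrame
    as_candidates: pd.DataFrame
    de_mirnas: pd.DataFrame
    target_hits: pd.DataFrame
    gene_chains: pd.DataFrame
    protein_chains: pd.DataFrame
    candidates: pd.DataFrame
    graph: object
    hubs: list
    components: list
    report: dict


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_all(
    expression: pd.DataFrame,
    proteins: pd.DataFrame,
    mirna_counts: pd.DataFrame,
    mirna_seqs: dict,
    cds_seqs: dict,
    as_events: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    thresholds: Thresholds | None = None,
    osmotic_genes: set | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full integration workflow on in-memory tables.

    When ``outdir`` is given every intermediate table is written there
    along with ``report.json`` summarising all set sizes and subset
    correlations.
    """
    thr = thresholds or Thresholds()

    deg = _stage("deg")(diffexpr.call_all_degs)(expression, thr)
    dap = _stage("dap")(proteomics.call_all_daps)(proteins, thr)
    tallies = proteomics.tally_identification(proteins)

    pairs = _stage("concordance")(concordance.classify_pairs)(deg, dap)
    correlations = concordance.correlate_subsets(pairs)

    as_counts = _stage("splicing")(splicing.count_events)(as_events)
    as_degs = splicing.select_as_degs(as_events, deg)
    as_candidates = splicing.rank_as_candidates(as_degs, deg, thr.require_tolerant_as)

    de_mir = _stage("mirna")(mirna.call_all_de_mirnas)(mirna_counts, thr)
    de_ids = sorted(set(de_mir.loc[de_mir["status"] != "ns", "mirna_id"]))
    hits = mirna.scan_all_targets({m: mirna_seqs[m] for m in de_ids}, cds_seqs, thr)
    gene_chains = mirna.anticorrelated_pairs(de_mir, hits, deg)
    protein_chains = mirna.protein_level_chains(de_mir, hits, pairs)

    candidates = _stage("screening")(screening.screen_all)(pairs, deg, dap, thr)
    candidates = screening.annotate_candidates(candidates, as_degs, osmotic_genes)

    graph = _stage("network")(network.build_network)(
        sorted(set(candidates["id"])), ortholog_map, ppi_edges, thr.ppi_score_min
    )
    hubs, components = network.find_hubs(graph)

    report = {
        "n_genes": int(len(expression)),
        "n_proteins": int(len(proteins)),
        "identification_tiers": tallies,
        "degs_per_comparison": {
            c: int(((deg["comparison"] == c) & (deg["status"] != "ns")).sum())
            for c in COMPARISONS
        },
        "daps_per_comparison": {
            c: int(((dap["comparison"] == c) & (dap["status"] != "ns")).sum())
            for c in COMPARISONS
        },
        "category_counts": concordance.category_counts(pairs).to_dict(orient="records"),
        "correlations": correlations.round(6).to_dict(orient="records"),
        "as_events_total": int(as_counts["count"].sum()),
        "as_degs": int(len(as_degs)),
        "as_candidates": int(len(as_candidates)),
        "de_mirnas": int(de_mir.loc[de_mir["status"] != "ns", "mirna_id"].nunique()),
        "target_hits": int(len(hits)),
        "gene_chains": int(len(gene_chains)),
        "protein_chains": int(len(protein_chains)),
        "candidates_per_rule": {
            r: int((candidates["rule"] == r).sum())
            for r in ("i", "ii", "iii", "iv", "v", "protein_only")
        },
        "candidates_total": int(len(candidates)),
        "network_nodes": int(graph.number_of_nodes()),
        "network_edges": int(graph.number_of_edges()),
        "hubs": [list(h) for h in hubs],
        "n_components": int(len(components)),
    }

    result = PipelineResult(
        deg_results=deg,
        dap_results=dap,
        tallies=tallies,
        pairs=pairs,
        correlations=correlations,
        as_counts=as_counts,
        as_degs=as_degs,
        as_candidates=as_candidates,
        de_mirnas=de_mir,
        target_hits=hits,
        gene_chains=gene_chains,
        protein_chains=protein_chains,
        candidates=candidates,
        graph=graph,
        hubs=hubs,
        components=components,
        report=report,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_table(deg, outdir / "deg_results.tsv")
        io.write_table(dap, outdir / "dap_results.tsv")
        io.write_table(pd.DataFrame([tallies]), outdir / "identification_tallies.tsv")
        io.write_table(pairs, outdir / "concordance_pairs.tsv")
        io.write_table(correlations, outdir / "correlations.tsv")
        io.write_table(as_counts, outdir / "as_counts.tsv")
        io.write_table(as_degs, outdir / "as_degs.tsv")
        io.write_table(as_candidates, outdir / "as_candidates.tsv")
        io.write_table(de_mir, outdir / "de_mirnas.tsv")
        io.write_table(hits, outdir / "target_hits.tsv")
        io.write_table(gene_chains, outdir / "gene_chains.tsv")
        io.write_table(protein_chains, outdir / "protein_chains.tsv")
        io.write_table(candidates, outdir / "candidates.tsv")
        network.write_sif(graph, outdir / "network.sif")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result


def run_from_files(config: PipelineConfig) -> PipelineResult:
    """Load every input named in the config and run the workflow."""
    expression = io.read_expression(config.expression)
    proteins = io.read_table(config.proteins)
    mirna_counts = io.read_mirna_counts(config.mirna_counts)
    mirna_seqs = io.read_fasta(config.mirna_fasta)
    cds_seqs = io.read_fasta(config.cds_fasta)
    as_events = io.read_table(config.as_events)
    ortholog_map = io.read_table(config.ortholog_map)
    ppi_edges = io.read_table(config.ppi_edges)
    osmotic = None
    if config.osmotic_genes:
        try:
            osmotic = io.read_gene_list(config.osmotic_genes)
        except FileNotFoundError:
            log.warning("osmotic gene list %s not found; flags left false", config.osmotic_genes)
    return run_all(
        expression,
        proteins,
        mirna_counts,
        mirna_seqs,
        cds_seqs,
        as_events,
        ortholog_map,
        ppi_edges,
        thresholds=config.thresholds,
        osmotic_genes=osmotic,
        outdir=config.outdir,
    )
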