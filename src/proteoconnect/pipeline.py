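"""End-to-end orchestration: simulate -> preprocess -> differential ->
signature selection -> ortholog mapping -> connectivity -> enrichment.

Every stage writes its artifact to the output directory as plain text
(TSV/GMT/grp) and logs its key counts; identical configuration and seeds
give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import io as pio
from .config import CompoundDbConfig, PipelineConfig
from .connectivity import CMap2Result, CompoundSummary, cmap2_score, summarize, summary_frame
from .differential import run_comparison
from .enrich import enrich_collection
from .idmap import QuerySignature, map_to_human
from .preprocess import PreprocessReport, preprocess
from .quant import ProteinQuantTable
from .selection import SignatureSets, flowchart_report, select_signatures
from .simulate import (
    GroundTruth,
    generate_compound_db,
    generate_gene_sets,
    generate_ortholog_map,
    generate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory handle on every stage artifact of one pipeline run."""

    table: ProteinQuantTable
    report: PreprocessReport
    comparisons: dict[str, pd.DataFrame]
    signatures: SignatureSets
    query: QuerySignature
    connectivity: list[CompoundSummary]
    cmap2: list[CMap2Result]
    enrichment: pd.DataFrame
    truth: GroundTruth | None = None
    artifacts: dict[str, str] = field(default_factory=dict)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run every stage on a simulated or loaded study table.

    When ``outdir`` is given, each stage writes its TSV artifact there and a
    run log echoes every flowchart count.
    """
    cfg_hash = _config_hash(config)
    logger.info("pipeline start (config %s)", cfg_hash)

    truth: GroundTruth | None = None
    if config.input_table == "simulate":
        table, truth = generate_study(config.study)
        logger.info("simulated %d proteins x %d samples", table.n_proteins(), len(table.samples))
    else:
        table = pio.read_quant_tsv(config.input_table)
        logger.info("loaded %d proteins x %d samples from %s",
                    table.n_proteins(), len(table.samples), config.input_table)

    # preprocessing: contaminant/peptide filter + median normalization
    clean, report = preprocess(table)
    logger.info("preprocess: %d -> %d proteins; mean missing %.2f%%",
                report.n_input, report.n_after_filters, 100 * report.mean_missing)

    # differential abundance per comparison
    diff_kwargs = dict(
        alpha=config.alpha, test=config.test, selection_mode=config.selection_mode,
        min_obs=config.min_obs, percentile=config.percentile,
        percentile_method=config.percentile_method,
    )
    comparisons = {cid: run_comparison(clean, cid, **diff_kwargs)
                   for cid in ("Set1", "Set2", "Set3")}
    for cid, res in comparisons.items():
        logger.info("%s: %d retained, %d significant", cid, len(res),
                    int(res["significant"].sum()))

    # flowchart selection
    signatures = select_signatures(
        comparisons["Set1"], comparisons["Set2"], comparisons["Set3"],
        filter2_policy=config.filter2_policy,
    )
    text, trace_table = flowchart_report(signatures)
    for line in text.splitlines():
        logger.info("flowchart %s", line)

    # ortholog mapping to a human query signature
    gene_of = clean.meta["gene_symbol"].to_dict()
    ortho = generate_ortholog_map(
        list(clean.protein_ids), [gene_of[p] for p in clean.protein_ids],
        seed=config.seed,
    )
    query = map_to_human(signatures.ri_up, signatures.ri_down, ortho)
    logger.info("query signature: %d up, %d down (log %s)",
                len(query.up_genes), len(query.down_genes), query.mapping_log)

    # connectivity against a synthetic compound database with a planted reverser
    db_cfg = dataclasses.replace(config.compound_db, seed=config.seed)
    if db_cfg.n_genes < 2 * query.size:
        db_cfg = dataclasses.replace(db_cfg, n_genes=2 * query.size)
    db = generate_compound_db(db_cfg, query)
    conn = summarize(db, query, n_perm=config.n_perm, n_null=config.n_null_queries,
                     seed=config.seed)
    cmap2 = cmap2_score(db, query, n_reference=config.n_reference_queries,
                        seed=config.seed)
    logger.info("connectivity: top compound %s (enrichment %.3f)",
                conn[0].name, conn[0].enrichment)

    # overlap enrichment against a generated gene-set collection
    universe = sorted({str(g).upper() for g in clean.meta["gene_symbol"]})
    planted = {"PLANTED_RI_SET": sorted(query.up_genes | query.down_genes)}
    gene_sets = generate_gene_sets(universe, planted=planted, seed=config.seed)
    enrichment = enrich_collection(query.up_genes | query.down_genes, gene_sets)
    logger.info("enrichment: top set %s (q=%.3g)",
                enrichment.iloc[0]["set_name"], enrichment.iloc[0]["fdr_q"])

    result = PipelineResult(
        table=clean, report=report, comparisons=comparisons, signatures=signatures,
        query=query, connectivity=conn, cmap2=cmap2, enrichment=enrichment, truth=truth,
    )
    if outdir is not None:
        result.artifacts = _write_artifacts(result, trace_table, cfg_hash, outdir)
    return result


def _write_artifacts(result: PipelineResult, trace_table: pd.DataFrame,
                     cfg_hash: str, outdir: str) -> dict[str, str]:
    pio.ensure_dir(outdir)
    paths: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path

    for cid, res in result.comparisons.items():
        save(res, f"comparison_{cid.lower()}.tsv")

    sig = result.signatures
    r1 = result.comparisons["Set1"].set_index("protein_id")
    rows = []
    for name, up, down in (
        ("dkd", sig.dkd_up, sig.dkd_down),
        ("ri", sig.ri_up, sig.ri_down),
        ("rs", sig.rs_up, sig.rs_down),
    ):
        frame = pd.DataFrame(
            sorted([(p, "up") for p in up] + [(p, "down") for p in down]),
            columns=["protein_id", "direction"],
        )
        if len(frame):
            frame["log2fc_set1"] = [r1.loc[p, "log2fc"] for p in frame["protein_id"]]
            frame["p_set1"] = [r1.loc[p, "p_value"] for p in frame["protein_id"]]
        save(frame, f"{name}.tsv")
        rows.append((name, len(up), len(down)))

    save(trace_table, "trace.tsv")
    save(summary_frame(result.connectivity), "connectivity_cmap1.tsv")
    save(
        pd.DataFrame([(r.score, r.name) for r in result.cmap2], columns=["score", "name"]),
        "connectivity_cmap2.tsv",
    )
    save(result.enrichment, "enrichment.tsv")

    up_path = os.path.join(outdir, "query_up.grp")
    down_path = os.path.join(outdir, "query_down.grp")
    pio.write_grp(result.query.up_genes, up_path)
    pio.write_grp(result.query.down_genes, down_path)
    paths["query_up.grp"] = up_path
    paths["query_down.grp"] = down_path

    log_path = os.path.join(outdir, "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write(f"config_hash\t{cfg_hash}\n")
        fh.write(f"mean_missing_pct\t{100 * result.report.mean_missing:.4f}\n")
        for _, row in trace_table.iterrows():
            fh.write(f"{row['quantity']}\t{row['count']}\n")
    paths["run_log.txt"] = log_path
    return paths
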