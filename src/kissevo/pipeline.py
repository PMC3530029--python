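"""Pipeline assembly: run mine -> paralogon -> classify -> dollo from a
single configuration mapping (typically parsed from YAML)."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

from .dollo import scenario_report
from .errors import KissevoError, PipelineError
from .formats import read_annotation_tsv, read_presence_tsv, read_tree
from .miner import MinerParams, default_consensus, mine_precursors, write_calls_gff3
from .model import AnnotationTable
from .synteny import (
    build_neighborhood,
    classify_gene,
    detect_paralogons,
)

log = logging.getLogger("kissevo")

STAGES = ("mine", "paralogon", "classify", "dollo")


def reference_neighborhoods(
    annotation: AnnotationTable, family_id: str, k: int = 15
) -> list[tuple[str, Any]]:
    """Labeled neighborhoods around every member of a family (label =
    gene symbol), for use as classification references."""
    refs = []
    for rec in annotation:
        if rec.family_id == family_id:
            refs.append(
                (rec.symbol or rec.gene_id, build_neighborhood(annotation, rec.gene_id, k))
            )
    return refs


def _require(config: Mapping[str, Any], stage: str, key: str) -> Any:
    try:
        return config[key]
    except KeyError:
        raise PipelineError(f"stage {stage!r}: missing config key {key!r}") from None


def _input_path(stage: str, value) -> Path:
    path = Path(value)
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: input path not found: {path}")
    return path


def run_pipeline(config: Mapping[str, Any], out_dir: Optional[Path] = None) -> dict:
    """Execute the configured stages in order and write their outputs.

    ``config`` maps stage names (``mine``, ``paralogon``, ``classify``,
    ``dollo``) to their inputs; only configured stages run. Returns a summary
    dict (also written to ``summary.json``). A stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir or config.get("output_dir", "kissevo_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    for stage in STAGES:
        if stage not in config:
            continue
        t0 = time.monotonic()
        try:
            runner = _RUNNERS[stage]
            summary[stage] = runner(config[stage] or {}, out_dir)
        except PipelineError:
            raise
        except (KissevoError, OSError, KeyError, ValueError) as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _run_mine(cfg: Mapping[str, Any], out_dir: Path) -> dict:
    genome = _input_path("mine", _require(cfg, "mine", "genome"))
    params = MinerParams(
        min_orf_codons=int(cfg.get("min_orf", 20)),
        require_cleavage=not bool(cfg.get("permissive", False)),
        acceptor_window=int(cfg.get("acceptor_window", 500)),
    )
    consensus = default_consensus(min_score=int(cfg.get("min_score", 10)))
    calls = mine_precursors(genome, consensus, params)
    write_calls_gff3(calls, out_dir / "mined_precursors.gff3")
    return {
        "calls": len(calls),
        "motifs": sorted(c.cleavage_motif for c in calls),
    }


def _run_paralogon(cfg: Mapping[str, Any], out_dir: Path) -> dict:
    path = _input_path("paralogon", _require(cfg, "paralogon", "annotation"))
    tables = read_annotation_tsv(path)
    tau = int(cfg.get("tau", 2))
    k = int(cfg.get("k", 15))
    species = cfg.get("species")
    wanted = [species] if species else sorted(tables)
    result: dict[str, Any] = {}
    rows = []
    for sp in wanted:
        if sp not in tables:
            raise PipelineError(f"stage 'paralogon': species {sp!r} not in {path}")
        paralogons = detect_paralogons(tables[sp], tau=tau, k=k)
        result[sp] = [
            {
                "regions": [f"{r.seq_id}:{r.start}-{r.end}" for r in p.regions],
                "supporting_families": sorted(p.supporting_families),
            }
            for p in paralogons
        ]
        for i, p in enumerate(paralogons):
            for r in p.regions:
                rows.append(
                    "\t".join(
                        [sp, str(i), r.seq_id, str(r.start), str(r.end),
                         ",".join(sorted(p.supporting_families))]
                    )
                )
    with open(out_dir / "paralogons.tsv", "w") as fh:
        fh.write("species\tparalogon\tseq_id\tstart\tend\tsupporting_families\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))
    return result


def _run_classify(cfg: Mapping[str, Any], out_dir: Path) -> dict:
    path = _input_path("classify", _require(cfg, "classify", "annotation"))
    tables = read_annotation_tsv(path)
    query_species = _require(cfg, "classify", "query_species")
    query_gene = _require(cfg, "classify", "query_gene")
    ref_species = _require(cfg, "classify", "reference_species")
    family = cfg.get("family", "KISS")
    k = int(cfg.get("k", 15))
    tau = int(cfg.get("tau", 2))
    query = build_neighborhood(tables[query_species], query_gene, k)
    refs = reference_neighborhoods(tables[ref_species], family, k)
    label = classify_gene(query, refs, tau=tau)
    result = {"gene": query_gene, "label": label or "unclassified"}
    with open(out_dir / "classification.tsv", "w") as fh:
        fh.write("gene_id\tlabel\n")
        fh.write(f"{query_gene}\t{result['label']}\n")
    return result


def _run_dollo(cfg: Mapping[str, Any], out_dir: Path) -> dict:
    matrix = read_presence_tsv(_input_path("dollo", _require(cfg, "dollo", "matrix")))
    tree = read_tree(_input_path("dollo", _require(cfg, "dollo", "tree")))
    report = scenario_report(matrix, tree, origins=cfg.get("origins"))
    report.to_dataframe().to_csv(out_dir / "loss_scenarios.tsv", sep="\t", index=False)
    with open(out_dir / "loss_events.txt", "w") as fh:
        for branch, lineages in report.losses_by_branch().items():
            fh.write(f"{branch}: loss of {', '.join(lineages)}\n")
    return {
        lineage: {"origin": sc.origin, "losses": list(sc.losses)}
        for lineage, sc in report.scenarios.items()
    }


_RUNNERS = {
    "mine": _run_mine,
    "paralogon": _run_paralogon,
    "classify": _run_classify,
    "dollo": _run_dollo,
}
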