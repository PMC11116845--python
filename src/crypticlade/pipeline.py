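"""End-to-end orchestration: delineate, quantify, tree, summarise.

``run_full`` executes the complete analysis over a genotype table and/or an
aligned FASTA: stepwise ordination to a lineage assignment, allele-frequency
tabulation, pairwise fixed-difference and Nei's D matrices, an NJ tree over
sites (Nei's D between sites, labelled by lineage), and — when an alignment
is supplied — a p-distance matrix and clade divergence summary.  Every
artefact is written to the output directory with provenance (config hash,
seed, package version); machine outputs are TSV/JSON, the human-readable
report is markdown-ish plain text.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import crypticlade
from crypticlade.diagnosability import (
    allele_frequencies,
    nei_unbiased_D,
    pairwise_matrices,
    render_combined_table,
)
from crypticlade.genotypes import LineageAssignment, read_genotypes
from crypticlade.ordination import stepwise_delineate
from crypticlade.seqdiv import (
    CladePartition,
    clade_divergence_summary,
    pairwise_p_matrix,
    prune_alignment,
    read_alignment,
)
from crypticlade.trees import DistanceMatrix, neighbor_joining, write_newick

__all__ = ["RunConfig", "run_full", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    genotypes: str | None = None
    alignment: str | None = None
    clades: str | None = None  # id,clade CSV for the sequence summary
    pins: str | None = None  # individual,lineage CSV of pinned assignments
    gap_factor: float = 3.0
    min_cluster: int = 4
    tolerance: float = 0.10
    tolerance_mode: str = "max"
    deletion: str = "pairwise"
    window: tuple[int, int] | None = None
    seed: int = 0
    out_dir: str = "crypticlade_out"

    def config_hash(self) -> str:
        # identifies the analysis, not its destination
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _site_distance_matrix(dataset, assignment: LineageAssignment) -> DistanceMatrix:
    """Nei's D between sites (sites with an unscoreable pairing get inf,
    which the NJ stage reports as an error)."""
    table = allele_frequencies(dataset, "site")
    sites = table.groups
    k = len(sites)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = nei_unbiased_D(table, sites[i], sites[j]).distance
            values[i, j] = values[j, i] = d
    return DistanceMatrix(sites, values, source="nei-D")


def run_full(config: RunConfig) -> dict:
    """Run every applicable stage; returns a summary dict (also written as
    report.json).  Any stage failure raises :class:`PipelineError` naming
    the stage; artefacts from completed stages are retained."""
    if config.genotypes is None and config.alignment is None:
        raise PipelineError("inputs", "need a genotype table or an alignment")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str) + "\n"
    )
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": crypticlade.__version__,
    }

    if config.genotypes is not None:
        stage = "read_genotypes"
        try:
            dataset = read_genotypes(config.genotypes)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(stage, str(exc)) from exc
        report["n_individuals"] = len(dataset)
        report["n_loci"] = len(dataset.loci)

        stage = "delineate"
        try:
            pins = None
            if config.pins:
                pin_df = pd.read_csv(config.pins, dtype=str)
                pins = dict(zip(pin_df.iloc[:, 0], pin_df.iloc[:, 1]))
            assignment = stepwise_delineate(
                dataset,
                gap_factor=config.gap_factor,
                min_cluster=config.min_cluster,
                tolerance=config.tolerance,
                tolerance_mode=config.tolerance_mode,
                pins=pins,
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        assignment.to_frame().to_csv(out / "assignment.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(assignment.provenance, indent=2) + "\n"
        )
        report["lineages"] = assignment.labels
        report["n_admixed"] = len(assignment.admixed)

        stage = "diagnose"
        try:
            table = allele_frequencies(dataset, assignment.mapping)
            table.to_frame().to_csv(out / "allele_frequencies.tsv", sep="\t",
                                    index=False)
            if len(assignment.labels) >= 2:
                fixed, nei = pairwise_matrices(
                    table,
                    tolerance=config.tolerance,
                    mode=config.tolerance_mode,
                )
                fixed.to_csv(out / "fixed_differences.tsv", sep="\t")
                nei.to_csv(out / "nei_D.tsv", sep="\t")
                (out / "diagnosability_table.txt").write_text(
                    render_combined_table(fixed, nei) + "\n"
                )
                report["fixed_differences"] = {
                    f"{a}|{b}": int(fixed.loc[a, b])
                    for i, a in enumerate(fixed.index)
                    for b in fixed.index[i + 1 :]
                }
                report["nei_D"] = {
                    f"{a}|{b}": (None if math.isinf(nei.loc[a, b])
                                 else round(float(nei.loc[a, b]), 6))
                    for i, a in enumerate(nei.index)
                    for b in nei.index[i + 1 :]
                }
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        stage = "nj_tree"
        try:
            if len(dataset.sites) >= 3:
                site_dm = _site_distance_matrix(dataset, assignment)
                site_dm.to_tsv(out / "site_nei_D.tsv")
                if np.all(np.isfinite(site_dm.values)):
                    tree = neighbor_joining(site_dm)
                    write_newick(tree, path=out / "sites_nj.nwk")
                    report["nj_tree"] = "sites_nj.nwk"
                else:
                    logger.warning(
                        "site Nei's D matrix has infinite entries; NJ skipped"
                    )
                    report["nj_tree"] = None
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    else:
        report["lineages"] = None

    if config.alignment is not None:
        stage = "p_distance"
        try:
            aln = read_alignment(config.alignment)
            if config.window is not None:
                aln = prune_alignment(aln, *config.window)
            dm = pairwise_p_matrix(aln, deletion=config.deletion)
            dm.to_tsv(out / "p_distance.tsv")
            report["alignment_length"] = aln.length
            report["n_sequences"] = len(aln)
            if config.clades:
                partition = CladePartition.from_csv(config.clades)
                summary = clade_divergence_summary(dm, partition)
                summary.to_frame().to_csv(out / "clade_divergence.tsv", sep="\t")
                report["clade_divergence"] = {
                    f"{a}|{b}": (None if cell is None
                                 else [round(cell[0], 6), round(cell[1], 6)])
                    for (a, b), cell in summary.among.items()
                }
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
    else:
        report["alignment_length"] = None

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
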