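"""End-to-end orchestration: groupings, tables and report bundle.

``run_pipeline`` ties the stages together for one grouping scheme: read and
validate the ORF FASTA, load expression, assign expression bins, and emit
per group the RSCU table, the RSCU ratio map against a reference group
(ribosomal by default), the codon-pair context table with bias calls, the
top-k preferred/avoided pairs, and a differential context map against the
reference — plus the expression summaries and a machine-readable manifest.
Every table is TSV with a one-line header; the bundle is a pure function of
(inputs, config) and is digest-stable across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from . import __version__
from .context import BIAS_THRESHOLD, PairContextTable, differential_map, top_pairs
from .expression import (ExpressionMatrix, assign_bins, fold_change_bins,
                         fold_changes, group_members, normalized_display,
                         summary_bins)
from .rscu import count_codons, ratio_map, rscu_table
from .sequences import (MIN_ORF_LENGTH, OrfSet, read_flags_tsv, read_orf_fasta)

logger = logging.getLogger(__name__)

REFERENCE_GROUP = "R"
VIRAL_GROUP = "viral"


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run; defaults reproduce the
    documented per-module behaviour."""

    fasta: str
    expression_tsv: str
    outdir: str
    flags_tsv: str | None = None
    scheme: str = "HV"
    condition: str | None = None  # for scheme="EC"
    reference_group: str = REFERENCE_GROUP
    include_stop: bool = True
    threshold: float = BIAS_THRESHOLD
    residual_mode: str = "adjusted"
    top_k: int = 5
    top_expressed_k: int = 10
    min_length: int = MIN_ORF_LENGTH
    strict: bool = False
    #: fraction of expression ids allowed to miss from the FASTA before abort.
    id_mismatch_tolerance: float = 0.0
    seed: int = 0
    render_png: bool = False

    @classmethod
    def from_yaml(cls, path: "Path | str", **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def _slug(label: str) -> str:
    return (label.replace("≥", "ge").replace(">", "gt").replace("(", "")
            .replace(")", "").replace("/", "-").replace(" ", "_"))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def top_expressed(
    matrix: ExpressionMatrix,
    ribosomal_ids: Iterable[str] = (),
    k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k tables: highest RPKM with its condition, and highest fold-change
    with the [max/min] condition label; ribosomal ORFs are excluded from
    both.  Ties are kept stable by orf_id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ribo = set(ribosomal_ids)
    keep = [oid for oid in matrix.orf_ids if oid not in ribo]
    sub = matrix.restrict(keep)
    peak = sub.rpkm.max(axis=1)
    peak_cond = sub.rpkm.idxmax(axis=1)
    by_rpkm = pd.DataFrame({
        "orf_id": peak.index,
        "rpkm": peak.values,
        "condition": [f"({c})" for c in peak_cond],
    }).sort_values(["rpkm", "orf_id"], ascending=[False, True]).head(k)
    fc = fold_changes(sub).dropna(subset=["ratio"]).reset_index(names="orf_id")
    by_fold = fc[["orf_id", "ratio", "label"]].rename(columns={"ratio": "fold_change"})
    by_fold = by_fold.sort_values(
        ["fold_change", "orf_id"], ascending=[False, True]).head(k)
    return by_rpkm.reset_index(drop=True), by_fold.reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    orfs = read_orf_fasta(config.fasta, strict=config.strict,
                          min_length=config.min_length,
                          skip_log=outdir / "skipped_orfs.tsv")
    if config.flags_tsv:
        orfs = orfs.with_flags(read_flags_tsv(config.flags_tsv))
    matrix = ExpressionMatrix.from_tsv(config.expression_tsv)

    fasta_ids = set(orfs.ids)
    expr_ids = set(matrix.orf_ids)
    missing = expr_ids - fasta_ids
    if missing:
        frac = len(missing) / len(expr_ids)
        if frac > config.id_mismatch_tolerance:
            raise ValueError(
                f"{len(missing)} expression ids absent from FASTA "
                f"({100 * frac:.1f}% > tolerance)")
        logger.warning("dropping %d expression ids absent from FASTA", len(missing))
        matrix = matrix.restrict(expr_ids & fasta_ids)
    # ORFs without expression take part only in flag-defined groups
    ribosomal_ids = {r.orf_id for r in orfs if r.is_ribosomal and r.orf_id in expr_ids}
    viral_ids = [r.orf_id for r in orfs if r.is_viral]

    # --- expression summaries -------------------------------------------
    summary_hv = summary_bins(matrix, basis="highest")
    summary_hv.rename_axis("bin").to_frame("percent").to_csv(
        outdir / "expression_summary_highest.tsv", sep="\t", float_format="%.2f")
    summary_ec = summary_bins(matrix, basis="per-condition")
    summary_ec.rename_axis("condition").to_csv(
        outdir / "expression_summary_per_condition.tsv", sep="\t", float_format="%.2f")
    fc = fold_changes(matrix)
    fold_change_bins(fc["ratio"]).rename_axis("bin").to_frame("percent").to_csv(
        outdir / "fold_change_bins.tsv", sep="\t", float_format="%.2f")
    by_rpkm, by_fold = top_expressed(matrix, ribosomal_ids, k=config.top_expressed_k)
    by_rpkm.to_csv(outdir / "top_rpkm.tsv", sep="\t", index=False, float_format="%.2f")
    by_fold.to_csv(outdir / "top_fold_change.tsv", sep="\t", index=False,
                   float_format="%.2f")
    normalized_display(matrix).to_csv(outdir / "normalized_rpkm.tsv", sep="\t",
                                      index_label="orf_id", float_format="%.4f")

    # --- grouping --------------------------------------------------------
    assignments = assign_bins(matrix, scheme=config.scheme,
                              ribosomal_ids=ribosomal_ids,
                              condition=config.condition)
    assignments.to_csv(outdir / "group_assignments.tsv", sep="\t",
                       float_format="%.4f")
    groups = group_members(assignments)
    if viral_ids:
        groups[VIRAL_GROUP] = viral_ids

    # --- per-group RSCU and codon context -------------------------------
    rscu_tables = {}
    context_tables = {}
    for label, members in groups.items():
        counts = count_codons(orfs, members)
        table = rscu_table(counts, group_label=label)
        rscu_tables[label] = table
        table.to_tsv(outdir / f"rscu_{_slug(label)}.tsv")
        ctx = PairContextTable.build(orfs, members, group_label=label,
                                     include_stop=config.include_stop,
                                     mode=config.residual_mode)
        context_tables[label] = ctx
        ctx.to_tsv(outdir / f"context_{_slug(label)}.tsv")
        for direction in ("preferred", "avoided"):
            top_pairs(ctx, k=config.top_k, direction=direction).to_csv(
                outdir / f"top_{direction}_{_slug(label)}.tsv",
                sep="\t", index=False, float_format="%.4f")

    ref = config.reference_group
    if ref in rscu_tables:
        for label, table in rscu_tables.items():
            if label == ref:
                continue
            ratio_map(table, rscu_tables[ref]).to_tsv(
                outdir / f"rscu_ratio_{_slug(label)}_vs_{_slug(ref)}.tsv")
            differential_map(context_tables[label], context_tables[ref],
                             band=config.threshold).to_tsv(
                outdir / f"context_diff_{_slug(label)}_vs_{_slug(ref)}.tsv")
    else:
        logger.warning("reference group %r is empty; ratio and differential "
                       "maps omitted", ref)

    if config.render_png:
        from . import plotting
        for label, table in rscu_tables.items():
            if ref in rscu_tables and label != ref:
                plotting.save_ratio_heatmap(
                    ratio_map(table, rscu_tables[ref]),
                    outdir / f"rscu_ratio_{_slug(label)}_vs_{_slug(ref)}.png")
        for label, ctx in context_tables.items():
            plotting.save_residual_heatmap(
                ctx, outdir / f"context_{_slug(label)}.png")

    manifest = {
        "package": "codonscope",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            "fasta": _sha256(config.fasta),
            "expression_tsv": _sha256(config.expression_tsv),
            **({"flags_tsv": _sha256(config.flags_tsv)} if config.flags_tsv else {}),
        },
        "n_orfs": len(orfs),
        "n_expression": len(matrix),
        "group_sizes": {label: len(m) for label, m in groups.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
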