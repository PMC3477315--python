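"""End-to-end composition: filter -> quantify -> stoichiometry.

Every run writes a provenance JSON (config echo, seed, package
version) next to its outputs so any result can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import pandas as pd

import discstoich
from discstoich import io as dio
from discstoich.errors import ConfigError, PipelineStageError
from discstoich.filtering import ProteinFilterResult, filter_protein_records
from discstoich.quant import (
    StoichiometryResult,
    aggregate_replicates,
    build_quant_table,
    compute_nsaf,
    compute_relative_saf,
    group_stoichiometry,
    probability_abundance_scatter,
)
from discstoich.records import FilterCriteria, ProteinRecord


@dataclass
class RunConfig:
    """Configuration for an end-to-end analysis run."""

    output_dir: Path
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    categories: Mapping[str, str] | None = None
    reference_accession: str | None = None
    normalization_set: Sequence[str] | None = None
    length_overrides: Mapping[str, int] | None = None
    lengths: Mapping[str, int] | None = None
    pooled_controls: bool = False
    seed: int = 0

    def provenance(self) -> dict:
        crit = dataclasses.asdict(self.criteria)
        crit["contaminant_accessions"] = sorted(crit["contaminant_accessions"])
        crit["whitelist_accessions"] = sorted(crit["whitelist_accessions"])
        return {
            "package": "discstoich",
            "version": discstoich.__version__,
            "seed": self.seed,
            "criteria": crit,
            "reference_accession": self.reference_accession,
            "normalization_set": (
                sorted(self.normalization_set)
                if self.normalization_set is not None
                else None
            ),
            "pooled_controls": self.pooled_controls,
        }


def split_by_run(
    records: Sequence[ProteinRecord],
) -> Dict[int, Dict[str, List[ProteinRecord]]]:
    """Group records as {replicate_id: {sample_label: [records]}}."""
    out: Dict[int, Dict[str, List[ProteinRecord]]] = defaultdict(
        lambda: {"treated": [], "control": []}
    )
    for rec in records:
        out[rec.replicate_id][rec.sample_label].append(rec)
    return dict(out)


def apply_lengths(
    records: Sequence[ProteinRecord], lengths: Mapping[str, int] | None
) -> List[ProteinRecord]:
    """Override table lengths with FASTA-derived residue counts.

    FASTA lengths are authoritative; disagreements with the table value
    are resolved in favor of the sequence.
    """
    if not lengths:
        return list(records)
    return [
        rec.with_length(lengths[rec.accession])
        if rec.accession in lengths
        else rec
        for rec in records
    ]


def filter_all_replicates(
    records: Sequence[ProteinRecord],
    criteria: FilterCriteria,
    pooled_controls: bool = False,
) -> ProteinFilterResult:
    """Run the protein filter per replicate (default) or against the
    pooled control across replicates."""
    by_run = split_by_run(records)
    pooled: Dict[str, ProteinRecord] = {}
    if pooled_controls:
        agg: Dict[str, ProteinRecord] = {}
        for runs in by_run.values():
            for rec in runs["control"]:
                prev = agg.get(rec.accession)
                if prev is None:
                    agg[rec.accession] = rec
                else:
                    agg[rec.accession] = dataclasses.replace(
                        prev,
                        spectral_count=prev.spectral_count + rec.spectral_count,
                        unique_peptides=max(
                            prev.unique_peptides, rec.unique_peptides
                        ),
                    )
        pooled = agg
    retained: List[ProteinRecord] = []
    removed = []
    whitelisted: set = set()
    for rep in sorted(by_run):
        runs = by_run[rep]
        control = (
            list(pooled.values()) if pooled_controls else runs["control"]
        )
        res = filter_protein_records(runs["treated"], control, criteria)
        retained.extend(res.retained)
        removed.extend(res.removed)
        whitelisted |= set(res.whitelisted)
    return ProteinFilterResult(retained, removed, frozenset(whitelisted))


@dataclass
class PipelineResult:
    filter_result: ProteinFilterResult
    quant_table: pd.DataFrame
    summary: pd.DataFrame
    stoichiometry: StoichiometryResult | None


def run_pipeline(
    records: Sequence[ProteinRecord], config: RunConfig
) -> PipelineResult:
    """Execute filter -> quantify -> stoichiometry, writing artifacts.

    Writes into ``config.output_dir``: provenance.json, filtered
    protein and removal-audit TSVs, the per-replicate quant TSV, the
    aggregated summary TSV, a scatter-table TSV when a reference
    accession is declared, and stoichiometry.json when a category map
    is supplied.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_json_report(config.provenance(), out / "provenance.json")

    try:
        records = apply_lengths(records, config.lengths)
        filt = filter_all_replicates(
            records, config.criteria, config.pooled_controls
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("filter", exc) from exc
    dio.write_protein_table(filt.retained, out / "filtered_proteins.tsv")
    dio.write_removal_audit(filt, out / "removal_audit.tsv")

    try:
        table = build_quant_table(filt.retained, config.length_overrides)
        if config.reference_accession:
            table = compute_relative_saf(table, config.reference_accession)
        table = compute_nsaf(table, config.normalization_set)
        summary = aggregate_replicates(table)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("quantify", exc) from exc
    _write_quant_tsv(table, out / "quant_per_replicate.tsv")
    _write_summary_tsv(summary, out / "quant_summary.tsv")
    if config.reference_accession:
        scatter = probability_abundance_scatter(summary)
        _write_quant_tsv(scatter, out / "probability_abundance_scatter.tsv")

    stoich: StoichiometryResult | None = None
    if config.categories is not None:
        try:
            stoich = group_stoichiometry(table, config.categories)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("stoichiometry", exc) from exc
        payload = stoich.to_dict()
        payload["whitelisted"] = sorted(filt.whitelisted)
        dio.write_json_report(payload, out / "stoichiometry.json")
    return PipelineResult(filt, table, summary, stoich)


def _write_quant_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(dio.format_float)
    out.to_csv(path, sep="\t", index=False)


def _write_summary_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.reset_index().copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(dio.format_float)
    out.to_csv(path, sep="\t", index=False)
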