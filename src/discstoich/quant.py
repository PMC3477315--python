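"""Spectral-count quantitation: SAF, relative SAF, NSAF, stoichiometry.

The spectral abundance factor of protein *i* in one run is

    SAF_i = SpC_i / L_i

(spectral count over sequence length in residues), and the normalized
SAF is

    NSAF_i = SAF_i / sum_j SAF_j

with the sum over a declared normalization set, so NSAF values sum to 1
per replicate. Because expected spectral counts scale with molar
abundance times length, NSAF ratios estimate mole ratios; dividing each
category's combined NSAF by that of the FADD adaptor category yields
the per-FADD stoichiometry of the complex.

Quant tables are pandas DataFrames with one row per (accession,
replicate) and columns ``accession, replicate_id, spectral_count,
length, protein_probability`` plus the derived ``saf, relative_saf,
nsaf`` columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from discstoich.errors import (
    DegenerateReplicateError,
    ReferenceAccessionError,
    StoichiometryUndefinedError,
)
from discstoich.records import ProteinRecord

CATEGORIES = ("receptor", "FADD", "DED_only", "other")


def compute_saf(spectral_count: float, length: int) -> float:
    """SAF = spectral count / protein length (counts per residue)."""
    if length < 1:
        raise ValueError(f"length must be >= 1 residue, got {length}")
    if spectral_count < 0:
        raise ValueError("spectral_count must be nonnegative")
    return spectral_count / length


def build_quant_table(
    records: Iterable[ProteinRecord],
    length_overrides: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble a per-(accession, replicate) quant table with SAF.

    ``length_overrides`` substitutes lengths per accession — e.g. for
    cleaved species quantified against a processed form rather than the
    full-length database sequence.
    """
    overrides = length_overrides or {}
    rows = []
    for rec in records:
        length = overrides.get(rec.accession, rec.length)
        rows.append(
            {
                "accession": rec.accession,
                "replicate_id": rec.replicate_id,
                "spectral_count": rec.spectral_count,
                "length": length,
                "protein_probability": rec.protein_probability,
                "saf": compute_saf(rec.spectral_count, length),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "replicate_id",
            "spectral_count",
            "length",
            "protein_probability",
            "saf",
        ],
    )


def compute_relative_saf(
    table: pd.DataFrame, reference_accession: str
) -> pd.DataFrame:
    """Add ``relative_saf`` = SAF / SAF(reference), within each replicate.

    The reference must be present with nonzero SAF in every replicate;
    its own relative SAF is exactly 1.
    """
    table = table.copy()
    rel = np.empty(len(table))
    for rep, idx in table.groupby("replicate_id").groups.items():
        sub = table.loc[idx]
        ref = sub.loc[sub["accession"] == reference_accession, "saf"]
        if ref.empty:
            raise ReferenceAccessionError(
                f"reference {reference_accession!r} absent from replicate {rep}"
            )
        ref_saf = float(ref.iloc[0])
        if ref_saf <= 0:
            raise ReferenceAccessionError(
                f"reference {reference_accession!r} has zero SAF in replicate {rep}"
            )
        rel[table.index.get_indexer(idx)] = sub["saf"].to_numpy() / ref_saf
    table["relative_saf"] = rel
    return table


def compute_nsaf(
    table: pd.DataFrame,
    normalization_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Add ``nsaf`` = SAF / sum(SAF over normalization set), per replicate.

    The default normalization set is every accession in the table (the
    retained protein set). Accessions outside the set receive an NSAF
    computed against the same denominator, so NSAF sums to 1 over the
    set in each replicate.
    """
    table = table.copy()
    norm = set(normalization_set) if normalization_set is not None else set(
        table["accession"]
    )
    if not norm:
        raise ValueError("normalization set must be nonempty")
    nsaf = np.empty(len(table))
    for rep, idx in table.groupby("replicate_id").groups.items():
        sub = table.loc[idx]
        denom = float(sub.loc[sub["accession"].isin(norm), "saf"].sum())
        if denom <= 0:
            raise DegenerateReplicateError(
                f"all SAF values are zero over the normalization set in "
                f"replicate {rep}"
            )
        nsaf[table.index.get_indexer(idx)] = sub["saf"].to_numpy() / denom
    table["nsaf"] = nsaf
    return table


def aggregate_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a per-replicate quant table per accession.

    Reports the median protein probability and median relative SAF over
    the replicates in which the protein was detected, and the mean NSAF
    with its dispersion over *all* replicates — an accession absent
    from a replicate contributes NSAF 0 there (non-detection is treated
    as zero abundance, not missing-at-random).

    Dispersion convention: SEM (sd / sqrt(n)) for n >= 3 replicates,
    min-max range for n = 2, not available (NaN) for n = 1; the
    convention used is named in ``dispersion_kind``.
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty quant table")
    replicates = sorted(table["replicate_id"].unique())
    n = len(replicates)
    # absent accessions -> NSAF 0 in that replicate
    nsaf_wide = (
        table.pivot_table(
            index="accession", columns="replicate_id", values="nsaf",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=replicates, fill_value=0.0)
    )
    mean_nsaf = nsaf_wide.mean(axis=1)
    if n >= 3:
        dispersion = nsaf_wide.std(axis=1, ddof=1) / math.sqrt(n)
        kind = "sem"
    elif n == 2:
        dispersion = nsaf_wide.max(axis=1) - nsaf_wide.min(axis=1)
        kind = "range"
    else:
        dispersion = pd.Series(np.nan, index=nsaf_wide.index)
        kind = "na"

    grouped = table.groupby("accession")
    summary = pd.DataFrame(
        {
            "median_protein_probability": grouped["protein_probability"].median(),
            "mean_nsaf": mean_nsaf,
            "nsaf_dispersion": dispersion,
            "nsaf_min": nsaf_wide.min(axis=1),
            "nsaf_max": nsaf_wide.max(axis=1),
            "n_replicates": n,
            "n_detected": grouped.size(),
        }
    )
    if "relative_saf" in table.columns:
        summary["median_relative_saf"] = grouped["relative_saf"].median()
    summary["dispersion_kind"] = kind
    return summary.sort_index()


@dataclass
class StoichiometryResult:
    """Per-category combined NSAF normalized to the FADD category.

    ``table`` is indexed by category with columns ``combined_nsaf``
    (mean over replicates of the per-replicate category NSAF sum),
    ``ratio_to_fadd``, ``dispersion`` and ``dispersion_kind``.
    """

    table: pd.DataFrame
    n_replicates: int
    reference_category: str = "FADD"

    def ratio(self, category: str) -> float:
        return float(self.table.loc[category, "ratio_to_fadd"])

    def to_dict(self) -> dict:
        return {
            "reference_category": self.reference_category,
            "n_replicates": self.n_replicates,
            "categories": {
                cat: {
                    "combined_nsaf": float(row["combined_nsaf"]),
                    "ratio_to_fadd": float(row["ratio_to_fadd"]),
                    "dispersion": (
                        None
                        if pd.isna(row["dispersion"])
                        else float(row["dispersion"])
                    ),
                    "dispersion_kind": row["dispersion_kind"],
                }
                for cat, row in self.table.iterrows()
            },
        }


def group_stoichiometry(
    table: pd.DataFrame,
    categories: Mapping[str, str],
    reference_category: str = "FADD",
) -> StoichiometryResult:
    """Combine NSAF by category and normalize to the FADD category.

    Per replicate, category NSAF is the sum of member NSAFs (absent
    members contribute 0); combined NSAF is its mean over replicates;
    ratios divide by the reference (FADD) category, whose ratio is 1 by
    construction. Raises StoichiometryUndefinedError rather than
    emitting an infinite ratio when the reference NSAF is zero.
    """
    table = table.copy()
    unknown = set(table["accession"]) - set(categories)
    if unknown:
        # uncategorized accessions fall into "other"
        pass
    table["category"] = table["accession"].map(
        lambda a: categories.get(a, "other")
    )
    if reference_category not in set(categories.values()):
        raise StoichiometryUndefinedError(
            f"no accession mapped to reference category {reference_category!r}"
        )
    replicates = sorted(table["replicate_id"].unique())
    n = len(replicates)
    per_rep = (
        table.pivot_table(
            index="category", columns="replicate_id", values="nsaf",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=replicates, fill_value=0.0)
    )
    combined = per_rep.mean(axis=1)
    ref = combined.get(reference_category, 0.0)
    if ref <= 0:
        raise StoichiometryUndefinedError(
            f"combined NSAF of {reference_category!r} is zero; "
            "stoichiometry ratios are undefined"
        )
    if n >= 3:
        dispersion = per_rep.std(axis=1, ddof=1) / math.sqrt(n)
        kind = "sem"
    elif n == 2:
        dispersion = per_rep.max(axis=1) - per_rep.min(axis=1)
        kind = "range"
    else:
        dispersion = pd.Series(np.nan, index=per_rep.index)
        kind = "na"
    result = pd.DataFrame(
        {
            "combined_nsaf": combined,
            "ratio_to_fadd": combined / ref,
            "dispersion": dispersion,
        }
    )
    result["dispersion_kind"] = kind
    return StoichiometryResult(result, n, reference_category)


def probability_abundance_scatter(summary: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (accession, median PP, median relative SAF) table.

    Suitable for the confidence-vs-abundance scatter used to separate
    genuine complex components (high probability, high relative SAF)
    from background. Requires aggregation with a declared reference.
    """
    if summary.empty:
        return pd.DataFrame(
            columns=["accession", "median_protein_probability",
                     "median_relative_saf"]
        )
    if "median_relative_saf" not in summary.columns:
        raise ValueError(
            "summary lacks median_relative_saf; aggregate a table with a "
            "declared reference accession first"
        )
    out = summary.reset_index()[
        ["accession", "median_protein_probability", "median_relative_saf"]
    ]
    return out
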