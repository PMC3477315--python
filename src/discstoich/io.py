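"""Readers and writers for the pipeline's plain-text formats.

Tabular inputs are tab-separated with a fixed, versioned header
(schema v1):

PSM table columns
    peptide_sequence, assigned_accession, peptide_probability,
    ion_score, parent_mass_error, mass_error_unit, sample_label,
    replicate_id[, spectrum_id]

Protein table columns
    accession, description, length, protein_probability,
    spectral_count, unique_peptides, sample_label, replicate_id

All writers are deterministic: stable column order, floats rendered
with 6 significant digits, records sorted where order is not
meaningful. FASTA parsing goes through Biopython; coordinates use the
PDB ATOM subset via gemmi.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import gemmi
import pandas as pd
from Bio import SeqIO

from discstoich.errors import TableParseError
from discstoich.filtering import ProteinFilterResult
from discstoich.geometry import ChainModel, DomainCoordinates
from discstoich.records import ProteinRecord, SpectrumMatch

SCHEMA_VERSION = "1"

PSM_COLUMNS = [
    "peptide_sequence",
    "assigned_accession",
    "peptide_probability",
    "ion_score",
    "parent_mass_error",
    "mass_error_unit",
    "sample_label",
    "replicate_id",
]

PROTEIN_COLUMNS = [
    "accession",
    "description",
    "length",
    "protein_probability",
    "spectral_count",
    "unique_peptides",
    "sample_label",
    "replicate_id",
]


def format_float(x: float) -> str:
    """Render a float with 6 significant digits, platform-stable."""
    if x != x:  # NaN
        return "NA"
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(
            f"{path}: missing required column(s) {missing}; "
            f"expected schema v{SCHEMA_VERSION}"
        )


def _parse_number(value, row: int, column: str, kind=float):
    try:
        out = kind(value)
    except (TypeError, ValueError):
        raise TableParseError(
            f"non-numeric value {value!r}", row=row, column=column
        ) from None
    if isinstance(out, float) and not math.isfinite(out):
        raise TableParseError(f"non-finite value {value!r}", row=row,
                              column=column)
    return out


def _parse_probability(value, row: int, column: str) -> float:
    p = _parse_number(value, row, column)
    if not (0.0 <= p <= 1.0):
        raise TableParseError(
            f"probability {p} outside [0, 1]", row=row, column=column
        )
    return p


def read_psm_table(path: str | Path) -> List[SpectrumMatch]:
    """Read a PSM TSV into validated SpectrumMatch records.

    Errors name the offending row (1-based, excluding the header) and
    column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PSM_COLUMNS, str(path))
    has_spectrum = "spectrum_id" in df.columns
    out: List[SpectrumMatch] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(
                SpectrumMatch(
                    peptide_sequence=rec["peptide_sequence"],
                    assigned_accession=rec["assigned_accession"],
                    peptide_probability=_parse_probability(
                        rec["peptide_probability"], i, "peptide_probability"
                    ),
                    ion_score=_parse_number(rec["ion_score"], i, "ion_score"),
                    parent_mass_error=_parse_number(
                        rec["parent_mass_error"], i, "parent_mass_error"
                    ),
                    mass_error_unit=rec["mass_error_unit"],
                    sample_label=rec["sample_label"],
                    replicate_id=_parse_number(
                        rec["replicate_id"], i, "replicate_id", int
                    ),
                    spectrum_id=(rec["spectrum_id"] or None)
                    if has_spectrum
                    else None,
                )
            )
        except ValueError as exc:
            raise TableParseError(str(exc), row=i) from exc
    return out


def write_psm_table(matches: Sequence[SpectrumMatch], path: str | Path) -> None:
    rows = []
    for m in matches:
        rows.append(
            {
                "peptide_sequence": m.peptide_sequence,
                "assigned_accession": m.assigned_accession,
                "peptide_probability": format_float(m.peptide_probability),
                "ion_score": format_float(m.ion_score),
                "parent_mass_error": format_float(m.parent_mass_error),
                "mass_error_unit": m.mass_error_unit,
                "sample_label": m.sample_label,
                "replicate_id": m.replicate_id,
                "spectrum_id": m.spectrum_id or "",
            }
        )
    pd.DataFrame(rows, columns=PSM_COLUMNS + ["spectrum_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_protein_table(path: str | Path) -> List[ProteinRecord]:
    """Read a protein TSV into validated ProteinRecord objects."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PROTEIN_COLUMNS, str(path))
    out: List[ProteinRecord] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(
                ProteinRecord(
                    accession=rec["accession"],
                    description=rec["description"],
                    length=_parse_number(rec["length"], i, "length", int),
                    protein_probability=_parse_probability(
                        rec["protein_probability"], i, "protein_probability"
                    ),
                    spectral_count=_parse_number(
                        rec["spectral_count"], i, "spectral_count", int
                    ),
                    unique_peptides=_parse_number(
                        rec["unique_peptides"], i, "unique_peptides", int
                    ),
                    sample_label=rec["sample_label"],
                    replicate_id=_parse_number(
                        rec["replicate_id"], i, "replicate_id", int
                    ),
                )
            )
        except ValueError as exc:
            raise TableParseError(str(exc), row=i) from exc
    return out


def write_protein_table(
    records: Sequence[ProteinRecord], path: str | Path
) -> None:
    rows = [
        {
            "accession": r.accession,
            "description": r.description,
            "length": r.length,
            "protein_probability": format_float(r.protein_probability),
            "spectral_count": r.spectral_count,
            "unique_peptides": r.unique_peptides,
            "sample_label": r.sample_label,
            "replicate_id": r.replicate_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PROTEIN_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)


def write_removal_audit(
    result: ProteinFilterResult, path: str | Path, criteria_echo: str = ""
) -> None:
    """Removal-audit TSV: accession, reason, whitelist flag, criteria."""
    rows = []
    for rr in result.removed:
        rows.append(
            {
                "accession": rr.record.accession,
                "sample_label": rr.record.sample_label,
                "replicate_id": rr.record.replicate_id,
                "status": "removed",
                "reason": rr.reason,
            }
        )
    for acc in sorted(result.whitelisted):
        rows.append(
            {
                "accession": acc,
                "sample_label": "treated",
                "replicate_id": "",
                "status": "retained (whitelist)",
                "reason": "whitelist override of control subtraction",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["accession", "sample_label", "replicate_id", "status",
                 "reason"],
    )
    with open(path, "w") as fh:
        if criteria_echo:
            fh.write(f"# criteria: {criteria_echo}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_fasta_lengths(path: str | Path) -> Dict[str, int]:
    """Map FASTA accession -> residue count; duplicates are an error."""
    lengths: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise TableParseError(
                f"duplicate FASTA accession {rec.id!r} in {path}"
            )
        lengths[rec.id] = len(rec.seq)
    if not lengths:
        raise TableParseError(f"no FASTA records found in {path}")
    return lengths


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def write_lengths_fasta(
    lengths: Mapping[str, int], path: str | Path, seed: int = 0
) -> None:
    """Write synthetic sequences of the stated lengths (random residues,
    seeded) so downstream length recomputation round-trips."""
    import numpy as np

    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for acc in sorted(lengths):
            seq = "".join(
                rng.choice(list(AMINO_ACIDS), size=lengths[acc])
            )
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_category_map(path: str | Path) -> Dict[str, str]:
    """Two-column TSV (accession, category) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["accession", "category"], str(path))
    out: Dict[str, str] = {}
    for i, rec in enumerate(df.to_dict("records"), start=1):
        acc = rec["accession"]
        if acc in out and out[acc] != rec["category"]:
            raise TableParseError(
                f"accession {acc!r} mapped to two categories", row=i
            )
        out[acc] = rec["category"]
    return out


def write_category_map(categories: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(categories.items()), columns=["accession", "category"]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coordinates (PDB ATOM subset, via gemmi)


def read_domain_pdb(
    path: str | Path,
    chain: str | None = None,
    residues: Sequence[int] | None = None,
    atom_name: str = "CA",
) -> DomainCoordinates:
    """Read one domain selection from a PDB file.

    Selects ATOM records by chain, residue range/list and atom name
    (default alpha-carbon).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    wanted = set(residues) if residues is not None else None
    labels: List[Tuple[int, str]] = []
    coords: List[Tuple[float, float, float]] = []
    model = st[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            seqid = res.seqid.num
            if wanted is not None and seqid not in wanted:
                continue
            for atom in res:
                if atom_name and atom.name != atom_name:
                    continue
                labels.append((seqid, atom.name))
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not labels:
        raise TableParseError(
            f"no matching ATOM records in {path} "
            f"(chain={chain!r}, atom={atom_name!r})"
        )
    import numpy as np

    return DomainCoordinates(tuple(labels), np.array(coords))


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def write_chain_pdb(chain_model: ChainModel, path: str | Path) -> None:
    """Write a multi-copy chain model with one chain identifier per copy."""
    st = gemmi.Structure()
    st.name = "ded_chain_model"
    model = gemmi.Model("1")
    serial = 1
    for k, copy in enumerate(chain_model.copies):
        ch = gemmi.Chain(_CHAIN_IDS[k % len(_CHAIN_IDS)])
        current_res: gemmi.Residue | None = None
        for (res_idx, atom_name), pos in zip(copy.labels, copy.coords):
            if current_res is None or current_res.seqid.num != res_idx:
                current_res = gemmi.Residue()
                current_res.name = "ALA"
                current_res.seqid = gemmi.SeqId(int(res_idx), " ")
                ch.add_residue(current_res)
                current_res = ch[-1]
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(*map(float, pos))
            atom.serial = serial
            serial += 1
            current_res.add_atom(atom)
        model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


def write_pairing_tsv(
    pairing: Sequence[Tuple[int, int]], path: str | Path
) -> None:
    pd.DataFrame(pairing, columns=["residue_ded1", "residue_ded2"]).to_csv(
        path, sep="\t", index=False
    )


def read_pairing_tsv(path: str | Path) -> List[Tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["residue_ded1", "residue_ded2"], str(path))
    return [
        (int(a), int(b))
        for a, b in zip(df["residue_ded1"], df["residue_ded2"])
    ]


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        if obj != obj:
            return None
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_json_report(payload: Mapping, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, 6 significant digits on floats."""
    with open(path, "w") as fh:
        json.dump(_round_floats(dict(payload)), fh, indent=2, sort_keys=True)
        fh.write("\n")
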