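"""Retention filtering of AP-MS identifications.

Implements the retention criteria applied before quantitation: PSM-level
thresholds (peptide probability, Mascot ion score, parent-ion mass
error), protein-level probability and contaminant exclusion, and
control-run subtraction with a whitelist escape hatch. Every removal is
audited with an explicit reason so retained and removed records always
partition the input.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from discstoich.errors import DuplicateRecordError, UnitMismatchError
from discstoich.records import FilterCriteria, ProteinRecord, SpectrumMatch

RunKey = Tuple[str, int]  # (sample_label, replicate_id)

REASON_CONTAMINANT = "contaminant"
REASON_PROTEIN_PROBABILITY = "protein probability"
REASON_CONTROL = "present in control"


@dataclass(frozen=True)
class RemovedRecord:
    """A protein record removed by a filter, with its removal reason."""

    record: ProteinRecord
    reason: str


@dataclass
class ProteinFilterResult:
    """Partition of an input protein table into retained and removed.

    ``whitelisted`` lists accessions retained only because they were on
    the whitelist (they would otherwise have been removed by control
    subtraction); such retentions are always flagged in reports.
    """

    retained: List[ProteinRecord]
    removed: List[RemovedRecord] = field(default_factory=list)
    whitelisted: frozenset = frozenset()

    def removal_reasons(self) -> Dict[str, str]:
        return {rr.record.accession: rr.reason for rr in self.removed}


def spectrum_match_passes(match: SpectrumMatch, criteria: FilterCriteria) -> bool:
    """Single-record PSM retention predicate.

    Retains a PSM iff peptide probability meets the threshold, the ion
    score strictly exceeds the minimum (a score of exactly 30 is
    rejected under the default), and the absolute parent-ion mass error
    is within tolerance.
    """
    return (
        match.peptide_probability >= criteria.min_peptide_probability
        and match.ion_score > criteria.min_ion_score
        and abs(match.parent_mass_error) <= criteria.max_parent_mass_error
    )


def filter_spectrum_matches(
    matches: Sequence[SpectrumMatch], criteria: FilterCriteria
) -> List[SpectrumMatch]:
    """Apply PSM-level retention criteria, preserving input order.

    Raises UnitMismatchError if the matches (or the matches and the
    criteria) disagree on the mass-error unit — a 0.2 Da tolerance
    applied to ppm values would be silently meaningless.
    """
    units = {m.mass_error_unit for m in matches}
    if len(units) > 1:
        raise UnitMismatchError(
            f"mixed parent-mass-error units in input: {sorted(units)}"
        )
    if units and units != {criteria.mass_error_unit}:
        raise UnitMismatchError(
            f"matches use {units.pop()!r} but criteria specify "
            f"{criteria.mass_error_unit!r}"
        )
    return [m for m in matches if spectrum_match_passes(m, criteria)]


def compute_spectral_counts(
    matches: Iterable[SpectrumMatch],
    protein_probabilities: Mapping[str, float] | None = None,
) -> Dict[RunKey, Dict[str, int]]:
    """Aggregate retained PSMs into per-run spectral counts.

    Returns ``{(sample_label, replicate_id): {accession: count}}``.

    Shared peptides: matches within one run carrying the same non-None
    ``spectrum_id`` are one spectrum listed under several accessions;
    the spectrum is counted once, razor-assigned to the accession with
    the highest protein probability (lexicographically smallest
    accession on ties, and when no probabilities are supplied). Rows
    with ``spectrum_id=None`` each count as their own spectrum, so the
    total count equals the number of distinct retained spectra.
    """
    probs = protein_probabilities or {}
    counts: Dict[RunKey, Dict[str, int]] = defaultdict(Counter)
    # spectra seen per run -> best accession so far
    razor: Dict[Tuple[RunKey, str], str] = {}
    for m in matches:
        run = (m.sample_label, m.replicate_id)
        if m.spectrum_id is None:
            counts[run][m.assigned_accession] += 1
            continue
        key = (run, m.spectrum_id)
        acc = m.assigned_accession
        if key not in razor:
            razor[key] = acc
            counts[run][acc] += 1
        else:
            best = razor[key]
            # higher probability wins; lexicographic accession breaks ties
            if (probs.get(acc, 0.0), ) > (probs.get(best, 0.0), ) or (
                probs.get(acc, 0.0) == probs.get(best, 0.0) and acc < best
            ):
                counts[run][best] -= 1
                if counts[run][best] == 0:
                    del counts[run][best]
                counts[run][acc] += 1
                razor[key] = acc
    return {run: dict(c) for run, c in counts.items()}


def _index_by_accession(
    records: Sequence[ProteinRecord], side: str
) -> Dict[str, ProteinRecord]:
    index: Dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.accession in index:
            raise DuplicateRecordError(
                f"duplicate accession {rec.accession!r} in {side} run "
                f"(sample={rec.sample_label}, replicate={rec.replicate_id})"
            )
        index[rec.accession] = rec
    return index


def subtract_control(
    treated: Sequence[ProteinRecord],
    control: Sequence[ProteinRecord],
    criteria: FilterCriteria,
) -> ProteinFilterResult:
    """Remove treated identifications explained by the control run.

    A treated protein is retained iff it is absent from the control, or
    present there in dramatically lower abundance (treated:control count
    ratio >= ``control_fold_threshold`` and control count <=
    ``control_max_count``), or whitelisted. Whitelist-only retentions
    are reported in ``whitelisted``.
    """
    control_index = _index_by_accession(control, "control")
    _index_by_accession(treated, "treated")  # duplicate check

    retained: List[ProteinRecord] = []
    removed: List[RemovedRecord] = []
    flagged = set()
    for rec in treated:
        ctl = control_index.get(rec.accession)
        if ctl is None:
            retained.append(rec)
            continue
        fold_ok = (
            rec.spectral_count / max(ctl.spectral_count, 1)
            >= criteria.control_fold_threshold
            and ctl.spectral_count <= criteria.control_max_count
        )
        if fold_ok:
            retained.append(rec)
        elif rec.accession in criteria.whitelist_accessions:
            retained.append(rec)
            flagged.add(rec.accession)
        else:
            removed.append(RemovedRecord(rec, REASON_CONTROL))
    return ProteinFilterResult(retained, removed, frozenset(flagged))


def exclude_contaminants(
    records: Sequence[ProteinRecord], criteria: FilterCriteria
) -> ProteinFilterResult:
    """Drop known contaminants and low-probability identifications.

    Contaminants are matched by accession against the criteria's
    contaminant set (shipping default: biotin-dependent carboxylases and
    common bead background). Records below the protein-probability
    threshold are removed with their own reason.
    """
    retained: List[ProteinRecord] = []
    removed: List[RemovedRecord] = []
    for rec in records:
        if rec.accession in criteria.contaminant_accessions:
            removed.append(RemovedRecord(rec, REASON_CONTAMINANT))
        elif rec.protein_probability < criteria.min_protein_probability:
            removed.append(RemovedRecord(rec, REASON_PROTEIN_PROBABILITY))
        else:
            retained.append(rec)
    return ProteinFilterResult(retained, removed)


def filter_protein_records(
    treated: Sequence[ProteinRecord],
    control: Sequence[ProteinRecord],
    criteria: FilterCriteria,
) -> ProteinFilterResult:
    """Full protein-level retention filter for one treated/control pair.

    Composes contaminant/probability exclusion with control
    subtraction. The union of retained and removed records is exactly
    the treated input.
    """
    stage1 = exclude_contaminants(treated, criteria)
    stage2 = subtract_control(stage1.retained, control, criteria)
    return ProteinFilterResult(
        retained=stage2.retained,
        removed=stage1.removed + stage2.removed,
        whitelisted=stage2.whitelisted,
    )
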