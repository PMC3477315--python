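"""Domain record types for identification filtering and quantitation.

Records are plain frozen dataclasses validated on construction. A
*spectrum match* is one peptide-spectrum match (PSM) from an upstream
search-engine/validation stack (Mascot scores, PeptideProphet /
ProteinProphet posteriors are consumed as given, never recomputed). A
*protein record* is one protein identification in one sample run, with
its spectral count and sequence length — the inputs to SAF = SpC / L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Literal

MassErrorUnit = Literal["Da", "ppm"]
SampleLabel = Literal["treated", "control"]

VALID_UNITS = ("Da", "ppm")
VALID_LABELS = ("treated", "control")


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SpectrumMatch:
    """One peptide-spectrum match in one run.

    ``spectrum_id`` identifies the underlying spectrum so that a single
    spectrum listed under several candidate accessions (a shared
    peptide) can be recognized and razor-assigned once. ``None`` means
    the row is its own spectrum.
    """

    peptide_sequence: str
    assigned_accession: str
    peptide_probability: float
    ion_score: float
    parent_mass_error: float
    mass_error_unit: MassErrorUnit = "Da"
    sample_label: SampleLabel = "treated"
    replicate_id: int = 1
    spectrum_id: str | None = None

    def __post_init__(self) -> None:
        _check_probability("peptide_probability", self.peptide_probability)
        if not math.isfinite(self.ion_score):
            raise ValueError(f"ion_score must be finite, got {self.ion_score!r}")
        if not math.isfinite(self.parent_mass_error):
            raise ValueError("parent_mass_error must be finite")
        if self.mass_error_unit not in VALID_UNITS:
            raise ValueError(
                f"mass_error_unit must be one of {VALID_UNITS}, "
                f"got {self.mass_error_unit!r}"
            )
        if self.sample_label not in VALID_LABELS:
            raise ValueError(
                f"sample_label must be one of {VALID_LABELS}, "
                f"got {self.sample_label!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """One protein identification in one sample run."""

    accession: str
    length: int
    protein_probability: float
    spectral_count: int
    unique_peptides: int = 0
    description: str = ""
    sample_label: SampleLabel = "treated"
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1 aa, got {self.length}")
        _check_probability("protein_probability", self.protein_probability)
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be nonnegative")
        if self.unique_peptides < 0:
            raise ValueError("unique_peptides must be nonnegative")
        if self.spectral_count < self.unique_peptides:
            raise ValueError(
                "spectral_count must be >= unique_peptides "
                f"({self.spectral_count} < {self.unique_peptides})"
            )

    def with_length(self, length: int) -> "ProteinRecord":
        return replace(self, length=length)


#: Biotin-dependent carboxylases plus common bead-binding background.
#: These co-purify on (strept)avidin beads because biotin is their
#: cofactor, or stick to beads nonspecifically; user-extensible via
#: FilterCriteria.contaminant_accessions.
DEFAULT_CONTAMINANTS: FrozenSet[str] = frozenset(
    {
        # biotin-dependent carboxylases
        "PC",      # pyruvate carboxylase
        "ACACA",   # acetyl-CoA carboxylase alpha
        "ACACB",   # acetyl-CoA carboxylase beta
        "PCCA",    # propionyl-CoA carboxylase alpha
        "PCCB",    # propionyl-CoA carboxylase beta
        "MCCC1",   # methylcrotonyl-CoA carboxylase alpha
        "MCCC2",   # methylcrotonyl-CoA carboxylase beta
        # common affinity-purification background
        "KRT1",
        "KRT2",
        "KRT9",
        "KRT10",
        "ALB",
        "TRYP_PIG",   # digestion trypsin
        "SAV_STRAV",  # streptavidin leaching from beads
    }
)


@dataclass(frozen=True)
class FilterCriteria:
    """Retention thresholds for identification filtering.

    Defaults: peptide probability >= 0.95, protein probability >= 0.50,
    Mascot ion score strictly > 30, |parent-ion mass error| <= 0.2 Da
    (QTof-class accuracy; switch ``mass_error_unit`` to ``ppm`` for ppm
    tolerances). A treated protein seen in the control survives only in
    "dramatically lower" control abundance, quantified as a
    treated:control count ratio >= ``control_fold_threshold`` with at
    most ``control_max_count`` control spectra — or by whitelist
    (the adaptor-protein exception), always flagged.
    """

    min_peptide_probability: float = 0.95
    min_protein_probability: float = 0.50
    min_ion_score: float = 30.0
    max_parent_mass_error: float = 0.2
    mass_error_unit: MassErrorUnit = "Da"
    control_fold_threshold: float = 5.0
    control_max_count: int = 2
    contaminant_accessions: FrozenSet[str] = DEFAULT_CONTAMINANTS
    whitelist_accessions: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        _check_probability("min_peptide_probability", self.min_peptide_probability)
        _check_probability("min_protein_probability", self.min_protein_probability)
        for name in ("min_ion_score", "max_parent_mass_error",
                     "control_fold_threshold", "control_max_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mass_error_unit not in VALID_UNITS:
            raise ValueError(f"mass_error_unit must be one of {VALID_UNITS}")
        object.__setattr__(
            self, "contaminant_accessions", frozenset(self.contaminant_accessions)
        )
        object.__setattr__(
            self, "whitelist_accessions", frozenset(self.whitelist_accessions)
        )
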