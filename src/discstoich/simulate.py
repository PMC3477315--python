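"""Synthetic AP-MS spectral-count data and toy tandem-domain structures.

The count generator emulates the statistical structure spectral-count
quantitation assumes: the expected spectral count of component *i* is
proportional to (copies per complex) x (sequence length), so that
NSAF-derived mole ratios recover copy-number ratios. Treated runs carry
the complex plus a contaminant background; matched control runs carry
the background alone (plus optional low-level component leakage). All
randomness flows from a single recorded seed.

The toy-structure generator builds a two-domain "tandem" in which the
second domain is a known rigid transform of the first, providing a
ground truth for interface-transform recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from discstoich.errors import DegenerateTruthError
from discstoich.geometry import DomainCoordinates, RigidTransform
from discstoich.records import ProteinRecord


@dataclass(frozen=True)
class ComponentSpec:
    """One complex component: accession, length (aa), copies per
    complex, and stoichiometry category."""

    accession: str
    length: int
    copy_number: float
    category: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass(frozen=True)
class ContaminantSpec:
    """A background protein present in treated and control runs alike.

    ``intensity`` is on the same weight scale as copy_number x length
    for components, so a contaminant with intensity 500 draws counts
    like a 500-residue single-copy component would.
    """

    accession: str
    length: int
    intensity: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a spectral-count simulation.

    ``depth`` is the expected total spectral counts per treated run.
    ``detectability_model`` is "length-proportional" (expected counts
    scale with copies x length — the SAF assumption) or "uniform"
    (counts scale with copies only, which biases NSAF ratios by the
    length ratio). ``count_law`` is "poisson" or "negative-binomial"
    (with ``nb_dispersion`` the gamma shape; smaller = more replicate
    overdispersion). ``control_leak_rate`` is the fraction of each
    component's treated mean that bleeds into the control run.
    """

    components: Tuple[ComponentSpec, ...]
    contaminants: Tuple[ContaminantSpec, ...] = ()
    n_replicates: int = 3
    depth: float = 5000.0
    detectability_model: str = "length-proportional"
    count_law: str = "poisson"
    nb_dispersion: float = 10.0
    control_leak_rate: float = 0.0
    contaminant_probability: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.detectability_model not in ("length-proportional", "uniform"):
            raise ValueError(
                "detectability_model must be 'length-proportional' or 'uniform'"
            )
        if self.count_law not in ("poisson", "negative-binomial"):
            raise ValueError("count_law must be 'poisson' or 'negative-binomial'")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "contaminants", tuple(self.contaminants))

    def component_weights(self) -> Dict[str, float]:
        if self.detectability_model == "length-proportional":
            return {
                c.accession: c.copy_number * c.length for c in self.components
            }
        return {c.accession: c.copy_number for c in self.components}

    def category_map(self) -> Dict[str, str]:
        return {c.accession: c.category for c in self.components}

    def lengths(self) -> Dict[str, int]:
        out = {c.accession: c.length for c in self.components}
        out.update({c.accession: c.length for c in self.contaminants})
        return out

    def true_category_ratios(self, reference: str = "FADD") -> Dict[str, float]:
        """Ground-truth mole ratios of category copy-number sums to the
        reference category."""
        sums: Dict[str, float] = {}
        for c in self.components:
            sums[c.category] = sums.get(c.category, 0.0) + c.copy_number
        ref = sums[reference]
        return {cat: v / ref for cat, v in sums.items()}


#: Canonical DISC component roster used by the 3:1:9 preset. Lengths are
#: realistic residue counts for the human proteins; all data remain
#: synthetic — no measured spectra stand behind these fixtures.
_DISC_COMPONENTS: Tuple[ComponentSpec, ...] = (
    ComponentSpec("TRAIL-R1", 468, 1.0, "receptor"),
    ComponentSpec("TRAIL-R2", 440, 2.0, "receptor"),
    ComponentSpec("FADD", 208, 1.0, "FADD"),
    ComponentSpec("CASP8", 479, 5.0, "DED_only"),
    ComponentSpec("CASP10", 521, 2.0, "DED_only"),
    ComponentSpec("CFLAR", 480, 2.0, "DED_only"),
)

#: Background roster: biotin-dependent carboxylases (in the default
#: contaminant table) plus one generic bead-binder that only control
#: subtraction can remove.
_DISC_CONTAMINANTS: Tuple[ContaminantSpec, ...] = (
    ContaminantSpec("PC", 1178, 600.0),
    ContaminantSpec("ACACA", 2346, 450.0),
    ContaminantSpec("PCCA", 728, 300.0),
    ContaminantSpec("NONSPEC1", 550, 350.0),
)


def disc_3_1_9(
    depth: float = 5000.0,
    n_replicates: int = 3,
    seed: int = 0,
    **overrides,
) -> SyntheticTruth:
    """The receptor:FADD:DED-only = 3:1:9 preset.

    Copy numbers sum to 3 receptors (1 + 2), 1 FADD and 9 DED-only
    proteins (5 + 2 + 2) per complex, with length-proportional
    detectability — the regime in which NSAF category ratios are
    consistent for the copy-number ratios 3:1:9.
    """
    return SyntheticTruth(
        components=_DISC_COMPONENTS,
        contaminants=_DISC_CONTAMINANTS,
        n_replicates=n_replicates,
        depth=depth,
        seed=seed,
        **overrides,
    )


@dataclass
class SimulatedDataset:
    """Treated and control protein tables per replicate, plus truth."""

    treated: Dict[int, List[ProteinRecord]]
    control: Dict[int, List[ProteinRecord]]
    truth: SyntheticTruth

    def all_records(self) -> List[ProteinRecord]:
        out: List[ProteinRecord] = []
        for rep in sorted(self.treated):
            out.extend(self.treated[rep])
        for rep in sorted(self.control):
            out.extend(self.control[rep])
        return out


def _draw_count(rng: np.random.Generator, mean: float, law: str,
                dispersion: float) -> int:
    if mean <= 0:
        return 0
    if law == "poisson":
        return int(rng.poisson(mean))
    # negative binomial as gamma-Poisson mixture with shape=dispersion
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return int(rng.poisson(lam))


def _unique_peptides(rng: np.random.Generator, count: int, length: int) -> int:
    if count == 0:
        return 0
    cap = max(1, length // 25)  # rough tryptic-peptide capacity
    return int(min(count, cap, 1 + rng.poisson(math.sqrt(count))))


def simulate_counts(truth: SyntheticTruth) -> SimulatedDataset:
    """Draw treated/control spectral-count tables from the truth.

    Per replicate, each protein's treated count is drawn from the
    configured count law with mean depth x w_i / W, where w_i is
    copy_number x length for components (or copy_number under uniform
    detectability) and the stated background intensity for
    contaminants, and W is the total weight. Controls draw contaminants
    at the same means (comparable background in both runs) and
    components at the leak rate. Zero draws produce no record — an
    undetected protein is simply absent. Component protein
    probabilities are 1.0; contaminant probabilities are configurable.
    Identical seeds reproduce identical tables.
    """
    comp_w = truth.component_weights()
    cont_w = {c.accession: c.intensity for c in truth.contaminants}
    total = sum(comp_w.values()) + sum(cont_w.values())
    if total <= 0:
        raise DegenerateTruthError("total sampling weight is zero")
    lengths = truth.lengths()
    rng = np.random.default_rng(truth.seed)

    treated: Dict[int, List[ProteinRecord]] = {}
    control: Dict[int, List[ProteinRecord]] = {}
    for rep in range(1, truth.n_replicates + 1):
        t_rows: List[ProteinRecord] = []
        c_rows: List[ProteinRecord] = []
        for comp in truth.components:
            mean = truth.depth * comp_w[comp.accession] / total
            count = _draw_count(rng, mean, truth.count_law, truth.nb_dispersion)
            if count > 0:
                t_rows.append(
                    ProteinRecord(
                        accession=comp.accession,
                        length=lengths[comp.accession],
                        protein_probability=1.0,
                        spectral_count=count,
                        unique_peptides=_unique_peptides(rng, count, comp.length),
                        description=f"synthetic component ({comp.category})",
                        sample_label="treated",
                        replicate_id=rep,
                    )
                )
            leak = _draw_count(
                rng, mean * truth.control_leak_rate, truth.count_law,
                truth.nb_dispersion,
            )
            if leak > 0:
                c_rows.append(
                    ProteinRecord(
                        accession=comp.accession,
                        length=lengths[comp.accession],
                        protein_probability=1.0,
                        spectral_count=leak,
                        unique_peptides=_unique_peptides(rng, leak, comp.length),
                        description=f"synthetic component ({comp.category})",
                        sample_label="control",
                        replicate_id=rep,
                    )
                )
        for cont in truth.contaminants:
            mean = truth.depth * cont_w[cont.accession] / total
            for label, rows in (("treated", t_rows), ("control", c_rows)):
                count = _draw_count(rng, mean, truth.count_law,
                                    truth.nb_dispersion)
                if count > 0:
                    rows.append(
                        ProteinRecord(
                            accession=cont.accession,
                            length=cont.length,
                            protein_probability=truth.contaminant_probability,
                            spectral_count=count,
                            unique_peptides=_unique_peptides(
                                rng, count, cont.length
                            ),
                            description="synthetic contaminant",
                            sample_label=label,
                            replicate_id=rep,
                        )
                    )
        treated[rep] = t_rows
        control[rep] = c_rows
    return SimulatedDataset(treated, control, truth)


# ---------------------------------------------------------------------------
# Toy structures


@dataclass(frozen=True)
class ToyStructureTruth:
    """Ground truth for a synthetic tandem-domain structure."""

    n_residues: int = 30
    transform: RigidTransform | None = None
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_residues < 3:
            raise ValueError("need >= 3 residues for a usable domain")

    def resolved_transform(self) -> RigidTransform:
        if self.transform is not None:
            return self.transform
        return default_interface_transform()


def default_interface_transform() -> RigidTransform:
    """A domain-sized repeat operator: ~100 degree twist with a ~25 A
    step, the scale of one globular domain packing against the next."""
    axis = np.array([0.3, 0.5, 0.81])
    axis = axis / np.linalg.norm(axis)
    return RigidTransform.from_screw(
        axis=axis, point=(10.0, -4.0, 2.0), twist=100.0, rise=25.0
    )


def make_toy_domain(n_residues: int = 30) -> DomainCoordinates:
    """Alpha-helical CA trace standing in for a small globular domain.

    Ideal helix geometry: 2.3 A radius, 1.5 A rise and 100 degrees per
    residue — compact, non-collinear, deterministic.
    """
    idx = np.arange(n_residues)
    theta = np.radians(100.0) * idx
    coords = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx]
    )
    labels = tuple((int(i + 1), "CA") for i in idx)
    return DomainCoordinates(labels, coords)


@dataclass
class ToyTandem:
    """Synthetic two-domain structure with a known inter-domain transform."""

    ded1: DomainCoordinates
    ded2: DomainCoordinates
    pairing: Tuple[Tuple[int, int], ...]
    truth: ToyStructureTruth


def make_toy_tandem(truth: ToyStructureTruth) -> ToyTandem:
    """Build a tandem structure whose second domain is the ground-truth
    transform of the first, with optional Gaussian coordinate jitter,
    plus the identity residue correspondence."""
    domain = make_toy_domain(truth.n_residues)
    op = truth.resolved_transform()
    coords2 = op.apply(domain.coords)
    if truth.jitter_sd > 0:
        rng = np.random.default_rng(truth.seed)
        coords2 = coords2 + rng.normal(0.0, truth.jitter_sd, coords2.shape)
    ded2 = DomainCoordinates(domain.labels, coords2)
    pairing = tuple((r, r) for r, _ in domain.labels)
    return ToyTandem(domain, ded2, pairing, truth)
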