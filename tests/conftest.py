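import numpy as np
import pytest

from discstoich.records import FilterCriteria, ProteinRecord, SpectrumMatch


@pytest.fixture
def criteria():
    return FilterCriteria()


def random_matches(rng: np.random.Generator, n: int, label="treated",
                   replicate=1):
    """Random PSMs straddling every threshold, for oracle comparisons."""
    return [
        SpectrumMatch(
            peptide_sequence="PEPTIDE",
            assigned_accession=f"P{rng.integers(0, 20)}",
            peptide_probability=float(rng.uniform(0.8, 1.0)),
            ion_score=float(rng.uniform(0.0, 80.0)),
            parent_mass_error=float(rng.normal(0.0, 0.2)),
            sample_label=label,
            replicate_id=replicate,
        )
        for _ in range(n)
    ]


def random_protein_records(rng: np.random.Generator, n: int, label="treated",
                           replicate=1, accession_prefix="P"):
    """Random protein identifications with unique accessions per run."""
    out = []
    for i in range(n):
        count = int(rng.integers(0, 60))
        out.append(
            ProteinRecord(
                accession=f"{accession_prefix}{i}",
                length=int(rng.integers(50, 2000)),
                # rounded as upstream tools print it; survives the
                # 6-significant-digit TSV writers unchanged
                protein_probability=round(float(rng.uniform(0.0, 1.0)), 6),
                spectral_count=count,
                unique_peptides=int(rng.integers(0, count + 1)),
                sample_label=label,
                replicate_id=replicate,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
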