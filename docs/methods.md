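# Methods

## Retention filtering

Upstream identification software supplies, per run, peptide-spectrum
matches (PSMs) with PeptideProphet-style peptide probabilities, Mascot ion
scores and parent-ion mass errors, and protein-level identifications with
ProteinProphet-style probabilities and spectral counts. These posteriors
and scores are consumed as given; the package never recomputes them.

A PSM is retained when its peptide probability is at least
`min_peptide_probability` (default 0.95), its ion score strictly exceeds
`min_ion_score` (default 30 — a score of exactly 30 is rejected), and its
absolute parent-ion mass error is within `max_parent_mass_error`. The mass
tolerance defaults to 0.2 Da, a QTof-class accuracy; a `ppm` unit mode is
provided, and mixing units within one input (or between data and criteria)
is an error rather than a silent misinterpretation.

Protein-level filtering removes accessions in the contaminant table (the
shipped default covers the biotin-dependent carboxylases — pyruvate
carboxylase, the acetyl-, propionyl- and methylcrotonyl-CoA carboxylases —
which co-purify whenever biotinylated bait meets (strept)avidin beads,
plus keratins, albumin, trypsin and streptavidin) and identifications
below `min_protein_probability` (default 0.50). Control subtraction then
removes any treated protein also found in the matched control unless its
abundance there is *dramatically lower*. That phrase needs a number to be
testable; here it is quantified as treated:control spectral-count ratio
≥ 5 with at most 2 control spectra, both configurable. The choice is
deliberately conservative: a protein with more than a couple of control
spectra is treated as background no matter how abundant it is in the
treated run. Subtraction operates per replicate by default, with a pooled
option (`pooled_controls`) that sums control counts across replicates
before comparison.

Adaptor proteins can be genuinely present yet so substoichiometric that
they fail control subtraction in a weaker dataset. Rather than hard-coding
any particular protein, the filter exposes a whitelist; whitelist-only
retentions are always flagged in the removal audit so a reader can see
exactly which results rest on the exception.

Shared peptides: a spectrum listed under several candidate accessions is
counted once, razor-assigned to the accession with the highest protein
probability (lexicographically smallest accession on ties). Detecting this
requires a spectrum identity, so `SpectrumMatch` carries an optional
`spectrum_id`; rows without one are each their own spectrum. Duplicate
accessions within one run are an error, not a silent merge — malformed
exports should fail loudly.

Every input record ends up in exactly one of retained or removed, each
removal carrying a reason (`contaminant`, `protein probability`,
`present in control`); the audit TSV is the exhaustive partition.

## Quantitation

SAF is spectral count over sequence length in residues; NSAF divides each
SAF by the per-replicate sum over a normalization set, so NSAF sums to 1
per replicate (asserted to 1e-9). The default normalization set is the
retained protein set; because the denominator cancels in any NSAF ratio,
the FADD-normalized stoichiometry is invariant to this choice whenever all
category members are in the set — a property the tests assert numerically.
Relative SAF divides by a declared reference accession within each
replicate (used for confidence-vs-abundance scatter tables).

Lengths come from the protein table or, when a FASTA is supplied, from the
sequences (authoritative on disagreement). Cleaved species quantified
against a processed form can be handled with per-accession length
overrides; the default is the full-length database sequence.

Aggregation over replicates reports the median protein probability and
median relative SAF over replicates where the protein was detected, and
the mean NSAF over *all* replicates, an absent accession contributing NSAF
0 — non-detection is treated as zero abundance rather than
missing-at-random, which biases means downward for marginal proteins but
never invents abundance. Dispersion follows the convention: SEM
(sd/sqrt(n)) for n ≥ 3, min–max range for n = 2, not available for n = 1;
the convention used is always named alongside the number.

Category stoichiometry sums member NSAFs per replicate, averages over
replicates, and divides by the FADD category; FADD's ratio is 1 by
construction and a zero FADD NSAF raises an error instead of emitting
infinity. Only spectral counting is implemented — no intensity-based
(XIC/iBAQ) quantitation, and no significance testing of ratio differences:
the ratios are descriptive.

## Chain geometry

Superposition uses the least-squares optimal proper rotation (Kabsch, via
scipy's rotation machinery) on one representative atom per residue, by
default the backbone alpha-carbon; reflections are never returned, so a
mirrored input shows up as a large residual rather than being silently
flipped. Fewer than three pairs or collinear points raise a degeneracy
error.

The repeat operator of a DED chain is derived by superposing the first
domain of a tandem-DED structure onto the second over an explicitly
supplied residue correspondence. Automatic sequence alignment is
deliberately out of scope: the pairing encodes a structure-based
alignment, and guessing it would hide the most consequential input.
Propagation is refused when the superposition RMSD reaches the similarity
threshold (default 3 Å) — domains that dissimilar do not define a credible
repeat interface. Both the operator and its inverse can be propagated
(`--inverse`), since the growth direction of a modeled chain is a
biological question the geometry alone cannot settle.

Any rigid transform decomposes into a screw: twist about and rise along a
unique axis (Chasles' theorem). The twist comes from the rotation vector,
the rise is the axial translation component, and the axis point is the
minimum-norm solution of (I − R)p = t_perp. Reconstruction from screw
parameters reproduces the transform to machine precision (tested), and an
n-repeat chain advances n × rise along the axis. Transforms with twist
below 1e-9 rad are reported as pure translations with the axis along the
translation (z for the identity).

The long-range topology of a propagated chain is reported, never
asserted: small interface changes swing the helix parameters widely, so
the geometry report includes a sensitivity analysis — twist and rise
re-derived under seeded Gaussian jitter (default sd 0.5 Å, 50 replicates)
of the interface coordinates — rather than a single claimed helix. The
clash check counts representative-atom pairs within a cutoff (default
4.0 Å) between non-adjacent copies; adjacent-copy contacts are tallied
separately because they *are* the modeled interface. Catalytic-subunit
placement, docking and energy minimization are out of scope.

## Synthetic data

The count generator draws, per replicate, each protein's treated count
from a stated law with mean depth × w_i / W, where w_i is copy_number ×
length for components under the default length-proportional detectability
(the assumption under which NSAF ratios are consistent for mole ratios),
copy_number alone under uniform detectability (which biases NSAF ratios by
the length ratio — the generator exposes the SAF assumption instead of
hiding it), and a stated background intensity for contaminants; W is the
total weight. Controls draw contaminants at the same means — comparable
background in both runs, the regime control subtraction is built for — and
components at a configurable leak rate (default 0; a nonzero rate
exercises the "dramatically lower abundance" branch). The count law is
Poisson by default with a negative-binomial (gamma-Poisson) option for
replicate overdispersion, since replicate SEMs alone do not pin down a
noise model. Zero draws yield no record: an undetected protein is absent,
which also exercises the absent-equals-zero aggregation rule. Component
protein probabilities are emitted as 1.0, contaminants at 0.97 (above the
0.5 threshold, so their removal genuinely tests the contaminant table and
control subtraction rather than the probability filter).

The `disc-3-1-9` preset encodes a DISC-like roster with realistic lengths
(TRAIL-R1 468, TRAIL-R2 440, FADD 208, caspase-8 479, caspase-10 521,
c-FLIP 480 aa) and copy numbers 1+2 receptors, 1 FADD, 5+2+2 DED-only —
category totals 3 : 1 : 9 — plus three carboxylase-type contaminants and
one generic bead-binder ("NONSPEC1") that only control subtraction can
remove. Default depth is 5,000 expected spectra per run with 3 replicates,
a realistic scale for a gel-based LC-MS/MS complex pull-down. All fixtures
are synthetic and generated at run time; FASTA sequences are random
residues of the stated lengths.

What passing recovery tests show — and what they do not: the generator
satisfies the proportionality assumption by construction, so recovery of
3 : 1 : 9 within ±15 % over ≥95 % of seeds demonstrates the pipeline's
correctness and its sampling-noise behavior at that depth, not the
accuracy of NSAF on real data, where digestion efficiency, ion
suppression, peptide detectability and shared peptides perturb the
count–abundance relationship. Those effects are intentionally not modeled.

## Numerical conventions

Text outputs render floats with 6 significant digits and fixed column
order, so identical inputs give byte-identical files; JSON reports sort
keys and round the same way. Exactness tolerances in the geometry tests
are 1e-6 Å on coordinates (the superposition backend leaves ~1e-7
residue) and 1e-9 on NSAF conservation. Problem sizes used by the
validation script — 100 simulation seeds, 1,000 random NSAF tables, 10^4
filter records, 20-point superposition clouds — keep a full run under a
minute on one CPU while leaving Monte-Carlo margins far from the asserted
thresholds.
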