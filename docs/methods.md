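# Methods

This note documents the models, conventions and design choices behind
`pepdock`, in the spirit of the methods documentation of mature scientific
packages: what each quantity is, which knobs matter, what the synthetic
generators do and do not emulate, and where genuinely open choices were
resolved.

## Structure model

A complex is exactly two chains — a folded receptor and a short peptide —
of amino-acid residues with heavy atoms. At read time (PDB or mmCIF, via
gemmi) hydrogens, waters and non-amino-acid heteroatoms are dropped, only
the first model of multi-model files is used, and alternate conformations
are resolved to a single conformer by keeping the highest-occupancy altloc
(ties go to the first encountered). Chains are addressed by author ids, the
convention behind entry names like `6A8N_AP`; mmCIF label ids are reachable
via a flag. The release/deposition date is read from the header when
present and drives the training-library date filter. A configurable
peptide-length predicate (default 3–25 residues) is provided for corpus
filtering; full crystallographic curation (cofactors, crystal contacts) is
out of scope.

## Docking accuracy

**Contacts and interfaces.** A native contact is a receptor–peptide residue
pair with any heavy-atom distance < 5 Å; interface residues use the same
rule at 10 Å. Both cutoffs are config keys. These are the conventional
values for the composite docking-quality score and make "binding site" and
"contact" mutually consistent across modules.

**DockQ.** `score = (Fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²))/3`,
with iRMSD the backbone RMSD over native interface residues after
superposing on those residues, and LRMSD the peptide backbone RMSD after
superposing receptor backbones. Superpositions use a Kabsch SVD fit with a
proper-rotation correction; degenerate (collinear) point sets are rejected.
Self-comparison gives exactly 1.0. Categories: poor < 0.23 ≤ acceptable ≤
0.49 < medium ≤ 0.80 < high. Residue correspondence defaults to identical
sequence order; unequal chains are an error rather than silently aligned.

**Peptide RMSD.** Computed in the receptor frame: superpose predicted
receptor backbone onto native, then evaluate `sqrt((1/N) Σ |pred−nat|²)`
over the N peptide backbone atoms without re-fitting. Default atoms are
N, CA, C, O with a Cα-only switch — the backbone definition was genuinely
open and the 4-atom choice is the stricter, more common reading.

**Atomic accuracy.** Passed iff Fnat > 0.9 (strict, per ">90%"), zero
clashes, peptide all-atom RMSD < 2 Å and interface all-atom RMSD < 3 Å.
"Clash" is not standardized; here it is any inter-chain heavy-atom pair
< 2.0 Å in the prediction (config-exposed) — simple, deterministic, and
catches interpenetration. The peptide all-atom RMSD uses the
receptor-backbone frame (consistent with the peptide RMSD above); the
interface all-atom RMSD superposes on the native interface heavy atoms.

**TM-score.** Cα-based, `d0 = 1.24(L−15)^⅓ − 1.8` floored at 0.5, maximized
by the standard iterative scheme: fragment seeds of length L, L/2 and 4 at
every 4th position, each refined by re-superposing on residues within a
growing cutoff (d0+1 … d0+4, 20 iterations). Exactness is established
against a multi-start rigid-body optimisation oracle in the tests (0.02
tolerance), not bit-for-bit against any particular program. Only
equal-length traces (same protein) are supported; flexible alignment of
non-identical sequences is a non-goal.

**Secondary structure.** A deliberately simplified dihedral classifier
stands in for hydrogen-bond-based assignment: helix candidates at
φ∈(−100°,−30°), ψ∈(−80°,−5°) promoted in runs of ≥4; strand candidates at
φ∈(−170°,−40°), ψ∈(90°,180°] in runs of ≥3; termini and everything else
are loop. It is deterministic and adequate for comparing ideal-geometry
synthetic conformations; it is not DSSP.

## Distograms and RMSD_map

The representative atom is Cβ (Cα for glycine), matching the common
distogram convention. Predicted bin-probability tensors are collapsed to
probability-weighted mean bin midpoints; an open final bin takes its lower
edge plus half the preceding bin width. `RMSD_map` is the RMS difference
between native and predicted distances over the native-defined inter-chain
pair set: pairs with native distance ≤ 12 Å (config). The native-defined
convention means the statistic is not symmetric under swapping arguments —
deliberately, since the native map is the reference. Neither the Nc pair
rule nor the predicted-distance collapse is printed in the source material;
both defaults are documented parameters, with 12 Å chosen to span the
near-interface block. Success cutoffs: RMSD_map < 2.5 Å, peptide RMSD
< 12 Å (both strict, both config keys).

## MSAs, pairing and coevolution

**Formats.** Aligned FASTA and Stockholm are read via Biopython; A3M is
parsed directly because its lowercase insertion states must be removed so
that columns index query positions. Species tags come from configurable
header regexes (UniProt `OX=` and `_SPECIES`-suffix conventions); untagged
rows are never paired.

**Pairing.** Queries are always paired. Within each species, rows are
ranked by percent identity to their query and rank-i pairs with rank-i (the
multimer-pipeline convention; the tie-breaking rule was not specified in
the source description). Leftovers and untagged rows sit block-diagonally,
gap-padded in the other chain's block. `paired_rows` counts rows non-gap in
both blocks, query included.

**Shuffle null.** The peptide halves of the paired non-query rows are
permuted uniformly at random (seeded). Every block keeps its exact sequence
multiset, so single-column statistics are invariant and only the
inter-chain pairing — hence any coevolutionary covariation — is destroyed.

**Mutual information.** Plug-in MI in bits over rows with no gap in either
column; gaps are not a 21st symbol by default and no pseudocounts are
applied (both config-exposed; whether the original analysis used either is
unstated, and the plug-in estimator is the most transparent default). The
plug-in estimator is biased upward at shallow depth — roughly
(|A|−1)(|B|−1)/(2N ln 2) bits — which is visible in background MI at depth
a few hundred and negligible at the depths where conclusions are drawn
(5,000 in the tests). No APC correction by default.

**Conservation.** Per-column Jensen–Shannon divergence (base-2 logs, hence
in [0,1]) between the column's amino-acid frequencies over non-gap rows and
a background distribution — uniform over the 20 amino acids by default —
multiplied by (1 − gap fraction) as a gap penalty, with no window
smoothing. All-gap columns score 0 and are flagged. The depth filter
predicate requires ≥ 50 sequences.

**Ablations and hydrophobicity.** Peptide variants: mask (all 'X'),
poly-Gly, and seeded scramble that preserves composition and rejects the
identity permutation whenever any other ordering exists. Hydrophobicity is
the arithmetic mean of Kyte–Doolittle values; 'X' is skipped.

## Binding sites and match search

The binding site is the set of receptor residues with any heavy atom < 5 Å
from the peptide (the Fnat contact rule, so sites and contacts agree).
Site identity uses Jaccard overlap with a 0.25 "same site" threshold
(config). The match search against a dated library proceeds: strict date
filter (entries released on/after the cutoff are dropped); receptor
homology by global sequence identity ≥ 30% OR TM-score ≥ 0.5 (either arm
suffices, both config-gated — the exact tools and thresholds used upstream
are not recoverable, so these conventional homology bounds are defaults,
not claims of fidelity); superposition of the entry receptor onto the query
receptor (Cα Kabsch, alignment-derived correspondence when lengths differ);
and partner Cα RMSD under that fixed superposition, sliding the shorter
chain along the longer for the best contiguous window when lengths differ.
A match requires partner RMSD < 10 Å. Cα rather than full backbone was
chosen for the partner RMSD as the minimal deterministic convention.

## Confidence

Ranking confidence is the weighted 0.8·ipTM + 0.2·pTM (reported under the
label "ipTM+pTM"; the literal sum is selectable — the weighted form is the
default because confidence cutoffs near 0.75 only make sense on a [0,1]
scale). iPAE is the mean PAE over both inter-chain blocks. pDockQ is
`0.018 + 0.724/(1+exp(−0.052(x−152.611)))` with `x = mean interface pLDDT ×
ln(interface contacts)`, interface contacts under the 5 Å rule and natural
log, per the originating convention.

## Synthetic data

The generators are pure functions of their specs (seed included) and
emulate, at desk scale, the input classes of a prediction-evaluation study:

- **Toy complexes** (default 60-residue receptor, 12-residue peptide,
  ≥ 4 native contacts): ideal internal-coordinate backbones (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, standard angles, ω = 180°) with Cβ stubs,
  built as ideal helices (φ=−60°, ψ=−45°) or strands (φ=−120°, ψ=135°); the
  peptide is slid radially against the receptor face until the closest
  heavy-atom gap is ~4 Å. There are no sidechains beyond Cβ, no packing and
  no energetics — the point is exact, controllable geometry.
- **Perturbed predictions**: receptor untouched; peptide optionally
  relocated to a wrong site (mirrored across the receptor axis and shifted
  axially, re-docked to the surface, ≥ 20 Å centroid displacement), rotated
  about a seeded axis through its centroid, rigidly translated by an exact
  magnitude along a seeded direction whose component away from the receptor
  is forced non-negative (so growing magnitudes leave the interface and
  accuracy degrades monotonically), and/or jittered with per-atom Gaussian
  noise.
- **MSAs**: per-column categorical sampling at the requested depth (default
  conserved fraction 0.2, conserved columns put 90% of mass on one symbol).
  Coevolving column pairs are drawn from a mixture
  `P(a,b) = w/k·δ_ab + (1−w)/k²` over a seeded 4-symbol sub-alphabet, with
  w solved by bisection (to 1e-6 bits) so the analytic MI equals the
  target. Row i of both MSAs shares a species tag; by default one species
  per row pair, because with shared species the identity-rank pairing rule
  cannot be guaranteed to reconstitute the generating pairs — smaller
  species pools remain available for exercising the pairing logic itself.
- **Match libraries**: matches are jittered (σ = 0.2 Å), 20%-mutated copies
  of the query dated inside the window; homolog non-matches carry their
  partner displaced 25 Å; non-homologs are random-coil decoys with random
  sequences (low identity by chance, low TM-score by construction); one
  match-like entry is dated after the cutoff to exercise the date rule.

What the generators do **not** emulate: real sidechain packing, realistic
contact densities and interface chemistry, alignment errors and taxonomic
structure in MSAs, or the correlated error modes of actual predictors.
Passing tests therefore demonstrate the *correctness of the computations*
under controlled conditions — exact parameter recovery, planted-signal
detection, strict threshold behavior — not predictive performance on real
complexes.

## Numerical choices and degenerate inputs

- Superposition requires ≥ 3 points and a rank-≥2 covariance; reflections
  are corrected to proper rotations.
- Zero native contacts make DockQ undefined (error), as does an empty
  native inter-chain pair set for RMSD_map; empty binding sites are legal.
- Distogram symmetry and zero diagonal are validated to 1e-6; bin
  distributions must sum to 1 within 1e-4.
- Statistical comparisons delegate to scipy (Wilcoxon signed-rank with
  zero-splitting, two-sided Mann–Whitney U) and refuse n < 5;
  Benjamini–Hochberg adjustment is available and labeled, raw p-values are
  the default report.
- Problem sizes in the test suite (60+12-residue complexes, depth-5,000
  MSAs, 30-complex end-to-end batches, 100 shuffle replicates) were chosen
  as the smallest scales at which each property is sharply decidable.

## Known limitations

- Two chains only; multi-chain complexes and assemblies are out of scope.
- The secondary-structure stand-in is dihedral-only (no hydrogen bonds).
- TM-score requires equal-length traces; the match search's structure arm
  is skipped for unequal-length receptors (the sequence arm still applies).
- The JSD "low-quality MSA" filter threshold is exposed as configuration
  without a claimed default, since no value is recoverable from the source
  description.
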