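# Methods

This note documents the models and procedures mutascan implements, the
defaults it ships with, and the design choices made where more than one
reasonable reading existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Amplicon parsing

The sequencing construct is, in canonical orientation,

    fwd_demux .. fwd_const | insert | rev_const .. revcomp(rev_demux)

with an insert of 48 nt encoding a 16-mer peptide. The parser joins mates
on read id, reverse-complements the reverse mate, and requires all four
motifs by exact, first-occurrence substring match — no mismatch tolerance,
because none is defined for the assay and exact matching is deterministic
and conservative. Each mate must independently yield the insert; the pair
is accepted only when the two inserts are identical, N-free and exactly 48
nt. Quality strings are carried but never used for filtering. Failure
modes are statuses (`reject_missing_motif`, `reject_discordant`,
`reject_size`, `reject_ambiguous`), never exceptions, so every read is
classified exactly once and tallies partition the input. Only peptides in
the designed library are counted; accepted off-library peptides are
tallied separately. Coordinates are 0-based half-open internally and never
exposed.

## Enrichment

With input and output frequencies f_in, f_out, enrichment is
log2E = log2(f_out / f_in) and Δlog2E subtracts the parent's log2E per
target. Two imputation dialects avoid infinities:

- **add_one** (default): pseudocount 1 on every designed-library member,
  then normalise. Total-support, suited to dense combinatorial libraries.
- **impute_min**: normalise observed counts; unobserved members get the
  per-sample minimum observed proportion and are flagged. Suited to sparse
  single-mutant (NNK) screens. "Minimum" is taken per sample, not across
  samples; this is configurable in principle but per-sample is the default
  reading because samples differ in depth.

Variants with log2E > 0 (strict) on the non-specific control target are
excluded from all downstream analysis, after Δ computation and before any
ranking. One output sample per target per run is assumed (the final
selection round is the one sequenced).

## Mutation selection

Per class scope (CC, CXnC), each single mutation is scored by its mean
Δlog2E over in-scope targets and its peak (maximum) Δlog2E. At each parent
position the best mutation by mean and the best by peak are kept;
candidates must then pass peak ≥ 5 **or** mean ≥ 0.55 (defaults). The OR
combination reflects the two-pronged intent — mean captures overall
affinity, peak captures single-target diversity; AND is available via
`SelectionConfig(combine="and")`. Survivors are sorted by (mean desc, peak
desc, position asc, target residue asc) — mean primary, peak secondary,
deterministic positional tie-breaks — truncated to the class top-N
(defaults 10 for CC, 12 for CXnC), and the two pools are united with pool
membership recorded. Whether the mean threshold applies to per-class or
all-chemokine means is not fully determined by the procedure's description;
per-class is implemented since the thresholds feed per-class pools.

Combinatorial mutants are ranked by **median** Δlog2E over ALL / CC / CXnC
scopes (median rewards breadth of binding rather than a few strong
targets). CM-max / CM-min are the top / bottom five by the all-target
median; CM-maxCC / CM-maxCXnC analogous on class medians. Medians over an
even number of targets are midpoints of the central pair; ties break on
(median, mean, sequence). Chemokine type labels
(inflammatory/dual/homeostatic) are carried into reports but never used in
ranking.

## Library design

Per mutation pool, every subset of size ≥ 2 whose positions are pairwise
distinct is applied to the parent. Same-position subsets are excluded at
enumeration time rather than collapsed after application: the reported
maximum number of simultaneous substitutions in such libraries equals the
number of mutated residues, implying conflicting pairs never co-occur; the
apply-then-dedupe alternative is available with
`exclude_same_position=False`. Pool outputs are united and deduplicated on
sequence (first provenance kept, pool origins united); singles, the parent
and a scrambled parent control are appended. The scrambled control is a
seeded permutation guaranteed distinct from the parent; for reproduction
runs it should be supplied explicitly since published scrambles are
generally not derivable.

Reverse translation uses an embedded E. coli K-12 codon-usage table with
two modes: `most_frequent` (deterministic) and `weighted_sample` (seeded,
proportional to usage). A `gc_biased` flag restricts choice to the two
highest-GC codons per residue, emulating GC-biased codon selection; codon
choice never affects peptide-level results. Oligos carry the printed
cloning arms (5′ GCAGCCTCTTCATCTGGC, 3′ GGTGGAGGATCCGGA).

The default parent for synthetic runs, `SYNTHETIC_PARENT =
EEDDYTAGAPLTCGFT`, is a documented synthetic 16-mer; two positions (8 and
14) are glycine placeholders because no published residue is available for
them. It is never presented as the real evasin-derived peptide, whose
sequence is a required input for reproduction runs.

## Dose-response and potency

Responses follow f(x) = c + (d − c) / (1 + exp(b (ln x − ln e))). Agonist
(EC) fits are done on responses normalised to percent of the maximal
per-dose mean (the normalisation convention is a package choice, logged
here) with d fixed at 100; inhibitor (IC) fits fix c = 0. Both are
3-parameter fits. Before an EC fit, doses above the peak-response dose
whose mean response falls below the peak are excluded (receptor
desensitization); the peak and all sub-peak doses are always retained.
Raw replicates are fitted, not per-dose means. The optimizer is
`scipy.optimize.least_squares` with multi-start over slope sign and a
log-spaced midpoint grid and tolerances of 1e-14; non-convergence is
flagged on the fit object, never silently replaced. Effective doses come
from the closed form x = e ((100 − f)/f)^(1/b); potencies are
pX = −log10(X in mol/L).

Chemokine pools are designed as molar fractions proportional to mean TPM
over the supplied chemokine list; no expression filtering is applied beyond
the mean, and gene inclusion is the caller's responsibility.

## Dunnett comparisons

Many-to-one comparisons use pooled one-way-ANOVA error variance and
two-sided adjusted p-values from the equicoordinate probability of the
many-to-one multivariate t distribution with product correlation
ρ_ij = λ_i λ_j, λ_i = sqrt(n_i/(n_i + n_0)). The probability is evaluated
by writing T_i = (sqrt(1 − λ_i²) U_i + λ_i Z_0)/S and integrating the
conditional product of normal CDFs over the shared control variate
(48-node Gauss–Hermite) and the chi-distributed scale (64 quantile
midpoints). A single comparison reduces exactly to the two-sided Student t
tail. Accuracy against an independent implementation is on the order of
1e-3 or better, adequate for the star bins used in reporting
(≤0.05/0.01/0.001/0.0001); node counts are parameters of `dunnett_sf` if
more precision is wanted. The quadrature is vectorised, which is what makes
the 10⁴-replicate familywise-error null calibration practical.

## Structure contacts and occlusion

Models are read with gemmi from mmCIF or PDB; hydrogens are dropped and
altlocs resolved to the highest-occupancy atom. Binding-site residues are
residue-level: any heavy-atom pair within 5.0 Å. Atom-pair interaction
typing is a simplified fixed-rule classifier: hydrophobic = apolar C···C
≤ 4.5 Å; hydrogen = donor···acceptor ≤ 3.5 Å; ionic = opposite formal
charges ≤ 4.0 Å (Asp/Glu −, Lys/Arg +, His neutral at physiological pH);
polar = uncharged polar pair ≤ 3.5 Å; carbonyl = carbonyl C···O ≤ 3.6 Å;
aromatic = aromatic-ring carbon pair ≤ 4.0 Å (no ring-centroid geometry, so
π–π and atom–ring interactions are deliberately not typed); van der Waals =
distance ≤ r_a + r_b + 0.5 Å over element radii. Residue-pair classes are
unions over atom pairs; unknown residue names degrade to element-only
typing with a log message. These rules are documented constants, not a
re-implementation of a full interatomic-interaction engine; counts are
comparable across models analysed with the same rules, which is all the
occlusion and bond-summary analyses require.

Occlusion: the binding site is computed on the chemokine:partner model;
a site residue is "blocked" when the same chemokine residue (number and
name checked across models, mismatches are an error) lies within 5 Å of
the peptide in the chemokine:peptide model. Blocked ⊆ site holds by
construction and is asserted. The peptide chain can be auto-detected as the
shortest chain but is normally passed explicitly.

## Synthetic data

The selection simulator models proportional retention: per round,
post-selection proportions are p_i w_i / Σ p_j w_j with latent weights
w = 2^(baseline + Σ per-mutation effects + Σ pairwise epistasis terms);
counts are drawn multinomially only at sequencing, at the configured depth.
This reproduces the log-linear enrichment the analysis assumes —
E[Δlog2E] = rounds × log2(w_variant/w_parent) — while ignoring bead
kinetics, amplification bias, PCR chimeras and index hopping, so passing
recovery tests demonstrates correctness of the analysis chain, not
robustness to those real-data artefacts. Read synthesis embeds inserts in
the exact scaffold with optional per-base substitution errors; chemotaxis
simulation draws Gaussian (percent scale) or negative-binomial (count
scale) replicates around a true log-logistic curve; TPM tables come in
uniform, lognormal and sparse profiles. All generators are deterministic
under fixed seeds.

## Validation studies and problem sizes

`mutascan.validation` bundles the two simulator-based studies the test
suite and acceptance script run:

- **Improving-mutation recovery**: the 305-member NNK library of the
  synthetic parent, 6-target panel (3 CC, 3 CXnC), 12 true improving
  mutations at distinct positions with per-target effects drawn from
  [1, 2] log2 units, depth 10⁵, 3 rounds, minimum-proportion imputation.
  Recovery is the fraction of the true set present in the selected union.
  The panel omits the control target here: under the null the control's
  log2E is symmetric noise around zero, so strict >0 exclusion would
  remove half the library by coin flip — a property of the exclusion rule
  itself, not of the selection stage this study validates.
- **pIC50 recovery**: 100 refits of noisy inhibitor curves (Gaussian sd 5%
  of the 100% span, 3 replicates, 8 doses, true IC50 drawn log-uniformly
  over 10⁻⁸–10⁻⁶·⁵ M), scored by |pIC50 error| ≤ 0.1.

The familywise-error calibration uses 6 groups of 3 under a Gaussian null
with 10⁴ replicates. These sizes were chosen as the smallest that give
stable Monte-Carlo estimates for the properties being checked.

## Known limitations

- No quality-based filtering, adapter trimming or error correction; the
  parser assumes clean amplicons and rejects anything imperfect.
- Enrichment uses raw frequency ratios; no variance shrinkage across
  counts, so low-count variants have noisy log2E.
- The interaction classifier is distance-threshold-only; it will not agree
  atom-for-atom with SIFT-style engines, and typed classes overlap (a pair
  can be both hydrogen and vdw).
- The combinatorial enumerator's count for a given pool transcription is
  exposed (`enumerate_combinations`), but published library sizes can only
  be checked once the exact per-pool mutation lists are supplied.
- Dose-response fits assume homoscedastic noise on the fitted scale.
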