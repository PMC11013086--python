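# Methods

This note documents the models, parameter choices, numerical details
and known limitations of each kincascade module, in the order data
flows through the pipeline.

## Sequence and annotation model (`core_io`)

Sequences are validated against explicit alphabets (20 amino acids plus
`X`, or `ACGTN`; `-` is tolerated so aligned FASTA round-trips through
the same type) and stored uppercase; trailing `*` stop symbols are
stripped with a logged note. Coordinates are GFF3-style 1-based
inclusive everywhere; any half-open arithmetic is confined to slicing
inside serialization helpers, which avoids off-by-one drift between
modules. Gene ranks — the ordinal position of each gene along its
chromosome, sorted by start with ties broken by gene id — are computed
once at annotation load and reused by both the tandem rule and the
collinearity chain detector. The unplaced bin `Un` is a legal
chromosome name but is excluded from rank-based tandem calling, since
ranks on an unordered bin are not positional evidence.

## Motif engine (`motifs`)

Patterns are token lists (literal, wildcard `x`, fixed gap `xN`,
alternation `(A/B)` with the bare-slash shorthand `G/A` normalized to
an alternation on the preceding literal). Scanning compiles tokens to a
regular expression inside a lookahead so overlapping occurrences are
all reported; `X` in a sequence matches no token, including wildcards.
An independent window-by-window oracle backs the scanner in tests.

Classification scans all six tier signatures and takes the matched
pattern with the most non-wildcard positions (specificity), with the
fixed tie order MAP4K > ZIK > MEKK > MAP2K > MAPK > RAF. This rule is
needed because the consensi nest: every MAP4K signature instance
contains a MEKK and a RAF match, which is surfaced (never silently
discarded) through `ambiguous_with`. A MAP4K call additionally requires
at least 2 of the 4 catalytic hallmarks, so members with a substituted
glycine-rich loop still classify as MAP4K while the audit flags them as
likely inactive — families routinely retain such members.

Audit details: the glycine-rich loop is the first `GxGxx(G/A/S)` match
and its status is the residue at the sixth position; the invariant
lysine is the first K 10–35 residues C-terminal of the loop end (the
window reflects canonical kinase subdomain I–II spacing and is a
parameter; without a loop anchor the lysine is reported absent); `HRD`
and `DFG` are literal triplets with DFG required C-terminal of HRD.
`predicted_active` demands the canonical loop plus all three catalytic
features. The catalytic motif is matched as `HRD` only; an `HRH`
variant spelling occasionally seen in survey tables is treated as
typographical and not matched.

## Protein properties (`properties`)

Molecular weight sums average (not monoisotopic) residue masses plus
one water, matching the convention of standard proteome property
tables; `math.fsum` keeps the sum permutation-invariant. The
isoelectric point is the root of the net-charge curve
Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)) under a
pinned EMBOSS-style pKa table (C-term 3.6, N-term 8.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); Q is strictly decreasing in pH,
so bisection on [0, 14] converges to the unique root (60 iterations,
well past the 1e-4 charge tolerance). The table is overridable to
approximate other predictors, which use slightly different pKa sets —
absolute pI values are therefore convention-dependent, while orderings
and monotonicity (adding K raises pI, adding D lowers it) are not.
GRAVY is the mean Kyte–Doolittle index; `X` residues are an error for
MW and GRAVY rather than a silent guess.

## Homology search (`homology`)

Member identification replaces external BLASTP/HMMER searches with
transparent in-repo equivalents: global Needleman–Wunsch alignment
(affine gaps; a gap of length L costs gap_open + L·gap_extend, defaults
10 + L·1; BLOSUM62) behind a shared-4-mer count prefilter, and a
position-specific log-odds profile (pseudocount-smoothed against a
uniform background) for profile scanning. The pairwise engine is
Biopython's `PairwiseAligner` configured to this scoring convention;
tests verify its scores against exhaustive enumeration of all
alignments on short pairs. Identity is computed over paired (gap-free)
columns and coverage as the paired fraction of each sequence;
candidates must meet both thresholds (defaults 0.4 identity, 0.5
coverage — explicit stand-ins, as surveys rarely publish their
cutoffs). Redundancy removal keeps the longest isoform per gene (ties
by transcript id); identical full-length sequences shared across genes
are retained but flagged, mirroring the manual de-duplication step of a
survey as an explicit, testable rule.

## Phylogeny (`phylogeny`)

Distances from a precomputed alignment: p-distance over columns where
neither pair member is gapped, or Poisson −ln(1−p) (the default, the
common protein-distance default of tree-building GUIs; the choice is a
parameter because surveys rarely state it). Neighbor joining is the
classic Saitou–Nei Q-criterion iteration with a deterministic smallest
(i,j) tie-break; negative limb estimates are clamped to zero (standard
practice) with the deficit logged. On additive matrices the output
metric reproduces the input exactly (tested to 1e-9), and at n = 5 the
NJ topology matches exhaustive least-squares over all 15 topologies.
Bootstrap resamples columns with replacement; the support of an
internal edge of the full-data tree is the percentage of replicate
trees containing the same bipartition; degenerate replicates (e.g. a
saturated pair) are skipped. The convenience multiple aligner is
center-star over the pairwise engine — adequate for the closely related
members it is used on, and documented as not equivalent to a
progressive aligner; tree inference accepts any external alignment.

## Ka/Ks and duplication typing (`kaks`)

NG86 as published: per-codon synonymous-site fractions enumerate the
nine single-nucleotide neighbors with stop-codon neighbors excluded
from the denominator; S and N are averaged over the two sequences (so
S + N = 3 × codons exactly); multi-difference codons are resolved by
averaging syn/nonsyn step counts over all minimal mutational pathways
that avoid stops, with equal path weights; if every ordering crosses a
stop (rare), all orderings are used as a fallback. Proportions are
corrected with Jukes–Cantor; Ks (or Ka) is undefined when p ≥ 3/4 and
ω is undefined when Ks = 0 — both reported as NaN with a reason flag,
never silently zeroed. pS ≥ 0.75 raises the saturation flag.
Divergence time is T = Ks/(2λ) reported in Mya, λ defaulting to
6.5×10⁻⁹ synonymous substitutions/site/year (the grass-clock constant).

Collinear blocks: anchors (homolog pairs mapped to gene ranks) are
chained per chromosome pair into maximal runs with strictly monotone
ranks on both chromosomes (increasing or decreasing for inverted
blocks) and consecutive rank gaps ≤ max_gap (default 10); chains are
peeled off longest-first (ties: increasing orientation, then the
lexicographically smallest index sequence), each anchor joining at most
one block, and chains shorter than min_block (default 3) are dropped.
Intra-chromosomal collinearity is out of scope — the tandem rule takes
precedence on one chromosome anyway. Duplication typing: tandem iff
same chromosome and rank difference ≤ tandem_gap + 1 (default gap 5
intervening genes); else segmental iff the pair anchors a block; else
dispersed. The three thresholds are explicit configuration because
published surveys use differing tool defaults; tests pin the shipped
values.

## Promoter census (`promoters`)

The promoter is the 1500 bp upstream of the annotated CDS start on the
gene's strand (minus-strand genes: downstream in chromosome
coordinates, reverse-complemented), truncated at the chromosome
boundary with a flag. Elements are IUPAC consensus strings from an
editable TSV catalog grouped into the four functional categories
(hormone, stress, development, other). The shipped catalog carries
literature-standard consensus strings under the PlantCARE element
vocabulary; it is data, not code, because the matrices behind web
scanners are not published — parity with any particular server is
explicitly not a goal, and tests rely on planted fixtures instead.
Occurrences are counted on both strands pooled, overlapping matches
included (deterministic and oracle-checkable); a palindromic site whose
forward and reverse matches coincide on the same interval counts once.
Counting match intervals as a set makes the census invariant under
reverse-complementing the promoter. The rollup reports both total
occurrences and the number of genes with ≥ 1 occurrence, since surveys
quote both statistics interchangeably.

## Expression and qPCR (`expression`)

Transform: log10(x+1) — the pseudocount handles the zeros real
expression matrices contain while preserving monotonicity and zero.
Clustering: rows are z-scored (constant rows set to 0), then
average-linkage agglomeration on Euclidean distance, cut into k groups.
DE calling: Welch's unequal-variance t-test on log2(x+1) replicate
values per condition against the designated control; direction requires
both p < alpha and |log2FC| ≥ the threshold (defaults 0.05 and 1.0 —
configuration, since "significant" is rarely quantified in survey
text). Welch is implemented from the textbook statistic with
Welch–Satterthwaite degrees of freedom (identical samples yield p = 1);
tests check it against an independent reference implementation to
1e-10. qPCR follows Livak: per-replicate ΔCt = Ct_target −
Ct_reference, ΔΔCt as the difference of mean ΔCt between condition and
control, RQ = 2^−ΔΔCt; the t-test runs on the per-replicate ΔCt values
and stars follow * p < 0.05, ** p < 0.01, *** p < 0.001. The control
against itself is exactly 1 by construction.

## Synthetic data (`synthetic`)

One global seed drives a named substream per generator
(`default_rng([seed, stream_id])`), so outputs are byte-identical for a
fixed seed while generators stay independent. Backgrounds are uniform
over 20 amino acids / 4 nucleotides — the simplest null; compositional
realism is irrelevant to correctness testing and deliberately not
modeled.

- **Proteome**: default tier counts follow the wheat kinase census
  composition (48 MAPK, 17 MAP2K, 27 MEKK, 107 RAF, 10 ZIK, 25 MAP4K)
  plus 200 decoys; lengths 300–600 aa. Each member is a signature
  instantiation planted in signature-free background (rejection
  sampled); MAP4K members carry the four hallmarks in N→C order with
  the invariant K placed inside its 10–35 window, and 76% of them get
  the third-G → A substitution (the fraction reported for wheat).
  Assembled sequences are re-validated (classification recovers the
  planted tier; the audit reads the planted hallmarks) and resampled
  otherwise, which turns stochastic fixtures into exact oracles.
- **Layout**: tandem arrays occupy consecutive ranks; block anchors are
  placed order-consistently with rank gaps ≤ 2 on chromosome pairs of
  their own; dispersed pairs go to chromosome pairs no block uses, at
  most two per pair of chromosomes so they can never chain into a
  block. Truth therefore matches the classifier exactly when the
  classifier runs at its default thresholds.
- **Codon pairs**: one stop-free ancestor per pair, two independent
  lineages, m proposal mutations each (default 90 over 300 codons,
  ≈ 10% per-lineage divergence — comfortably inside the Jukes–Cantor
  domain). Proposals creating stops are redrawn; synonymous proposals
  are accepted with probability min(1, 1/ω) and nonsynonymous with
  min(1, ω), so the realized Ka/Ks expectation tracks the target ω.
  Accepted syn/nonsyn counts are recorded as truth.
- **Promoters**: whole-sequence rejection sampling cannot terminate for
  5-nt elements (≈ 1.5 expected matches per strand per 1500 bp), so
  backgrounds are repaired iteratively — one base inside each residual
  match is randomized until no catalog match remains. Planted instances
  are placed non-overlapping, on either strand; the finished promoter
  is re-scanned and redrawn unless counts equal the design exactly
  (planting mutually reverse-complementary elements, e.g. CGTCA/TGACG
  together, is detected this way and rejected with a clear error).
- **Expression / Ct**: log-normal abundances with planted log2 effects
  and N(0, 0.25) replicate noise on the log2 scale; Ct tables satisfy
  E[ΔΔCt] = −log2(fold) with N(0, 0.2) replicate noise and a
  reference gene constant in expectation. Triplicates by default, as in
  standard qPCR practice.

## What passing tests do and do not show

The generators plant exactly the structure the analyses assume: uniform
background, exact motif instances, noise-free or Gaussian-noise
designs. Passing therefore demonstrates algorithmic correctness —
recovery of planted truth, agreement with brute-force oracles, exact
reproduction of closed-form examples — not performance on real
proteomes, where motif degeneracy beyond the shipped consensi,
composition bias, alternative splicing, and annotation errors all
matter. In particular, headline counts from any real genome survey
(family sizes, element totals, node ages) depend on the genome build
and external databases and are out of scope here.

## Problem sizes

Default test and acceptance runs use 434-protein proteomes (×20 seeds
for recovery), 200 codon pairs of 300 codons per ω setting, 100
eight-leaf trees plus the 15-topology exhaustive check at n = 5,
50 promoters of 1500 bp, ≤ 12-anchor instances for exhaustive synteny
comparison, and 50 null expression simulations of 100 genes — sizes at
which every exhaustive oracle is exact and the whole suite runs in
well under a minute per module on one core.
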