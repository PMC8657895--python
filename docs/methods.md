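# Methods

## Signature-site classification

A CAD family membership call requires the joint presence of the catalytic
Zn-binding, structural Zn-binding and NADP(H)-binding sites.  Each site
is a degenerate pattern of literal residues and fixed-length wildcard
runs; the parser treats `(X)n` as a run of exactly *n* positions (no
elasticity), a bare `X` or `(X)` as a run of one, and hyphens as
typographic.  Matching slides a window of the pattern's span across the
protein and counts mismatches at literal positions only; wildcard
positions accept anything, including the unknown residue `X`, while `X`
at a literal position always counts as a mismatch (a conservative
choice: an unsequenced residue is never taken as evidence for a site).

The per-site mismatch budget defaults to 2 and is configurable per site.
Family-definition conventions in the literature accept sites "with minor
mutations" without quantifying them; 2 mismatches per site keeps the
catalytic and structural sites (5 literals each) meaningfully
constrained while tolerating the kind of lineage-specific substitutions
observed in real families, some of which carry heavier NADP(H)-site
mutations — hence the budget is per-site, so a lenient NADP(H) budget
can be combined with strict Zn-site budgets.  The best match per site is
the one with the fewest mismatches, ties broken by the smallest start,
which makes classification a pure function of (sequence, patterns,
budgets).

## Neighbor joining and bootstrap

Distances come from pairwise deletion by default (per pair, only columns
where neither sequence is gapped are compared; complete deletion is an
option): p = mismatches / compared columns, and the Poisson correction
d = −ln(1 − p) is the default protein model, with plain p-distance
available.  p = 1 under the correction is a saturation error naming the
pair, and a pair with no shared ungapped columns is an error.

NJ follows the Saitou–Nei Q-criterion; the Q matrix is evaluated on the
upper triangle only (the two float evaluations of a symmetric entry can
differ in the last bit, so minimizing over one triangle both avoids a
spurious asymmetry and implements the documented tie-break: the
lowest-index pair among minimal entries is joined first).  Estimated
negative branch lengths are clamped to zero after estimation, which
preserves exactness on additive inputs.  The final three nodes are
joined at a trifurcation by the three-point formula, so the tree is
genuinely unrooted (internal vertices of degree 3).

The bootstrap resamples alignment columns with replacement, recomputes
distances and the NJ tree, and tallies the non-trivial bipartitions of
the full-data tree; support is the percentage of successful replicates
containing each bipartition, mapped onto the full-data tree (not a
consensus tree).  Replicates whose resampled distances are saturated or
undefined are skipped and counted; more than 50% skipped aborts the run.
Only the distance-based NJ chain is implemented: it is fully specified,
deterministic given a seed, and testable against exact oracles
(additivity, and exhaustive least-squares topology enumeration for
n ≤ 6), which a likelihood tree search is not at this scale.

## Promoter scanning

Elements are IUPAC consensus strings scanned for exact degenerate
matches on the forward strand and (by default) the reverse complement,
with minus-strand hits reported at forward coordinates (1-based,
inclusive) of the supplied promoter.  An `N` in the sequence matches
only an `N` in the consensus — an unsequenced base is never evidence for
an element.  Overlapping matches are all reported and all counted; no
merging, since any merging convention would be arbitrary.  The shipped
consensus table (ABRE = ACGTG, CGTCA-motif = CGTCA, GARE-motif =
TCTGTTG, LTR = CCGAAA, MBS = CAACTG, MRE = AACCTAA, MYB = CAACAG,
P-box = CCTTTTG, TCA-element = CCATCTTTTT, TCT-motif = TCTTAC,
TGACG-motif = TGACG) is PlantCARE-derived **default configuration**, not
a fixed fact: the scanner takes any {name, consensus, note} table.

## Expression filtering and stress calls

The tissue-expression filter keeps genes with ≥ `min_fpkm` (0.05) in at
least `min_samples` samples; "more than six of 26 tissues" is read
literally as ≥ 7 and both numbers are configurable.  The heatmap
transform is log2(FPKM + 1); the +1 offset keeps zeros at zero and is
the usual choice when the transform's offset is not otherwise pinned
down.

Fold change is fc = (treated + ε)/(control + ε) with pseudocount
ε = 0.1 FPKM by default, computed after averaging replicates
(arithmetic mean FPKM).  The pseudocount exists for the zero-control
case — an induced gene silent in control must yield a finite, large,
reportable ratio — and 0.1 is small against typical expressed-gene FPKM
while keeping ratios bounded by ~10·treated.  Calls are two-fold by
default: up if fc ≥ 2, down if fc ≤ 0.5.  Genes whose maximum FPKM over
all samples is below 1 are flagged as too weakly expressed and receive
no call; the value 1 FPKM is a design choice for an otherwise
unquantified "too low for analysis" convention.

## Co-expression network

Pearson correlation is computed over full profiles (no missing data);
zero-variance genes are skipped with a warning rather than failing the
run.  Thresholds are **inclusive**: r ≥ 0.7 positive, r ≤ −0.5 negative.
The two conventions in circulation (strict `> 0.7 / < −0.5` vs the range
statement "0.7 to 1 and −0.5 to −1") differ only on exact boundary
values, which have measure zero on real data; the inclusive reading is
the default and both thresholds are configurable.  No p-values or
multiple-testing corrections are applied — the network is a raw-PCC
threshold construct, and edges are reported with their r for downstream
filtering.  Either all unordered pairs or seed-gene × universe pairs are
evaluated; both modes exist because family studies are run both ways.

## Synthetic data: what it does and does not emulate

The generators produce the *shape* of the study inputs with exact
ground truth:

- **Protein families** — random 20-letter backbones (default 360 aa,
  roughly CAD length) with the three sites planted in separate thirds of
  the sequence, each with 0–2 random literal mutations.  Decoys omit at
  least one site; because a ≤2-mismatch window for a 5-literal site
  arises in a random 360-aa background with probability ≈ 0.3, the
  generator rescans each decoy for its omitted sites and redraws until
  clean, so ledger labels are exact.
- **Alignments** — i.i.d. columns evolved along a known tree; on a
  branch of length b each site experiences a substitution event with
  probability 1 − e^(−b), redrawing the residue uniformly over all 20
  (an event is silent 1/20 of the time; an infinitely long branch
  leaves an expected 19/20 of sites changed).  This is a deliberately
  minimal Poisson-style contract — no empirical substitution matrix, no
  rate heterogeneity, no indels — sufficient for testing NJ recovery.
- **Expression matrices** — 26 samples; module genes share a latent
  factor, z_g = √ρ·F + √(1−ρ)·ε_g, so within-module latent correlation
  is exactly ρ; FPKM = exp(1 + 0.5·z) is non-negative and right-skewed.
  The exponentiation attenuates correlations slightly, so the 0.9
  target is asserted within ±0.05 on the FPKM scale over seeds.
- **Stress tables** — per-gene base levels ≈ 10 FPKM, multiplicative
  log-normal replicate noise (σ = 0.05), planted fold changes applied to
  the treatment groups; low-expression genes sit below 1 FPKM.
- **Promoters** — uniform-random 2 kb background with concrete
  realizations of element consensi planted at recorded positions and
  strands.

None of these reproduce real biology: no codon structure, no domain
architecture beyond the planted sites, no tissue-specific expression
programs, no promoter GC structure.  Passing tests therefore demonstrate
the *algorithms* are correct against known ground truth, not that any
biological conclusion would be recovered from real data.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline splits a single top-level seed per stage via `SeedSequence`
  (seeds kept below 2³¹).  Reruns with the same config are
  byte-identical; the manifest records parameters and derived seeds.
- NJ additive-case exactness is asserted at 1e-9; Pearson against the
  direct two-pass formula at 1e-12; Newick branch lengths round-trip at
  1e-9 (12 significant digits written).
- Degenerate inputs: equidistant matrices resolve by the lowest-index
  tie-break with a zero-length internal edge; proteins shorter than a
  pattern span simply have no windows; an empty FASTA classifies to an
  empty table; an all-gene-removing filter warns rather than errors.
- Problem sizes in tests and the acceptance script (20-seed classifier
  sweeps, 200 additive matrices up to 8 taxa, 200 bootstrap replicates
  on 500-column alignments, 100-seed module-recovery runs) are chosen so
  the full suite completes in seconds while keeping every estimate's
  sampling error far from its pass boundary.

## Known limitations

- No maximum-likelihood tree search, no alignment construction, no
  motif *discovery* — inputs must be pre-aligned, and the site patterns
  are given, not learned.
- The promoter scanner reports exact consensus matches only; no PWM
  scoring, no p-values.
- Stress calls are plain fold-change thresholds with no replicate-aware
  statistics; that is the method being reimplemented, not a
  recommendation.
- FPKM is taken as given; no normalization or batch handling.
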