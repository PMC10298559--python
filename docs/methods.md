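# Methods

`tehorizon` implements a comparative analysis of transposable-element
(TE) dynamics across a set of species with a time-calibrated phylogeny:
dating TE activity from copy divergence, relating TE load to genome
size, measuring the phylogenetic signal of TE load and reconstructing
its ancestral values, and detecting horizontal TE transfer (HTT) from
synonymous-rate anomalies. This note records the models, the parameters
that matter, and the design choices made where the procedure was
genuinely open.

## Copy-divergence dating

Each annotated TE copy carries a nucleotide divergence from its
subfamily consensus. Divergences computed from sequence use Kimura's
two-parameter distance,

    K = -(1/2) ln[(1 - 2P - Q) sqrt(1 - 2Q)],

with P and Q the transition and transversion proportions over aligned
ACGT columns (gaps and ambiguity codes excluded — standard practice).
Under a neutral clock with rate `r` substitutions/site/generation and
`g` generations per year, divergence converts to an insertion age

    T = K / (2 r g),

the factor 2 reflecting that divergence accrues on both the copy's and
the master lineage's path. Defaults: `r = 2.9e-9` (a lepidopteran
estimate), `g = 1`. With these values K = 0.10 maps to 17.24 My.

Repeat landscapes bin annotated bases (and copy counts — both are
emitted since either convention is used in practice) by divergence in
half-open bins `[lo, hi)` of width 0.01, with an age axis obtained by
converting bin midpoints; midpoints are a choice — the conversion is
linear, so any within-bin convention shifts ages by at most half a bin.
When both copy and consensus sequences are available the K2P distance
to the consensus overrides the annotation's divergence column, keeping
the pipeline reproducible from self-contained inputs.

## dS estimation

HTT detection rests on synonymous substitutions per synonymous site
(dS), estimated by Nei–Gojobori (1986) counting with a Jukes–Cantor
correction:

* per-codon synonymous-site fractions, averaged over the two sequences
  (S + N = 3 × compared codons, an enforced invariant);
* observed differences resolved by averaging over all minimal
  mutational pathways (all orderings of the differing positions);
* mutations creating stop codons counted as nonsynonymous (one of the
  standard NG86 conventions; fixed and documented here);
* `dS = -(3/4) ln(1 - (4/3) pS)`, undefined (flagged saturated) at
  `pS >= 3/4`.

NG86 was chosen over ML codon models because the downstream test uses
dS only through ranks and quantiles, which are insensitive to the
multiple-hit model; the estimator entry point is pluggable. Alignment
length filters are strict: TE pairs must exceed 300 aligned
nucleotides, ortholog pairs 300 aligned amino acids. Ortholog pairing
takes reciprocal best hits that share a single-copy-ortholog
identifier, with bitscore ties broken lexicographically for
determinism.

## HTT calling

For each species pair, the null for vertical inheritance is the
empirical distribution of ortholog dS. A cross-species TE pair is
called a transfer when its dS is *strictly below* the q-quantile
(default q = 0.025) of that pair's ortholog dS, computed with linear
interpolation on `(n-1)q` — the quantile convention is fixed because
"2.5%" alone does not pin down an order statistic. SINE pairs are
excluded (no protein, no dS). Pairs with fewer than 40 finite ortholog
dS values fall back, with a warning, to the threshold pooled over all
pairs; a flag forces pooled thresholds everywhere.

## Lineages and minimal events

A transfer predating a radiation leaves similar copies in every
descendant, so raw hits overcount events. Species are collapsed
bottom-up into lineages: a clade becomes one lineage when every
cross-pair inside it has more than 0.3% of ortholog dS below the
highest within-genome TE nucleotide divergence, or the clade is younger
than 40 My. "Highest nucleotide divergence of TEs" is ambiguous in the
procedure this reconstructs; it is an explicit parameter, defaulting to
the maximum pairwise K2P divergence among same-subfamily copies within
one genome — the ceiling of what vertical inheritance can look like.

Within-lineage hits are discarded. Remaining hits form a graph: two
hits are connected when they join the same unordered lineage pair,
involve the same subfamily, and on each side the copies' K2P divergence
is below `2 r T_split`, with `T_split` the divergence time of the two
lineages — a single transfer between two lineages must postdate their
split, so copies descending from one event cannot be more diverged than
that. (A per-lineage crown-age ceiling was considered and rejected: it
assigns singleton lineages a ceiling of zero, which forbids clustering
any hits that share a singleton donor and defeats the minimal-event
semantics.) Connected components are the minimal events. Unavailable
copy-pair divergences create no edge, which errs toward more events.
The per-subfamily summary reports transfers per thousand copies
(two decimals; scientific notation below 0.01) with class subtotals.

## Phylogenetic comparative methods

TE load (percent of genome, per class or total) is treated as a
continuous trait on an ultrametric timetree, multivariate normal with
mean `z0·1` and covariance per model:

* **BM** `sigma2·C`, `C` = shared root-to-MRCA path lengths;
* **lambda** off-diagonals of C scaled by λ, searched on
  `[0, height / deepest-internal-node-depth]` (so λ̂ can exceed 1);
  p-value from the likelihood ratio against λ = 0 (χ², 1 df);
* **OU** `V_ij = sigma2/(2α) e^(-2α d_ij)(1 - e^(-2α t_ij))`;
* **EB** rate decaying as `e^(a s)` from the root (`a ≤ 0`), i.e.
  `V_ij = sigma2 (e^(a t_ij) - 1)/a`, BM in the limit `a → 0`;
* **WN** `sigma2·I`.

`sigma2` and `z0` are always profiled analytically by GLS; only the one
shape parameter is optimised numerically (bounded L-BFGS-B, five fixed
starts plus the bounds, tolerance 1e-8 — determinism over speed).
Model choice uses AICc, `-2 logL + 2k + 2k(k+1)/(n-k-1)` (k = 2 for
BM/WN, 3 for OU/EB; NaN when `n ≤ k+1`).

Blomberg's K uses the phylogenetically corrected mean and the analytic
BM expectation of MSE0/MSE; its p-value is a seeded tip-permutation
test (default 1000 permutations, the reference implementation's
default). On a star tree λ has no effect on the likelihood; the result
is returned with a `degenerate` flag rather than a spurious estimate.
Both statistics were verified to reproduce the reference R
implementation (phytools) to at least four decimals on a fixed
tree/trait.

Ancestral states under BM (or EB after rescaling shared times by the
fitted exponent) are the GLS conditional means given the tips with the
root at its GLS estimate — equivalent to joint ML over internal states,
which the tests confirm against direct numerical maximisation. Branch
direction calls compare child to parent state; exact ties (within 1e-12
of the trait range) are labelled `no_change` rather than forced into
expansion/reduction.

Trees may contain rooted polytomies (a star tree is a legal input);
single-child roots, missing branch lengths, and trees whose tip depths
differ by more than 1e-6 × height are rejected.

## Synthetic data: what it emulates, and what it does not

The generator produces a complete dataset — timetree, RepeatMasker-style
annotations with copy sequences, consensus sequences, codon-aligned
ortholog pairs, TE coding pairs, genome table — from an explicit
genealogy, so every estimate can be checked against its generating
truth. Key choices:

* **Two clocks, one rate.** TE genomic sequences evolve under K2P with
  transition/transversion ratio 2 at rate `r` per site per year.
  Synonymous (third) positions of coding sequences — built from the six
  fourfold-degenerate codon families — substitute uniformly over the
  three alternatives, so the NG86+JC dS estimator is *exactly*
  calibrated to the generating clock and dS truth is exact
  (`E[dS] = 2 r T` for a divergence time `T`). Mixing a ts/tv-biased
  model into the synonymous clock would bias the JC correction by a few
  percent and blur truth-based tests without adding realism that
  matters here.
* **Copies branch off the species lineage.** A copy with insertion age
  `a` in species `s` branches the root-to-`s` ortholog-style lineage at
  `a` My and evolves independently to the present, so cross-species
  vertical TE pairs have dS distributed exactly like orthologs — the
  property the false-positive calibration of the HTT test rests on.
  Genomically, the copy diverges from the consensus by `2 r a`
  (landscape dating recovers burst ages).
* **Transfers.** An HTT event at age `t` branches the donor lineage at
  `t`; deposited copies (optionally in several descendants of a common
  recipient ancestor) diverge from each other and from the transferred
  master only since `t`.
* Insertion ages are Gaussian bursts (configurable means, sd 1 My
  default) truncated to `[0, tree height]`.
* The genome table derives sizes as simulated TE bases plus a constant
  200 Mb non-TE baseline, making the TE-load/genome-size correlation
  positive by construction.
* Same seed ⇒ byte-identical files.

Not emulated: indels and alignment error, nested or fragmented
insertions, assembly artifacts, rate variation among sites or lineages,
selection on TEs, and misclassification between subfamilies. Passing
tests therefore demonstrate the statistical machinery is correct under
the stated model, not that real annotations are free of those
complications.

## Problem sizes

The recovery studies run at sizes chosen to make sampling noise small
relative to the tested effects: HTT calibration uses 2000 vertical TE
pairs against 2000 ortholog genes of 301 codons across a 60-My split
(the binomial 95% band around q = 2.5% is then ±0.68 points); recall
uses five transfers at 2 My; clustering scenarios use 60-gene
ortholog sets; comparative recovery uses a 64-tip, 100-My tree with
200 Brownian replicates for λ and K and 100 Early-Burst replicates
(`a = -0.05/My`) for model selection. `scripts/acceptance.py` recomputes
all of these from scratch at the same sizes.

## Known limitations

* dS saturates near `pS = 3/4`; deep species pairs can lose ortholog
  pairs to saturation, thinning the null. Thresholds then fall back to
  pooled quantiles.
* The minimal-event count is a heuristic lower bound: independent
  transfers of one subfamily between the same lineage pair merge
  whenever the involved copies happen to fall under the vertical
  ceiling.
* `fitContinuous`-style OU fitting on ultrametric trees cannot separate
  `z0` from the optimum; the implementation reports the stationary
  single-optimum parameterisation.
* The RepeatMasker parser treats each `.out` row as one copy; defragment
  upstream if fragment merging is required (the ≥80%-of-consensus
  length filter is what downstream analyses condition on).
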