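# Methods

This note records the models, conventions and numerical choices behind
`parasym`, including the places where the design was genuinely open and
the package had to commit to one reading.

## The trio model

Every analysis unit is a trio: two gene duplicates (`copy1`, `copy2`) of
identical age — the whole-genome-duplication setting — plus a distant
ortholog (`outgroup`) on an unrooted three-leaf tree with a single
internal node, the duplication node. All rates and counts are per branch,
measured from that node.

Alignments are in-frame codon alignments over `{A,C,G,T,N,-}`. Any codon
column containing a gap, an `N`, or a (terminal) stop codon in any of the
three sequences is masked from all counting and likelihood computation.
This is the conservative choice; the alternative (per-sequence masking)
would let site denominators differ between branches. Domain coordinates
are 1-based inclusive amino-acid positions on the aligned protein
(codon column *k* ↔ amino acid *k*), so a domain table computed on the
aligned duplicates applies to all three sequences when their architectures
are identical — which is exactly the admission criterion.

## Counting engine

* **Ancestral inference.** Majority-rule parsimony per codon column with
  outgroup tie-break: the duplication-node codon is the one shared by at
  least two sequences; when all three differ, the outgroup codon is used
  and the column flagged ambiguous. On a three-leaf star this is the
  Fitch solution; a full ML reconstruction is deliberately out of scope.
* **NG86 sites.** Per codon position, the synonymous fraction of the
  non-stop single-nucleotide changes; each position contributes exactly
  one site, so S_sites + N_sites = 3 per codon. Site totals per branch
  average the ancestral and descendant sequences (symmetric convention).
* **NG86 substitutions.** For a codon pair differing at *d* positions,
  all *d*! shortest mutational pathways are enumerated; pathways crossing
  a stop codon are excluded and the synonymous/non-synonymous step
  classification is averaged over the rest with uniform weights. In the
  standard code every sense-codon pair has at least one stop-free
  pathway; the fallback (flagged averaging over non-stop steps) never
  fires in practice.
* **Rates.** dN and dS apply the Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3) to the proportions N/N_sites and S/S_sites;
  p ≥ 3/4 is reported as saturated (NaN + flag) rather than silently
  clipped. ω = dN/dS is undefined when dS = 0 or either rate saturated.
* **Admission filter.** Pairs enter the asymmetry analyses only when
  0.2 ≤ dS ≤ 2 on both duplicate branches (large enough to be
  informative, small enough to avoid saturation) and, where domain tables
  are supplied, when the ordered domain-name sequences of both copies and
  the outgroup agree.

Known estimator properties, measured with the package's own simulator:
NG86 ignores the transition/transversion bias, so at κ = 2 the engine
shows a systematic ≈ −11 % bias at ω = 1 and a small upward bias at low
ω; on an equal-branch star at 10,000 codons all of ω ∈ {0.2, 0.5, 1.0}
are recovered within ±20 %. With a *near-saturated* outgroup branch the
parsimony ancestor degrades — misattributed changes inflate both
duplicate branches symmetrically. This keeps the null FET calibrated but
costs power; see "Scenario geometry" below.

## Fisher-exact asymmetry testing

The 2×2 table contrasts (N, S) between the duplicate branches. Four
levels share one construction: non-synonymous counts from the region of
interest (whole protein / union of domains / one domain / non-domain
complement), synonymous counts from the whole protein. The whole-protein
synonymous background is the primary reading of the method; for the
combined-domain analysis a `cda_background="region"` switch restricts
the background to the region as well. Fractional counts are rounded
half-away-from-zero before testing. The two-sided exact p-value follows
the point-probability rule (sum of hypergeometric probabilities of all
tables with fixed margins no more probable than the observed table);
`scipy.stats.fisher_exact` provides the computation and the test suite
pins it against an exhaustive enumeration oracle for all margins ≤ 12.

Benjamini–Hochberg FDR (default 10 %) is applied across the units of one
level within one run (per batch — per-species pooling is just multiple
batches). The faster-evolving copy is the branch with the larger
add-one-smoothed odds N/(S+1); exact ties are reported as `tie`.

Robustness companions: a codon bootstrap (columns resampled with
replacement, FET repeated, support = fraction of significant replicates)
and a length-matched control that re-runs the whole-protein FET on random
column subsets of a given length to quantify how much of the domain-level
power loss is simply shorter alignments.

## GY94 likelihood engine

The branch model uses the Goldman–Yang rate matrix: single-nucleotide
changes at rate π_j, multiplied by κ for transitions and by the branch's
ω for non-synonymous changes; each branch generator is rescaled to unit
mean rate so branch lengths are expected substitutions per codon. Codon
frequencies are F3x4 estimated from the trio (floored at 1e-6 and
renormalized); κ is shared across branches. The likelihood is Felsenstein
pruning rooted at the internal node with site-pattern compression, and
transition matrices come from the symmetric eigendecomposition that
reversibility permits (the simulator uses the same matrices — one source
of truth).

Fitting maximizes over {log κ, three log branch lengths, log ω's} with
L-BFGS-B (bounds e^±, lnL tolerance 1e-6). The free model has three ω's;
the constrained model ties ω1 = ω2 and leaves the outgroup ω free in both
— with only three branches this is the consistent reading of "other
branches vary freely". The first start is a counting-based guess where
branch lengths come from *pairwise* NG86 distances split by the
three-point formula (per-branch parsimony counts grossly underestimate a
long outgroup branch and strand the optimizer); optional extra starts
perturb it with seeded log-normal noise (default 3). The LRT convenience
wrapper additionally restarts the free model from the constrained
optimum, guaranteeing lnL_free ≥ lnL_constrained up to tolerance. The
statistic 2·|ln L1 − ln L2| is referred to χ²(1); over 200 null
simulations at 300 codons the rejection rate at α = 0.05 is 2.5 % —
slightly conservative, inside the 5 % ± 3 % calibration band.

## Downstream pattern statistics

* **Clustering.** Per copy and domain, one-sided FET of
  [[N_dom, S_dom], [N_other, S_other]] for enrichment of non-synonymous
  changes in the domain; `clustered` requires p ≤ α (default 0.05, the
  exposed `cluster_alpha`) *and* a larger smoothed N/S odds than the
  remainder. Proteins need ≥ 2 domains.
* **Assortment.** The null assigns the observed total number of
  asymmetric domains uniformly over all domain slots, preserving
  per-protein domain counts. The expected number of proteins with exactly
  one asymmetric domain has a hypergeometric closed form (used directly);
  the p-value is a seeded permutation upper tail with the +1
  small-sample correction.
* **Family frequency.** Per domain family, hypergeometric
  over/under-representation of asymmetry calls against the pooled rate.
  The original study's printed under-representation p for the homeobox
  family could not be reconstructed from its description; the
  hypergeometric construction here is documented and self-consistent
  rather than matched to that value.
* **Runs test.** Copy-specific substitution positions (amino-acid changes
  relative to the inferred ancestor unique to one copy) ordered along the
  protein give a two-symbol sequence; too few runs indicates contiguous,
  non-interleaved divergence. Exact conditional distribution for n ≤ 20,
  normal approximation with continuity correction above; per-gene
  p-values combine via Stouffer's method. The aggregation used by the
  original supplementary analysis is not visible; Stouffer is this
  package's declared choice.

## Divergence scores and expression overlap

Inter-copy amino-acid differences within a domain are scored with the
canonical BLOSUM62 matrix (biopython's copy; gap/ambiguous positions
excluded; identical domains have no defined score). Group comparisons are
one-sided rank-sum tests (exact for combined n ≤ 20, tie-corrected normal
otherwise). The percentile-matched control samples, for each asymmetric
domain, one symmetric domain whose pooled-percentile rank lies within a
10-point window (uniformly among candidates, seeded); unmatched domains
are dropped with a warning and counted. Scores are averaged per domain by
default — whether to pool all substitutions per group instead is exposed
by simply passing per-substitution scores to the comparison function.

Expression overlap is the Jaccard index of anatomy-term sets per
developmental stage present in both profiles; stages annotated with the
sentinel term `"whole organism"` in either gene are excluded as
ubiquitous (no ontology reasoning). Stage-level values enter the group
comparison unaggregated.

## Simulator and scenario geometry

Sequences evolve from a root drawn from π (uniform over the 61 sense
codons by default) independently along the three branches, segment-wise
where per-domain ω overrides apply. Reproducibility is bit-for-bit given
(scenario, seed); a goodness-of-fit test checks simulated single-branch
codon transitions against the matrix exponential.

Default null scenario (the false-positive calibration): ω = 1 on all
branches, κ = 2, duplicate branch lengths 0.45 substitutions/codon and
outgroup branch 6.0. These were calibrated once, against the package's
own counting engine, so that each duplicate branch measures dS ≈ 0.6
(comfortably inside the admission window) and the duplicate-to-outgroup
pairwise dS ≈ 2, reproducing the regime of a teleost duplicate pair with
a mouse outgroup whose synonymous distance is near saturation. Under this
null, 500 replicates of 2,000 codons yield a raw FET rejection rate
below 5 % and a post-FDR flagged fraction of 0 %.

Power and pattern scenarios (domain-specific detection, clustering,
faster-copy concordance) use shorter outgroups — typically 2× the
duplicate branches, up to the 4× boundary — because the parsimony
ancestor under a near-saturated outgroup adds symmetric noise that
dilutes regional signal. This is also why, in this implementation, the
likelihood-ratio test is *not* less sensitive than the FET: the original
analysis fed the FET with codeml's ML branch counts, whereas here the FET
consumes parsimony counts. The side-by-side comparison (engine `both`)
remains available; on asymmetric simulations at a 4× outgroup the LRT
flags slightly more pairs than the FET.

Expression simulation draws, per stage, a shared-term count k solving
J = k/(2n − k) for the target Jaccard J (randomized between floor and
ceil so the expectation is exact) and fills the remainder with disjoint
terms from a large vocabulary.

## Problem sizes and limitations

The test suite runs the full stack at desk scale: 500 × 2,000-codon null
replicates for FET calibration, 200 × 300-codon null fits for LRT
calibration, 50 × 10,000-codon trios per ω for parameter recovery, and
seeded qualitative scenarios for the domain-level patterns (a few minutes
in total on one CPU). Known limitations: no among-site rate variation, no
indels (simulated alignments are gap-free), standard genetic code only,
no codon-frequency-weighted site counting, parsimony (not ML) ancestors —
so absolute rate estimates on deep outgroups inherit the biases described
above, and passing tests demonstrate correctness of the machinery under
the simulator's assumptions, not robustness to alignment error or rate
heterogeneity in real data.
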