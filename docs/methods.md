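# Methods

This note records the models, conventions and design choices behind
`efp-loopscape`, in the spirit of the methods documentation of packages
like msprime or statsmodels: what is computed, under which assumptions,
with which defaults, and what the synthetic benchmark does and does not
demonstrate.

## The biological question

Bacterial elongation factor P (EF-P) rescues ribosomes stalled on
consecutive prolines. Its activity requires a post-translational
modification of the residue at the tip of the β3Ωβ4 loop — the seven-residue
apical loop of the KOW-like N-domain, residues 31–37 in *E. coli*
numbering. Two positions of this window carry the signal the package
analyses: the tip (position 34; lysine in lysine-type EF-Ps, modified by the
EpmA/EpmC β-lysylation pathway; arginine in arginine-type EF-Ps, modified by
the EarP rhamnosyltransferase) and the −2 position (position 32), which is a
near-invariant proline in lysine-type loops and selected against in
arginine-type ones. The pipeline quantifies this co-occurrence across a
genome collection and asks, by ancestral state reconstruction, which state
is ancestral.

## Curation

EF-P candidates are proteins whose set of *significant domain types*
(per-domain independent E-value ≤ 0.001 in the HMMER dialect) equals exactly
{EFP_N, EFP, Elong-fact-P_C}: a missing domain or any extra significant
domain rejects the protein; repeated hits of one type collapse to the type.
Two readings of the E-value threshold are possible for HMMER output
(full-sequence vs per-domain); the stricter per-domain independent E-value
is used. YeiP paralogs share the three-domain architecture and are removed
by annotation matching (case-insensitive token "yeip" or the phrase
"elongation factor P-like"); no remote database lookup is performed, so the
records must carry their annotations. Modification enzymes are detected per
genome as proteins with exactly one significant domain type equal to
`tRNA-synt_2` (EpmA), `EpmC`, `EarP` or `DS` (DHS-like); a multi-domain
protein containing `tRNA-synt_2` (e.g. a full aspartyl-tRNA synthetase) is
deliberately *not* counted.

All curation operations are order-independent and pure: permuting input
rows never changes any output.

## Loop extraction

The window is defined on a reference sequence (default: the *E. coli* EF-P
N-domain, 65 residues, window `KPGKGQA` at 31–37; any reference can be
supplied). Coordinates are 1-based and inclusive everywhere at the API
surface; conversion to internal 0-based indices happens at the boundary.
Reference residues 31–37 are counted over non-gap reference characters of
the alignment; the query characters at those columns form the loop. A query
gap in any window column, or a query-only insertion column strictly inside
the window, rejects the sequence with reason `gap-in-window` — the automated
analogue of manually deleting sequences that break the 7-column homology.
Insertions at the window boundary do not reject.

When no MSA is supplied, each query is aligned to the reference by optimal
global alignment with affine gaps (Needleman–Wunsch/Gotoh as implemented by
Biopython's `PairwiseAligner`). Defaults are the standard protein settings
BLOSUM62, gap open 11, gap extend 1, with a gap of length L costing
`open + (L−1)·extend`; residues outside the matrix alphabet score as X.
Scores are the exact DP optimum (checked against an independent
brute-force affine-gap recursion); among co-optimal tracebacks the aligner's
deterministic canonical alignment is reported.

## Conservation statistics

Per-column frequencies are empirical categorical distributions over the 20
amino acids. Logos use the Schneider–Stephens information-content
convention: `IC = log₂(20) − H(column)` bits, letter height
`frequency × IC`, with the optional small-sample correction
`e(n) = 19/(2·ln2·n)` (off by default — subset sizes in this application are
in the hundreds, where the correction is ≤ 0.02 bits; enabling it floors IC
at 0). Bits is used because it is the community default for protein logos.

Co-occurrence tables report, per tip residue / loop type / enzyme flag, the
group count and the percentage of loops with proline at −2 (plus, when
annotations are available, the percentage of genomes carrying each enzyme).
Percentages are reported half-up rounded to 2 decimals; unrounded values are
retained for computation and testing. Count-weighted pooling of subset
frequency matrices reproduces the global matrix exactly.

## Tree handling and the Mk model

Trees are dendropy objects; Newick round trips preserve topology, branch
lengths, leaf labels and internal support labels. Midpoint rooting places
the root halfway along the longest leaf-to-leaf path (computed by a
single-pass post-order scan); among equally long paths the lexicographically
smallest leaf pair is chosen, and a midpoint falling exactly on a node makes
that node the root. The implementation is fully deterministic — identical
input bytes give identical output bytes. Ultrametric conversion levels all
root-to-leaf depths to the input maximum by top-down proportional rescaling:
each child path is stretched by `allotted/path-length`, recursively; the
defining contract is equal depths with unchanged topology, not equivalence
to any particular external tool.

The Mk model is a k-state continuous-time Markov chain with equal-rates
(ER), symmetric (SYM) or all-rates-different (ARD) parameterisation.
Transition matrices use the ER closed form
`P_ii = 1/k + (k−1)/k·e^{−kμt}`, an eigendecomposition for SYM, and
`scipy.linalg.expm` for ARD; zero-length branches get the identity (no
pseudo-lengthening). Likelihoods are computed by Felsenstein pruning with
per-node max-rescaling to prevent underflow; missing tips (`"?"`)
contribute all-ones partials. Marginal posteriors combine the pruning
partials with outside probabilities from a pre-order down-pass; every
posterior vector is normalized to 1 and leaf posteriors are point masses on
the observations.

Rate fitting for ER is bounded scalar optimization on μ ∈ [1e−8, 1e3]
performed in log-rate space: a 41-point log-grid scan brackets the optimum
before Brent refinement (tolerance 1e−9). The grid stage matters because
the negative log-likelihood is flat over the high-rate plateau and an
unbracketed bounded search can stall there. SYM/ARD use L-BFGS-B in
log-rate space from a deterministic all-rates-1 start. The default
reconstruction is ER with a uniform root prior — the documented default of
the standard `ace`-style reconstruction functions; this is an assumption,
not an inference, and both the form and the prior are configurable. The
position-32 character is recoded to binary P / not-P; the position-34
character uses the six-residue alphabet (K, R, A, M, N, Q) with other tips
treated as missing rather than pooled.

## The synthetic generator

The generator emulates the statistical structure of a curated EF-P dataset
so that every stage has a testable ground truth:

* **Tree**: pure-birth (Yule) process conditioned on n tips, one extra
  waiting time after the n-th tip, so the expected root height is
  `Σ_{k=2..n} 1/(k·λ)`.
* **Characters**: one joint Markov chain on the product space
  (tip residue) × (P / not-P) — a joint chain rather than two independent
  ones because the co-occurrence of the two positions is the object under
  study, and the product-space rates let tests dial the coupling directly.
  The tip evolves F81-style with stationary frequencies set to the
  published composition of the curated family (81.11 % K, 14.75 % R,
  0.51 % A, 0.77 % M, 2.23 % N, 0.6 % Q); conditional on the tip, the −2
  position relaxes toward Bernoulli(p(tip)) with the published conditionals
  (K 98.73 %, R 2.33 %, A and N 100 %, M and Q 0 %). The default relaxation
  rate (20 events/unit time vs tip rate 0.7) makes leaf-level −2 states
  nearly conditionally independent given the tips, so the observed
  co-occurrence tracks the configured conditional to binomial accuracy.
  Residual relaxation lag after recent tip substitutions biases rare-tip
  conditionals by a few percentage points (visible as an R-row P32 share a
  few points above its configured 2.33 %); this is a property of the joint
  chain, not an estimator error.
* **Sequences**: a fixed 65-residue backbone (the *E. coli* EF-P N-domain)
  carrying a 7-mer emitted from per-state profiles (default: point mass on
  the lysine-type consensus `KPGKGQA` or the homologous arginine-type
  window `KSGRNSA`, with tip and −2 forced to the character state); backbone
  positions outside the window mutate at `backbone_noise_rate`
  (default 0.02). The family-level within-type loop variability is not
  characterized in the literature beyond logos, so profile sharpness is a
  free parameter.
* **Decoys**: YeiP paralogs (three-domain architecture, YeiP annotation)
  and wrong-architecture proteins (one domain dropped or one significant
  extra domain), `decoy_fraction` (default 0.2) of the genome count; true
  domain hits draw E-values log-uniform on [1e−60, 1e−10], sub-threshold
  distractor hits on [1e−2, 1].
* **Enzymes**: EpmA is emitted for K-tip genomes and EarP for R-tip
  genomes, each flipped with probability `enzyme_leak` (default 0.02 — the
  two systems are observed to be mutually exclusive with few exceptions);
  EpmC accompanies EpmA with probability 0.4 and a DHS-like protein appears
  in 10 % of K/N genomes, echoing the relative enzyme counts reported for
  the family.

One root seed drives everything; per-stage child streams are derived
deterministically so stages can be re-run independently, and identical
configurations produce byte-identical FASTA/TSV/Newick outputs.

What passing the synthetic benchmark shows: the filters implement their
definitions exactly (planted-set recovery is exact when decoy annotations
are noiseless), the statistics recover configured couplings to binomial
accuracy, and the reconstruction machinery is consistent (oracle-exact
likelihoods, calibrated rate recovery). What it does not show: robustness
to real-data features the generator omits — indels inside the loop window,
annotation errors on real YeiP proteins, HMM scoring noise, tree-inference
error, codon-level processes.

## Study conditions used by the tests and the acceptance script

Simulation sizes were chosen as the package's standard benchmark
conditions: full-pipeline runs use 2000 genomes (co-occurrence standard
errors ≈ 0.5 percentage points); the rate-recovery experiment uses 20
replicates of 500-leaf Yule trees rescaled to unit height with binary ER
μ = 0.5, so that μ·height = 0.5 keeps the tips informative about the root;
the root-call demonstration uses 600 genomes on a short tree
(birth rate 6) with slow character rates (tip 0.3, relaxation 0.6),
producing deep proline-dominant lineages with derived arginine/not-P
clades. Oracle comparisons use 100 random trees of ≤ 5 leaves (exhaustive
enumeration) and 200 random peptide pairs of length 3–6 (brute-force
affine DP).

## Known limitations

* The headline percentages of the real curated family can only be
  recomputed from the deposited family alignment; the package ships the
  reproduction mode (`efp-loopscape reproduce`) but no copy of that
  dataset, and all bundled numbers come from synthetic runs.
* Midpoint rooting and ultrametric leveling are conventions, not
  inferences; reconstructions inherit their assumptions (and those of the
  externally supplied tree).
* Correlated-character (dependent-model) inference is out of scope: the
  dependence between positions 32 and 34 is assessed through co-occurrence
  statistics, and each character is reconstructed marginally.
* The YeiP screen is annotation-text matching only; unannotated paralogs
  with the same architecture would not be caught.
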