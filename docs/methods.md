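# Methods

## Model

A domain architecture (DA) is the ordered N→C list of domain superfamily
tokens in one protein. Its probability is approximated first-order: with a
NULL sentinel marking both termini,

    P(d1 d2 ... dn) = p(d1 | NULL) · p(d2 | d1) · ... · p(NULL | dn),

a product of n+1 conditional factors. Conditionals are estimated from
bigram counts over the *unique* architectures of a training corpus
(deduplication removes the bigram over-representation caused by gene
duplication) with Add-k smoothing:

    p(y | x) = (C(x, y) + k) / (Σ_z C(x, z) + k · |continuations(x)|).

Continuation sets: every alphabet token continues into alphabet ∪ {NULL}
(N_D + 1 outcomes); the NULL start context continues into the alphabet only
(N_D outcomes), so the empty architecture has probability zero and every
context's conditionals sum to exactly 1. The k = 0 limit reproduces the
raw bigram relative frequencies. Whether the start context should be
smoothed identically to interior contexts is underdetermined by the data
model; the uniform treatment above is a documented convention, and its only
observable consequence is the first factor of the product.

The default pseudocount is k = 1/N_D, computed from the trained alphabet
(≈ 0.0009 at the metazoan scale of ~1100 superfamilies). This offsets the
O(N_D) pseudocounts added per context, keeps smoothing mild, and — because
every conditional becomes strictly positive — connects the state space so
the simulator's chain is irreducible.

## Simulator

Evolution is a Metropolis–Hastings chain over architectures. A length-n
state has n + (n+1)·N_D neighbours (n deletions, (n+1)·N_D insertions;
2·N_D for n = 1, where deletion is forbidden). Per iteration:

1. choose gain vs loss — gains get ~N_D-fold odds so all adjacent states
   are proposed near-uniformly;
2. choose the site (and, for gains, the token) uniformly;
3. accept with min(1, P(t)/P(s)). The ratio telescopes to three
   conditionals, evaluated in log space; a randomized test battery keeps
   it equal to the full-product ratio to 1e-12 relative.

A loss proposed from a single-domain state is vetoed: it consumes an
iteration (a flag restores the alternative semantics) and is tallied
separately from Metropolis rejections. Extinction is therefore impossible.

Three proposal modes:

* `paper` (default): gain probability 1 − 1/N_D, i.e. a uniform draw above
  1/N_D selects a gain; acceptance is plain min(1, ratio).
* `symmetric`: gain probability N_D/(N_D + 1). For a gain from length n,
  q(s→t) = 1/((N_D+1)(n+1)) and the reverse loss has exactly the same
  proposal probability, for every n.
* `exact-hastings`: the `symmetric` proposal with the residual proposal
  ratio folded into acceptance. Because paired proposal probabilities
  cancel, the residual is identically 1 at unit gain/loss bias — the mode
  exists to make the detailed-balance argument explicit and to stay exact
  under a user-set `gain_loss_bias`, where the residual becomes 1/bias.
  Under this mode the stationary law is provably the first-order
  distribution restricted to nonempty architectures, which is what the
  stationarity test measures.

The `paper` and `symmetric` gain probabilities differ by O(1/N_D²) per
step; both are provided because the two published descriptions of the
proposal differ at exactly that order.

RNG: PCG64. Replicate r draws its stream from SeedSequence(seed,
spawn_key=(r,)), so replicates are independent and individually
reproducible. Each iteration consumes exactly one block of four uniforms;
the chunked chain loop and the single-`step` reference implementation are
therefore bit-identical, and a test asserts it.

Positions are 0-based for insertion sites (0..n) and 1-based for domain
positions (1..n) everywhere, including trace output.

## Training input

Annotation files are tab-separated, one domain assignment per line; the
default column order is genome id, protein id, region (`start-end`, with
multi-segment regions collapsed to their outer span), superfamily id, and
a column-mapping dialect supports other layouts. Per protein, domains are
ordered by ascending region start; ties break by region end then
superfamily id; overlapping regions are both kept (counted and logged) —
no resolution is attempted. Architectures from all input genomes are
pooled before deduplication. Monograms are counted with multiplicity
across unique architectures (per-DA presence is available as an option);
bigrams and trigrams include NULL-boundary padding, a single-domain DA
contributing the (NULL, d, NULL) triple.

## Evaluation battery

All statistics are computed identically on two sets of unique
architectures and paired over the union of keys observed in either set,
zero-filled (an intersection-only mode exists); agreement is summarized by
Pearson correlation. The rows: singleton/bigram/trigram frequencies
(normalized within each set); per-unordered-pair co-occurrence counts
(both tokens anywhere in one DA); unique-neighbor counts (both sides,
self-adjacency counts the token itself, NULL excluded); weighted bigram
promiscuity; per-superfamily mean tandem-array length (a tandem array is a
maximal run of ≥2 identical adjacent tokens); and matched quantiles
(type-7 linear interpolation, 101 points) of per-DA log-probabilities
after each set independently sheds its longest 1% (ties broken by lower
probability).

Weighted bigram promiscuity is implemented as score(d) = Σ over distinct
partners p of 1/deg(p), with deg the partner's own distinct-neighbor
count: a domain scores high when it combines with many, themselves
choosy, partners. The cited literature formula is not restated in our
sources; this concrete variant is isolated in a single function so an
alternative can be swapped in without touching callers. For set
comparison, set A's top-100 tokens are scored in both sets.

Event-position histograms bin accepted gains (sites 1..n+1) and losses
(positions 1..n) by the *pre-move* architecture length (the post-move
binning is the other defensible choice; pre-move is used consistently).
The terminal excess statistic is (first+last bin frequency) / (2/bins),
so values above 1 indicate terminal preference.

Gelman–Rubin: the classic PSRF R̂ = sqrt(V̂/W) with
V̂ = (n−1)/n·W + (m+1)/(m·n)·B on the post-burn-in half of m equal-length
chains; identical chains report exactly 1. The sampling-variability
degrees-of-freedom correction of the original formulation is available
behind a flag but off by default. Convergence verdict at the conventional
1.1 threshold.

## Synthetic ground truth

The generator draws a fully known first-order conditional table and
samples corpora from it ancestrally (start from the NULL row, emit until
NULL; duplicates are re-drawn, so corpora are unique-DA sets like real
training data). Its defaults encode the features of genuine corpora that
the evaluation battery actually measures:

* **Heavy-tailed usage.** Token weights follow a Zipf-like law (exponent
  0.9); genuine superfamily frequencies are strongly heavy-tailed, and
  without this property sparse n-gram count vectors degenerate into
  Poisson noise and the battery's correlations are meaningless.
* **Sparsity.** A fraction (default 0.3) of token→token transitions is
  forbidden, mirroring the extreme sparsity of genuine bigram matrices.
* **A repeat-former class.** 20% of tokens get a sticky self-transition
  drawn in [0.2, 0.8]; the rest have self-adjacency suppressed 200-fold.
  Genuine tandem behavior is concentrated in dedicated repeat-forming
  superfamilies (zinc fingers, EGF, cadherin repeats) with arrays of
  dozens, while most superfamilies never tandem.
* **Length scale.** Termination probability ≈ 0.25 jittered per context
  gives mean lengths in the genuine 3.6–6.2 range with right-skewed
  distributions. The closed-form expected length (absorbing-chain
  fundamental matrix) is exposed and checked against sampling.

Presets: `small` (20 tokens / 200 DAs) for seconds-scale unit tests,
`medium` (150 tokens / 3000 DAs, the scale used by the equilibrium,
convergence and recapitulation checks), `paper-scale` (1100 / 7000) for
manual experiments. Fixed internal seeds make presets byte-identical.

What the generator does **not** emulate: gene-duplication redundancy
(removed in real pipelines by deduplication anyway), selection beyond
first-order adjacency, genome-level heterogeneity, and the extreme-outlier
architectures of vertebrate genomes (titin-like proteins of hundreds of
domains). Passing the battery on synthetic corpora therefore shows the
machinery is self-consistent — train → simulate → evaluate closes — not
that genuine evolution is first-order.

## Problem sizes and numerical choices

The verification experiments run at sizes chosen to give stable statistics
on a single CPU: stationarity uses a two-token model with 10^6 post-burn-in
iterations (total-variation distance to the exact law over the 14 shortest
architectures); equilibrium uses one 1.6M-iteration chain on the medium
fixture (second-half accepted-gain/loss ratio, 10-block trend test on the
last quarter of length samples at the 1% level); convergence uses 10
chains of 300k iterations sampled every 100; recapitulation uses
corpus-matched replicates (3000) of 30k iterations each, which is well
past the length plateau for this fixture; event positions use 300 traced
replicates; recovery uses nested corpora of 200/800/3200 unique DAs from a
60-token mild-tail ground truth — recovery needs the unique-DA space to be
far from saturated, since deduplicated corpora otherwise acquire a
type-frequency bias that places a floor under the estimation error (a
genuine property of unique-DA training, not an implementation artifact).

In the recapitulation ordering check, the n-gram rows are compared
individually (singleton ≥ bigram ≥ trigram) and the heterogeneous
combination-statistic class (co-occurrence, neighbors, promiscuity,
tandem) by its mean, since its members' order varies while the class as a
whole sits below the n-gram rows.

Log-space probability arithmetic throughout; ratios with a zero numerator
return 0 before any subtraction so that -inf − -inf never occurs. Burn-in
for diagnostics discards the first half of sampled series. Deduplicated
sets and all statistic key universes are sorted, so every output is
deterministic given (inputs, seed).

## Known limitations

* The first-order model cannot express longer-range constraints
  (co-occurrence beyond adjacency is recapitulated only insofar as it is
  induced by bigrams).
* `paper` mode's stationary law deviates from the first-order distribution
  at O(1/N_D²) per step (proposal asymmetry); use `exact-hastings` when
  exactness matters.
* Monogram-weighted starts require a count-backed model; probability-table
  models (synthetic ground truths) support uniform starts only.
* The evaluation battery compares sets of unique architectures; abundance
  information within a genome is deliberately out of scope.
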