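# Methods

## Model and scope

The package analyzes a finite family of discrete random variables
`X1..Xn` through the information functions defined on the *simplicial*
lattice of variable subsets: every non-empty subset `S` (up to a maximum
degree `kmax`) carries its joint entropy `H(S)` and its co-information
`I(S)`. The simplicial restriction is what makes computation feasible: the
full lattice of partitions grows with Bell-number combinatorics, while
subsets grow as `2^n`, with `C(n,k)` elements per degree. The price is that
dependences not expressible through subset joins are invisible; this is a
known, accepted blind spot of the subset lattice.

All quantities are in bits (base-2 logarithms) and `0·log 0 := 0`
throughout. Comparisons with zero use an absolute tolerance of `1e-10` bits
unless stated otherwise.

## Estimation

Probabilities are estimated by the plug-in (maximum-likelihood) rule:
counts divided by the sample size `m`, with unobserved states at probability
zero. No pseudocounts and no bias correction are applied — the package
deliberately lets the data speak and leaves bias control to the sample size
and the graining. Rows with missing values are dropped listwise with a
logged count.

Continuous inputs are discretized per column into `N`-letter alphabets
(default `N = 8`), by quantile binning by default — it spreads a finite
sample across codes and thus uses the available marginal entropy — with
equal-width binning available. Codes are monotone in the raw values and the
boundaries are recorded. The alphabet size plays the role of an inverse
temperature: coarser graining = hotter, finer = colder; no quantitative
temperature mapping is attempted beyond re-binning.

Probability tables are stored densely; a guard refuses joint alphabets above
`2^24` states. Every computation within the lattice cap (below) fits
comfortably in dense storage, so no sparse branch exists.

## Lattice computation

`compute_structure` estimates `H(S)` once per subset (by direct counting on
data matrices, by marginalization on explicit joints) and derives every
`I(S)` by inclusion–exclusion over the cached entropies:
`I(S) = Σ_{T⊆S} (−1)^{|T|−1} H(T)`. The direct state-sum definition of
co-information is retained in the test suite as an independent oracle. The
default complexity cap of `2^21` subset evaluations (overridable with
`force`) matches what a single workstation handles; the enumeration refuses
beyond it, reporting the projected count.

Landscapes group the per-degree values into `(value, degeneracy)` multisets
under an absolute grouping tolerance of `1e-9` bits; exact grouping would
report degeneracy 1 nearly everywhere for empirical values. Mean paths
report `<H_k>` and `<I_k>`, the degree-wise averages over all `C(n,k)`
subsets — a homogeneous (mean-field-like) summary with internal energy
`U_hom = n·<I_1>` and free energy `G_hom = Σ_{k≥2} (−1)^k C(n,k) <I_k>`,
satisfying `H_n = U_hom − G_hom` exactly when `kmax = n`. The homogeneous
critical dimension is the degree of the first local minimum of `<I_k>`; the
final degree counts as a minimum when the mean path arrives there strictly
decreasing, since the profile beyond it is unobserved.

## Energies

The decomposition `H = U − G` takes `U = Σ_i H(X_i)` and `G = U − H`, which
equals both the total correlation and the alternating sum
`Σ_{k≥2} (−1)^k Σ_{|T|=k} I(T)` (the equality is verified in the tests
rather than assumed). Elementary per-state energies
`E(x) = −Σ_j log2 p_j(x_j)` are the unique assignment additive over
independent coordinates; states with a zero marginal get `+inf` and are
flagged — such states have zero joint probability, so expectations stay
finite. Gibbs laws `p ∝ 2^{−βE}` are normalized with a log-sum-exp shift;
`β` is dimensionless (physical constants absorbed).

## Paths and the complex

A path is an ordering of variables; profiles evaluate `H` or `I` on the
growing prefix. Derivatives are exactly `+` conditional entropy
(entropy kind — hence nondecreasing profiles, audited by
`second_law_audit`) and `−` conditional mutual information (information
kind). The first critical dimension of an information path is the degree of
its first local minimum — the point where the next conditional information
turns strictly negative; conditional informations of pairs are non-negative,
so the value is never below 3 (enforced as an assertion).

A *positive* path has a strictly decreasing profile (`> tol` at each step).
Extension stops either at conditional independence (the step ties with zero
within `tol`) or at negativity; the stop reason is recorded per facet. A
`strict=False` mode extends through ties for exploratory use, since tie
behavior at exact conditional independence is a genuine modeling choice.
Because step positivity depends only on the nested subset chain — not on the
order within the prefix — the search runs depth-first over subsets with
memoization instead of enumerating `k!` permutations; exhaustive permutation
enumeration is kept as a test oracle up to `n = 6`.

The maximal positive-path variable sets, pruned for containment, are the
facets of the minimum free energy complex; faces are their downward closure.
Two dimension conventions coexist: the variable-count dimension (a k-set has
dimension k, matching critical dimensions) and the geometric face dimension
`|S| − 1` used for the Euler characteristic
`χ = Σ_s (−1)^{s−1} f_s`. The minimum free energy characteristic is
`H+ = Σ_{faces F} (−1)^{|F|−1} I(F)`; when the complex is the full simplex
this telescopes to the joint entropy.

For plug-in estimates the default tolerance can be replaced by the
data-driven `(log2 e)/(2m)` (the order of the plug-in bias) via
`plug_in_tolerance`, since exact ties in the true law become small non-zero
fluctuations in estimates.

## Cohomology checks

Information cochains assign to `k` disjoint variable groups the
co-information of the groups, each group acting as one joint variable, with
conditioning as the module action. The three coboundary operators (left
action, trivial/topological action, symmetric action) are alternating sums
of face maps that join adjacent arguments. In low degrees they reproduce the
information functions: degree 1 gives the chain rule (left), `I_2`
(topological) and `−I_2` (symmetric, whose cocycles are exactly the
Shannon pseudo-metric `V_2 = H_2 − I_2`); degree 2 gives `−I_3` (left) and
zero (topological, symmetric); degree 3 gives zero (left), `I_4`
(topological) and `−I_4` (symmetric); the parity pattern continues in higher
degrees (even degree: left `−I_{k+1}`, others zero; odd degree: left zero,
topological `+I_{k+1}`, symmetric `−I_{k+1}`) and is exercised to degree 4
on binary alphabets.

Every cochain value is an integer-coefficient linear combination of subset
entropies, so verification happens in two layers: numerically (evaluating
both sides through floating-point entropies and reporting the residual) and
exactly (cancelling the integer coefficient vectors, which is immune to
floating error). Exact rational evaluation of the *entropies themselves* is
not meaningful — entropies of rational laws are irrational — which is why
the exact layer works on coefficients instead.

## Synthetic generators

The generators produce laws with closed-form information structure: product
laws (all `I_k = 0` for `k ≥ 2`), fully redundant copies
(`H_k = I_k = H_1`), the three-bit parity configuration (uniform marginals,
pairwise independent, `I_3 = −1` bit, elementary energies 3 bits,
`U = 3`, `G = 1`, `H = 2`), strictly positive Dirichlet-random laws for
fuzzing, a tensor-product composer for planting modules, and a seeded
sampler. They emulate the *dependence structure* of real data, not its
measurement process: no dropout, no library-size or batch effects, no
continuous noise before binning. Passing tests therefore demonstrate the
correctness and convergence of the machinery, not robustness to
real-world measurement artifacts.

Test and acceptance problem sizes were chosen as the smallest scales at
which every property is non-trivially exercised: lattices to `n = 6`,
identity fuzzing on 100 seeded 4-variable binary laws, estimator-consistency
checks at `m = 10^5` draws. The planted-module recovery check (a parity
block tensored with independent noise bits recovered as a facet, with no
block/noise mixing beyond pairs) stands in for module detection on real
expression data, which requires datasets outside the package's scope.

## Known limitations

- Only the subset (simplicial) lattice; partition-lattice dependences are
  out of reach by design.
- Plug-in estimation is biased at small `m`; no bias-corrected or Bayesian
  estimators are provided.
- Fully redundant modules do not form positive paths (their first extension
  ties at zero conditional information) and therefore appear as singleton
  facets, not as blocks; the complex detects synergy-bearing modules.
- Homology beyond the Euler characteristic (Betti numbers, persistence) is
  not computed.
- The conjectured higher cocycle classes have no computable closed form;
  only `I_k = 0` detection is available.
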