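# Methods

## Scope and model of the data

`paraconv` operates downstream of alignment and ancestral-state
reconstruction. Its unit of input is the *ancestral record*: a rooted
guide tree with labeled internal nodes and branch lengths (expected
replacements per site), a positive relative rate rᵢ per alignment column,
and one amino-acid sequence per tree node — tips and reconstructed
ancestors alike. External reconstruction programs are deliberately not
wrapped; the record file is the contract, and any tool whose output can be
written as that file (CODEML, RAxML, a simulator) plugs in. Alignment
columns containing gaps or any character outside the 20 uppercase
canonical amino acids are assumed removed before reconstruction;
`trim_alignment` applies exactly that rule and returns the kept-column map
so positions (always 1-based columns of the trimmed alignment) can be
translated back.

## Branch-pair eligibility

Replacements on two branches can only evidence independent evolution if
the branches are disjoint in descent. Two exclusions implement this:
branches sharing a parent node (siblings), and branches on one
root-to-path line (either child node an ancestor of the other, which also
covers parent–child edges). "Neighboring" pairs are read as node-sharing
pairs; once the ancestor rule is in place, siblings are the only
node-sharing pairs left, so the implemented predicate is
`not siblings ∧ not ancestor-either-way`. Multifurcations are accepted
(the sibling rule generalizes to "same parent"), the root may have any
number of children, and root-adjacent edges are ordinary branches. For a
bifurcating tree with L leaves and K cherries this yields exactly
C(L,2) − K comparable tip–tip pairs, a closed form the test suite checks
against brute force.

## Event definition

For pair {b₁, b₂} at site i, with a₁→d₁ and a₂→d₂ the parent→child states
on the two branches: an event requires a₁≠d₁, a₂≠d₂, d₁=d₂; it is parallel
iff a₁=a₂, else convergent. The dichotomy makes at most one event per
(pair, site) possible, and no further condition applies (in particular
d₁ = a₂ does not block an event). Counts tables include zero rows for
every comparable pair so the identification, expectation and test outputs
join on identical keys.

## Substitution model and transition probabilities

Models are reversible empirical matrices in PAML `.dat` layout: lower
triangle of exchangeabilities S, then frequencies π, residue order
A R N D C Q E G H I L K M F P S T W Y V. The generator is Q_ij = S_ij·π_j
(i≠j), rows summing to zero, scaled by μ = −Σ π_i Q_ii so the mean rate is
one and branch lengths read as expected replacements per site — the
convention of maximum-likelihood guide trees. P(d) = exp(Qd) is computed
through the symmetric similarity transform Π^{1/2}QΠ^{−1/2} and its real
eigendecomposition: exact for reversible generators, stable at any
distance (no scaling-and-squaring), and automatically satisfying detailed
balance to round-off. Entries are clipped to [0,1] after a −1e−12
tolerance check; rows sum to 1 within 1e−9. All operations are generic in
alphabet size n ≥ 2, which is what lets 2-letter closed forms serve as
independent oracles in the tests.

The bundled JTT file carries the standard Jones–Taylor–Thornton
exchangeabilities and frequencies. Any PAML-format file may be substituted
(`-m/--model`); frequencies within 1e−4 of summing to 1 are renormalized,
anything further off is rejected as a malformed file.

## Expected counts

Both expectation routes share the distance d = rᵢ·t per site and branch.

**Analytic.** Conditioning on the recorded (point-estimate) ancestral
states and on branch-wise independence given those states,

    λ_P = Σᵢ [a₁=a₂] Σ_{c≠a₁} P_{a₁c}(rᵢt₁) P_{a₂c}(rᵢt₂)
    λ_C = Σᵢ [a₁≠a₂] Σ_{c∉{a₁,a₂}} P_{a₁c}(rᵢt₁) P_{a₂c}(rᵢt₂).

This is the only form computable from the record's contents alone
(matrix, rates, lengths, ancestors); integrating over ancestral-state
uncertainty would require per-node posteriors the record does not carry,
and is a known limitation. λ_P and λ_C are monotone non-decreasing in each
branch length for the symmetric 2-letter chain on [0,1], a property the
suite verifies on a grid.

**Simulation.** Replicate records are evolved along the tree: root drawn
i.i.d. from the trimmed tip-alignment frequencies (zero counts floored at
1e−6 to avoid absorbing states; the model's π is the fallback when tips
carry no usable data), each branch a CTMC step sampling from row
`parent_state` of P(rᵢt). The replicate's *true* simulated ancestors are
used when rescanning for events — no re-reconstruction — matching
workflows where simulated internal sequences are available directly.
Expectations are per-pair means over replicates; the default is 100
replicates, and a seed is mandatory so runs are bit-reproducible.

## Test

Observed k vs expectation λ per pair and category, k ~ Poisson(λ): lower
tail P(X ≤ k) when k < λ, upper tail P(X ≥ k+1) otherwise (equality takes
the upper tail; the strictly-greater form is required to reproduce the
published values, e.g. k=1, λ=0.35 → 0.0487). k=λ=0 is undefined → `N/A`;
λ=0 with k>0 returns 0 (impossible under the null). Tails come from
scipy's Poisson distribution functions and are clipped to [0,1];
significance flags `*`/`**` at 0.05/0.01 are computed on the reported
p-values. No correction is applied by default; Bonferroni or
Benjamini–Hochberg can be requested and is applied jointly across all
non-N/A p-values of both categories, with flags then reflecting the
corrected values.

## Synthetic data generator

`make_fixture` produces the offline test bed: a Yule tree (uniform random
tip splits) with i.i.d. exponential branch lengths of mean 0.1
replacements per site — short enough that multiple hits are rare, long
enough that events occur, i.e. the regime of a typical protein guide
tree — sequences simulated under the bundled JTT model with unit site
rates and stationary root frequencies, default 8 leaves × 200 sites.
Everything is deterministic per seed. The generator emulates the
*structure* of reconstruction output, not its failure modes: real records
carry reconstruction error and posterior uncertainty in ancestral states,
among-site rate variation, and alignment error, none of which the fixture
contains. Passing tests therefore demonstrate correctness of
identification, expectation and testing given a record — not robustness
to reconstruction artifacts.

## Numerical and design choices

- Record layout: lines 2 and 4 are written blank and ignored on read; a
  missing/blank rate line defaults to rᵢ = 1 with a warning.
- Internal-node auto-labels are preorder `N<k>` with collision skipping,
  so labels never clash with existing names and relabeling is idempotent.
- Missing branch lengths are tolerated (read as 0) for identification,
  but raise for either expectation route, which genuinely needs them.
- Newick parsing is delegated to dendropy; the writer is native so child
  order is preserved and lengths print at 9 significant digits, making
  pipeline outputs byte-reproducible.
- Problem sizes in the test suite (records of 5–9 leaves × 20–200 sites,
  200 trees for the enumeration oracle, 2·10⁴ replicates / 2·10⁵
  conditional draws for the Monte-Carlo oracles) were chosen so each
  oracle's 3-standard-error band is a few percent of the quantity checked
  while the whole suite stays interactive.

## Known limitations

- Point-estimate ancestors only; no posterior-weighted averaging.
- No indel model: simulation emits gapless sequences, and sites with gaps
  must be trimmed upstream.
- Site rates are taken as given; no among-site rate-model fitting.
- Codon/nucleotide models, tree inference, rerooting and topology tests
  are out of scope.
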