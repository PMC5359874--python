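# Methods

This note documents the models, conventions, and numerical choices
behind `glasstree`, and what the synthetic-data generators do and do
not emulate.

## Character matrices and missing data

The internal currency is a taxa × characters grid of single-character
state symbols with one reserved missing symbol (`?`). Both the NEXUS
missing symbol and the gap symbol map to that one internal missing
state at read time, because in unordered parsimony on
morphology-plus-recoded-nucleotide matrices gaps are treated as missing
data. Case folding and RNA `U → T` normalization also happen at read
time. Taxon labels are matched across blocks after collapsing
whitespace runs to underscores, since NEXUS dialects interchange the
two.

Nucleotide recoding for mixed-data parsimony replaces `A,C,G,T` with
`0,1,2,3`; every IUPAC ambiguity code (including `N`) and the gap
become missing. Distinct alignment patterns are counted per partition
and summed, with the missing symbol participating in pattern identity
as its own symbol; for raw alignments the missing fraction is reported
both counting only `-`/`?` and additionally counting ambiguity codes,
because published "percent missing" figures do not always state the
convention.

## Parsimony

Per-character steps are computed by a unit-cost Sankoff dynamic
program vectorized over characters (`cost(s) = Σ_children
min(c_child(s), min_t c_child(t) + 1)`). On binary trees this equals
the Fitch count; on polytomies it is still the exact minimum, which
plain Fitch is not. Missing cells carry the universal state set (zero
cost in every state); characters entirely missing on the induced leaf
set contribute zero steps. Step bounds are `m = (#observed states) − 1`
and `g = n_scored − (count of the modal state)`; the ensemble indices
are `CI = Σm/Σs`, `RI = (Σg − Σs)/(Σg − Σm)` with `g = m` characters
excluded from the RI sums, and `RC = CI·RI`. Indices are computed over
all characters of the matrix (the empirical matrices contain only
parsimony-informative characters by construction) and, when compared
with printed two-decimal values, rounded half-up.

The implied-weights objective is `Σ_i h_i/(h_i + K)` with homoplasy
`h_i = s_i − m_i` and concavity `K = 3.0` by default. Tree lengths
reported next to implied-weights results are always raw step counts.

The search is seeded random stepwise addition followed by steepest-
descent branch swapping (NNI, SPR, or full TBR — SPR with re-rooting of
the pruned subtree). It deliberately replaces specialised
"new-technology" heuristics of dedicated parsimony programs; the
equivalence claim is score parity, judged against exhaustive topology
enumeration on six-taxon instances in the tests, not tree-set
identity. Distinct co-optimal trees are collected across starts and
de-duplicated/ordered by a canonical unrooted-split key, so a given
seed always returns an identical tree list. The number of co-optimal
trees found is search-effort-dependent and is not a contract.

Bootstrap pseudoreplicates resample characters with replacement and
are analyzed with a reduced-effort search (one addition start per
replicate); support is the percentage of replicate best trees
containing each reference split. Character tracing combines Sankoff
down-pass costs with rootward costs to give exact MPR state sets at
every node (also under polytomies); origin/loss counts refer to one
deterministic resolution (preorder, smallest state consistent with a
minimum-length extension of the parent state).

## Mk and GTR likelihoods

Branch lengths are expected substitutions per site/character. The
symmetric k-state model is parameterized by the total leaving rate `q`
(`p_stay(t) = 1/k + (k−1)/k · e^{−kμt}` with `μ = q/(k−1)`), so `q` is
directly comparable across `k`. The asymmetric binary model has
independent gain (`q01`) and loss (`q10`) rates with stationary
frequencies `π₀ = q10/(q01+q10)`. GTR is normalized to one expected
substitution per unit length and exponentiated through the
π-symmetrized spectral decomposition. Rate variation uses the standard
discrete gamma: four equal-probability classes represented by their
class means, averaged in likelihood space.

Likelihoods use Felsenstein pruning with per-node rescaling (underflow
becomes an explicit `−inf`, never a silent zero). Matrices assembled
from variable or parsimony-informative characters only can be
conditioned on that ascertainment: the excluded-pattern probability is
computed by pruning with indicator tips over the k constant patterns
(`variable-only`) plus every single-taxon-deviant pattern
(`informative-only`), and the corrected likelihood is
`Σ log L_i − n·log(1 − P_excluded)`. For k = 2 the constant-plus-
singleton set is exactly the parsimony-uninformative patterns; for
k > 2 it is a (slightly conservative) subset, which is irrelevant here
because the informative-only correction is used for binary morphology.

Fitting is bounded Nelder–Mead on the log-parameter scale with rates
in `[10⁻⁶, 100]`, gamma shape in `[10⁻², 100]`, tolerance `1e−8`, and
seeded multi-start (3 starts by default); non-convergence is flagged
in the result.

## Ancestral states

Marginal proportional likelihoods combine the tipward partial of each
node with a rootward partial propagated from the root prior
(equilibrium frequencies by default; the "equal frequencies" variant
exists but is not recommended — on presence/absence data it easily
produces biologically implausible root states). Rates are fitted per
character. Trees without stored branch lengths (parsimony trees) adopt
the all-unit convention, mirroring the default of common ASR programs;
this is auto-detected and can be forced. Polytomies are treated as
hard. Reports round proportional likelihoods half-up to two decimals
and are ordered by (character, clade, model). The gamma correction is
off for ASR by default (configurable), as rate variation settings for
published single-character reconstructions are typically unstated.

## Morphology-based placement

Each character is weighted by its retention index on the molecular
reference tree (undefined RI ⇒ weight 0), so characters incongruent
with the molecular backbone are down-weighted exactly in the spirit of
weighted morphology-based binning; fidelity to any particular binning
program's internals is explicitly not claimed. A query is tried on
every reference edge and edges are ranked by the weighted parsimony
score of the augmented tree, ties broken by postorder edge index. Two
identifiability facts are worth knowing (both are provable and encoded
in the tests): a query whose true sibling is a single leaf cannot be
strictly placed (its pair character has no defined RI on the pruned
reference), and the stem edge of a root-adjacent sibling group is the
same unrooted edge as its complement. At moderate homoplasy (mean
character RI ≈ 0.6) roughly 60% of leave-one-out placements land
inside the true sibling group in our simulations; wrong edges
genuinely score better in most failures, i.e. this is a limit of the
data, consistent with the mixed reputation of binning on real
morphology.

## Pipeline conventions

Morphology-only analyses are rooted with an artificial all-zero
outgroup taxon (a coding device, not a taxon: zero-coded in
morphological partitions, missing in molecular ones). Combined
analyses use a functional outgroup from the other subclass whose
morphology is coded absent. Subclass trees are grafted by removing the
functional outgroups and joining the two ingroups under a new root — a
rooted bifurcation at the subclass split (the alternative basal
trichotomy is not used). Every stage is seeded; outputs are a pure
function of (inputs, config, seeds), and the manifest records SHA-256
checksums of all artifacts (only the manifest's timestamp differs
between identical runs).

## Synthetic data: what it emulates, what it does not

The generators mirror the structure of the empirical datasets: two
reciprocally monophyletic "subclasses" (defaults 13 + 113 genera)
joined at the root of a Yule tree (branch lengths scaled by 0.15,
giving morphology-scale depths); binary morphology simulated under Mk
(`q = 0.1`, gamma shape 0.5) and rejection-filtered to
parsimony-informative characters (defaults 29 + 108 characters); a
4-partition molecular supermatrix (4806 sites under GTR+Γ) restricted
to ~45% of the taxa with ~30% marker-block dropout inside the
sequenced set. The resulting total-evidence matrix lands at ~66%
missing, inside the ~62–65% regime of the empirical genus-level
matrices. Rates and dimensions were chosen once on those grounds and
are fully configurable.

Not emulated: correlation among morphological characters, RNA
secondary-structure covariation, alignment error, and non-random
(phylogenetically clustered) sequencing effort. A green test on this
world therefore establishes algorithmic correctness and statistical
behaviour under the stated model — not robustness to model violation
in real matrices.

The default end-to-end workflow configuration runs this world scaled
down (20 taxa, ~300 molecular sites, reduced search effort) so a full
run takes seconds; the full-scale generator is exercised by the
acceptance script.

## Known limitations

* The parsimony search is a generic heuristic; on large matrices
  (>~30 taxa) it is slow in pure Python and is not intended to replace
  dedicated programs for production searches.
* GTR+Γ is provided for likelihood evaluation, not full ML tree
  search.
* Bootstrap support uses reduced per-replicate search effort; support
  values on difficult matrices are accordingly approximate.
* The binning placement scores by weighted parsimony; an Mk-likelihood
  scorer would be a natural alternative but is not implemented.
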