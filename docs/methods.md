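# Methods

## Model

A metabolic network is a stoichiometric matrix S ∈ Q^{m×n} over metabolites
(rows) and reactions (columns), with the reactions partitioned into a
reversible set Rev and an irreversible set Irr. At steady state the feasible
flux distributions form the polyhedral *flux cone*

    C = { v ∈ R^n | Sv = 0, v_j ≥ 0 for all j ∈ Irr }.

All the objects this package computes live in the face lattice of C:

- **Lineality space** L = { v | Sv = 0, v_Irr = 0 }, dimension t. It is the
  reversible core of the network; C is pointed iff t = 0.
- **Elementary flux modes (EFMs)**: nonzero v ∈ C of inclusionwise minimal
  support. Verified by the exact rank test
  rank(S_{⋆,supp(v)}) = |supp(v)| − 1.
- **Degree** of v ∈ C: the dimension of the smallest face of C containing
  v, computed as n − rank of S stacked with unit rows for the irreversible
  reactions at zero in v. Vectors in L have degree t, vectors in minimal
  proper faces degree t+1, vectors in relint(C) degree dim C. The degree
  measures how "elementary" a flux vector is; it must be evaluated in the
  original cone, never in the reversible-split reconfiguration (where every
  extreme ray trivially has degree 1).
- **Metabolic behaviors**: the irreversible support of some v ∈ C; the
  inclusion-minimal ones (MMBs) are in 1–1 correspondence with the minimal
  proper faces (dimension t+1).
- **Decomposition**: every v ∈ C with deg(v) = k is a positive combination
  of at most k EFMs of degree ≤ t+1, all inside the minimal face of v
  (Carathéodory reduction of a feasible nonnegative solution).

## Exact arithmetic

Every geometric decision — a rank, a dimension, a support, a feasibility
verdict — is an integer or yes/no answer. A floating-point tolerance could
silently change a degree or merge two faces, so the entire kernel works
over `fractions.Fraction`: RREF-based rank/nullspace, and a two-phase
tableau simplex with Bland's smallest-index rule (guaranteed termination on
degenerate problems) for feasibility certificates, blocked-reaction and
redundancy detection, and flux balance analysis. The simplex handles free
variables by splitting and finite bounds by shifting plus slack rows.
scipy's HiGHS LP is used only in the test suite, as an independent
feasibility oracle for random instances; it never decides anything in the
library. Canonical vector form: clear denominators by the lcm, divide by
the gcd, sign so the lowest-index nonzero entry is positive — except that
vectors with nonempty irreversible support are oriented so their
irreversible entries are positive (membership in C fixes the sign).

## Canonicalization

Blocked irreversible reactions (implicit equalities, found by exact
feasibility of {v ∈ C, v_j = 1}) are kept as equalities with their columns
retained, so vector indices always align with the input network. Redundant
irreversibility constraints are detected one at a time (is {Sv = 0,
v_i ≥ 0 for i ∈ Irr∖{j}, v_j = −1} infeasible?) and shifted to Rev in
lexicographic order of the reaction index by default, re-testing after each
shift, because the resulting irredundant description depends on the removal
order. Canonicalization never changes the point set of C; MMBs, however,
genuinely depend on the description, so nothing canonicalizes silently —
lattice and facet operations require an explicitly canonicalized cone and
raise otherwise.

## EFM enumeration

`enumerate_efms` splits each reversible reaction into forward/backward
nonnegative variables, giving a pointed cone {w ≥ 0 | [S, −S_{⋆,Rev}] w = 0}
whose extreme rays are found by the double description method: start from
the unit rays of the orthant, impose the equality rows in ascending index
order, and combine adjacent positive/negative ray pairs, with adjacency
decided by the exact rank test on the common zero-set plus the processed
equality rows. Rays supported on exactly one split pair are futile
two-cycles and discarded; an extreme ray using both directions of a split
reaction would indicate a bug and raises. EFMs supported entirely on
reversible reactions come in ± pairs; one canonical representative is kept
and flagged, and counts are reported both ways since both conventions are
in use.

`efms_brute_force` is the independent oracle: scan all support candidates
up to size rank(S)+1 (larger supports cannot pass the rank test), accept a
candidate iff the restricted matrix has a one-dimensional kernel with no
zero entry that is sign-feasible on the irreversible part. It is
exponential in n and guarded at n ≤ 14 by default; both guards are
arguments, not hard-coded constants.

## Face lattice

On a canonical description every proper face is an intersection of facets,
and faces are represented by canonical zero-sets over the unblocked
irreversible reactions. The lattice is the meet-closure of the facet
zero-sets under union, with each candidate canonicalized through the EFMs
it contains (the canonical zero-set is the free irreversible set minus the
union of irreversible supports of the contained EFMs). Relative-interior
witnesses are sums of contained EFMs in canonical orientation — positive
exactly on the realizable coordinates — with an exact-LP fallback
(`face_from_zero_set`) when no EFM list is at hand. Cover edges are
computed by reverse zero-set inclusion with an explicit betweenness check.

## Decomposition

`decompose` collects all EFMs of degree ≤ t+1 inside the minimal face of
the target (both orientations for reversible-pair EFMs), finds one exact
nonnegative solution over all candidates at once, then Carathéodory-reduces:
while the active vectors are dependent, shift an exact kernel combination
off the coefficients with the largest step keeping them nonnegative (ties
broken by lowest candidate index, making the result deterministic), and
drop zeroed terms. The reduced active set is linearly independent, so the
term count is bounded by the face dimension, i.e. by deg(v).
`count_minimal_decompositions` enumerates k-subsets of the candidates
(guard: 25 candidates) and accepts a subset iff an exact LP maximizing the
smallest coefficient certifies a strictly positive solution.

## Synthetic test networks

`random_network(m, n, n_irr, seed, density=0.4, entry_range=2)` draws
integer stoichiometries uniformly from {−2..2}∖{0} at density 0.4 and
resamples so every metabolite and reaction touches the network; the
reversible/irreversible split is a uniform random subset. This emulates the
sparsity and small integer coefficients of curated central-metabolism
models at desk scale; it does not emulate genome-scale dimensions,
compartments, biomass-style dense columns, or the strong modularity of real
reconstructions. Passing tests on this generator therefore demonstrate the
exactness and mutual consistency of the algorithms (enumeration vs. oracle,
bounds with zero violations, decomposition guarantees) but not performance
or numerical behavior at genome scale, which is out of scope. The test and
acceptance pool uses 50 seeded networks with m ≤ 5 and n ≤ 10 — sizes where
the 2^n brute-force oracle stays well inside a second per instance — with
shapes derived deterministically from the seed.

## Parameters and guards

| Parameter | Default | Meaning |
| --- | --- | --- |
| `DD_SIZE_LIMIT` | 60 | max n + |Rev| for double description |
| `BRUTE_FORCE_LIMIT` | 14 | max n for the 2^n support scan |
| `FACET_LIMIT` | 25 | max facets for full lattice enumeration |
| `CANDIDATE_LIMIT` | 25 | max candidates for decomposition counting |
| `density` | 0.4 | nonzero fraction in random networks |
| `entry_range` | 2 | stoichiometric coefficients in {−2..2} |

All guards are overridable per call; exceeding one raises a resource error
rather than silently truncating.

## Degenerate inputs and tie-breaks

The zero vector has degree dim L and minimal face L; it is rejected by EFM
tests and decomposition. Networks with Irr = ∅ have C = L: no facets, a
single lattice face, and every member in the relative interior. Blocked
reversible reactions are detected (two feasibility LPs) but need no
equality bookkeeping since they do not carry sign constraints. Simplex
pivoting uses Bland's rule throughout; double-description insertion order
is ascending row index; Carathéodory pivots break ties toward the lowest
candidate index — all choices fixed so results are reproducible
bit-for-bit.

## Known limitations

- Enumeration is exact but not engineered for genome-scale networks; the
  double description step has no sparsity tricks or parallelism.
- FBA uses the exact simplex and is intended for small and mid-size models;
  external genome-scale reproductions (e.g. BiGG models via SBML) are
  supported as input but not exercised by the shipped tests.
- The l-simplicity statistic requires the full lattice and is therefore
  only available where the lattice enumeration guard admits it.
- Decomposition counting is exhaustive over k-subsets and meant for the
  small candidate sets typical of low-degree targets.
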