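# fluxgeom

Exact polyhedral geometry of steady-state flux cones for constraint-based
metabolic modeling.

Given a stoichiometric matrix S and a partition of the reactions into
reversible and irreversible ones, the feasible steady-state flux
distributions form the *flux cone*

    C = { v ∈ ℝⁿ | S v = 0,  v_j ≥ 0 for all j ∈ Irr }.

`fluxgeom` is for modelers and method developers who want the *geometry* of
this cone, exactly: which reactions are blocked, which irreversibility
constraints are redundant, the lineality space L and the dimensions of C
and its faces, the elementary flux modes (EFMs — nonzero flux vectors of
inclusionwise minimal support, verified by the rank test
rank(S_{⋆,supp(v)}) = |supp(v)| − 1), the **degree**

    deg(v) = dim of the smallest face of C containing v
           = n − rank(S stacked with unit rows for {j ∈ Irr : v_j = 0}),

minimal metabolic behaviors (MMBs, in 1–1 correspondence with the faces of
dimension dim L + 1), the full face lattice for small cones, and the
decomposition of any flux vector of degree k into at most k EFMs of degree
at most dim L + 1.

Everything geometric is computed in exact rational arithmetic
(`fractions.Fraction`): ranks by exact RREF, feasibility and flux balance
analysis by an exact simplex with Bland's rule, EFM enumeration by
reversible splitting plus an exact double description method,
cross-checked against an independent brute-force rank-test oracle. No
result ever depends on a floating-point tolerance.

## Worked example

The bundled 2-metabolite, 4-reaction toy network (reactions 1, 2
reversible; 3, 4 irreversible):

```python
import fluxgeom as fg

net = fg.fixture_ex54()           # S = [[1,-1,0,0],[0,1,1,-1]]
cone = fg.build_cone(net)
print(cone.dim_cone, cone.dim_lineality)   # 2 0

efms = fg.enumerate_efms(cone)
for i, e in enumerate(efms):
    print(f"E{i+1} deg={e.degree}", tuple(int(x) for x in e.vector.values))

v = net.flux([0, 0, 1, 1])
print(fg.in_relative_interior(cone, v))    # True
d = fg.decompose(cone, v, efms)
print([(int(c), tuple(int(x) for x in e.vector.values)) for c, e in d.terms])
print(fg.count_minimal_decompositions(cone, v, efms))
```

prints

```
2 0
E1 deg=1 (1, 1, 0, 1)
E2 deg=2 (0, 0, 1, 1)
E3 deg=1 (-1, -1, 1, 0)
True
[(1, (1, 1, 0, 1)), (1, (-1, -1, 1, 0))]
1
```

The cone is pointed (dim L = 0) and 2-dimensional. Two EFMs have degree 1 —
they are the extreme rays — while (0,0,1,1) has degree 2: it lies in the
relative interior of C and splits as the sum of the two rays, the unique
such decomposition into deg = 2 EFMs. Its degree attains the bound
dim L + rank(S_{⋆,Irr}) + 1 = 0 + 1 + 1 = 2 with equality.

The larger bundled example (8 metabolites, 13 reactions, `fixture_fig1`)
exercises the full pipeline: reaction 13 is blocked, the constraint
v₆ ≥ 0 is redundant, dim C = 5 and dim L = 2, the MMBs are
{2},{6,7},{6,8} on the original description and {2},{7},{8} after
lexicographic canonicalization, and the face lattice has eight faces with
dimensions 2,3,3,3,4,4,4,5.

## Command line

```sh
fluxgeom fixtures export fig1 fig1.json
fluxgeom analyze fig1.json                  # cone, EFM, MMB report (JSON)
fluxgeom analyze fig1.json --no-canonicalize
fluxgeom degree fig1.json vectors.tsv       # per-vector degree + minimal face
fluxgeom decompose fig1.json vectors.tsv
fluxgeom fba net.json R_target --bounds bounds.tsv
```

Networks are JSON (`{"metabolites": [...], "reactions": [{"id", "reversible"}],
"S": [[...]]}`, with non-integer coefficients as `"p/q"` or decimal strings
for lossless round-trips), TSV (matrix + reversibility sidecar), or SBML.

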