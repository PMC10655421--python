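# Methods

## Model

All computations operate on *qualitative* metabolic networks: a network is
a set of reactions, a reaction a pair of non-empty compound sets
(reactants, products) with a reversibility flag. Stoichiometric
coefficients, kinetics and compartments are deliberately out of the model;
compound identity is the bare string id, so any compartment suffix present
in an SBML source simply stays part of the id. This matches the semantics
of network expansion, where producibility is a reachability question, not
a flux question. The SBML reader/writer handles the Level 3 core subset
this model needs (species, reactions, speciesReference, `reversible`); the
writer emits a canonical sorted document so equal networks give
byte-identical files.

## Network expansion

The scope of a network on seed medium *S* is the least fixed point of:
a reaction whose reactants are all reachable adds its products. Reversible
reactions are compiled to two irreversible reactions at expansion time,
which makes the fixed point manifestly order-independent. The
implementation is a worklist indexed by per-reaction unmet-reactant
counts — linear in total reaction arity — but the contract is the fixed
point itself: the test suite compares it exactly against an independent
naive repeated-sweep closure on hundreds of random networks, and checks
monotonicity in seeds and in reactions, and idempotence.

Two views are reported: `full_scope` (seeds included) and `producible`
(seeds removed). Size summaries conventionally count seeds while
"newly producible" lists exclude them; exposing both removes the
ambiguity. Seed compounds absent from a network still count as available
substrates — the medium is external to any genome. Community scopes pool
all members' reactions (mixed-bag assumption: free internal exchange);
host reactions join the pool when a host is given.

## Minimal communities

The solver looks for minimum-cardinality member subsets whose mixed-bag
scope covers every *producible* target; targets unreachable even by the
full community plus host are reported separately and excluded from the
covering requirement with a warning, because real target lists routinely
contain unreachable compounds. The host supports coverage but is never
selectable and never counts toward community size.

Algorithm: iterative deepening over subset size with a feasibility prune
(a partial selection is abandoned when even pooling all remaining species
cannot cover the goal), exhaustive at the optimum depth so *all* optima
are enumerated, up to a cap (default 1000). The search internally looks
one solution past the cap, so the `truncated` flag is set only when more
optima actually exist. Members are explored in lexicographic id order and
solutions sorted lexicographically, making output deterministic. The
objective is species cardinality only — no minimization of exchanged
compounds — because the quantity of interest downstream is community
membership. Exactness is verified against brute-force subset enumeration
on instances up to 12 species.

Essential symbionts are the intersection of all optima, alternative
symbionts the union minus the intersection. Classification refuses a
truncated enumeration outright: with optima missing it would be unsound.

## Reverse ecology

The compound graph has an edge from every reactant to every product of
each reaction (mirrored for reversible reactions). Seed sets are the
source strongly-connected components of this graph — components with no
incoming edge — computed via condensation; each seed compound gets
confidence 1/|component|, so confidences sum to 1 per component. A
brute-force reachability characterization (a compound is a seed iff every
node reaching it is reached back from it) serves as the oracle in tests.

Indices are confidence-weighted on the focal side only and normalized by
the focal total, hence in [0, 1]. An unweighted variant (plain set
fractions) is available on every index because the weighting convention is
a modeling choice, not a mathematical necessity. MCI is implemented as the
complementarity formula exposed under the host–microbe entry point: one
implementation, two names, no silent divergence. BSS counts *any*
supporter compound, seeds included — it measures presence, not
biosynthetic exclusivity (complementarity is the exclusive variant). No
confidence threshold filters seeds by default, and no currency-metabolite
list is applied unless the caller supplies one (the only safe default is
to exclude nothing). An optional exclusion list is honored in graph
construction only, never in expansion.

## PGPT screening

Matching is exact gene symbol, case-insensitive, trimmed; homology search
is upstream and out of scope. The packaged catalog transcribes its printed
source verbatim: eight categories, with the printed duplicates (`nodX`,
`nodO` twice each) collapsed and the unusual entries (`node`, `nod`,
`*_like`) retained as printed. The source states a total of 86 genes that
does not reconcile with the 91 distinct printed symbols; the catalog
surfaces this in its metadata rather than guessing which symbols to drop.
Users can pass a corrected custom catalog (a symbol in two categories is
rejected). Completeness per category is the fraction of catalog genes
present; the complete flag requires exactly 1.

## Selection pipeline

`design_syncom` runs one minimal-community enumeration per host (hostless
when no host is given), pools essentiality as *essential in every run in
which the targets were producible* — a per-run breakdown stays in the
report so stricter or looser pooling can be applied downstream — then
prunes competitors: while any off-diagonal competition exceeds the
threshold (strict `>`, default 0.6), remove the species in the most
violating pairs, breaking ties by greater mean off-diagonal competition
and then by lexicographically last id, recording each removal with its
triggering value. Iterative single removals generalize a one-step removal
of the most competitive members while staying auditable; a rule-consistency
test confirms on small fixtures that no smaller removal set satisfies the
threshold. The report keeps the full before/after matrices and the
excluded species' rows for transparency. Removing every member is an
error, reported with the exclusion trail.

## Synthetic instances

The generator builds instances whose optima are known *by construction*,
never by running the solver: each target is a linear pathway chain from a
fresh seed compound through `chain_length` single-substrate reactions;
chain reactions are partitioned across the hub so every hub member holds
at least one single-copy (hence indispensable) reaction. Decoys hold one
reaction gated by a dead compound (produced by nothing, absent from
seeds), so they are provably inert; leftover species slots become
additional decoys. Planting a competitor pair adds two clones of one hub
member — three interchangeable copies, pairwise competition exactly 1,
optimum ambiguity flagged, the cloned member dropping out of the essential
set. Planting host support gives the host a copy of a different hub
member's reactions, so the optimum with the host is one smaller than
without. Chains rather than random graphs are used for the planted core
because minimality must be provable by construction.

Defaults (10 species: 4-member hub, one clone pair, 4 decoys; 3 targets;
4-reaction chains; threshold 0.6) describe a community in which most
species are dispensable, a few are essential and a couple compete
strongly — the statistical shape of a real rhizosphere design problem at a
size where exhaustive verification is still feasible. What the generator
does *not* emulate: realistic genome sizes, KEGG/MetaCyc reaction-degree
statistics, branched or cyclic pathways, shared intermediates between
species, or annotation noise. Passing tests therefore demonstrate
correctness of the algorithms on networks with known structure, not
robustness to the idiosyncrasies of automatically reconstructed GSMNs.

## Numerical and degenerate-input choices

All index computations are exact rational arithmetic in floating point
(sums of 1/k terms); test tolerances are exact except where an explicit
`isclose` guards a float sum. Empty seed medium is allowed (scope = ∅);
an empty focal seed set makes every index undefined and raises a typed
error rather than returning a sentinel. An empty compound graph yields an
empty seed set; an isolated compound is its own seed. Matrices include
self-pairs, with diagonals at each metric's self-value (competition and
BSS 1, complementarity and MCI 0).

## Problem sizes

Property suites run on the order of 100 random networks (≤ 50 reactions)
for expansion and seed-set oracles, ~30 planted instances (≤ 12 species)
for solver exactness, and 50 planted instances for end-to-end hub
recovery — sizes at which brute-force oracles remain exact and the whole
suite completes in seconds on one core.

## Known limitations

- Producibility only: no explanation paths, no flux, no yields.
- The competition threshold is applied to whichever weighting variant the
  caller selects; weighted is the default.
- Essentiality pooling across hosts is one defensible rule among several;
  the per-run breakdown in the report exists precisely so users can apply
  their own.
- The enumeration cap bounds memory on adversarial instances; capped runs
  refuse downstream classification instead of silently degrading.
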