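# Methods

## Bistructures and coordinates

Positions are 1-based; two formal vertices 0 and n+1 carry no nucleotide and
bound the rainbow arc (0, n+1) added to each layer.  The two rainbows are
distinct, layer-tagged objects, so every bistructure has exactly
|arcs(R)| + |arcs(S)| + 2 loops: each non-rainbow arc is maximal for exactly
one loop, plus the two exterior loops.  The canonical pair set is fixed to
{AU, UA, GC, CG, GU, UG}; rainbow arcs impose no sequence constraint.

Dot-bracket parsing accepts only `(`, `)` and `.` — bracket layers used for
pseudoknots are rejected, since the whole construction assumes
pseudoknot-free layers.  The minimum hairpin size defaults to 3 (physical);
0 is allowed so that formal examples (hairpins of size < 3, used throughout
the topology and DP test fixtures) are constructible.

## Energy models

`KT` is fixed at 0.61633 kcal/mol (gas constant × 310.15 K).

* **zero** — every loop contributes 0; partition functions become counts of
  bicompatible sequences.  Used for counting cross-checks.
* **arcpair** — a loop contributes a single term for its maximal arc:
  ε(GC/CG) = −3.0, ε(AU/UA) = −2.0, ε(GU/UG) = −1.0 kcal/mol; exterior loops
  contribute 0.  Because every arc is maximal for exactly one loop, the
  structure energy is the sum of ε over all arcs.  This model is cheap,
  sequence-dependent, and exactly enumerable — the workhorse of the test
  oracles.
* **turner** — a nearest-neighbor model read from the bundled plain-text
  tables (`src/bicompat/data/turner_params.txt`): stacking (6×6, rotation
  symmetric), hairpin initiation by size with a terminal mismatch (sizes
  0–2 carry a large penalty so formal loops remain finite), bulge initiation
  by size (size-1 bulges keep the flanking stack), interior initiation by
  size with both terminal mismatches and a capped asymmetry penalty
  (0.6·|s1−s2|, max 3.0), an affine multiloop a + b·branches + c·unpaired
  (a = 3.4, b = 0.4, c = 0.1; the closing arc counts as a branch), and
  exterior loops at 0.  Loops larger than 30 unpaired positions extrapolate
  logarithmically.  There are deliberately **no dangling ends, no coaxial
  stacking, and no tetraloop bonuses**: the model is this package's own
  parameterization of the standard loop types, not a bit-for-bit
  reproduction of any published folding program, and the ranking statistic
  accepts externally computed mfe energies through an adapter for users who
  want a specific folder.

## Partition function

For a substructure X (a loop subset), the table Q(X, τ) is indexed by
nucleotide assignments τ over X's key positions, bases ordered A < C < G < U
and positions ascending.  Removing loop L from X splits the rest into
irreducible components X_1..X_k and

    Q(X, τ_X) = Σ_σ  w(L, σ) · Π_i Q(X_i, τ_{X_i}),

where w is the loop's Boltzmann factor and each non-rainbow arc of L
contributes a canonical-pairing indicator.  Selectors weight loop energies
by layer: `avg` gives η(σ, B) (each loop at ½), `R_only`/`S_only` give the
restricted partition functions Q(R)|_S and Q(S)|_R, which sum over
bicompatible sequences only (sequences outside the bicompatible set have
undefined loop energies on the other layer, so Q(R) itself is computed on
the single-layer bistructure with S arc-free).  Scaling `1/n` divides
energies by n — the length-scaled variant used by the adaptability
densities.  The Boltzmann sign (negative exponent) is the default; a
`paper`/positive convention is selectable by flag, since with a positive
exponent the weighting of stable sequences inverts.

Numerics: tables are dense numpy arrays with one length-4 axis per key
position, renormalized by their maximum after every step; the logarithm of
the accumulated factor is tracked exactly, so results are returned as
(mantissa, log-offset) and never overflow.  Tables are keyed by the
positions actually read by factors applied later — the energy supports and
arc endpoints of already-removed loops — rather than by every shared vertex;
positions no factor ever reads contribute an exact factor of 4 each.  This
keeps the largest array within 4^κ of the schedule.  An internal audit
asserts that every position is summed exactly once.

## Scheduling and κ

The step cost of removing L from X is |L ∪ ⋃_i E^{X_i}| where a child's
exposed set is counted **against the substructure currently being
decomposed**: positions shared only with already-removed loops are not
charged again.  κ is the maximum step cost of a schedule.  Under this
accounting the nesting-order schedule — always remove the loop whose maximal
arc is outermost — matches the exhaustive minimum over all removal orders on
every crossing-free, overlap-free instance we generated (hundreds of
instances, up to 7 loops, exhaustively checked).  Counting exposure against
the full bistructure instead makes that schedule demonstrably suboptimal
(small counterexamples exist), which is why this convention was chosen.

The only incomparable pair in the nesting order is the two rainbows
(identical spans); `schedule_noncrossing` evaluates both resolutions of that
tie and keeps the cheaper schedule, with the R layer winning exact κ ties.

General instances are scheduled by first splitting overlaps — a vertex that
ends a non-rainbow arc in both layers becomes two adjacent positions,
attached so the two arcs nest or become disjoint, never cross — and then
greedily resolving crossing components: while a component contains crossing
maximal arcs, the involved loop whose removal costs least is taken (ties:
leftmost maximal arc, then layer R before S).  The greedy rule is this
package's concrete choice where only "greedy" is specified; mapping sphere
resolution to TSP-style optimization is explicitly not implemented.  A
schedule whose κ exceeds the cap (default 20, the practical reliability
limit for 4^κ table sizes) raises `KappaExceeded`; the cap is configurable.

## Topology

The loop nerve is enumerated per vertex: the loops containing a position
(at most four — two per layer) span all simplices through it, so no simplex
of dimension > 3 can exist and the complex is downward closed by
construction.  Homology ranks are computed from simplicial boundary
matrices with exact integer arithmetic (sympy), avoiding floating-point
rank instability; r2 equals the number of crossing components of the
overlap-split bistructure, and the two routes are cross-checked on every
tested instance.  The "tree-likeness" of the triangle structure is tested on
the bipartite incidence graph of triangles and their edges: several
triangles may share one and the same edge (a branch point) without forming a
closed band, and only closed bands — spheres — should count as cycles.  The
raw triangle-adjacency graph is still exported for inspection.  The quotient
space itself (apple-tree/ribbon visualization, homotopy classification) is
out of scope; only the computable signatures (r2, H0, H1, the band test) are
provided.

## Downstream statistics

* **Spectra** — half-open bins (a_{s−1}, a_s], anchor 0, width Δ = 1
  kcal/mol, default sample size 10^4.  A value exactly on an edge belongs to
  the bin it closes.
* **Ranking** — r_R = η(σ, R)/η(σ, M(σ)) with M the mfe structure folded
  under the active model (min hairpin 3); samples with mfe energy 0 have
  undefined ratios and are excluded with a warning.  External mfe energies
  can be supplied per sequence.
* **Adaptability** — w_R = Q̃(R)|_S / Q̃(R) with the 1/n-scaled DP.  The
  ratio lies in (0, 1] and is reported as the headline value, together with
  its (nonpositive) log; a log cannot itself "equal 1" when all sequences
  are bicompatible, so the ratio is taken as the intended quantity and both
  are emitted.

## Random structure pairs

`random_structure_pair` produces control pairs.  Defaults are the study
conditions: length 150 (the typical riboswitch scale) and
`fold_random_seq` — two uniform random sequences folded to their mfe
structures under the active model.  `uniform_structure` samples valid
structures directly (rejection-sampled arc insertion, min hairpin 3).  The
oracle-side `random_bistructure` generator uses min hairpin 0 so that formal
loops exercise the topology and DP code; energy-model tests that require
physical hairpins build their own fixtures.

## mfe folding

A Zuker-style DP over the active model: V(i,j) for paired spans (hairpin,
stack/bulge/interior capped at 30 unpaired, multiloop via an affine segment
matrix), exterior segments at 0.  The traceback is deterministic: at the
leftmost undecided position pairing is preferred over leaving the position
unpaired, and the smallest co-optimal partner is chosen.  This realizes *a*
minimum-energy structure whose energy equals the exhaustive minimum (checked
against full structure enumeration at small n); among co-optimal structures
the choice is deterministic but not guaranteed to be the globally
lexicographically smallest dot-bracket.

## What the synthetic generators do and do not show

The random bistructure generator produces sparse, uniform-ish arc sets; real
riboswitch structure pairs are longer, helix-dense, and strongly correlated
(shared switching sequences).  Passing tests therefore demonstrate
correctness of the algorithms (partition functions equal literal enumeration,
samplers hit the exact Boltzmann distribution, schedules are κ-optimal,
topological invariants hold), not biological claims about riboswitches.  The
qualitative spectrum-shift pattern — bicompatibility barely moves the energy
spectrum for non-conflicting pairs but shifts it for interleaved ones — is
reproduced on small enumerable pairs as a smoke check only.

## Known limitations

* The nearest-neighbor tables are a self-contained parameterization; ranking
  against a specific published folding program requires the external mfe
  adapter.
* The greedy sphere resolution carries no optimality guarantee; κ can exceed
  the optimum on crossing-heavy instances (the exhaustive oracle bounds this
  in tests).
* The DP's dense tables make κ ≈ 20 the practical ceiling; the Python
  implementation is comfortable for the test-scale instances (n ≤ ~40 and
  κ ≤ ~14) and is not tuned for genome-scale screening.
* Sampling for three or more simultaneous structures and sequence-masked
  sampling are not supported.
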