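# Methods

## Representation

A structure with N secondary structure elements (SSEs) is represented by
an N×N tableau and an N×N distance matrix.  SSEs are taken from a DSSP
summary-letter assignment (H→`xa`, G→`xg`, I→`xi`, E→`e`; other letters
are coil), as maximal single-type runs broken at chain boundaries.  Runs
shorter than 3 residues (helix) or 2 (strand) are discarded — these
defaults exist because 1–2-residue helices give no meaningful axis fit —
and are configurable.  Structures with no surviving SSEs raise an
`EmptyStructureError`; database builders skip them.

Each SSE's axis is fitted by total least squares: the principal direction
of the centered Cα coordinates (SVD), oriented so it points from the first
residue toward the last; with exactly two residues the normalized
difference is used.  TLS was chosen because it is rotation-invariant and
standard; the axis-fitting algorithm is otherwise an open design choice.

The interaxial angle of SSEs i<j is the angle between their axis vectors
projected onto the plane normal to their mutual perpendicular:
ω = atan2(u×w·n̂, u·w) with n̂ = ±(u×w)/‖u×w‖ flipped so that it points
from centroid i toward centroid j.  The i→j sign reference (using Cα
centroids, which double as the distance-matrix points) fixes the chirality
of the crossing-left/right distinction; without a fixed convention the
L/R and S/T letters would not be reproducible.  Axes with ‖u×w‖ < 1e-9
are treated as parallel (ω = 0) or anti-parallel (ω = 180) by the sign of
u·w.  The matrix stores ω(i,j) computed with i<j and mirrors it.

## Double-quadrant encoding

Angles are classified twice into four 90° sectors offset by 45°:

| first char | sector            | second char | sector          |
|------------|-------------------|-------------|-----------------|
| P          | [−45°, 45°)       | E           | [0°, 90°)       |
| R          | [45°, 135°)       | T           | [90°, 180°]     |
| O          | [135°,180°] ∪ (−180°,−135°) | D | [−90°, 0°)      |
| L          | [−135°, −45°)     | S           | (−180°, −90°)   |

Intervals are half-open toward increasing angle.  The offset guarantees a
perturbation below 45° changes at most one character, so near-identical
orientations always score ζ ≥ 1.  Anti-parallel pairs encode as OT
(positive ω, e.g. 143°) or OS (negative ω).  The assignment of E/D/S/T to
the rotated sectors is a fixed convention; only the OT/OS split at
anti-parallel angles is externally constrained, the placement of the other
two letters is arbitrary and documented here for reproducibility.

ζ(a, b) = 2 if a = b, 1 if the codes agree in exactly one character
position, −2 otherwise.  ζ is symmetric and total over the 16×16 table.

## Matching objective

State: a vector v of length N_A; v_i = j matches A's SSE i to B's SSE j
(1-based), v_i = 0 leaves it unmatched.  Nonzero entries are pairwise
distinct, class-compatible (the three helix types are one class, strands
the other), and in sequential mode strictly increasing.  The objective

g(v) = Σ over ordered pairs i ≠ k with v_i = j, v_k = l (both nonzero) of
ζ(t_ik^A, t_jl^B) if |d_ik^A − d_jl^B| ≤ τ, else 0.

Conventions chosen here: the sum runs over ordered pairs with the i = k
diagonal excluded (the diagonal holds SSE types, not codes), so every
unordered pair counts twice and the perfect self-match of an N-SSE
structure scores 2N(N−1); the distance threshold is realized as a soft
zero-contribution rule rather than a hard feasibility constraint.  The
uniform factor of two cancels in norm2-normalized comparisons.  Note that
g is not monotone in τ: a larger threshold admits additional pairs which
may carry ζ = −2.

## Simulated annealing

- Initialization: scanning i = 1..N_A, with probability p_m = 0.5 match
  SSE i to the lowest-index unused class-compatible SSE of B beyond the
  previously assigned index.  The result is order-preserving regardless of
  mode.
- Move: pick i uniformly; re-map it to a uniform choice from the feasible
  candidate set (class-compatible, unused, inside the ordering window in
  sequential mode, excluding the current assignment — a proposal always
  changes the state); if the set is empty, unmap the SSE.
- Acceptance: a proposal is accepted when its objective exceeds the best
  value seen so far in the schedule, or when exp(Δ/T) > p with p uniform
  on [0,1).  Since exp(Δ/T) ≥ 1 for Δ ≥ 0, this is Metropolis acceptance
  plus best-state tracking; `SearchParams.accept_reference="current"`
  selects the conventional better-than-current clause, which is
  behaviourally identical for the same reason.
- Schedule: T₀ = 10, T multiplied by α = 0.95 after every proposed move,
  100 moves per schedule; the best state visited is returned.
- Restarts: M = 128 by default; the best result over restarts is reported.
  Deltas are computed incrementally in O(N_A) per move and are exact in
  integer arithmetic (property-tested against full recomputation).

Defaults T₀, α, iteration count, p_m, M and τ = 4.0 Å are the method's
tuned operating point and are exposed in `SearchParams`.

## Determinism

Restart r of the comparison (query q, entry e) draws from a
`random.Random` stream seeded with the first 8 bytes of
SHA-256(f"{seed}|{q}|{e}|{r}").  Results are therefore bit-identical for
any worker count and any database ordering (size-sorting is purely a
scheduling aid), replacing per-thread generator banks with a
schedule-independent contract.  Ties between restarts keep the earliest
restart; exhaustive enumeration breaks ties toward the lexicographically
smallest state vector.

## Evaluation

Scores from multiple queries are pooled after normalization; self-pairs
are excluded; gold-standard pairs without a score receive
min(provided) − 1, a deterministic instance of "at least as low as the
lowest provided score".  AUC is the rank (Mann–Whitney) statistic with
half credit for ties — the convention of standard ROC packages — and its
standard error is the 1982 Hanley–McNeil closed form with Q₁ = A/(2−A),
Q₂ = 2A²/(1+A); the 95% interval is A ± 1.96·SE clipped to [0,1].  The Q
score utility N_align²/((1+(RMSD/3.0Å)²)·N₁·N₂) converts alignment
size/RMSD pairs into a comparable score.

## Synthetic data

Random entries are generated from actual 3D placements — centroids
uniform in a 40 Å box, uniform random axis directions, strand fraction
0.5 by default, helix subtypes drawn 0.8/0.15/0.05 (xa/xg/xi) — and then
encoded through the standard geometry path, so distance matrices are
metric and codes geometrically consistent with them.  Planted-motif
fixtures copy a host's tableau and distances exactly at chosen positions,
so the planted correspondence is feasible and scores ζ = 2 on every pair.
Ideal-geometry generators (α-helix: 1.5 Å rise, 100° twist, 2.3 Å radius;
strand: 3.5 Å step with ±0.25 Å zigzag — textbook constants fixed here
for reproducibility) exercise the axis-fitting and file-parsing pipeline
end to end via emitted PDB and DSSP-layout text.

What the synthetic generator does not emulate: real packing density,
sheet topology, SSE length/composition statistics, or assignment noise
from real DSSP output.  Passing tests therefore demonstrate correctness
of the encoding, objective, annealer and evaluation machinery — not
fold-classification accuracy on real structure databases, which requires
external data.  Test problem sizes (instances of ≤ 8 SSEs for exact
enumeration, 512 restarts for oracle-agreement checks, 15-SSE hosts for
motif recovery) were chosen so exhaustive oracles stay tractable.

## Numerical choices and edge cases

- Degenerate-parallel tolerance ‖u×w‖ < 1e-9; coincident points raise a
  degenerate-axis error.
- Database text stores distances to 3 decimals; round-trips are exact at
  that precision and write∘read∘write is byte-identical.
- Single-SSE entries are valid: empty lower triangle, score 0 against
  anything (no pairs exist).
- Multi-chain files: SSEs over all chains in file order unless a chain
  filter is given.  NMR multi-model files: first model only.  Altloc:
  highest occupancy, ties to the first altloc identifier.
- DSSP input: classic columnar layout (v2–v4); only residue number,
  insertion code, chain and summary letter columns are read.

## Known limitations

- Non-sequential mode is the default; whether published benchmark runs of
  comparable tools enabled the ordering constraint is generally unstated,
  so rankings under the two modes should be compared explicitly.
- The annealer is a heuristic: oracle-agreement guarantees are statistical
  (≥95/100 small instances) and degrade for large N with few restarts.
- No residue-level superposition or alignment extension is provided; the
  output correspondence is at SSE granularity.
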