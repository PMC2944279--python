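"""Maximally-similar subtableaux extraction by simulated annealing.

The matching problem: given two structures A and B with tableaux T_A, T_B
and SSE centroid distance matrices D_A, D_B, find an injective partial
mapping of A's SSEs onto B's SSEs (same helix/strand class, optionally
order-preserving) maximizing

    g(v) = Σ_{i≠k, v_i=j≠0, v_k=l≠0} ζ(t_ik^A, t_jl^B) · [|d_ik^A − d_jl^B| ≤ τ]

where the sum runs over ordered SSE pairs of A, so every unordered pair
counts twice and a perfect self-match of an N-SSE structure scores
2N(N−1).  Matched pairs whose intra-structure centroid distances differ by
more than the threshold τ contribute nothing.  The tableau diagonal holds
SSE types, not orientation codes, so i = k terms do not exist.

The state is a vector v of length N_A with v_i = j meaning SSE i of A is
matched to SSE j of B (1-based) and v_i = 0 meaning unmatched.  Annealing
starts from a random greedy-sequential initialization, proposes single-SSE
remappings, accepts a proposal when its objective exceeds the best value
seen so far or by the Metropolis rule exp(Δ/T) > p, and cools the
temperature geometrically (T_k = T0·α^k) after every proposed move.  The
best state visited is returned.  The whole schedule is restarted M times
from independent random initializations and the best result over all
restarts reported.  Proposal deltas are evaluated incrementally in O(N_A)
rather than by recomputing g.

Raw scores are compared across differently sized structures via the norm2
normalization, 2·score/(N_A + N_B).

Randomness: each restart draws from its own stream seeded by hashing
(seed, query id, entry id, restart index), so a database search is
bit-reproducible for any number of workers and any database ordering.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass
from typing import Sequence

from joblib import Parallel, delayed

from .codes import ALL_CODES, sse_class, zeta
from .containers import StructureEntry
from .db import TableauDatabase
from .errors import ValidationError

__all__ = [
    "MatchState",
    "SearchParams",
    "SearchResult",
    "objective_full",
    "objective_delta",
    "random_init",
    "propose_move",
    "anneal_once",
    "search_pair",
    "search_database",
    "norm2_score",
]

# ζ over integer-encoded codes (index = 4*first + second in P,O,L,R × E,D,S,T)
_CODE_INDEX = {c: k for k, c in enumerate(ALL_CODES)}
_ZETA16 = [[zeta(a, b) for b in ALL_CODES] for a in ALL_CODES]


@dataclass(frozen=True)
class MatchState:
    """An SSE correspondence: v[i] = j matches A's SSE i+1 to B's SSE j.

    Entries are 1-based indices into B; 0 means unmatched.  The vector is
    stored as a tuple so states are hashable and immutable.
    """

    v: tuple[int, ...]

    def __init__(self, v: Sequence[int]):
        object.__setattr__(self, "v", tuple(int(x) for x in v))

    def __len__(self) -> int:
        return len(self.v)

    @property
    def n_matched(self) -> int:
        return sum(1 for x in self.v if x)

    def pairs(self) -> list[tuple[int, int]]:
        """Matched (i, j) pairs, both 1-based."""
        return [(i + 1, j) for i, j in enumerate(self.v) if j]

    def validate(
        self, A: StructureEntry, B: StructureEntry, sequential: bool = False
    ) -> None:
        """Check length, range, injectivity, type-class and (optional) ordering."""
        if len(self.v) != A.n:
            raise ValidationError(f"state length {len(self.v)} != N_A = {A.n}")
        nonzero = [x for x in self.v if x]
        if any(not (1 <= x <= B.n) for x in nonzero):
            raise ValidationError(f"matched indices must lie in 1..{B.n}")
        if len(set(nonzero)) != len(nonzero):
            raise ValidationError("matched indices must be pairwise distinct")
        for i, j in enumerate(self.v):
            if j and sse_class(A.tableau.type(i)) != sse_class(B.tableau.type(j - 1)):
                raise ValidationError(
                    f"type-class mismatch: A SSE {i + 1} ({A.tableau.type(i)}) "
                    f"vs B SSE {j} ({B.tableau.type(j - 1)})"
                )
        if sequential and any(a >= b for a, b in zip(nonzero, nonzero[1:])):
            raise ValidationError("nonzero entries must be strictly increasing")


@dataclass(frozen=True)
class SearchParams:
    """Annealing schedule and matching options.

    Defaults are the tuned values: initial temperature T0 = 10, geometric
    cooling factor alpha = 0.95, 100 iterations per restart, initial match
    probability pm = 0.5, M = 128 restarts, distance-difference threshold
    tau = 4.0 Å.  ``sequential`` enables the order-preserving constraint
    (off by default: non-sequential matching is a headline capability).

    ``accept_reference`` selects the non-Metropolis acceptance clause:
    "best" accepts any proposal scoring above the best state seen so far
    in this restart (the default), "current" accepts any proposal scoring
    above the current state.  The two behave identically in practice
    because the Metropolis draw already accepts every non-worsening move.
    """

    T0: float = 10.0
    alpha: float = 0.95
    iterations: int = 100
    pm: float = 0.5
    restarts: int = 128
    tau: float = 4.0
    sequential: bool = False
    seed: int = 0
    accept_reference: str = "best"

    def __post_init__(self):
        if self.T0 <= 0 or not (0 < self.alpha < 1):
            raise ValidationError("need T0 > 0 and 0 < alpha < 1")
        if self.iterations < 1 or self.restarts < 1:
            raise ValidationError("iterations and restarts must be ≥ 1")
        if not 0.0 <= self.pm <= 1.0:
            raise ValidationError("pm must lie in [0, 1]")
        if self.tau <= 0:
            raise ValidationError("tau must be positive (Å)")
        if self.accept_reference not in ("best", "current"):
            raise ValidationError("accept_reference must be 'best' or 'current'")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of matching a query against one database entry."""

    db_id: str
    raw_score: int
    norm_score: float
    best_state: MatchState


def norm2_score(raw: int, nA: int, nB: int) -> float:
    """Size normalization: 2·raw/(nA + nB)."""
    if nA < 1 or nB < 1:
        raise ValidationError("structure sizes must be ≥ 1")
    return 2.0 * raw / (nA + nB)


# ---------------------------------------------------------------------------
# precomputed pair view for the hot loop (plain lists: faster than ndarray
# for scalar-indexed inner loops at tableau sizes)

class _Pair:
    __slots__ = ("nA", "nB", "zA", "zB", "dA", "dB", "cands", "tau", "sequential")

    def __init__(self, A: StructureEntry, B: StructureEntry, tau: float, sequential: bool):
        self.nA = A.n
        self.nB = B.n
        self.tau = float(tau)
        self.sequential = bool(sequential)
        self.zA = _code_index_matrix(A)
        self.zB = _code_index_matrix(B)
        self.dA = [[float(x) for x in row] for row in A.distances]
        self.dB = [[float(x) for x in row] for row in B.distances]
        class_B = [sse_class(B.tableau.type(j)) for j in range(B.n)]
        self.cands = []
        for i in range(A.n):
            ci = sse_class(A.tableau.type(i))
            self.cands.append([j + 1 for j in range(B.n) if class_B[j] == ci])


def _code_index_matrix(E: StructureEntry) -> list[list[int]]:
    n = E.n
    m = [[-1] * n for _ in range(n)]
    for i in range(n):
        for j in range(i):
            k = _CODE_INDEX[E.tableau.code(i, j)]
            m[i][j] = m[j][i] = k
    return m


def _contrib(pair: _Pair, v: list[int], i: int, j: int) -> int:
    """Score contributed by matching A's SSE i (0-based) to B's SSE j
    (1-based) against the other matched entries of v.  Covers both ordered
    pairs (i, k) and (k, i), hence the factor 2.  v[i] itself is ignored."""
    zAi = pair.zA[i]
    dAi = pair.dA[i]
    zBj = pair.zB[j - 1]
    dBj = pair.dB[j - 1]
    tau = pair.tau
    zeta16 = _ZETA16
    s = 0
    for k, l in enumerate(v):
        if l and k != i and abs(dAi[k] - dBj[l - 1]) <= tau:
            s += zeta16[zAi[k]][zBj[l - 1]]
    return 2 * s


def _objective(pair: _Pair, v: list[int]) -> int:
    # Σ_i contrib(i) counts every ordered pair twice over
    s = 0
    for i, j in enumerate(v):
        if j:
            s += _contrib(pair, v, i, j)
    return s // 2


def _feasible_moves(pair: _Pair, v: list[int], i: int) -> list[int]:
    """Candidate new mappings for SSE i: same class, unused elsewhere,
    ordering-feasible given the other entries (sequential mode), and
    different from the current v[i]."""
    vi = v[i]
    used = {x for k, x in enumerate(v) if x and k != i}
    if pair.sequential:
        lo = 0
        for k in range(i - 1, -1, -1):
            if v[k]:
                lo = v[k]
                break
        hi = pair.nB + 1
        for k in range(i + 1, pair.nA):
            if v[k]:
                hi = v[k]
                break
        return [j for j in pair.cands[i] if j != vi and j not in used and lo < j < hi]
    return [j for j in pair.cands[i] if j != vi and j not in used]


def _random_init(pair: _Pair, pm: float, rng: random.Random) -> list[int]:
    v = [0] * pair.nA
    last = 0
    for i in range(pair.nA):
        if rng.random() < pm:
            for j in pair.cands[i]:
                if j > last:
                    v[i] = j
                    last = j
                    break
    return v


def _propose(pair: _Pair, v: list[int], rng: random.Random) -> tuple[int, int]:
    i = rng.randrange(pair.nA)
    J = _feasible_moves(pair, v, i)
    if not J:
        return i, 0
    return i, J[rng.randrange(len(J))]


def _anneal(pair: _Pair, params: SearchParams, rng: random.Random) -> tuple[list[int], int]:
    v = _random_init(pair, params.pm, rng)
    g = _objective(pair, v)
    best = g
    best_v = list(v)
    track_best = params.accept_reference == "best"
    T = params.T0
    alpha = params.alpha
    exp = math.exp
    for _ in range(params.iterations):
        i, j_new = _propose(pair, v, rng)
        vi = v[i]
        if j_new == vi:
            delta = 0
        else:
            old = _contrib(pair, v, i, vi) if vi else 0
            new = _contrib(pair, v, i, j_new) if j_new else 0
            delta = new - old
        g_new = g + delta
        reference = best if track_best else g
        p = rng.random()
        # exp(Δ/T) ≥ 1 > p whenever Δ ≥ 0, so the guard only matters for
        # worsening moves; testing Δ ≥ 0 first also avoids overflow.
        if g_new > reference or delta >= 0 or exp(delta / T) > p:
            v[i] = j_new
            g = g_new
            if g > best:
                best = g
                best_v = list(v)
        T *= alpha
    return best_v, best


# ---------------------------------------------------------------------------
# public operations (validated wrappers over the hot-loop internals)


def objective_full(
    A: StructureEntry, B: StructureEntry, v: MatchState | Sequence[int], tau: float = 4.0
) -> int:
    """Evaluate g(v) exactly: the tableau matching score under the
    distance-difference threshold τ (Å), over ordered SSE pairs."""
    state = v if isinstance(v, MatchState) else MatchState(v)
    state.validate(A, B)
    pair = _Pair(A, B, tau, sequential=False)
    return _objective(pair, list(state.v))


def objective_delta(
    A: StructureEntry,
    B: StructureEntry,
    v: MatchState | Sequence[int],
    i: int,
    j_new: int,
    tau: float = 4.0,
) -> int:
    """Score change g(v′) − g(v) when SSE *i* (1-based) is remapped to
    *j_new* (1-based, 0 to unmap), computed in O(N_A).

    The resulting state must itself satisfy the matching invariants.
    """
    state = v if isinstance(v, MatchState) else MatchState(v)
    state.validate(A, B)
    if not 1 <= i <= A.n:
        raise ValidationError(f"SSE index {i} out of range 1..{A.n}")
    new_v = list(state.v)
    new_v[i - 1] = j_new
    MatchState(new_v).validate(A, B)
    pair = _Pair(A, B, tau, sequential=False)
    vi = state.v[i - 1]
    old = _contrib(pair, list(state.v), i - 1, vi) if vi else 0
    new = _contrib(pair, list(state.v), i - 1, j_new) if j_new else 0
    return new - old


def random_init(
    A: StructureEntry,
    B: StructureEntry,
    pm: float = 0.5,
    sequential: bool = False,
    rng: random.Random | None = None,
) -> MatchState:
    """Random initial state: scanning A's SSEs N→C, each is matched with
    probability *pm* to the lowest-index still-unused SSE of B of the same
    class beyond the previously assigned index.  The result is always
    sequential-valid, whichever mode the search then runs in."""
    rng = rng or random.Random()
    pair = _Pair(A, B, tau=1.0, sequential=sequential)
    return MatchState(_random_init(pair, pm, rng))


def propose_move(
    A: StructureEntry,
    B: StructureEntry,
    v: MatchState | Sequence[int],
    sequential: bool = False,
    tau: float = 4.0,
    rng: random.Random | None = None,
) -> tuple[int, int]:
    """Draw a neighbour move: a uniformly chosen SSE i of A (1-based) and a
    uniform candidate j from B satisfying the type, injectivity and
    (optionally) ordering constraints, excluding the current mapping.
    If no candidate exists, j = 0 (the SSE is removed from the mapping)."""
    rng = rng or random.Random()
    state = v if isinstance(v, MatchState) else MatchState(v)
    state.validate(A, B, sequential=sequential)
    pair = _Pair(A, B, tau, sequential=sequential)
    i, j = _propose(pair, list(state.v), rng)
    return i + 1, j


def anneal_once(
    A: StructureEntry,
    B: StructureEntry,
    params: SearchParams,
    rng: random.Random | None = None,
) -> tuple[MatchState, int]:
    """One annealing schedule from a fresh random initialization.

    Returns the best state visited and its objective value.
    """
    rng = rng or random.Random(params.seed)
    pair = _Pair(A, B, params.tau, params.sequential)
    best_v, best = _anneal(pair, params, rng)
    return MatchState(best_v), best


def _restart_rng(seed: int, qid: str, did: str, restart: int) -> random.Random:
    digest = hashlib.sha256(f"{seed}|{qid}|{did}|{restart}".encode()).digest()
    return random.Random(int.from_bytes(digest[:8], "little"))


def search_pair(
    A: StructureEntry, B: StructureEntry, params: SearchParams
) -> SearchResult:
    """Best match of query A against entry B over M independent restarts.

    Restart r draws from a stream seeded by hashing (seed, A.id, B.id, r),
    so the result does not depend on scheduling or database order.  Ties
    between restarts keep the earliest restart's state.
    """
    pair = _Pair(A, B, params.tau, params.sequential)
    best = None
    best_v: list[int] = [0] * A.n
    for r in range(params.restarts):
        rng = _restart_rng(params.seed, A.id, B.id, r)
        v, score = _anneal(pair, params, rng)
        if best is None or score > best:
            best = score
            best_v = v
    assert best is not None
    return SearchResult(
        db_id=B.id,
        raw_score=best,
        norm_score=norm2_score(best, A.n, B.n),
        best_state=MatchState(best_v),
    )


def search_database(
    query: StructureEntry,
    db: TableauDatabase,
    params: SearchParams,
    workers: int = 1,
) -> list[SearchResult]:
    """Match a query against every database entry, ranked by norm2 score
    (descending; ties broken by entry id).

    ``workers`` only controls process-level parallelism; the output is
    bit-identical for any value, as every (query, entry, restart) triple
    has its own seeded random stream.
    """
    if workers < 1:
        raise ValidationError("workers must be ≥ 1")
    entries = list(db)
    if not entries:
        return []
    if workers == 1 or len(entries) == 1:
        results = [search_pair(query, e, params) for e in entries]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(search_pair)(query, e, params) for e in entries
        )
    results.sort(key=lambda r: (-r.norm_score, r.db_id))
    return results
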