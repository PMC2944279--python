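"""Matching objective, annealing moves, restarts, determinism."""

import math
import random

import pytest

from tabsearch.containers import StructureEntry, Tableau
from tabsearch.db import TableauDatabase, sort_by_size
from tabsearch.errors import ValidationError
from tabsearch.fixtures import brute_force_optimum, gen_random_entry, plant_motif
from tabsearch.search import (
    MatchState,
    SearchParams,
    anneal_once,
    norm2_score,
    objective_delta,
    objective_full,
    propose_move,
    random_init,
    search_database,
    search_pair,
)


def _two_sse_pair(dA=10.0, dB=20.0, code="OT"):
    A = StructureEntry("A2", Tableau(["xa", "e"], [[], [code]]), [[0, dA], [dA, 0]])
    B = StructureEntry("B2", Tableau(["xa", "e"], [[], [code]]), [[0, dB], [dB, 0]])
    return A, B


# ------------------------------------------------------------- objective


def test_objective_empty_mapping_is_zero(small_pair):
    A, B = small_pair
    assert objective_full(A, B, [0] * A.n) == 0


def test_objective_self_match_counts_ordered_pairs():
    E = gen_random_entry(3, seed=9)
    assert objective_full(E, E, [1, 2, 3], tau=4.0) == 12  # 6 ordered pairs × ζ=2


def test_objective_distance_threshold_gates_contributions():
    A, B = _two_sse_pair(dA=10.0, dB=20.0)
    assert objective_full(A, B, [1, 2], tau=4.0) == 0
    assert objective_full(A, B, [1, 2], tau=15.0) == 4  # one unordered pair, counted twice


def test_tau_gates_a_growing_set_of_pairs(small_pair):
    """Raising τ admits a superset of contributing pairs; at τ = ∞ the
    objective equals the unconstrained tableau score.  (The score itself
    need not grow with τ — newly admitted pairs may carry ζ = −2.)"""
    A, B = small_pair
    rng = random.Random(0)
    v = list(random_init(A, B, pm=1.0, rng=rng).v)
    matched = [(i, j - 1) for i, j in enumerate(v) if j]

    def contributing(tau):
        return {
            (i, k)
            for (i, j) in matched
            for (k, l) in matched
            if i != k and abs(A.distances[i, k] - B.distances[j, l]) <= tau
        }

    def unconstrained():
        from tabsearch.codes import zeta

        return sum(
            zeta(A.tableau.code(i, k), B.tableau.code(j, l))
            for (i, j) in matched
            for (k, l) in matched
            if i != k
        )

    taus = (0.5, 2.0, 4.0, 10.0, 1e9)
    sets = [contributing(t) for t in taus]
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger
    assert objective_full(A, B, v, tau=1e9) == unconstrained()


def test_objective_rejects_invalid_states(small_pair):
    A, B = small_pair
    with pytest.raises(ValidationError):
        objective_full(A, B, [1, 1, 0, 0])  # not injective
    with pytest.raises(ValidationError):
        objective_full(A, B, [99, 0, 0, 0])  # out of range
    with pytest.raises(ValidationError):
        objective_full(A, B, [1, 0, 0])  # wrong length


def test_delta_noop_and_single_sse():
    A, B = _two_sse_pair()
    assert objective_delta(A, B, [1, 2], 1, 1, tau=15.0) == 0
    # unmapping one of two matched SSEs cancels the whole score
    assert objective_delta(A, B, [1, 2], 2, 0, tau=15.0) == -4


def test_delta_matches_full_recompute_randomly():
    """Exact integer agreement between O(N) delta and O(N²) recompute."""
    rng = random.Random(123)
    checked = 0
    for trial in range(60):
        nA = rng.randint(2, 8)
        nB = rng.randint(2, 8)
        A = gen_random_entry(nA, seed=300 + trial)
        B = gen_random_entry(nB, seed=600 + trial, entry_id=f"b{trial}")
        v = list(random_init(A, B, pm=0.7, rng=rng).v)
        for _ in range(20):
            i, j_new = propose_move(A, B, v, rng=rng)
            delta = objective_delta(A, B, v, i, j_new)
            before = objective_full(A, B, v)
            v[i - 1] = j_new
            after = objective_full(A, B, v)
            assert after - before == delta
            checked += 1
    assert checked == 1200


# ---------------------------------------------------------- init & moves


def test_random_init_pm_zero_and_one(small_pair):
    A, B = small_pair
    assert random_init(A, B, pm=0.0, rng=random.Random(1)).v == (0,) * A.n
    E = gen_random_entry(5, seed=77)
    assert random_init(E, E, pm=1.0, rng=random.Random(1)).v == (1, 2, 3, 4, 5)


def test_random_init_matched_fraction_tracks_pm():
    E = gen_random_entry(6, seed=88)
    rng = random.Random(42)
    total = matched = 0
    for _ in range(4000):
        v = random_init(E, E, pm=0.5, rng=rng).v
        matched += sum(1 for x in v if x)
        total += len(v)
    assert matched / total == pytest.approx(0.5, abs=0.02)


def test_random_init_always_sequential_valid(small_pair):
    A, B = small_pair
    rng = random.Random(3)
    for _ in range(200):
        random_init(A, B, pm=0.8, rng=rng).validate(A, B, sequential=True)


def test_propose_move_empty_candidates_unmaps():
    helix = gen_random_entry(2, type_mix=0.0, seed=1, entry_id="hh")
    strands = gen_random_entry(3, type_mix=1.0, seed=2, entry_id="ss")
    rng = random.Random(0)
    for _ in range(20):
        _, j = propose_move(helix, strands, [0, 0], rng=rng)
        assert j == 0


def test_propose_move_single_candidate():
    a = gen_random_entry(1, type_mix=0.0, seed=1, entry_id="a")
    b = gen_random_entry(1, type_mix=0.0, seed=2, entry_id="b")
    assert propose_move(a, b, [0], rng=random.Random(0)) == (1, 1)


def test_propose_move_uniform_over_candidates():
    """Each feasible (i, j) combination appears at its multinomial rate."""
    A = gen_random_entry(2, type_mix=0.0, seed=5, entry_id="q")
    B = gen_random_entry(5, type_mix=0.0, seed=6, entry_id="t")  # all helices
    rng = random.Random(9)
    counts = {}
    n_draws = 20000
    for _ in range(n_draws):
        i, j = propose_move(A, B, [1, 0], rng=rng)
        counts[(i, j)] = counts.get((i, j), 0) + 1
    # i uniform over 2; given i=1, J = {2..5} (4 options); given i=2, J = {2..5} too
    for (i, j), c in counts.items():
        p = 0.5 * 0.25
        sigma = math.sqrt(n_draws * p * (1 - p))
        assert abs(c - n_draws * p) < 4 * sigma, (i, j, c)


def test_propose_respects_sequential_window():
    E = gen_random_entry(4, type_mix=0.0, seed=11)
    rng = random.Random(2)
    for _ in range(300):
        i, j = propose_move(E, E, [0, 2, 0, 4], sequential=True, rng=rng)
        v = [0, 2, 0, 4]
        v[i - 1] = j
        MatchState(v).validate(E, E, sequential=True)


# ------------------------------------------------------------- annealing


def test_anneal_single_sse_scores_zero():
    a = gen_random_entry(1, type_mix=0.0, seed=1, entry_id="a")
    b = gen_random_entry(1, type_mix=0.0, seed=2, entry_id="b")
    state, score = anneal_once(a, b, SearchParams(seed=0), rng=random.Random(0))
    assert score == 0
    assert state.v in ((0,), (1,))


def test_greedy_limit_rejects_worsening_moves():
    """As T → 0 the Metropolis draw almost never accepts a worsening move."""
    rng = random.Random(6)
    accepted = 0
    trials = 10000
    T = 1e-12
    for _ in range(trials):
        delta = -rng.randint(1, 8)
        p = rng.random()
        if math.exp(delta / T) > p:
            accepted += 1
    assert accepted / trials < 1e-3


def test_search_pair_deterministic(small_pair):
    A, B = small_pair
    params = SearchParams(restarts=32, seed=17)
    r1 = search_pair(A, B, params)
    r2 = search_pair(A, B, params)
    assert r1 == r2


def test_restart_monotonicity(small_pair):
    """Best-of-M never decreases as M grows along the same seed stream."""
    A, B = small_pair
    scores = [
        search_pair(A, B, SearchParams(restarts=m, seed=3)).raw_score
        for m in (1, 2, 4, 8, 16, 32)
    ]
    assert scores == sorted(scores)


def test_search_pair_never_beats_brute_force():
    for k in range(15):
        A = gen_random_entry(random.Random(k).randint(2, 5), seed=50 + k)
        B = gen_random_entry(random.Random(k + 99).randint(2, 5), seed=80 + k, entry_id=f"b{k}")
        opt, _ = brute_force_optimum(A, B)
        got = search_pair(A, B, SearchParams(restarts=64, seed=k)).raw_score
        assert got <= opt


def test_substructure_containment_scores_full_motif():
    fx = plant_motif(12, (2, 5, 7, 10), seed=31)
    n_m = fx.motif.n
    result = search_pair(
        fx.motif, fx.host, SearchParams(restarts=256, sequential=True, seed=8)
    )
    assert result.raw_score == 2 * n_m * (n_m - 1)


def test_norm2_score():
    assert norm2_score(12, 3, 3) == 4.0
    assert norm2_score(0, 7, 9) == 0.0
    assert norm2_score(10, 4, 6) == 2.0
    with pytest.raises(ValidationError):
        norm2_score(1, 0, 3)


# ------------------------------------------------------- database search


def test_search_database_self_ranks_first():
    db = TableauDatabase(
        [gen_random_entry(5, seed=200 + k, entry_id=f"d{k}") for k in range(6)]
    )
    query = db.get("d3")
    results = search_database(query, db, SearchParams(restarts=64, seed=4))
    assert results[0].db_id == "d3"
    assert results[0].raw_score == 2 * 5 * 4


def test_search_database_worker_and_order_invariance():
    db = TableauDatabase(
        [gen_random_entry(3 + k % 3, seed=400 + k, entry_id=f"e{k}") for k in range(5)]
    )
    query = gen_random_entry(4, seed=999, entry_id="q")
    params = SearchParams(restarts=16, seed=12)
    serial = search_database(query, db, params, workers=1)
    parallel = search_database(query, db, params, workers=4)
    shuffled = search_database(query, sort_by_size(db), params, workers=1)
    assert serial == parallel == shuffled


def test_search_database_empty():
    q = gen_random_entry(3, seed=1)
    assert search_database(q, TableauDatabase(), SearchParams()) == []
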