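"""Synthetic entries, planted motifs, ideal geometry, brute-force oracle."""

import io
import itertools

import numpy as np
import pytest

from tabsearch.db import TableauDatabase, read_db, write_db
from tabsearch.errors import ValidationError
from tabsearch.fixtures import (
    brute_force_optimum,
    gen_ideal_coords,
    gen_random_entry,
    plant_motif,
)
from tabsearch.pipeline import fit_axis, interaxial_angle, SSEDescriptor
from tabsearch.search import objective_full


def test_gen_random_entry_deterministic_and_minimal():
    a = gen_random_entry(6, seed=5)
    b = gen_random_entry(6, seed=5)
    assert a == b
    single = gen_random_entry(1, seed=0)
    assert single.n == 1 and single.tableau.lower_rows() == [[]]


def test_gen_random_entry_distances_are_metric():
    e = gen_random_entry(7, seed=2)
    d = e.distances
    n = e.n
    for i, j, k in itertools.permutations(range(n), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_gen_random_entry_type_mix_extremes():
    assert all(t == "e" for t in gen_random_entry(8, type_mix=1.0, seed=1).tableau.types)
    assert all(t != "e" for t in gen_random_entry(8, type_mix=0.0, seed=1).tableau.types)


def test_plant_motif_is_exact_restriction():
    fx = plant_motif(12, (2, 5, 9), seed=3)
    assert fx.motif.n == 3
    pos0 = [p - 1 for p in fx.planted_map]
    for a in range(3):
        assert fx.motif.tableau.type(a) == fx.host.tableau.type(pos0[a])
        for b in range(a):
            assert fx.motif.tableau.code(a, b) == fx.host.tableau.code(pos0[a], pos0[b])
            assert fx.motif.distances[a, b] == fx.host.distances[pos0[a], pos0[b]]


def test_planted_map_scores_perfectly():
    fx = plant_motif(12, (2, 5, 9), seed=3)
    assert objective_full(fx.motif, fx.host, fx.planted_state(), tau=4.0) == 12
    opt, _ = brute_force_optimum(fx.motif, fx.host, max_n=12)
    assert opt >= 12


def test_plant_motif_validates_positions():
    for bad in [(5, 2), (0, 3), (1,), (3, 3, 7), (2, 99)]:
        with pytest.raises(ValidationError):
            plant_motif(10, bad, seed=0)


def test_ideal_strand_stays_near_line():
    coords, axis = gen_ideal_coords("strand", 8)
    t = coords @ axis
    perp = coords - np.outer(t, axis)
    perp -= perp.mean(axis=0)
    assert np.linalg.norm(perp, axis=1).max() < 0.5


def test_ideal_antiparallel_helices():
    h1, _ = gen_ideal_coords("helix", 12, origin=(0, 0, 0), direction=(0, 0, 1))
    h2, _ = gen_ideal_coords("helix", 12, origin=(8, 0, 16.5), direction=(0, 0, -1))
    sses = []
    for k, coords in enumerate([h1, h2]):
        point, d = fit_axis(coords)
        sses.append(
            SSEDescriptor(
                index=k + 1, type="xa", chain="A", first_res=(1, ""),
                last_res=(12, ""), ca_coords=coords,
                centroid=coords.mean(axis=0), axis_point=point, axis_dir=d,
            )
        )
    assert abs(abs(interaxial_angle(sses[0], sses[1])) - 180.0) < 10.0


def test_ideal_coords_input_guards():
    with pytest.raises(ValidationError):
        gen_ideal_coords("helix", 3)
    with pytest.raises(ValidationError):
        gen_ideal_coords("sheet", 8)
    with pytest.raises(ValidationError):
        gen_ideal_coords("strand", 5, direction=(0, 0, 0))


# ----------------------------------------------------------------- oracle


def test_brute_force_self_match_sequential_identity():
    E = gen_random_entry(3, seed=1)
    score, state = brute_force_optimum(E, E, sequential=True)
    assert score == 12 and state.v == (1, 2, 3)


def test_brute_force_single_sse_scores_zero():
    a = gen_random_entry(1, type_mix=0.0, seed=1, entry_id="a")
    b = gen_random_entry(1, type_mix=0.0, seed=2, entry_id="b")
    score, _ = brute_force_optimum(a, b)
    assert score == 0


def test_brute_force_never_takes_negative_pairs():
    """When every cross-pair scores ζ = −2, the optimum is the empty map."""
    from tabsearch.containers import StructureEntry, Tableau

    n = 3
    centroid_d = np.zeros((n, n))
    A = StructureEntry("pe", Tableau(["e"] * n, [["PE"] * i for i in range(n)]), centroid_d)
    B = StructureEntry("ot", Tableau(["e"] * n, [["OT"] * i for i in range(n)]), centroid_d)
    score, state = brute_force_optimum(A, B, tau=1e9)
    assert score == 0
    assert state.n_matched <= 1


def test_brute_force_sequential_never_beats_free():
    for k in range(8):
        A = gen_random_entry(4, seed=700 + k)
        B = gen_random_entry(5, seed=800 + k, entry_id=f"b{k}")
        seq, _ = brute_force_optimum(A, B, sequential=True)
        free, _ = brute_force_optimum(A, B, sequential=False)
        assert seq <= free


def test_brute_force_permutation_covariance():
    """Relabelling B's SSEs permutes the optimal state, same score."""
    A = gen_random_entry(4, seed=900)
    B = gen_random_entry(4, seed=901, entry_id="b")
    perm = [2, 0, 3, 1]  # B's old index -> position in permuted B
    from tabsearch.containers import StructureEntry, Tableau

    inv = np.argsort(perm)
    types = [B.tableau.type(inv[i]) for i in range(4)]
    codes = [
        [B.tableau.code(inv[i], inv[j]) for j in range(i)] for i in range(4)
    ]
    d = B.distances[np.ix_(inv, inv)]
    Bp = StructureEntry("bp", Tableau(types, codes), d)

    s1, v1 = brute_force_optimum(A, B, tau=4.0)
    s2, v2 = brute_force_optimum(A, Bp, tau=4.0)
    assert s1 == s2
    mapped = tuple(perm[j - 1] + 1 if j else 0 for j in v1.v)
    assert objective_full(A, Bp, mapped, tau=4.0) == s1


def test_brute_force_size_guard():
    big = gen_random_entry(8, seed=0)
    with pytest.raises(ValidationError):
        brute_force_optimum(big, big)


def test_generated_entries_survive_db_round_trip():
    db = TableauDatabase([gen_random_entry(5, seed=k, entry_id=f"g{k}") for k in range(3)])
    buf = io.StringIO()
    write_db(db, buf)
    db2 = read_db(io.StringIO(buf.getvalue()))
    for a, b in zip(db, db2):
        assert a.tableau == b.tableau  # codes re-encode identically
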