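"""Synthetic inputs with known structure, and the exhaustive-search oracle.

Everything here exists so the matcher can be validated without external
data: random structure entries derived from actual 3D SSE placements (so
distance matrices are metric and orientation codes geometrically
consistent), hosts with exactly-copied planted motifs, ideal-geometry
helix/strand coordinates for exercising the axis-fitting pipeline, and a
brute-force enumerator of all feasible matchings for use as an oracle on
small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import StructureEntry
from .errors import ValidationError
from .pipeline import SSEDescriptor, build_entry
from .search import MatchState, _Pair, _objective

__all__ = [
    "PlantedMotifFixture",
    "gen_random_entry",
    "plant_motif",
    "gen_ideal_coords",
    "brute_force_optimum",
    "ideal_pdb_text",
    "ideal_dssp_text",
]

# ideal-geometry constants (textbook values, fixed for reproducibility)
HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å
STRAND_STEP = 3.5      # Å per residue along the axis
STRAND_ZIGZAG = 0.25   # Å perpendicular offset, alternating sign

_HELIX_SUBTYPES = ["xa", "xg", "xi"]
_HELIX_WEIGHTS = [0.8, 0.15, 0.05]


@dataclass(frozen=True)
class PlantedMotifFixture:
    """A host entry, the motif cut out of it, and the planted correspondence.

    The motif's tableau codes and distances are exact copies of the host's
    restricted to the planted positions, so the planted map is a feasible
    matching whose every SSE pair contributes ζ = 2.
    """

    host: StructureEntry
    motif: StructureEntry
    planted_map: tuple[int, ...]  # 1-based host position of each motif SSE

    def planted_state(self) -> MatchState:
        """The planted correspondence as a motif→host match state."""
        return MatchState(self.planted_map)


def _random_sses(n: int, type_mix: float, rng: np.random.Generator) -> list[SSEDescriptor]:
    sses = []
    for i in range(n):
        if rng.random() < type_mix:
            t = "e"
        else:
            t = _HELIX_SUBTYPES[rng.choice(len(_HELIX_SUBTYPES), p=_HELIX_WEIGHTS)]
        centroid = rng.uniform(0.0, 40.0, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        # two token Cα points so descriptors are well-formed
        coords = np.array([centroid - 2.0 * d, centroid + 2.0 * d])
        sses.append(
            SSEDescriptor(
                index=i + 1,
                type=t,
                chain="A",
                first_res=(2 * i + 1, ""),
                last_res=(2 * i + 2, ""),
                ca_coords=coords,
                centroid=centroid,
                axis_point=centroid,
                axis_dir=d,
            )
        )
    return sses


def gen_random_entry(
    n: int, type_mix: float = 0.5, seed: int = 0, entry_id: str | None = None
) -> StructureEntry:
    """Random structure entry built from random 3D SSE placements.

    *n* SSEs with centroids uniform in a 40 Å box and uniform random axis
    directions; each SSE is a strand with probability ``type_mix``, else a
    helix (mostly α, occasionally 3₁₀ or π).  Codes and distances are
    derived through the standard geometry → tableau path, so they are
    mutually consistent and distances are metric.
    """
    if n < 1:
        raise ValidationError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    sses = _random_sses(n, type_mix, rng)
    return build_entry(entry_id or f"rand{n}s{seed}", sses)


def plant_motif(
    host_n: int,
    motif_positions,
    seed: int = 0,
    type_mix: float = 0.5,
) -> PlantedMotifFixture:
    """Generate a random host and cut an exact motif out of it.

    ``motif_positions`` are strictly increasing 1-based host SSE indices
    (at least two).  The motif entry is the exact restriction of the host's
    tableau and distance matrix to those positions.
    """
    positions = tuple(int(p) for p in motif_positions)
    if len(positions) < 2:
        raise ValidationError("need at least two motif positions")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValidationError("motif positions must be strictly increasing")
    if positions[0] < 1 or positions[-1] > host_n:
        raise ValidationError(f"motif positions must lie in 1..{host_n}")
    host = gen_random_entry(host_n, type_mix=type_mix, seed=seed, entry_id=f"host{host_n}s{seed}")
    idx0 = [p - 1 for p in positions]
    motif = StructureEntry(
        id=f"motif{len(positions)}s{seed}",
        tableau=host.tableau.restrict(idx0),
        distances=host.distances[np.ix_(idx0, idx0)],
    )
    return PlantedMotifFixture(host=host, motif=motif, planted_map=positions)


def gen_ideal_coords(
    kind: str,
    n_res: int,
    origin=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal-geometry Cα coordinates and the generating axis direction.

    ``kind="helix"``: α-helical spiral (rise 1.5 Å/residue, 100°/residue,
    radius 2.3 Å) around the given axis; needs ≥ 4 residues.
    ``kind="strand"``: points every 3.5 Å along the axis with a ±0.25 Å
    perpendicular zigzag; needs ≥ 2 residues.

    Returns ``(coords, axis_dir)`` with ``axis_dir`` the unit generating
    axis, against which a fitted axis can be checked.  The seed only picks
    the (arbitrary) phase frame perpendicular to the axis.
    """
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        raise ValidationError("direction must be a nonzero vector")
    w = direction / nrm
    origin = np.asarray(origin, dtype=float)

    # orthonormal frame perpendicular to w
    rng = np.random.default_rng(seed)
    trial = rng.normal(size=3)
    u = trial - w * float(np.dot(trial, w))
    while np.linalg.norm(u) < 1e-6:
        trial = rng.normal(size=3)
        u = trial - w * float(np.dot(trial, w))
    u /= np.linalg.norm(u)
    v = np.cross(w, u)

    if kind == "helix":
        if n_res < 4:
            raise ValidationError("an ideal helix needs ≥ 4 residues")
        coords = []
        for k in range(n_res):
            theta = math.radians(HELIX_TWIST * k)
            coords.append(
                origin
                + HELIX_RISE * k * w
                + HELIX_RADIUS * (math.cos(theta) * u + math.sin(theta) * v)
            )
        return np.array(coords), w
    if kind == "strand":
        if n_res < 2:
            raise ValidationError("a strand needs ≥ 2 residues")
        coords = [
            origin + STRAND_STEP * k * w + ((-1) ** k) * STRAND_ZIGZAG * u
            for k in range(n_res)
        ]
        return np.array(coords), w
    raise ValidationError(f"kind must be 'helix' or 'strand', got {kind!r}")


def brute_force_optimum(
    A: StructureEntry,
    B: StructureEntry,
    tau: float = 4.0,
    sequential: bool = False,
    max_n: int = 7,
) -> tuple[int, MatchState]:
    """Exact optimum of the matching objective by exhaustive enumeration.

    Enumerates every type-valid injective (and, in sequential mode,
    order-preserving) partial mapping in lexicographic order of the state
    vector and evaluates the objective exactly; ties therefore resolve to
    the lexicographically smallest optimal state.  Refuses instances with
    more than ``max_n`` SSEs on either side.
    """
    if A.n > max_n or B.n > max_n:
        raise ValidationError(
            f"instance too large to enumerate (N_A={A.n}, N_B={B.n}, guard={max_n})"
        )
    pair = _Pair(A, B, tau, sequential)
    best_score = None
    best_v: list[int] | None = None
    v = [0] * A.n

    def recurse(i: int, used: set[int], last: int):
        nonlocal best_score, best_v
        if i == A.n:
            score = _objective(pair, v)
            if best_score is None or score > best_score:
                best_score = score
                best_v = list(v)
            return
        # lexicographic: 0 (unmatched) first, then ascending j
        v[i] = 0
        recurse(i + 1, used, last)
        for j in pair.cands[i]:
            if j in used:
                continue
            if sequential and j <= last:
                continue
            v[i] = j
            used.add(j)
            recurse(i + 1, used, j if sequential else last)
            used.remove(j)
        v[i] = 0

    recurse(0, set(), 0)
    assert best_score is not None and best_v is not None
    return best_score, MatchState(best_v)


# ---------------------------------------------------------------------------
# minimal text emitters for end-to-end pipeline tests (synthetic data)


def ideal_pdb_text(segments) -> str:
    """PDB-format text for a list of Cα coordinate arrays (synthetic).

    Each segment becomes a run of consecutive alanine residues in chain A
    with only Cα atoms; segments are numbered contiguously.
    """
    lines = []
    serial = 1
    resseq = 1
    for coords in segments:
        for xyz in np.asarray(coords, dtype=float):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA A{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
            resseq += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def ideal_dssp_text(segment_letters) -> str:
    """Classic-layout DSSP-format text matching :func:`ideal_pdb_text`
    (synthetic; columns beyond residue/chain/structure are padding).

    ``segment_letters`` gives one DSSP summary letter per segment, applied
    to every residue of that segment (use ' ' for coil).
    """
    lines = [
        "==== Synthetic secondary structure assignment (DSSP layout) ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    serial = 1
    resseq = 1
    for letters in segment_letters:
        n, letter = letters
        for _ in range(n):
            lines.append(f"{serial:5d}{resseq:5d} A A  {letter}")
            serial += 1
            resseq += 1
    return "\n".join(lines) + "\n"


def write_random_db(n_entries: int, sizes, seed: int = 0, type_mix: float = 0.5):
    """A TableauDatabase of random entries (sizes cycled from ``sizes``)."""
    from .db import TableauDatabase

    db = TableauDatabase()
    sizes = list(sizes)
    for k in range(n_entries):
        n = sizes[k % len(sizes)]
        db.add(
            gen_random_entry(
                n, type_mix=type_mix, seed=seed + k, entry_id=f"syn{k:03d}n{n}"
            )
        )
    return db
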