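"""Build tableaux and distance matrices from coordinates and secondary
structure assignments.

The pipeline is: parse Cα coordinates from a PDB file, parse per-residue
secondary structure letters from a DSSP file, merge the two into SSE
descriptors (runs of helix/strand residues with fitted axes and Cα
centroids), then derive the orientation matrix of signed interaxial angles
and encode it as a tableau alongside the centroid distance matrix.

Sign convention for interaxial angles: for a pair (i, j) with i < j in
N→C order, the mutual-perpendicular reference axis n̂ is the normalized
cross product of the two SSE axis directions, flipped if necessary so that
it points from centroid i toward centroid j.  The signed angle is then
atan2(u×w · n̂, u·w).  The orientation matrix stores ω(i, j) computed with
i < j and defines ω(j, i) = ω(i, j), so the encoded tableau is symmetric by
construction.  A fixed convention is required for the chirality-sensitive
code letters (L/R and S/T) to be reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codes import encode_angle
from .containers import StructureEntry, Tableau
from .errors import (
    DegenerateAxisError,
    EmptyStructureError,
    InputError,
    ParseError,
    ValidationError,
)

__all__ = [
    "CAResidue",
    "SSEDescriptor",
    "read_calpha",
    "parse_dssp",
    "assign_sses",
    "fit_axis",
    "interaxial_angle",
    "orientation_matrix",
    "build_entry",
    "attach_geometry",
    "entry_from_files",
    "DEFAULT_MIN_LENGTHS",
]

#: Minimum residues per SSE class; shorter runs are discarded.  One- and
#: two-residue helices give no meaningful axis fit.
DEFAULT_MIN_LENGTHS: Mapping[str, int] = {"helix": 3, "strand": 2}

#: DSSP summary letters mapped to SSE type codes.  Letters not listed
#: (T, S, B, blank, ...) are treated as coil.
_DSSP_LETTER_TO_TYPE = {"H": "xa", "G": "xg", "I": "xi", "E": "e"}

_TYPE_CLASS = {"e": "strand", "xa": "helix", "xi": "helix", "xg": "helix"}


@dataclass(frozen=True)
class CAResidue:
    """One residue with its Cα coordinate, as read from a PDB file."""

    chain: str
    resseq: int
    icode: str  # insertion code, "" if none
    resname: str
    ca: np.ndarray  # 3-vector, Å

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)


@dataclass
class SSEDescriptor:
    """One secondary structure element with geometry.

    ``index`` is the 1-based ordinal from the N- to the C-terminus after
    short runs have been filtered out.  Geometry fields (``ca_coords``,
    ``centroid``, ``axis_point``, ``axis_dir``) are attached by
    :func:`attach_geometry`; descriptors fresh from :func:`assign_sses`
    carry only the residue range.
    """

    index: int
    type: str
    chain: str
    first_res: tuple[int, str]
    last_res: tuple[int, str]
    ca_coords: np.ndarray | None = None
    centroid: np.ndarray | None = None
    axis_point: np.ndarray | None = None
    axis_dir: np.ndarray | None = None

    @property
    def n_res(self) -> int:
        if self.ca_coords is None:
            raise ValidationError("geometry not attached")
        return len(self.ca_coords)


def read_calpha(pdb_file, chain_filter: str | None = None) -> list[CAResidue]:
    """Read ordered Cα coordinates from a PDB-format file.

    Only the first model of multi-model (NMR) files is used.  Alternate
    locations are resolved to the highest-occupancy conformer (ties broken
    by altloc identifier order).  Residues without a Cα atom are skipped.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("s", pdb_file)
    except Exception as exc:
        raise InputError(f"cannot parse PDB file {pdb_file}: {exc}") from exc

    models = list(structure.get_models())
    if not models:
        raise InputError(f"no models in PDB file {pdb_file}")
    model = models[0]

    residues: list[CAResidue] = []
    for chain in model:
        if chain_filter is not None and chain.id != chain_filter:
            continue
        for res in chain:
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                children = sorted(
                    atom.disordered_get_list(),
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                )
                atom = children[0]
            hetflag, resseq, icode = res.get_id()
            residues.append(
                CAResidue(
                    chain=chain.id,
                    resseq=resseq,
                    icode=icode.strip(),
                    resname=res.get_resname(),
                    ca=np.array(atom.get_coord(), dtype=float),
                )
            )
    if not residues:
        raise InputError(f"no Cα atoms found in {pdb_file}")
    return residues


def parse_dssp(dssp_file) -> list[tuple[str, int, str, str]]:
    """Parse a classic-format DSSP file into (chain, resseq, icode, letter).

    Only the residue identifier, chain and summary structure columns are
    read.  Chain-break records ('!') are returned with letter '!' so run
    detection can split on them.
    """
    if hasattr(dssp_file, "read"):
        text = dssp_file.read()
    else:
        try:
            text = Path(dssp_file).read_text()
        except OSError as exc:
            raise InputError(f"cannot read DSSP file {dssp_file}: {exc}") from exc

    lines = text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = k + 1
            break
    if start is None:
        raise ParseError("no '#  RESIDUE AA ...' header found in DSSP file")

    out: list[tuple[str, int, str, str]] = []
    for k in range(start, len(lines)):
        line = lines[k]
        if len(line) < 14 or not line[:5].strip():
            continue
        if line[13] == "!":
            out.append(("", 0, "", "!"))
            continue
        if len(line) < 17:
            raise ParseError("truncated DSSP residue record", line=k + 1)
        try:
            resseq = int(line[5:10])
        except ValueError as exc:
            raise ParseError(
                f"bad residue number {line[5:10]!r}", line=k + 1
            ) from exc
        icode = line[10].strip()
        chain = line[11].strip()
        ss = line[16].strip()
        out.append((chain, resseq, icode, ss))
    if not any(rec[3] != "!" for rec in out):
        raise ParseError("DSSP file contains no residue records")
    return out


def assign_sses(
    dssp_file,
    min_lengths: Mapping[str, int] | None = None,
    chain_filter: str | None = None,
) -> list[SSEDescriptor]:
    """Extract SSE descriptors (without geometry) from a DSSP file.

    Maximal runs of residues sharing one mapped type (H→xa, G→xg, I→xi,
    E→e) become SSEs; runs are broken by chain changes and chain-break
    records.  Runs shorter than the per-class minimum (helix/strand) are
    discarded, then survivors are numbered 1..N from the N-terminus.

    Raises :class:`EmptyStructureError` if nothing survives, mirroring the
    convention of omitting structures with no assigned SSEs.
    """
    if min_lengths is None:
        min_lengths = DEFAULT_MIN_LENGTHS
    records = parse_dssp(dssp_file)

    runs: list[tuple[str, str, tuple[int, str], tuple[int, str], int]] = []
    cur_type = None
    cur_chain = None
    cur_first = cur_last = None
    cur_len = 0

    def close():
        nonlocal cur_type, cur_len
        if cur_type is not None:
            runs.append((cur_type, cur_chain, cur_first, cur_last, cur_len))
        cur_type = None
        cur_len = 0

    for chain, resseq, icode, letter in records:
        if letter == "!" or (chain_filter is not None and chain != chain_filter):
            close()
            continue
        sse_type = _DSSP_LETTER_TO_TYPE.get(letter)
        if sse_type is None:
            close()
            continue
        if sse_type == cur_type and chain == cur_chain:
            cur_last = (resseq, icode)
            cur_len += 1
        else:
            close()
            cur_type = sse_type
            cur_chain = chain
            cur_first = cur_last = (resseq, icode)
            cur_len = 1
    close()

    sses = []
    for sse_type, chain, first, last, length in runs:
        if length < min_lengths.get(_TYPE_CLASS[sse_type], 1):
            continue
        sses.append(
            SSEDescriptor(
                index=len(sses) + 1,
                type=sse_type,
                chain=chain,
                first_res=first,
                last_res=last,
            )
        )
    if not sses:
        raise EmptyStructureError("no SSEs after assignment and length filtering")
    return sses


def fit_axis(ca_coords) -> tuple[np.ndarray, np.ndarray]:
    """Fit an axis to an ordered run of Cα positions.

    Returns ``(axis_point, axis_dir)`` where ``axis_point`` is the centroid
    and ``axis_dir`` the unit principal direction of the centered
    coordinates (total least squares), oriented so it points from the first
    residue toward the last.  With exactly two residues the direction is
    simply the normalized difference.
    """
    x = np.asarray(ca_coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise ValidationError(f"need ≥ 2 Cα coordinates as (m, 3), got {x.shape}")
    centroid = x.mean(axis=0)
    span = x[-1] - x[0]
    if x.shape[0] == 2:
        norm = np.linalg.norm(span)
        if norm < 1e-9:
            raise DegenerateAxisError("the two Cα positions coincide")
        return centroid, span / norm
    centered = x - centroid
    # principal direction via SVD (total least squares)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateAxisError("all Cα positions coincide")
    direction = vt[0]
    if float(np.dot(direction, span)) < 0:
        direction = -direction
    return centroid, direction


def interaxial_angle(sse_i: SSEDescriptor, sse_j: SSEDescriptor) -> float:
    """Signed interaxial angle between two SSE axes, degrees in (−180, 180].

    The angle between the axis vectors projected onto the plane normal to
    their mutual perpendicular; the sign reference points from centroid i
    toward centroid j.  Exactly (anti-)parallel axes return 0 or 180.
    """
    for s in (sse_i, sse_j):
        if s.axis_dir is None or s.centroid is None:
            raise ValidationError(f"SSE {s.index} has no fitted axis")
    u = np.asarray(sse_i.axis_dir, dtype=float)
    w = np.asarray(sse_j.axis_dir, dtype=float)
    cross = np.cross(u, w)
    cross_norm = float(np.linalg.norm(cross))
    if cross_norm < 1e-9:
        return 0.0 if float(np.dot(u, w)) > 0 else 180.0
    n = cross / cross_norm
    sep = np.asarray(sse_j.centroid, dtype=float) - np.asarray(sse_i.centroid, dtype=float)
    if float(np.dot(n, sep)) < 0:
        n = -n
    angle = math.degrees(math.atan2(float(np.dot(cross, n)), float(np.dot(u, w))))
    if angle <= -180.0:
        angle += 360.0
    return angle


def orientation_matrix(sses: Sequence[SSEDescriptor]) -> np.ndarray:
    """Symmetric matrix of signed interaxial angles ω(i, j), degrees.

    ω(i, j) is computed with i < j in N→C order and mirrored; the diagonal
    is zero by convention (it is never encoded).
    """
    n = len(sses)
    omega = np.zeros((n, n))
    for j in range(n):
        for i in range(j):
            a = interaxial_angle(sses[i], sses[j])
            omega[i, j] = omega[j, i] = a
    return omega


def attach_geometry(
    sses: Iterable[SSEDescriptor], residues: Sequence[CAResidue]
) -> list[SSEDescriptor]:
    """Fill in Cα coordinates, centroid and fitted axis for each SSE.

    Residues are matched by (chain, resseq, icode) between the DSSP-derived
    range endpoints and the PDB-derived residue list; the run is the
    contiguous slice between the endpoints in file order.
    """
    index = {r.key: k for k, r in enumerate(residues)}
    out = []
    for sse in sses:
        k0 = index.get((sse.chain, *sse.first_res))
        k1 = index.get((sse.chain, *sse.last_res))
        if k0 is None or k1 is None or k1 < k0:
            raise InputError(
                f"SSE {sse.index} residue range {sse.first_res}..{sse.last_res} "
                f"(chain {sse.chain!r}) not found in coordinate file"
            )
        coords = np.array([residues[k].ca for k in range(k0, k1 + 1)])
        axis_point, axis_dir = fit_axis(coords)
        sse.ca_coords = coords
        sse.centroid = coords.mean(axis=0)
        sse.axis_point = axis_point
        sse.axis_dir = axis_dir
        out.append(sse)
    return out


def build_entry(entry_id: str, sses: Sequence[SSEDescriptor]) -> StructureEntry:
    """Assemble a StructureEntry from SSE descriptors with geometry.

    The tableau diagonal holds the SSE types; each off-diagonal code is the
    double-quadrant encoding of the pairwise interaxial angle; the distance
    matrix holds Euclidean distances between Cα centroids.
    """
    if not sses:
        raise ValidationError("need at least one SSE")
    n = len(sses)
    types = [s.type for s in sses]
    omega = orientation_matrix(sses)
    codes = [[encode_angle(omega[i, j]) for j in range(i)] for i in range(n)]
    centroids = np.array([np.asarray(s.centroid, dtype=float) for s in sses])
    diff = centroids[:, None, :] - centroids[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry
    return StructureEntry(id=entry_id, tableau=Tableau(types, codes), distances=d)


def entry_from_files(
    entry_id: str,
    pdb_file,
    dssp_file,
    chain_filter: str | None = None,
    min_lengths: Mapping[str, int] | None = None,
) -> StructureEntry:
    """End-to-end: PDB + DSSP files → StructureEntry.

    Raises :class:`EmptyStructureError` if no SSEs survive filtering.
    """
    residues = read_calpha(pdb_file, chain_filter=chain_filter)
    sses = assign_sses(dssp_file, min_lengths=min_lengths, chain_filter=chain_filter)
    sses = attach_geometry(sses, residues)
    return build_entry(entry_id, sses)
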