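"""Geometric detection of base-pairing and base-stacking interactions.

Each complete base is fitted with a reference frame by least-squares
superposition of a standard planar base template onto the observed ring
atoms.  A pair of bases is annotated as base-paired when their frames are
roughly coplanar and close, and at least one donor-acceptor heavy-atom
contact links them; the interacting edge of each base (Watson-Crick,
Hoogsteen or Sugar) is assigned from which edge atoms carry the contacts,
and the cis/trans orientation from the glycosidic-bond vectors.  Stacking
is annotated from ring-centroid distance, inter-normal angle and projected
ring overlap.

Thresholds are deliberately exposed: the geometric windows used by the
established annotation tools are conventions, not physical constants, and
users may tighten them for high-resolution crystal structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from shapely.geometry import MultiPoint

from ._bases import (
    CANONICAL_COMBOS,
    EDGE_ATOMS,
    EDGE_PRIORITY,
    GLYCOSIDIC_N,
    POLAR_ATOMS,
    RING_ATOMS,
    template_coords,
)
from .structure_io import NucleotideResidue, RnaStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PairingParams",
    "StackingParams",
    "BaseReferenceFrame",
    "BasePair",
    "StackContact",
    "FrameUnavailableError",
    "compute_base_frame",
    "detect_base_pairs",
    "detect_stacking",
]


class FrameUnavailableError(Exception):
    """Raised when a base frame cannot be fitted (incomplete ring)."""


@dataclass(frozen=True)
class PairingParams:
    """Geometric windows for base-pair detection.

    d_prefilter : coarse C1'-C1' (or centroid) cutoff in angstroms
    d_origin    : maximum distance between the two base-frame origins
    a_plane_max : maximum angle between base planes, degrees
    v_offset_max: maximum displacement along the mean base normal
    h_min       : minimum number of donor-acceptor heavy-atom contacts
    d_hb_max    : heavy-atom distance defining a donor-acceptor contact
    """

    d_prefilter: float = 15.0
    d_origin: float = 9.0
    a_plane_max: float = 65.0
    v_offset_max: float = 2.5
    h_min: int = 1
    d_hb_max: float = 3.5

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StackingParams:
    """Geometric windows for base-stacking detection."""

    d_stack: float = 5.5
    a_stack: float = 30.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class BaseReferenceFrame:
    """Rigid frame of one base: ring centroid, template rotation, normal."""

    origin: np.ndarray
    rotation: np.ndarray  # maps standard-frame coords onto observed coords
    normal: np.ndarray
    rmsd_fit: float


@dataclass(frozen=True)
class BasePair:
    """A detected base-base pairing interaction between global indices i < j.

    ``canonical`` marks cis Watson-Crick/Watson-Crick A-U, G-C and wobble
    G-U pairs; all other geometries are non-canonical but participate in
    helices on equal footing.  ``borderline`` flags pairs within 10% of any
    detection threshold, as candidates for manual inspection.
    """

    i: int
    j: int
    edge_i: str
    edge_j: str
    orientation: str  # "cis" | "trans"
    canonical: bool
    origin_distance: float
    plane_angle: float
    vertical_offset: float
    n_hbonds: int
    borderline: bool = False

    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class StackContact:
    """A base-stacking contact between global indices i < j."""

    i: int
    j: int
    center_distance: float
    normal_angle: float
    overlap: float


def compute_base_frame(residue: NucleotideResidue) -> BaseReferenceFrame:
    """Fit the standard base template to the observed ring atoms.

    The returned rotation maps template (standard-frame) coordinates onto
    the observed base; the origin is the observed ring centroid and the
    normal is the image of the template +z axis.
    """
    observed = residue.ring_coords()
    if observed is None or not residue.complete_base:
        raise FrameUnavailableError(
            f"residue {residue.chain_id}/{residue.auth_number} ({residue.base_code}) "
            "is missing ring atoms"
        )
    template = template_coords(residue.parent, RING_ATOMS[residue.parent])
    obs_c = observed.mean(axis=0)
    tmpl_c = template.mean(axis=0)
    rot, rssd = Rotation.align_vectors(observed - obs_c, template - tmpl_c)
    rmsd = float(rssd) / np.sqrt(len(observed))
    matrix = rot.as_matrix()
    return BaseReferenceFrame(
        origin=obs_c,
        rotation=matrix,
        normal=matrix[:, 2].copy(),
        rmsd_fit=rmsd,
    )


def _frames_for(structure: RnaStructure) -> dict[int, BaseReferenceFrame]:
    frames: dict[int, BaseReferenceFrame] = {}
    for idx, res in enumerate(structure.residues, start=1):
        try:
            frames[idx] = compute_base_frame(res)
        except FrameUnavailableError:
            logger.info(
                "no base frame for residue %d (%s/%s); left unpaired",
                idx, res.chain_id, res.auth_number,
            )
    return frames


def _anchor_points(structure: RnaStructure, frames: dict[int, BaseReferenceFrame]) -> tuple[np.ndarray, list[int]]:
    """C1' position per framed residue (ring centroid when C1' is absent)."""
    pts, idxs = [], []
    for idx, res in enumerate(structure.residues, start=1):
        if idx not in frames:
            continue
        c1 = res.coord("C1'")
        pts.append(c1 if c1 is not None else frames[idx].origin)
        idxs.append(idx)
    return np.asarray(pts, dtype=float), idxs


def _aligned_normals(fi: BaseReferenceFrame, fj: BaseReferenceFrame) -> tuple[np.ndarray, float]:
    """Mean normal (sign-aligned) and inter-plane angle in degrees."""
    ni, nj = fi.normal, fj.normal
    # atan2 form is well conditioned for near-parallel planes
    cross = float(np.linalg.norm(np.cross(ni, nj)))
    dot = abs(float(np.dot(ni, nj)))
    angle = float(np.degrees(np.arctan2(cross, dot)))
    nj_s = nj if np.dot(ni, nj) >= 0 else -nj
    mean = ni + nj_s
    mean /= np.linalg.norm(mean)
    return mean, angle


def _hbond_contacts(ri: NucleotideResidue, rj: NucleotideResidue, d_hb: float) -> list[tuple[str, str, float]]:
    contacts = []
    for ai in POLAR_ATOMS[ri.parent]:
        pi = ri.coord(ai)
        if pi is None:
            continue
        for aj in POLAR_ATOMS[rj.parent]:
            pj = rj.coord(aj)
            if pj is None:
                continue
            d = float(np.linalg.norm(pi - pj))
            if d <= d_hb:
                contacts.append((ai, aj, d))
    return contacts


def _assign_edge(parent: str, atoms_in_contacts: list[str]) -> str:
    counts = {
        edge: sum(1 for a in atoms_in_contacts if a in EDGE_ATOMS[parent][edge])
        for edge in EDGE_PRIORITY
    }
    best = max(counts.values())
    for edge in EDGE_PRIORITY:  # tie -> WC > Hoogsteen > Sugar
        if counts[edge] == best:
            return edge
    return "WC"


def _orientation(ri: NucleotideResidue, rj: NucleotideResidue, mean_normal: np.ndarray) -> str:
    """cis when both glycosidic bonds fall on the same side of the pair axis."""
    gi, gj = GLYCOSIDIC_N[ri.parent], GLYCOSIDIC_N[rj.parent]
    ni, nj = ri.coord(gi), rj.coord(gj)
    ci, cj = ri.coord("C1'"), rj.coord("C1'")
    if ni is None or nj is None or ci is None or cj is None:
        logger.info("glycosidic atoms missing; orientation defaulted to cis")
        return "cis"
    axis = nj - ni
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        return "cis"
    axis = axis / nrm
    si = float(np.dot(np.cross(axis, ci - ni), mean_normal))
    sj = float(np.dot(np.cross(axis, cj - nj), mean_normal))
    return "cis" if si * sj > 0 else "trans"


def _near_threshold(value: float, limit: float, frac: float = 0.1) -> bool:
    return limit * (1.0 - frac) <= value <= limit


def detect_base_pairs(
    structure: RnaStructure,
    params: PairingParams | None = None,
) -> list[BasePair]:
    """Annotate base pairs geometrically; result sorted by (i, j).

    A candidate passing the coarse distance prefilter becomes a BasePair
    when the frame origins are within ``d_origin``, the base planes within
    ``a_plane_max`` degrees, the vertical offset within ``v_offset_max``
    (this is what separates pairing from stacking), and at least ``h_min``
    donor-acceptor contacts within ``d_hb_max`` link the two bases.
    Residues without frames are silently left unpaired (logged).  A residue
    may appear in several pairs: base triples are first-class results.
    """
    params = params or PairingParams()
    residues = structure.residues
    frames = _frames_for(structure)
    if not frames:
        return []
    pts, idxs = _anchor_points(structure, frames)
    tree = cKDTree(pts)
    pairs: list[BasePair] = []
    for a, b in sorted(tree.query_pairs(params.d_prefilter)):
        i, j = idxs[a], idxs[b]
        if i > j:
            i, j = j, i
        fi, fj = frames[i], frames[j]
        d_origin = float(np.linalg.norm(fi.origin - fj.origin))
        if d_origin > params.d_origin:
            continue
        mean_normal, angle = _aligned_normals(fi, fj)
        if angle > params.a_plane_max:
            continue
        v_offset = abs(float(np.dot(fj.origin - fi.origin, mean_normal)))
        if v_offset > params.v_offset_max:
            continue
        ri, rj = residues[i - 1], residues[j - 1]
        contacts = _hbond_contacts(ri, rj, params.d_hb_max)
        if len(contacts) < params.h_min:
            continue
        edge_i = _assign_edge(ri.parent, [c[0] for c in contacts])
        edge_j = _assign_edge(rj.parent, [c[1] for c in contacts])
        orientation = _orientation(ri, rj, mean_normal)
        canonical = (
            edge_i == "WC"
            and edge_j == "WC"
            and orientation == "cis"
            and frozenset({ri.parent, rj.parent}) in CANONICAL_COMBOS
        )
        borderline = (
            _near_threshold(d_origin, params.d_origin)
            or _near_threshold(angle, params.a_plane_max)
            or _near_threshold(v_offset, params.v_offset_max)
            or (len(contacts) == params.h_min and min(c[2] for c in contacts) >= 0.9 * params.d_hb_max)
        )
        pairs.append(
            BasePair(
                i=i,
                j=j,
                edge_i=edge_i,
                edge_j=edge_j,
                orientation=orientation,
                canonical=canonical,
                origin_distance=d_origin,
                plane_angle=angle,
                vertical_offset=v_offset,
                n_hbonds=len(contacts),
                borderline=borderline,
            )
        )
    pairs.sort(key=lambda p: (p.i, p.j))
    return pairs


def _ring_polygon_2d(ring: np.ndarray, origin: np.ndarray, u: np.ndarray, v: np.ndarray):
    proj = np.column_stack(((ring - origin) @ u, (ring - origin) @ v))
    return MultiPoint(proj.tolist()).convex_hull


def _projected_overlap(ring_i: np.ndarray, ring_j: np.ndarray, normal: np.ndarray) -> float:
    """Area of intersection of the two convex ring outlines projected onto
    the plane perpendicular to the mean normal."""
    origin = (ring_i.mean(axis=0) + ring_j.mean(axis=0)) / 2.0
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    poly_i = _ring_polygon_2d(ring_i, origin, u, v)
    poly_j = _ring_polygon_2d(ring_j, origin, u, v)
    return float(poly_i.intersection(poly_j).area)


def detect_stacking(
    structure: RnaStructure,
    params: StackingParams | None = None,
) -> list[StackContact]:
    """Annotate base-stacking contacts; result sorted by (i, j).

    A contact requires ring centroids within ``d_stack``, base normals
    within ``a_stack`` degrees, and a strictly positive projected overlap
    of the ring outlines.
    """
    params = params or StackingParams()
    residues = structure.residues
    frames = _frames_for(structure)
    if not frames:
        return []
    framed = sorted(frames)
    centroids = np.array([frames[i].origin for i in framed])
    tree = cKDTree(centroids)
    contacts: list[StackContact] = []
    for a, b in sorted(tree.query_pairs(params.d_stack)):
        i, j = framed[a], framed[b]
        if i > j:
            i, j = j, i
        fi, fj = frames[i], frames[j]
        d = float(np.linalg.norm(fi.origin - fj.origin))
        mean_normal, angle = _aligned_normals(fi, fj)
        if angle > params.a_stack:
            continue
        ring_i = residues[i - 1].ring_coords()
        ring_j = residues[j - 1].ring_coords()
        overlap = _projected_overlap(ring_i, ring_j, mean_normal)
        if overlap <= 0.0:
            continue
        contacts.append(
            StackContact(i=i, j=j, center_distance=d, normal_angle=angle, overlap=overlap)
        )
    contacts.sort(key=lambda s: (s.i, s.j))
    return contacts
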