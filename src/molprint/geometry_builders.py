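"""Synthetic molecular geometry: peptide chains, B-DNA traces, capsids.

These builders make the whole print pipeline testable without downloading
coordinates, and reconstruct the three example systems the toolkit targets:
a torsion-defined polypeptide (the backbone orientation of each residue is
set by its phi/psi dihedrals), a canonical B-form DNA double-helix trace,
and an icosahedral virus capsid assembled from 12 copies of one pentamer,
each pentamer being 5 rotated copies of a protomer.

All builders are deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import OverlapWarning, PrintabilityError
from .mesh import TriMesh
from .structure_io import AtomRecord, MolecularStructure

# ideal peptide backbone geometry (Engh & Huber-style ideal values), angstrom
# and degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

GOLDEN = (1.0 + 5.0 ** 0.5) / 2.0


@dataclass
class TorsionSpec:
    """Per-residue backbone dihedrals in degrees, in (-180, 180]."""

    phi: list[float]
    psi: list[float]
    omega: list[float] | None = None

    def __post_init__(self):
        self.phi = [float(a) for a in self.phi]
        self.psi = [float(a) for a in self.psi]
        if self.omega is None:
            self.omega = [180.0] * len(self.phi)
        else:
            self.omega = [float(a) for a in self.omega]
        if not (len(self.phi) == len(self.psi) == len(self.omega)):
            raise ValueError("phi, psi and omega lists must have equal length")
        for name, angles in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            for a in angles:
                if not (-180.0 < a <= 180.0):
                    raise ValueError(f"{name} angle {a} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n_res: int, phi: float, psi: float, omega: float = 180.0) -> "TorsionSpec":
        return cls([phi] * n_res, [psi] * n_res, [omega] * n_res)


@dataclass
class HelixParams:
    """Duplex helix parameters; defaults are canonical B-form DNA."""

    rise_per_bp: float = 3.4     # angstrom
    twist_per_bp: float = 36.0   # degrees (10 bp per turn)
    radius: float = 9.4          # phosphate backbone radius, angstrom

    def __post_init__(self):
        if self.rise_per_bp <= 0:
            raise ValueError("rise_per_bp must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class SymmetryOp:
    """Proper rigid transform ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# internal-to-Cartesian placement


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and dihedral a-b-c-d.

    Natural-extension reference frame construction: the new position is
    expressed in the local frame at c and rotated into world coordinates.
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if math.isclose(ang, -180.0, abs_tol=1e-12) else ang


def build_peptide_chain(n_res: int, torsions: TorsionSpec) -> MolecularStructure:
    """Backbone-only polypeptide (N, CA, C, O per residue) from dihedrals.

    The first residue is anchored canonically: N at the origin, CA on +x,
    C in the xy-plane. Residue i's phi is the C(i-1)-N-CA-C dihedral (the
    leading residue has none, so ``torsions.phi[0]`` is unused), psi is
    N-CA-C-N(i+1) and omega the CA-C-N(i+1)-CA(i+1) peptide-bond dihedral.
    The carbonyl O sits in the psi plane: dihedral N-CA-C-O = psi + 180.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if len(torsions) != n_res:
        raise ValueError(f"torsion spec length {len(torsions)} != n_res {n_res}")
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms: list[AtomRecord] = []
    serial = 1

    def emit(name, element, xyz, resnum):
        nonlocal serial
        atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                coords=xyz, chain_id="A", residue_name="GLY",
                                residue_number=resnum))
        serial += 1

    for i in range(n_res):
        if i > 0:
            N = place_atom(prev_N, prev_CA, prev_C, BOND_C_N, ANGLE_CA_C_N,
                           torsions.psi[i - 1])
            CA = place_atom(prev_CA, prev_C, N, BOND_N_CA, ANGLE_C_N_CA,
                            torsions.omega[i - 1])
            C = place_atom(prev_C, N, CA, BOND_CA_C, ANGLE_N_CA_C,
                           torsions.phi[i])
        psi_o = torsions.psi[i] + 180.0
        if psi_o > 180.0:
            psi_o -= 360.0
        O = place_atom(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psi_o)
        emit("N", "N", N, i + 1)
        emit("CA", "C", CA, i + 1)
        emit("C", "C", C, i + 1)
        emit("O", "O", O, i + 1)
        prev_N, prev_CA, prev_C = N, CA, C
    return MolecularStructure(atoms, source_label=f"peptide({n_res})")


def measure_torsions(s: MolecularStructure) -> TorsionSpec:
    """Measure phi/psi/omega back from built backbone coordinates.

    Undefined terminal dihedrals (phi of the first residue; psi/omega of the
    last use the carbonyl-O convention / repeat 180) are filled so the result
    aligns index-for-index with :func:`build_peptide_chain` input.
    """
    by_res: dict[int, dict[str, np.ndarray]] = {}
    for a in s.atoms:
        by_res.setdefault(a.residue_number, {})[a.name] = a.coords
    nums = sorted(by_res)
    phi, psi, omega = [], [], []
    for k, rn in enumerate(nums):
        r = by_res[rn]
        if k > 0:
            rp = by_res[nums[k - 1]]
            phi.append(dihedral(rp["C"], r["N"], r["CA"], r["C"]))
        else:
            phi.append(180.0)
        if k + 1 < len(nums):
            rn1 = by_res[nums[k + 1]]
            psi.append(dihedral(r["N"], r["CA"], r["C"], rn1["N"]))
            omega.append(dihedral(r["CA"], r["C"], rn1["N"], rn1["CA"]))
        else:
            # recover terminal psi from the carbonyl O (placed at psi + 180)
            ps = dihedral(r["N"], r["CA"], r["C"], r["O"]) - 180.0
            if ps <= -180.0:
                ps += 360.0
            psi.append(180.0 if math.isclose(ps, -180.0, abs_tol=1e-9) else ps)
            omega.append(180.0)
    return TorsionSpec(phi, psi, omega)


# ---------------------------------------------------------------------------
# B-DNA trace


def build_bdna_trace(n_bp: int, params: HelixParams | None = None) -> MolecularStructure:
    """Two antiparallel pseudo-atom strands on a B-form double helix.

    Each nucleotide contributes a phosphate site (element P, at the backbone
    radius) and a sugar site (element C, inset toward the axis). Strand B is
    strand A rotated 180 degrees about the dyad (the x-axis through the
    helix mid-height), the canonical duplex symmetry.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    p = params or HelixParams()
    sugar_radius = max(p.radius - 2.4, 0.5)
    sugar_offset_deg = -18.0  # sugar trails the phosphate around the helix
    atoms: list[AtomRecord] = []
    serial = 1
    z_mid = (n_bp - 1) * p.rise_per_bp / 2.0

    def helix_point(i: int, radius: float, phase_deg: float) -> np.ndarray:
        th = math.radians(i * p.twist_per_bp + phase_deg)
        return np.array([radius * math.cos(th), radius * math.sin(th), i * p.rise_per_bp])

    def dyad(v: np.ndarray) -> np.ndarray:
        return np.array([v[0], -v[1], 2.0 * z_mid - v[2]])

    for chain, flip in (("A", False), ("B", True)):
        for i in range(n_bp):
            pp = helix_point(i, p.radius, 0.0)
            ss = helix_point(i, sugar_radius, sugar_offset_deg)
            if flip:
                pp, ss = dyad(pp), dyad(ss)
            resnum = i + 1
            atoms.append(AtomRecord(serial=serial, name="P", element="P", coords=pp,
                                    chain_id=chain, residue_name="DN",
                                    residue_number=resnum))
            serial += 1
            atoms.append(AtomRecord(serial=serial, name="C4'", element="C", coords=ss,
                                    chain_id=chain, residue_name="DN",
                                    residue_number=resnum))
            serial += 1
    return MolecularStructure(atoms, source_label=f"bdna({n_bp})")


# ---------------------------------------------------------------------------
# icosahedral assembly


def icosahedron_vertices() -> np.ndarray:
    """12 unit vertex directions: cyclic permutations of (0, ±1, ±phi)."""
    verts = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            verts.append((0.0, s1, s2 * GOLDEN))
            verts.append((s1, s2 * GOLDEN, 0.0))
            verts.append((s1 * GOLDEN, 0.0, s2))
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotation_z_to(v: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z onto unit vector v (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])  # 180 degrees about x
    axis = np.cross(z, v)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def icosahedral_vertex_ops() -> list[SymmetryOp]:
    """12 proper rotations mapping +z onto each icosahedron vertex."""
    return [SymmetryOp(_rotation_z_to(v)) for v in icosahedron_vertices()]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    th = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1.0 - math.cos(th)) * (K @ K)


def build_pentamer(protomer, fivefold_axis=(0.0, 0.0, 1.0)):
    """Five copies of a protomer related by successive 72-degree rotations.

    ``protomer`` may be a :class:`TriMesh` or a :class:`MolecularStructure`;
    copy 0 is the identity placement.
    """
    axis = np.asarray(fivefold_axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("five-fold axis must be non-zero")
    return [
        protomer.transformed(rotation=rotation_about_axis(axis, 72.0 * k))
        for k in range(5)
    ]


def build_capsid(pentamer: TriMesh, capsid_radius: float,
                 overlap_fraction: float = 0.01) -> list[TriMesh]:
    """Place 12 rigid pentamer copies on the icosahedron vertices.

    Each copy is rotated by the vertex op and pushed out by ``capsid_radius``
    along its vertex direction. An :class:`OverlapWarning` fires when any two
    placed copies' axis-aligned bounding boxes intersect by more than
    ``overlap_fraction`` of one pentamer's bounding-box volume — a screen for
    a radius too small for the pentamer footprint, not a collision solver.
    """
    from .mesh_ops import validate_mesh

    if capsid_radius < 0:
        raise ValueError("capsid_radius must be >= 0")
    report = validate_mesh(pentamer, check_self_intersections=False)
    if not report.watertight:
        raise PrintabilityError(
            "capsid pentamer must be watertight "
            f"({report.boundary_edge_count} boundary edges)"
        )
    placed = []
    for op in icosahedral_vertex_ops():
        direction = op.rotation @ np.array([0.0, 0.0, 1.0])
        placed.append(pentamer.transformed(rotation=op.rotation,
                                           translation=capsid_radius * direction))
    ext = pentamer.extents
    pent_bbox_vol = float(np.prod(ext))
    worst = 0.0
    for i in range(len(placed)):
        bi = placed[i].bounds
        for j in range(i + 1, len(placed)):
            bj = placed[j].bounds
            inter = np.minimum(bi[1], bj[1]) - np.maximum(bi[0], bj[0])
            if np.all(inter > 0):
                worst = max(worst, float(np.prod(inter)))
    if pent_bbox_vol > 0 and worst > overlap_fraction * pent_bbox_vol:
        warnings.warn(
            f"placed pentamers overlap (bounding boxes intersect by "
            f"{worst / pent_bbox_vol:.1%} of a pentamer volume); "
            "capsid_radius is likely too small",
            OverlapWarning, stacklevel=2,
        )
    return placed
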