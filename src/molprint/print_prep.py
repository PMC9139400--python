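"""Print preparation: magnification, printer fit, magnet sockets.

A tangible molecular model is millions of times actual size. A fixed set of
magnifications keeps independently printed models comparable and lets them
interact: 40 million x for atomically-manipulable component sets, 20
million x for individual proteins, 10 million x for multi-chain protein
assemblies, 5 million x for very large assemblies and viruses, and 1
million x for cellular-scale structures. At 1 A = 1e-7 mm, a 50 A protein
printed at 20 million x is a comfortable 100 mm handful.

Assembly affordances follow the magnet-and-socket approach: cylindrical
holes are Boolean-subtracted at subunit interfaces so magnets glued in with
complementary polarity mimic the shape/charge complementarity that drives
the real assembly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import PrintabilityError, ThroughHoleWarning, UnitError
from .mesh import ANGSTROM, MM, TriMesh
from .structure_io import MolecularStructure
from . import voxel

ANGSTROM_TO_MM = 1e-7  # 1 A = 1e-7 mm


@dataclass(frozen=True)
class ScalePreset:
    category: str
    magnification: float

    def __post_init__(self):
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")


_SCALE_PRESETS = (
    ScalePreset("atomic-components", 40e6),
    ScalePreset("individual-protein", 20e6),
    ScalePreset("protein-assembly", 10e6),
    ScalePreset("large-assembly-virus", 5e6),
    ScalePreset("cellular-structure", 1e6),
)


def scale_registry() -> list[ScalePreset]:
    """The five standard model magnifications (largest to smallest)."""
    return list(_SCALE_PRESETS)


def lookup_scale(category: str) -> float:
    for p in _SCALE_PRESETS:
        if p.category == category:
            return p.magnification
    raise KeyError(
        f"unknown scale category {category!r}; "
        f"choose from {[p.category for p in _SCALE_PRESETS]}"
    )


@dataclass
class PrinterProfile:
    """Printable-feature limits of a printer technology class.

    The wall/rod limits are editable placeholders — consult the printer's
    datasheet for real values.
    """

    name: str
    technology: str  # FDM | SLA | powder-binder | SLS | laminated
    build_volume: tuple[float, float, float] = (200.0, 200.0, 200.0)  # mm
    min_wall: float = 1.0  # mm
    min_rod_diameter: float = 2.0  # mm
    full_color: bool = False
    support_style: str = "breakaway"  # breakaway | dissolvable | self-supporting

    def __post_init__(self):
        if any(v <= 0 for v in self.build_volume) or self.min_wall <= 0 or self.min_rod_diameter <= 0:
            raise ValueError("printer dimensions must be positive")


PRINTER_PROFILES: dict[str, PrinterProfile] = {
    "fdm": PrinterProfile("fdm", "FDM", (200.0, 200.0, 200.0), 1.0, 2.0,
                          full_color=False, support_style="breakaway"),
    "sla": PrinterProfile("sla", "SLA", (145.0, 145.0, 175.0), 0.5, 1.0,
                          full_color=False, support_style="breakaway"),
    "powder": PrinterProfile("powder", "powder-binder", (254.0, 381.0, 203.0), 2.0, 3.0,
                             full_color=True, support_style="self-supporting"),
    "sls": PrinterProfile("sls", "SLS", (300.0, 300.0, 300.0), 1.0, 1.5,
                          full_color=False, support_style="self-supporting"),
    "laminated": PrinterProfile("laminated", "laminated", (256.0, 169.0, 150.0), 2.0, 3.0,
                                full_color=True, support_style="breakaway"),
}


# ---------------------------------------------------------------------------
# scaling


def apply_scale(m: TriMesh, magnification: float) -> TriMesh:
    """Magnify an angstrom mesh into millimetres.

    Coordinates multiply by ``magnification x 1e-7`` (1 A = 1e-7 mm);
    topology is untouched. Scaling a mesh already in mm is an error — it
    would silently double-scale.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    if m.unit != ANGSTROM:
        raise UnitError(f"mesh unit is {m.unit!r}; apply_scale expects angstrom input")
    factor = magnification * ANGSTROM_TO_MM
    return TriMesh(m.vertices * factor, m.faces.copy(), MM,
                   None if m.vertex_colors is None else m.vertex_colors.copy())


@dataclass
class FitReport:
    fits: bool
    max_feasible_magnification: float
    orientation: tuple[int, int, int] | None  # axis permutation used


def fit_check(m: TriMesh, profile: PrinterProfile) -> FitReport:
    """Does the mesh fit the build volume in some axis-aligned orientation?

    All 6 axis permutations of the bounding box are tried (no arbitrary
    rotation search). ``max_feasible_magnification`` is the largest extra
    multiplier on the current size that still fits.
    """
    if m.n_faces == 0:
        raise ValueError("cannot fit-check an empty mesh")
    ext = m.extents
    build = np.asarray(profile.build_volume, dtype=float)
    best_mult = 0.0
    best_perm = None
    for perm in itertools.permutations(range(3)):
        mult = float(np.min(build / ext[list(perm)]))
        if mult > best_mult:
            best_mult, best_perm = mult, perm
    return FitReport(fits=best_mult >= 1.0, max_feasible_magnification=best_mult,
                     orientation=best_perm)


# ---------------------------------------------------------------------------
# interfaces and sockets


@dataclass
class InterfacePatch:
    """A contact region between two structures, ranked by contact count."""

    centroid: np.ndarray
    outward_normal: np.ndarray
    contact_count: int

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        n = np.asarray(self.outward_normal, dtype=float).reshape(3)
        ln = np.linalg.norm(n)
        if ln == 0:
            raise ValueError("patch normal must be non-zero")
        self.outward_normal = n / ln
        if self.contact_count < 1:
            raise ValueError("contact_count must be >= 1")


@dataclass
class SocketSpec:
    """Cylindrical magnet socket; ``center`` is the mouth on the surface."""

    center: np.ndarray
    axis: np.ndarray
    radius: float
    depth: float
    polarity: str  # "+" or "-"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.axis, dtype=float).reshape(3)
        ln = np.linalg.norm(a)
        if ln == 0:
            raise ValueError("socket axis must be non-zero")
        self.axis = a / ln
        if self.radius <= 0 or self.depth <= 0:
            raise ValueError("socket radius and depth must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")


def detect_interfaces(
    a: MolecularStructure,
    b: MolecularStructure,
    cutoff: float = 5.0,
    max_patches: int = 10,
) -> list[InterfacePatch]:
    """Contact patches between two structures.

    Atom pairs within ``cutoff`` are single-linkage clustered at 2 x cutoff
    on their midpoints; each cluster yields one patch at the contact
    centroid with the normal along the local a -> b direction. Patches are
    ranked by contact count (ties broken by lexicographic centroid order)
    and truncated to ``max_patches``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca, cb = a.coords(), b.coords()
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), cutoff)
    ia, ib = [], []
    for i, js in enumerate(pairs):
        ia.extend([i] * len(js))
        ib.extend(js)
    if not ia:
        return []
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    mid = (ca[ia] + cb[ib]) / 2.0
    link_pairs = cKDTree(mid).query_pairs(2.0 * cutoff, output_type="ndarray")
    g = sparse.coo_matrix(
        (np.ones(len(link_pairs)), (link_pairs[:, 0], link_pairs[:, 1])),
        shape=(len(mid), len(mid)),
    )
    _, labels = connected_components(g, directed=False)
    patches = []
    for lab in np.unique(labels):
        mask = labels == lab
        centroid = mid[mask].mean(axis=0)
        a_cent = ca[ia[mask]].mean(axis=0)
        b_cent = cb[ib[mask]].mean(axis=0)
        normal = b_cent - a_cent
        if np.linalg.norm(normal) < 1e-12:
            normal = np.array([0.0, 0.0, 1.0])  # degenerate symmetric contact
        patches.append(InterfacePatch(centroid, normal, int(mask.sum())))
    patches.sort(key=lambda p: (-p.contact_count, tuple(p.centroid)))
    return patches[:max_patches]


def _surface_point(m: TriMesh, point: np.ndarray) -> np.ndarray:
    from trimesh.proximity import closest_point_naive

    closest, _, _ = closest_point_naive(m.to_trimesh(), point.reshape(1, 3))
    return closest[0]


def place_sockets(
    m: TriMesh,
    patches: list[InterfacePatch],
    magnet_radius: float = 1.5,
    magnet_depth: float = 2.0,
    polarity_scheme: str = "alternating",
    clearance: float = 0.1,
    pitch: float | None = None,
) -> tuple[TriMesh, list[SocketSpec]]:
    """Carve one cylindrical magnet socket per interface patch.

    At the surface point nearest each patch centroid a cylinder of radius
    ``magnet_radius + clearance`` and ``magnet_depth`` is subtracted along
    the inward patch normal. ``polarity_scheme`` is ``"alternating"``
    (+,-,+,- in rank order) or ``"uniform+"`` / ``"uniform-"``; preparing
    two mating parts with complementary uniform schemes guarantees every
    opposed socket pair attracts. A socket deeper than the local wall emits
    a :class:`ThroughHoleWarning`.
    """
    if magnet_radius <= 0 or magnet_depth <= 0:
        raise ValueError("magnet dimensions must be positive")
    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    if polarity_scheme not in ("alternating", "uniform+", "uniform-"):
        raise ValueError(f"unknown polarity scheme {polarity_scheme!r}")
    if not patches:
        return m, []
    report_watertight(m, "place_sockets")
    hole_radius = magnet_radius + clearance
    if pitch is None:
        pitch = min(voxel.default_pitch(m), hole_radius / 3.0)
    grid = voxel.make_grid(m.bounds, pitch)
    field = voxel.mesh_fraction(m, grid)
    carve = np.zeros_like(field)
    sockets: list[SocketSpec] = []
    for rank, patch in enumerate(patches):
        mouth = _surface_point(m, patch.centroid)
        inward = -patch.outward_normal
        # start the cylinder slightly proud of the surface for a clean cut
        p0 = mouth - 0.25 * magnet_depth * inward
        p1 = mouth + magnet_depth * inward
        voxel.add_capsule_fraction(carve, grid, p0, p1, hole_radius)
        thickness = _wall_thickness_along(m, mouth, inward)
        if thickness is not None and thickness < magnet_depth:
            warnings.warn(
                f"socket {rank} depth {magnet_depth:g} exceeds local wall "
                f"thickness {thickness:g}: through hole",
                ThroughHoleWarning, stacklevel=2,
            )
        if polarity_scheme == "alternating":
            pol = "+" if rank % 2 == 0 else "-"
        else:
            pol = polarity_scheme[-1]
        sockets.append(SocketSpec(mouth, inward, magnet_radius, magnet_depth, pol))
    result = np.minimum(field, 1.0 - carve)
    out = voxel.field_to_mesh(result, grid, m.unit)
    return out, sockets


def report_watertight(m: TriMesh, op_name: str) -> None:
    from .mesh_ops import validate_mesh

    rep = validate_mesh(m, check_self_intersections=False)
    if not rep.watertight:
        raise PrintabilityError(
            f"{op_name} requires a watertight mesh "
            f"({rep.boundary_edge_count} boundary edges)"
        )


def _wall_thickness_along(m: TriMesh, origin: np.ndarray, direction: np.ndarray) -> float | None:
    from .mesh_ops import ray_first_hit

    eps = 1e-6 * float(np.linalg.norm(m.extents))
    t = ray_first_hit(m, (origin + eps * direction).reshape(1, 3),
                      direction.reshape(1, 3), t_min=eps)[0]
    return None if not np.isfinite(t) else float(t + eps)


# ---------------------------------------------------------------------------
# key-value config


_FLOAT_KEYS = {"magnet_radius", "magnet_depth", "socket_clearance", "hollow_wall"}


def load_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file.

    Recognized keys: ``magnet_radius``, ``magnet_depth``,
    ``socket_clearance``, ``hollow_wall`` (mm, floats) and
    ``profile.<name>.min_wall`` / ``profile.<name>.min_rod_diameter`` (mm)
    to override bundled printer profiles. Unknown keys are kept as strings.
    Lines starting with ``#`` are comments.
    """
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in _FLOAT_KEYS or key.startswith("profile."):
            out[key] = float(value)
        else:
            out[key] = value
    return out


def profiles_with_overrides(config: dict) -> dict[str, PrinterProfile]:
    """Bundled profiles with ``profile.<name>.<field>`` config overrides."""
    import copy

    profiles = {k: copy.deepcopy(v) for k, v in PRINTER_PROFILES.items()}
    for key, value in config.items():
        if not key.startswith("profile."):
            continue
        _, name, fieldname = key.split(".", 2)
        if name in profiles and hasattr(profiles[name], fieldname):
            setattr(profiles[name], fieldname, value)
    return profiles
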