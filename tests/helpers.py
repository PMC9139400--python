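"""Independent oracles used by the test suite.

Each oracle derives its answer by brute force or from first principles,
independently of the library code path it cross-checks.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def edge_incidence_oracle(faces) -> dict:
    """Count boundary / non-manifold edges by plain dictionary counting."""
    counts: Counter = Counter()
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            counts[frozenset((int(a), int(b)))] += 1
    return {
        "boundary": sum(1 for c in counts.values() if c == 1),
        "nonmanifold": sum(1 for c in counts.values() if c >= 3),
        "edges": len(counts),
    }


def dihedral_oracle(p0, p1, p2, p3) -> float:
    """Signed dihedral via plane-normal atan2 (independent formula)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p2 - p1
    n1 = np.cross(p1 - p0, b1)
    n2 = np.cross(b1, p3 - p2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)))
    return math.degrees(math.atan2(y, x))


def angle_oracle(p0, p1, p2) -> float:
    u = np.asarray(p0, float) - np.asarray(p1, float)
    v = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def place_atom_oracle(a, b, c, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Place the next atom by direct solution of the geometric constraints.

    The position is parameterized on the cone of directions making the
    requested bond angle at c; the two handedness candidates are evaluated
    with :func:`dihedral_oracle` and the one matching the requested torsion
    is returned — no shared frame convention with the library.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = c - b
    u /= np.linalg.norm(u)
    va = (a - b) - np.dot(a - b, u) * u
    m1 = va / np.linalg.norm(va)
    theta = math.radians(angle_deg)
    for m2 in (np.cross(u, m1), -np.cross(u, m1)):
        for phi_deg in (torsion_deg, -torsion_deg):
            phi = math.radians(phi_deg)
            w = (-math.cos(theta) * u
                 + math.sin(theta) * (math.cos(phi) * m1 + math.sin(phi) * m2))
            d = c + bond * w
            if (abs(angle_oracle(b, c, d) - angle_deg) < 1e-6):
                diff = (dihedral_oracle(a, b, c, d) - torsion_deg + 180.0) % 360.0 - 180.0
                if abs(diff) < 1e-6:
                    return d
    raise AssertionError("oracle could not satisfy the torsion constraint")


def peptide_chain_oracle(n_res, phi, psi, omega) -> dict:
    """Brute-force internal-to-Cartesian backbone with the same ideal values.

    Returns per-residue atom positions keyed (residue_number, atom_name).
    """
    from molprint.geometry_builders import (
        ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_N_CA_C,
        BOND_C_N, BOND_C_O, BOND_CA_C, BOND_N_CA,
    )

    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    out = {}
    for i in range(n_res):
        if i > 0:
            pN, pCA, pC = out[(i, "N")], out[(i, "CA")], out[(i, "C")]
            N = place_atom_oracle(pN, pCA, pC, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
            CA = place_atom_oracle(pCA, pC, N, BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
            C = place_atom_oracle(pC, N, CA, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        psi_o = (psi[i] + 180.0 + 180.0) % 360.0 - 180.0
        psi_o = 180.0 if psi_o == -180.0 else psi_o
        O = place_atom_oracle(N, CA, C, BOND_C_O, ANGLE_CA_C_O, psi_o)
        out[(i + 1, "N")], out[(i + 1, "CA")] = N, CA
        out[(i + 1, "C")], out[(i + 1, "O")] = C, O
    return out


def helix_rise_oracle(ca: np.ndarray) -> float:
    """Rise per residue from a principal-axis fit of the CA trace."""
    cen = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(cen)
    proj = cen @ vt[0]
    return abs(float(np.polyfit(np.arange(len(ca)), proj, 1)[0]))


def monte_carlo_volume(inside_fn, bounds, n: int, seed: int) -> float:
    """Fixed-seed point-membership volume estimate."""
    rng = np.random.default_rng(seed)
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    pts = rng.uniform(lo, hi, size=(n, 3))
    frac = float(np.mean(inside_fn(pts)))
    return frac * float(np.prod(hi - lo))


def overlap_components_oracle(coords, radii) -> int:
    """Connected components of the sphere-overlap graph by BFS."""
    n = len(coords)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < radii[i] + radii[j]:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return comps


def parse_vrml(text: str):
    """Minimal VRML 2.0 IndexedFaceSet reader (test-only)."""
    import re

    def block(name):
        m = re.search(name + r"\s*\[([^\]]*)\]", text)
        return m.group(1) if m else None

    pts = block(r"point")
    assert pts is not None
    coords = np.array([float(x) for x in re.split(r"[\s,]+", pts.strip()) if x])
    coords = coords.reshape(-1, 3)
    idx = block(r"coordIndex")
    nums = [int(x) for x in re.split(r"[\s,]+", idx.strip()) if x]
    faces = []
    cur = []
    for v in nums:
        if v == -1:
            faces.append(cur)
            cur = []
        else:
            cur.append(v)
    colors = None
    cb = block(r"color")
    if cb is not None:
        colors = np.array([float(x) for x in re.split(r"[\s,]+", cb.strip()) if x]).reshape(-1, 3)
    return coords, np.array(faces), colors
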