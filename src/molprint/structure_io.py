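"""PDB parsing, van-der-Waals radii and color schemes.

Only the fixed-column ATOM/HETATM/TER/END dialect is honored; every other
record type is ignored. The parser is deliberately narrow and strict: a
malformed coordinate field raises :class:`PDBParseError` naming the line, and
alternate locations collapse to the first conformer by default — a printable
model wants exactly one copy of each atom and no solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import numpy as np

from .errors import EmptyStructureError, MissingRadiusError, PDBParseError

# Bondi (1964) van der Waals radii, angstrom. The classic space-filling
# (CPK) model draws each atom at this radius.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NE": 1.54, "NA": 2.27, "MG": 1.73, "SI": 2.10, "P": 1.80, "S": 1.80,
    "CL": 1.75, "AR": 1.88, "K": 2.75, "NI": 1.63, "CU": 1.40, "ZN": 1.39,
    "GA": 1.87, "AS": 1.85, "SE": 1.90, "BR": 1.85, "KR": 2.02, "PD": 1.63,
    "AG": 1.72, "CD": 1.58, "IN": 1.93, "SN": 2.17, "TE": 2.06, "I": 1.98,
    "XE": 2.16, "PT": 1.75, "AU": 1.66, "HG": 1.55, "TL": 1.96, "PB": 2.02,
    "U": 1.86, "LI": 1.82,
}

RADIUS_SETS: dict[str, Mapping[str, float]] = {"bondi": BONDI_RADII}

# classic chemistry coloring: red oxygen, blue nitrogen, black carbon
ELEMENT_COLORS: dict[str, tuple[float, float, float]] = {
    "C": (0.0, 0.0, 0.0),
    "O": (1.0, 0.0, 0.0),
    "N": (0.0, 0.0, 1.0),
    "S": (1.0, 1.0, 0.0),
    "H": (1.0, 1.0, 1.0),
    "P": (1.0, 0.5, 0.0),
}
FALLBACK_COLOR = (1.0, 0.0, 1.0)  # magenta: "this element has no assigned color"

# 10-color qualitative cycle for chain coloring
CHAIN_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.12, 0.47, 0.71), (1.00, 0.50, 0.05), (0.17, 0.63, 0.17),
    (0.84, 0.15, 0.16), (0.58, 0.40, 0.74), (0.55, 0.34, 0.29),
    (0.89, 0.47, 0.76), (0.50, 0.50, 0.50), (0.74, 0.74, 0.13),
    (0.09, 0.75, 0.81),
)

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}

# elements whose two-letter symbol can be confused with a remoteness code
# in the atom-name heuristic (e.g. "CA" = alpha carbon vs calcium)
_TWO_LETTER = {k for k in BONDI_RADII if len(k) == 2}


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    radius: float | None = None
    chain_id: str = "A"
    residue_name: str = "UNK"
    residue_number: int = 1
    is_hetero: bool = False
    altloc: str = ""
    color: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")


@dataclass
class MolecularStructure:
    """Ordered atom records plus provenance label."""

    atoms: list[AtomRecord] = field(default_factory=list)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        r = [a.radius for a in self.atoms]
        if any(x is None for x in r):
            raise MissingRadiusError([a.element for a in self.atoms if a.radius is None])
        return np.asarray(r, dtype=float)

    def colors(self) -> np.ndarray | None:
        if any(a.color is None for a in self.atoms):
            return None
        return np.array([a.color for a in self.atoms], dtype=float)

    def select(self, predicate) -> "MolecularStructure":
        return MolecularStructure([a for a in self.atoms if predicate(a)], self.source_label)

    def transformed(self, rotation=None, translation=(0.0, 0.0, 0.0)) -> "MolecularStructure":
        t = np.asarray(translation, dtype=float)
        out = []
        for a in self.atoms:
            c = a.coords
            if rotation is not None:
                c = np.asarray(rotation, dtype=float) @ c
            out.append(replace(a, coords=c + t))
        return MolecularStructure(out, self.source_label)


@dataclass
class ColorScheme:
    mode: str = "element"  # element | chain | uniform
    palette: Mapping = None
    fallback: tuple[float, float, float] = FALLBACK_COLOR

    def __post_init__(self):
        if self.mode not in ("element", "chain", "uniform"):
            raise ValueError(f"unknown color mode {self.mode!r}")
        if self.palette is None:
            self.palette = ELEMENT_COLORS if self.mode == "element" else CHAIN_PALETTE
        for rgb in (list(self.palette.values()) if isinstance(self.palette, Mapping)
                    else list(self.palette)) + [self.fallback]:
            if any(not (0.0 <= c <= 1.0) for c in rgb):
                raise ValueError("RGB components must lie in [0, 1]")


# ---------------------------------------------------------------------------
# parsing


def _guess_element(name: str) -> str:
    """Element from a PDB atom-name field (columns 13-16)."""
    raw = name
    stripped = raw.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    # names starting in column 13 with two letters are genuine two-letter
    # elements (FE, ZN, ...); names indented to column 14 are organics (CA
    # = alpha carbon), whose element is the first letter
    if len(raw) >= 2 and raw[0] != " " and two in _TWO_LETTER:
        return two.capitalize()
    return stripped[0].upper()


def _parse_float(text: str, what: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text.strip()!r}", line_no) from None


def read_pdb(
    stream: IO[str] | Iterable[str],
    include_hetero: bool = False,
    altloc_policy: str = "keep-first",
    include_water: bool = False,
    source_label: str = "",
) -> MolecularStructure:
    """Parse fixed-column PDB text into a :class:`MolecularStructure`.

    Parameters
    ----------
    include_hetero:
        Accept HETATM records (waters still need ``include_water``).
    altloc_policy:
        ``"keep-first"`` keeps the first conformer seen per atom site;
        ``"keep-all"`` keeps every alternate-location record.
    """
    if altloc_policy not in ("keep-first", "keep-all"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    atoms: list[AtomRecord] = []
    seen_sites: set[tuple] = set()
    for line_no, line in enumerate(stream, start=1):
        rec = line[:6].rstrip()
        if rec == "END":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        is_het = rec == "HETATM"
        resname = line[17:20].strip() or "UNK"
        if is_het:
            if resname in _WATER_RESNAMES:
                if not include_water:
                    continue
            elif not include_hetero:
                continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError("record too short for coordinate fields", line_no)
        name = line[12:16]
        altloc = line[16].strip()
        chain = line[21].strip() or "A"
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(atoms) + 1
        try:
            resnum = int(line[22:26])
        except ValueError:
            resnum = 0
        x = _parse_float(line[30:38], "x coordinate", line_no)
        y = _parse_float(line[38:46], "y coordinate", line_no)
        z = _parse_float(line[46:54], "z coordinate", line_no)
        element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        if not element:
            raise PDBParseError("cannot determine element symbol", line_no)
        if altloc and altloc_policy == "keep-first":
            site = (chain, resnum, name.strip())
            if site in seen_sites:
                continue
            seen_sites.add(site)
        atoms.append(
            AtomRecord(
                serial=serial, name=name.strip(), element=element,
                coords=(x, y, z), chain_id=chain, residue_name=resname,
                residue_number=resnum, is_hetero=is_het, altloc=altloc,
            )
        )
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records accepted from input")
    return MolecularStructure(atoms, source_label)


def write_pdb(s: MolecularStructure, stream: IO[str]) -> None:
    """Serialize back to fixed-column PDB (ATOM/HETATM + TER/END)."""
    last_chain = None
    for a in s.atoms:
        if last_chain is not None and a.chain_id != last_chain:
            stream.write("TER\n")
        last_chain = a.chain_id
        rec = "HETATM" if a.is_hetero else "ATOM"
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        stream.write(
            f"{rec:<6s}{a.serial:>5d} {name:<4.4s}{a.altloc or ' ':1s}"
            f"{a.residue_name:>3.3s} {a.chain_id:1.1s}{a.residue_number:>4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element.upper():>2.2s}\n"
        )
    stream.write("END\n")


# ---------------------------------------------------------------------------
# radius / color assignment


def assign_radii(
    s: MolecularStructure,
    radius_set: str | Mapping[str, float] = "bondi",
    fallback: float | None = None,
) -> MolecularStructure:
    """Return a copy with van-der-Waals radii assigned per element.

    Unknown elements take ``fallback`` if given, else raise
    :class:`MissingRadiusError` listing every offending element.
    """
    table = RADIUS_SETS[radius_set] if isinstance(radius_set, str) else radius_set
    lookup = {k.upper(): v for k, v in table.items()}
    missing = []
    out = []
    for a in s.atoms:
        r = lookup.get(a.element.upper(), fallback)
        if r is None:
            missing.append(a.element)
            continue
        out.append(replace(a, radius=float(r)))
    if missing:
        raise MissingRadiusError(missing)
    return MolecularStructure(out, s.source_label)


def assign_colors(s: MolecularStructure, scheme: ColorScheme | None = None) -> MolecularStructure:
    """Return a copy with an RGB color on every atom.

    ``element`` mode looks the element up in the palette; ``chain`` mode
    assigns one palette color per chain in chain order, cycling; ``uniform``
    paints everything with the scheme's fallback color.
    """
    scheme = scheme or ColorScheme()
    if scheme.mode == "chain":
        palette = list(scheme.palette)
        chain_color = {
            c: tuple(palette[i % len(palette)]) for i, c in enumerate(s.chains)
        }
    out = []
    for a in s.atoms:
        if scheme.mode == "element":
            color = scheme.palette.get(a.element.upper(), scheme.fallback)
        elif scheme.mode == "chain":
            color = chain_color[a.chain_id]
        else:
            color = scheme.fallback
        out.append(replace(a, color=tuple(float(c) for c in color)))
    return MolecularStructure(out, s.source_label)
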