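"""Geometry I/O, density export, and synthetic fixture generators.

File conventions: coordinates in XYZ files are Angstrom (internally bohr);
cube files are written in bohr with Z-fastest value ordering.  The extended
XYZ comment line carries the cell (``Lattice="..."``) and per-atom fragment
and role columns, so a written geometry round-trips losslessly.

The generators stand in for external datasets: rigid water dimer scans,
idealized hydrogen-bonded clusters (pentamer, prism-like hexamer), and seeded
random water boxes.  They produce structurally analogous inputs, not any
published coordinates; every generator is deterministic given its seed.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field as dc_field
from math import cos, pi, radians, sin

import numpy as np

from .exceptions import PackingError, ParseError
from .grid import ScalarField, SimulationCell
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

__all__ = [
    "Geometry",
    "read_xyz",
    "write_xyz",
    "write_cube",
    "water_molecule",
    "generate_dimer_scan",
    "generate_symmetric_dimer",
    "generate_water_box",
    "generate_cluster",
    "hexamer_partitions",
    "bulk_study_tasks",
    "swap_roles",
]

_ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
    "K": 19, "Ca": 20, "Pd": 46,
}

# Rigid gas-phase water monomer (Angstrom / degrees)
R_OH_ANGSTROM = 0.9572
HOH_ANGLE_DEG = 104.52


@dataclass
class Geometry:
    """Atoms + cell + fragment bookkeeping (positions in bohr internally)."""

    elements: list
    positions: np.ndarray  # (n, 3) bohr
    cell: SimulationCell
    fragments: np.ndarray  # per-atom fragment (molecule) index
    roles: dict = dc_field(default_factory=dict)  # fragment index -> "QM" | "MM"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.fragments = np.asarray(self.fragments, dtype=int)
        if len(self.elements) != len(self.positions) or len(self.fragments) != len(
            self.positions
        ):
            raise ValueError("elements, positions and fragments must align")
        for f in np.unique(self.fragments):
            self.roles.setdefault(int(f), "MM")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def fragment_ids(self) -> list:
        return sorted(int(f) for f in np.unique(self.fragments))

    def fragment_atoms(self, fid: int) -> np.ndarray:
        return np.where(self.fragments == fid)[0]

    def fragments_with_role(self, role: str) -> list:
        return [f for f in self.fragment_ids if self.roles[f] == role]

    @property
    def partition_label(self) -> str:
        """The n/m label: n fragments at the QM level, m at the MM level."""
        return (
            f"{len(self.fragments_with_role('QM'))}/"
            f"{len(self.fragments_with_role('MM'))}"
        )

    def with_roles(self, roles: dict) -> "Geometry":
        new = dict(self.roles)
        new.update({int(k): v for k, v in roles.items()})
        return Geometry(
            list(self.elements), self.positions.copy(), self.cell,
            self.fragments.copy(), new,
        )

    def check_water_bonding(self, max_oh_angstrom: float = 1.3):
        """Sanity check: each declared water fragment is internally bonded."""
        for fid in self.fragment_ids:
            idx = self.fragment_atoms(fid)
            els = [self.elements[i] for i in idx]
            if sorted(els) != ["H", "H", "O"]:
                continue
            o = idx[els.index("O")]
            for i in idx:
                if self.elements[i] == "H":
                    d = np.linalg.norm(
                        self.cell.minimum_image(self.positions[i] - self.positions[o])
                    )
                    if d * ANGSTROM_PER_BOHR > max_oh_angstrom:
                        raise ValueError(
                            f"fragment {fid}: O-H distance {d * ANGSTROM_PER_BOHR:.2f} A "
                            f"exceeds {max_oh_angstrom} A"
                        )


def swap_roles(geom: Geometry) -> Geometry:
    """Exchange QM and MM labels on every fragment."""
    flipped = {f: ("MM" if r == "QM" else "QM") for f, r in geom.roles.items()}
    return geom.with_roles(flipped)


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def write_xyz(geom: Geometry, path):
    """Write extended XYZ (Angstrom) with cell, fragment and role columns."""
    lat = (geom.cell.lattice * ANGSTROM_PER_BOHR).reshape(-1)
    lat_str = " ".join(f"{x:.12f}" for x in lat)
    lines = [str(geom.n_atoms)]
    lines.append(
        f'Lattice="{lat_str}" '
        "Properties=species:S:1:pos:R:3:frag:I:1:role:S:1 pbc=\"T T T\""
    )
    for el, pos, frag in zip(geom.elements, geom.positions, geom.fragments):
        x, y, z = pos * ANGSTROM_PER_BOHR
        role = geom.roles[int(frag)]
        lines.append(f"{el:<2s} {x:18.12f} {y:18.12f} {z:18.12f} {int(frag):4d} {role}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> Geometry:
    """Read the extended XYZ written by :func:`write_xyz`."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise ParseError("empty file", line=1)
    try:
        natoms = int(raw[0].strip())
    except ValueError:
        raise ParseError(f"malformed atom count {raw[0]!r}", line=1) from None
    if len(raw) < natoms + 2:
        raise ParseError(f"expected {natoms} atom lines", line=len(raw))
    m = _LATTICE_RE.search(raw[1])
    if not m:
        raise ParseError("missing Lattice=\"...\" in comment line", line=2)
    lat = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
    cell = SimulationCell(lat * BOHR_PER_ANGSTROM)

    elements, positions, fragments, roles = [], [], [], {}
    for k in range(natoms):
        lineno = k + 3
        parts = raw[k + 2].split()
        if len(parts) < 6:
            raise ParseError(f"expected 6 columns, got {len(parts)}", line=lineno)
        el = parts[0]
        if el not in _ELEMENT_Z:
            raise ParseError(f"unknown element {el!r}", line=lineno)
        try:
            pos = [float(v) for v in parts[1:4]]
            frag = int(parts[4])
        except ValueError:
            raise ParseError("malformed coordinate or fragment column", line=lineno) from None
        role = parts[5]
        if role not in ("QM", "MM"):
            raise ParseError(f"role must be QM or MM, got {role!r}", line=lineno)
        elements.append(el)
        positions.append(np.array(pos) * BOHR_PER_ANGSTROM)
        fragments.append(frag)
        prev = roles.setdefault(frag, role)
        if prev != role:
            raise ParseError(f"fragment {frag} has conflicting roles", line=lineno)
    return Geometry(elements, np.array(positions), cell, np.array(fragments), roles)


def write_cube(field: ScalarField, geom: Geometry | None, path):
    """Write a Gaussian cube file (bohr header, Z-fastest value ordering)."""
    grid = field.grid
    n1, n2, n3 = grid.shape
    A = grid.cell.lattice
    vox = [A[d] / grid.shape[d] for d in range(3)]
    atoms = []
    if geom is not None:
        for el, pos in zip(geom.elements, geom.positions):
            atoms.append((_ELEMENT_Z.get(el, 0), pos))
    with open(path, "w") as fh:
        fh.write("dfqmmm scalar field\n")
        fh.write(f"integral = {float(np.sum(field.values)) * grid.dv:.10e}\n")
        fh.write(f"{len(atoms):5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        for n, v in zip(grid.shape, vox):
            fh.write(f"{n:5d} {v[0]:12.6f} {v[1]:12.6f} {v[2]:12.6f}\n")
        for z, pos in atoms:
            fh.write(
                f"{z:5d} {float(z):12.6f} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n"
            )
        flat = field.values.reshape(n1 * n2, n3)
        for row in flat:
            for start in range(0, n3, 6):
                chunk = row[start : start + 6]
                fh.write("".join(f"{v:13.5e}" for v in chunk) + "\n")


# ---------------------------------------------------------------------------
# Rigid water geometry
# ---------------------------------------------------------------------------

def water_molecule(center_bohr, rotation=None) -> np.ndarray:
    """Positions (3, 3) bohr of a rigid water: O, H, H.

    The reference monomer lies in the xz-plane with the HOH bisector along +z
    and O at the origin; ``rotation`` (3x3) is applied before translation.
    """
    r = R_OH_ANGSTROM * BOHR_PER_ANGSTROM
    half = radians(HOH_ANGLE_DEG) / 2.0
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [r * sin(half), 0.0, r * cos(half)],
            [-r * sin(half), 0.0, r * cos(half)],
        ]
    )
    if rotation is not None:
        local = local @ np.asarray(rotation, float).T
    return local + np.asarray(center_bohr, float)


def _rotation_about(axis, angle) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + sin(angle) * K + (1 - cos(angle)) * (K @ K)


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _water_geometry(centers, rotations, cell, roles=None) -> Geometry:
    elements, positions, fragments = [], [], []
    for i, (c, R) in enumerate(zip(centers, rotations)):
        pos = water_molecule(c, R)
        elements.extend(["O", "H", "H"])
        positions.extend(pos)
        fragments.extend([i, i, i])
    return Geometry(
        elements, np.array(positions), cell, np.array(fragments), roles or {}
    )


def generate_dimer_scan(
    r_min: float = 2.3,
    r_max: float = 7.7,
    n_points: int = 28,
    orientation: str = "donor-acceptor",
    cell_edge: float = 20.0,
) -> list[Geometry]:
    """Rigid water dimer geometries at evenly spaced O-O distances.

    Distances and the cell edge are in Angstrom.  The first fragment (index 0,
    the hydrogen-bond donor in the donor-acceptor orientation) is labeled QM,
    the second MM; :func:`swap_roles` gives the mirrored labeling for the
    QM/MM vs MM/QM consistency test.
    """
    if r_min >= r_max and n_points > 1:
        raise ValueError("r_min must be smaller than r_max")
    edge = cell_edge * BOHR_PER_ANGSTROM
    cell = SimulationCell.cubic(edge)
    center = np.full(3, edge / 2.0)
    rr = (
        np.linspace(r_min, r_max, n_points)
        if n_points > 1
        else np.array([r_min])
    ) * BOHR_PER_ANGSTROM

    geoms = []
    for d in rr:
        if orientation == "inversion":
            geoms.append(_symmetric_dimer_at(d, cell, center))
            continue
        # donor: one O-H bond pointing along +x toward the acceptor oxygen
        Rd = _rotation_about([0, 1, 0], pi / 2.0 - radians(HOH_ANGLE_DEG) / 2.0)
        donor_c = center - np.array([d / 2.0, 0.0, 0.0])
        # acceptor: bisector pointing away from the donor, tilted out of axis
        Ra = _rotation_about([0, 1, 0], -pi / 2.0) @ _rotation_about([1, 0, 0], pi / 3)
        accept_c = center + np.array([d / 2.0, 0.0, 0.0])
        geoms.append(
            _water_geometry(
                [donor_c, accept_c], [Rd, Ra], cell, roles={0: "QM", 1: "MM"}
            )
        )
    return geoms


def _symmetric_dimer_at(d_bohr, cell, center) -> Geometry:
    """Two waters exactly related by inversion through the cell center."""
    R = _rotation_about([0, 1, 0], pi / 3.0)
    pos_a = water_molecule(center - np.array([d_bohr / 2.0, 0, 0]), R)
    pos_b = 2.0 * center - pos_a  # inversion image
    elements = ["O", "H", "H"] * 2
    positions = np.vstack([pos_a, pos_b])
    return Geometry(
        elements, positions, cell, np.array([0, 0, 0, 1, 1, 1]),
        roles={0: "QM", 1: "MM"},
    )


def generate_symmetric_dimer(
    r_oo: float = 2.9, cell_edge: float = 12.0, angstrom: bool = True
) -> Geometry:
    """Inversion-symmetric water dimer (exact QM/MM <-> MM/QM symmetry)."""
    scale = BOHR_PER_ANGSTROM if angstrom else 1.0
    edge = cell_edge * scale
    cell = SimulationCell.cubic(edge)
    center = np.full(3, edge / 2.0)
    return _symmetric_dimer_at(r_oo * scale, cell, center)


def generate_water_box(
    n_molecules: int, box_edge: float, seed: int, min_oo: float = 2.4,
    max_attempts_per_molecule: int = 4000,
) -> Geometry:
    """Seeded random rigid-water packing (edges and distances in Angstrom).

    Oxygen positions are rejection-sampled so that every intermolecular O-O
    distance is at least ``min_oo`` Angstrom under the minimum image
    convention; orientations are uniform random rotations.  Deterministic for
    a given (n_molecules, box_edge, seed).
    """
    rng = np.random.default_rng(seed)
    edge = box_edge * BOHR_PER_ANGSTROM
    cell = SimulationCell.cubic(edge)
    dmin = min_oo * BOHR_PER_ANGSTROM
    centers = []
    attempts = 0
    budget = max_attempts_per_molecule * n_molecules
    while len(centers) < n_molecules:
        if attempts >= budget:
            raise PackingError(
                f"failed to place {n_molecules} molecules at O-O >= {min_oo} A "
                f"in a {box_edge} A box after {budget} attempts"
            )
        attempts += 1
        cand = rng.random(3) * edge
        ok = all(
            np.linalg.norm(cell.minimum_image(cand - c)) >= dmin for c in centers
        )
        if ok:
            centers.append(cand)
    rotations = [_random_rotation(rng) for _ in range(n_molecules)]
    return _water_geometry(centers, rotations, cell)


def generate_cluster(kind: str, oo_distance: float = 2.8, cell_edge: float = 16.0) -> Geometry:
    """Idealized hydrogen-bonded water clusters (distances in Angstrom).

    ``pentamer``: one central water plus its four nearest neighbors on
    tetrahedral directions (the central molecule is fragment 0, tagged QM).
    ``hexamer``: a prism-like arrangement of six waters, two stacked
    triangles.  These are structurally analogous fixtures, not any published
    cluster coordinates.
    """
    edge = cell_edge * BOHR_PER_ANGSTROM
    cell = SimulationCell.cubic(edge)
    center = np.full(3, edge / 2.0)
    d = oo_distance * BOHR_PER_ANGSTROM
    if kind == "pentamer":
        dirs = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
        centers = [center] + [center + d * u for u in dirs]
        rotations = [np.eye(3)]
        for u in dirs:  # neighbors: bisector pointing back at the center
            axis = np.cross([0.0, 0.0, 1.0], -u)
            ang = float(np.arccos(np.clip(-u[2], -1, 1)))
            R = _rotation_about(axis, ang) if np.linalg.norm(axis) > 1e-12 else np.eye(3)
            rotations.append(R)
        roles = {0: "QM", **{i: "MM" for i in range(1, 5)}}
        return _water_geometry(centers, rotations, cell, roles)
    if kind == "hexamer":
        tri = [
            np.array([cos(2 * pi * k / 3), sin(2 * pi * k / 3), 0.0]) * d / np.sqrt(3.0)
            for k in range(3)
        ]
        centers = [center + t - [0, 0, d / 2] for t in tri] + [
            center + t + [0, 0, d / 2] for t in tri
        ]
        rotations = [
            _rotation_about([0, 0, 1], 2 * pi * k / 6.0) @ _rotation_about([1, 0, 0], pi / 2)
            for k in range(6)
        ]
        return _water_geometry(centers, rotations, cell)
    raise ValueError(f"unknown cluster kind {kind!r}")


def hexamer_partitions(geom: Geometry, k: int | None = None):
    """Enumerate QM/MM partitions of a 6-molecule cluster.

    For a given ``k``, yields the binomial(6, k) geometries with k fragments
    at the QM level; with ``k=None`` yields the full 2^6 power set.
    """
    fids = geom.fragment_ids
    ks = range(len(fids) + 1) if k is None else [k]
    for kk in ks:
        for combo in itertools.combinations(fids, kk):
            roles = {f: ("QM" if f in combo else "MM") for f in fids}
            yield geom.with_roles(roles)


def bulk_study_tasks(
    n_boxes: int = 10, n_molecules: int = 64, box_edge: float = 12.42,
    base_seed: int = 0,
):
    """Enumerate the single-molecule interaction tasks of a bulk study.

    Each task promotes one molecule of one snapshot to the QM level (the n/m
    = 1/(n_molecules-1) partitioning); ``n_boxes`` snapshots of
    ``n_molecules`` waters yield n_boxes * n_molecules tasks.
    """
    tasks = []
    for b in range(n_boxes):
        for m in range(n_molecules):
            tasks.append(
                {
                    "box": b,
                    "seed": base_seed + b,
                    "molecule": m,
                    "box_edge": box_edge,
                    "n_molecules": n_molecules,
                    "label": f"1/{n_molecules - 1}",
                }
            )
    return tasks
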