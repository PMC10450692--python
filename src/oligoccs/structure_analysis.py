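"""Structure-derived observables for interpreting oligomer states.

Five desk-scale metrics link atomic models to the ion-mobility data:

* projection-approximation CCS — orientation-averaged projected shadow area
  of the hard-sphere atomic model, estimated by Monte-Carlo hit-or-miss
  sampling on the projection plane;
* Shrake-Rupley solvent-accessible surface area (probe 1.4 A by default)
  and the hydrophobic-SASA fraction;
* residue-residue contact maps (minimum heavy-atom distance, reported in nm);
* a 0-1 compactness score (equal-volume-sphere surface over total SASA;
  1 = maximally sphere-like, small = extended);
* gromos (Daura) conformational clustering of multi-model coordinate sets
  with an RMSD cutoff (0.4 nm by default).

Coordinates and radii are carried in Angstrom throughout; only contact maps
and the clustering cutoff use nm, matching field conventions.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("oligoccs")

#: Bondi van der Waals radii (A); unknown elements fall back to FALLBACK_RADIUS.
BONDI_RADII = {
    "H": 1.20, "HE": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "NE": 1.54, "SI": 2.10, "P": 1.80, "S": 1.80, "CL": 1.75, "AR": 1.88,
    "BR": 1.85, "I": 1.98, "ZN": 1.39, "CU": 1.40, "SE": 1.90,
}
FALLBACK_RADIUS = 1.70
WATER_PROBE_RADIUS = 1.4

#: Hydrophobic residues (Kyte-Doolittle positive plus Trp), 3-letter codes.
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "CYS", "TRP"}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, coordinates (A), vdW radius (A), residue bookkeeping."""

    element: str
    coordinates: tuple[float, float, float]
    radius: float
    chain_id: str = "A"
    residue_index: int = 1
    residue_name: str = "UNK"
    name: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


@dataclass
class StructureModel:
    """Atoms grouped into chains and residues, with cached coordinate arrays."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure must contain at least one atom")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        return sorted({a.chain_id for a in self.atoms})

    def chain_atoms(self, chain_id: str) -> list[int]:
        idx = [i for i, a in enumerate(self.atoms) if a.chain_id == chain_id]
        if not idx:
            raise ValueError(f"unknown chain id: {chain_id!r}")
        return idx

    def residues(self, chain_id: str) -> list[tuple[int, str, list[int]]]:
        """(residue_index, residue_name, atom indices) per residue, in order."""
        by_res: dict[int, list[int]] = {}
        names: dict[int, str] = {}
        for i in self.chain_atoms(chain_id):
            a = self.atoms[i]
            by_res.setdefault(a.residue_index, []).append(i)
            names[a.residue_index] = a.residue_name
        return [(r, names[r], by_res[r]) for r in sorted(by_res)]

    def translated(self, shift: Sequence[float]) -> "StructureModel":
        shift = np.asarray(shift, dtype=float)
        return StructureModel(
            [
                AtomRecord(
                    a.element, tuple(np.asarray(a.coordinates) + shift), a.radius,
                    a.chain_id, a.residue_index, a.residue_name, a.name,
                )
                for a in self.atoms
            ]
        )

    def rotated(self, matrix: np.ndarray) -> "StructureModel":
        matrix = np.asarray(matrix, dtype=float)
        return StructureModel(
            [
                AtomRecord(
                    a.element, tuple(matrix @ np.asarray(a.coordinates)), a.radius,
                    a.chain_id, a.residue_index, a.residue_name, a.name,
                )
                for a in self.atoms
            ]
        )


def element_radius(element: str) -> float:
    """Bondi vdW radius for an element symbol; falls back to 1.70 A with a warning."""
    key = element.strip().upper()
    if key in BONDI_RADII:
        return BONDI_RADII[key]
    logger.warning("unknown element %r: using fallback radius %.2f A", element, FALLBACK_RADIUS)
    return FALLBACK_RADIUS


def read_structure(pdb_text: str, frame: int = 1) -> StructureModel:
    """Parse PDB text into a StructureModel; ``frame`` selects the MODEL (1-based)."""
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("model", io.StringIO(pdb_text))
    models = list(structure.get_models())
    if not models:
        raise ValueError("PDB text contains no models")
    if not 1 <= frame <= len(models):
        raise ValueError(f"frame {frame} out of range (1..{len(models)})")
    model = models[frame - 1]
    atoms = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                element = (atom.element or atom.get_name()[:1]).strip()
                atoms.append(
                    AtomRecord(
                        element=element,
                        coordinates=tuple(float(x) for x in atom.coord),
                        radius=element_radius(element),
                        chain_id=chain.id.strip() or "A",
                        residue_index=residue.id[1],
                        residue_name=residue.get_resname().strip(),
                        name=atom.get_name(),
                    )
                )
    if not atoms:
        raise ValueError("PDB text contains no atoms")
    return StructureModel(atoms)


def read_frames(pdb_text: str) -> list[np.ndarray]:
    """Coordinate arrays (A) of every MODEL in a multi-model PDB."""
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("traj", io.StringIO(pdb_text))
    frames = [
        np.array([atom.coord for atom in model.get_atoms()], dtype=float)
        for model in structure.get_models()
    ]
    if not frames:
        raise ValueError("PDB text contains no models")
    return frames


# ---------------------------------------------------------------------------
# projection-approximation CCS
# ---------------------------------------------------------------------------

def _random_projection_bases(rng: np.random.Generator, count: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane bases (e1, e2) for ``count`` uniform random axes."""
    axis = rng.normal(size=(count, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    helper = rng.normal(size=(count, 3))
    e1 = helper - np.sum(helper * axis, axis=1, keepdims=True) * axis
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axis, e1)
    return e1, e2


def pa_ccs(
    structure: StructureModel,
    n_orientations: int = 1000,
    probe_radius: float = 0.0,
    seed: int | None = None,
    n_plane_samples: int = 512,
    return_sem: bool = False,
    scale_factor: float = 1.0,
):
    """Projection-approximation CCS (A^2) by Monte-Carlo shadow-area sampling.

    For each of ``n_orientations`` uniformly random orientations the atoms
    (inflated by ``probe_radius``) are projected onto the viewing plane and
    the union area of the resulting disks is estimated by hit-or-miss
    sampling of ``n_plane_samples`` points in the disks' bounding box. The
    CCS is the orientation average, optionally multiplied by ``scale_factor``
    (kept at 1.0 by default; tunable toward buffer-gas-calibrated values).
    Reproducible for a fixed ``seed``; with ``return_sem`` the
    orientation-to-orientation standard error is returned as well.
    """
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    coords = structure.coordinates
    radii = structure.radii + probe_radius
    rng = np.random.default_rng(seed)
    areas = np.empty(n_orientations)
    chunk = 1024
    done = 0
    while done < n_orientations:
        count = min(chunk, n_orientations - done)
        e1, e2 = _random_projection_bases(rng, count)
        px = coords @ e1.T  # (n_atoms, count)
        py = coords @ e2.T
        lo_x = (px - radii[:, None]).min(axis=0)
        hi_x = (px + radii[:, None]).max(axis=0)
        lo_y = (py - radii[:, None]).min(axis=0)
        hi_y = (py + radii[:, None]).max(axis=0)
        sx = lo_x[:, None] + rng.random((count, n_plane_samples)) * (hi_x - lo_x)[:, None]
        sy = lo_y[:, None] + rng.random((count, n_plane_samples)) * (hi_y - lo_y)[:, None]
        hit = np.zeros((count, n_plane_samples), dtype=bool)
        for i in range(coords.shape[0]):
            hit |= (sx - px[i][:, None]) ** 2 + (sy - py[i][:, None]) ** 2 <= radii[i] ** 2
        box_area = (hi_x - lo_x) * (hi_y - lo_y)
        areas[done : done + count] = box_area * hit.mean(axis=1)
        done += count
    mean = scale_factor * float(areas.mean())
    if return_sem:
        sem = scale_factor * float(areas.std(ddof=1) / np.sqrt(n_orientations)) if n_orientations > 1 else 0.0
        return mean, sem
    return mean


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _golden_spiral_points(count: int) -> np.ndarray:
    """Near-uniform unit-sphere quadrature points (golden-spiral lattice)."""
    k = np.arange(count, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / count
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    structure: StructureModel,
    probe_radius: float = WATER_PROBE_RADIUS,
    points_per_atom: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), Shrake-Rupley.

    Each atom's accessible sphere (radius vdW + probe) is sampled with a
    golden-spiral lattice; a point is accessible if no neighbouring atom's
    accessible sphere contains it. The per-atom area is the accessible
    fraction times the full sphere area; total SASA is the sum.
    """
    if points_per_atom < 32:
        raise ValueError("points_per_atom must be >= 32")
    coords = structure.coordinates
    radii = structure.radii + probe_radius
    sphere = _golden_spiral_points(points_per_atom)
    tree = cKDTree(coords)
    r_max = radii.max()
    areas = np.empty(len(structure.atoms))
    for i in range(coords.shape[0]):
        pts = coords[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + r_max) if j != i]
        if neighbours:
            nb_coords = coords[neighbours]
            nb_radii = radii[neighbours]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nb_radii[None, :] ** 2).any(axis=1)
            accessible = float((~buried).mean())
        else:
            accessible = 1.0
        areas[i] = accessible * 4.0 * np.pi * radii[i] ** 2
    return areas


def hydrophobic_sasa_ratio(
    structure: StructureModel,
    per_atom_areas: np.ndarray | None = None,
    hydrophobic_residue_set: set[str] = HYDROPHOBIC_RESIDUES,
    probe_radius: float = WATER_PROBE_RADIUS,
) -> float:
    """Fraction of total SASA contributed by atoms in hydrophobic residues."""
    if per_atom_areas is None:
        per_atom_areas = shrake_rupley_sasa(structure, probe_radius=probe_radius)
    hydrophobic = {ONE_TO_THREE.get(r, r).upper() for r in hydrophobic_residue_set}
    total = float(np.sum(per_atom_areas))
    if total <= 0:
        raise ValueError("total SASA is zero")
    mask = np.array([a.residue_name.upper() in hydrophobic for a in structure.atoms])
    return float(np.sum(per_atom_areas[mask])) / total


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def contact_map(
    structure: StructureModel,
    chain_a: str,
    chain_b: str | None = None,
    heavy_only: bool = True,
):
    """Residue x residue minimum-atom-distance matrix in nm.

    ``chain_b=None`` (or equal to ``chain_a``) gives the intra-chain map,
    which is symmetric with a zero diagonal. Hydrogens are excluded by
    default. Returns (matrix, residue indices of chain_a, of chain_b).
    """
    from scipy.spatial.distance import cdist

    coords = structure.coordinates

    def _residue_coords(chain: str):
        out = []
        for res_idx, _, atom_idx in structure.residues(chain):
            if heavy_only:
                atom_idx = [i for i in atom_idx if structure.atoms[i].element.upper() != "H"]
            if atom_idx:
                out.append((res_idx, coords[atom_idx]))
        return out

    res_a = _residue_coords(chain_a)
    res_b = _residue_coords(chain_b) if chain_b not in (None, chain_a) else res_a
    matrix = np.empty((len(res_a), len(res_b)))
    for i, (_, ca) in enumerate(res_a):
        for j, (_, cb) in enumerate(res_b):
            matrix[i, j] = cdist(ca, cb).min()
    matrix /= 10.0  # A -> nm
    return matrix, [r for r, _ in res_a], [r for r, _ in res_b]


# ---------------------------------------------------------------------------
# compactness
# ---------------------------------------------------------------------------

def monte_carlo_volume(
    structure: StructureModel,
    inflate_radius: float = 0.0,
    n_samples: int = 200_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo volume (A^3) of the union of atoms inflated by ``inflate_radius``."""
    coords = structure.coordinates
    radii = structure.radii + inflate_radius
    rng = np.random.default_rng(seed)
    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    pts = lo + rng.random((n_samples, 3)) * (hi - lo)
    inside = np.zeros(n_samples, dtype=bool)
    for i in range(coords.shape[0]):
        inside |= ((pts - coords[i]) ** 2).sum(axis=1) <= radii[i] ** 2
    return float(np.prod(hi - lo) * inside.mean())


def compactness(
    structure: StructureModel,
    probe_radius: float = WATER_PROBE_RADIUS,
    points_per_atom: int = 960,
    n_volume_samples: int = 200_000,
    seed: int | None = 0,
) -> float:
    """0-1 shape score: surface of the equal-volume sphere over total SASA.

    Volume and surface describe the same probe-inflated body, so the
    isoperimetric inequality bounds the ratio by 1 (a sphere minimises
    surface at fixed volume); extended shapes score lower. Monte-Carlo noise
    is clamped at the boundary.
    """
    sasa = float(np.sum(shrake_rupley_sasa(structure, probe_radius, points_per_atom)))
    if sasa <= 0:
        raise ValueError("total SASA is zero")
    volume = monte_carlo_volume(structure, probe_radius, n_volume_samples, seed)
    if volume <= 0:
        raise ValueError("degenerate zero-volume structure")
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(np.clip(4.0 * np.pi * r_eq**2 / sasa, 0.0, 1.0))


# ---------------------------------------------------------------------------
# gromos (Daura) clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Cluster assignments per frame, central frames, sizes (descending)."""

    assignments: np.ndarray          # cluster id per frame, 0 = largest
    centers: list[int]               # central frame index per cluster
    sizes: list[int]

    def __post_init__(self) -> None:
        if sum(self.sizes) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the frame count")


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares (Kabsch) RMSD in A after optimal superposition.

    SVD-based, so degenerate (planar/collinear) coordinate sets are handled;
    the proper-rotation constraint flips the smallest singular value when the
    optimal orthogonal map would be a reflection.
    """
    a = np.asarray(a, float) - np.mean(a, axis=0)
    b = np.asarray(b, float) - np.mean(b, axis=0)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shapes")
    u, s, vt = np.linalg.svd(a.T @ b)
    sign = np.sign(np.linalg.det(u @ vt))
    s[-1] *= sign
    n = a.shape[0]
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * np.sum(s)) / n
    return float(np.sqrt(max(msd, 0.0)))


def pairwise_rmsd_matrix(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs (A)."""
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = superposed_rmsd(frames[i], frames[j])
    return mat


def daura_cluster(frames: Sequence[np.ndarray], cutoff: float = 0.4) -> ClusterResult:
    """gromos conformational clustering with an RMSD ``cutoff`` in nm.

    Iteratively takes the frame with the most neighbours within the cutoff
    as a cluster centre, removes the cluster, and repeats on the remainder.
    Deterministic; neighbour-count ties break to the lowest frame index.
    Frames are coordinate arrays in A with equal atom counts.
    """
    if not len(frames):
        raise ValueError("frame list is empty")
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("frames must have equal atom counts")
    rmsd_nm = pairwise_rmsd_matrix(frames) / 10.0
    adjacency = rmsd_nm <= cutoff
    n = len(frames)
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cluster_id = 0
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax ties break to lowest index
        members = np.flatnonzero(adjacency[center] & remaining)
        assignments[members] = cluster_id
        centers.append(center)
        sizes.append(int(members.size))
        remaining[members] = False
        cluster_id += 1
    # relabel so cluster 0 is the largest (stable for equal sizes)
    order = sorted(range(len(sizes)), key=lambda k: (-sizes[k], k))
    relabel = {old: new for new, old in enumerate(order)}
    assignments = np.array([relabel[a] for a in assignments])
    centers = [centers[k] for k in order]
    sizes = [sizes[k] for k in order]
    return ClusterResult(assignments=assignments, centers=centers, sizes=sizes)


def write_structure_pdb(structure: StructureModel) -> str:
    """Minimal single-model PDB text for a StructureModel (pseudo-atoms allowed)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        x, y, z = a.coordinates
        name = (a.name or a.element)[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{a.residue_name[:3]:>4s} {a.chain_id[:1]}"
            f"{a.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {a.element[:2]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
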