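"""Rigid-body superposition and receptor-geometry angle measurements.

Two angle metrics describe how the IL10Rβ receptor sits on the ternary
complex:

* the *static rotation* between two complexes — after least-squares
  superposition on the shared IFNλR1 chain, the Cα of an outer-loop probe
  residue (Ala46 of IL10Rβ) is measured from a vertex placed at the
  midpoint of the two Tyr82 Cα positions, which occupy nearly the same
  spot in both complexes;
* the *center-of-mass geometry angle* — the angle at the ligand COM
  between the IFNλR1 D1 domain COM and the IL10Rβ SD1 domain COM,
  evaluated per structure (or per trajectory frame in
  :mod:`complexlens.trajectory_analysis`).

Superposition is the Kabsch SVD solution with reflections disallowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Selection, SelectionError, Structure

__all__ = [
    "RigidTransform",
    "DomainDefinition",
    "GeometrySeries",
    "kabsch_superpose",
    "superpose_coords",
    "center_of_mass",
    "three_point_angle",
    "complex_geometry_angle",
    "receptor_rotation_angle",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile coords onto a reference."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd_after: float
    n_atoms_fit: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class DomainDefinition:
    """A named atom subset whose center of mass defines a geometry point."""

    name: str
    selection: Selection
    mass_weighted: bool = True


@dataclass
class GeometrySeries:
    """Per-frame geometry angles with summary statistics and a histogram."""

    angles_deg: np.ndarray
    mean_deg: float
    min_deg: float
    max_deg: float
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    domain_names: tuple[str, str, str]

    @property
    def range_deg(self) -> float:
        return self.max_deg - self.min_deg


def superpose_coords(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch fit of paired coordinate sets; returns (R, t, rmsd).

    Minimises ||R·x + t − y|| over proper rotations. The SVD sign
    correction forbids reflections.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired coordinate shapes differ: {x.shape} vs {y.shape}")
    if x.shape[0] < 3:
        raise ValueError("at least 3 paired atoms are required for superposition")
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    h = (x - cx).T @ (y - cy)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cy - rot @ cx
    moved = x @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, t, rmsd


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    mobile_sel: Selection,
    reference_sel: Selection,
) -> RigidTransform:
    """Optimal rigid transform of ``mobile`` onto ``reference``.

    The two selections are paired in order and must have equal length ≥ 3.
    """
    if len(mobile_sel) != len(reference_sel):
        raise SelectionError(
            f"alignment selections differ in length: {len(mobile_sel)} vs "
            f"{len(reference_sel)}"
        )
    if len(mobile_sel) < 3:
        raise SelectionError("alignment needs at least 3 paired atoms")
    x = mobile.coords[list(mobile_sel.resolved_indices)]
    y = reference.coords[list(reference_sel.resolved_indices)]
    rot, t, rmsd = superpose_coords(x, y)
    return RigidTransform(
        rotation=rot, translation=t, rmsd_after=rmsd, n_atoms_fit=len(mobile_sel)
    )


def center_of_mass(
    structure: Structure,
    selection: Selection,
    mass_weighted: bool = True,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted mean position of a selection (or plain centroid).

    ``coords`` substitutes an alternative coordinate frame (same atom
    ordering as the structure), which is how per-frame trajectory COMs are
    computed without rebuilding structures.
    """
    if len(selection) == 0:
        raise SelectionError("center of mass of an empty selection")
    idx = list(selection.resolved_indices)
    xyz = (structure.coords if coords is None else np.asarray(coords, dtype=float))[idx]
    if not mass_weighted:
        return xyz.mean(axis=0)
    m = structure.masses[idx]
    return (xyz * m[:, None]).sum(axis=0) / m.sum()


def three_point_angle(p1: np.ndarray, vertex: np.ndarray, p3: np.ndarray) -> float:
    """Angle (degrees, in [0, 180]) subtended at ``vertex`` by p1 and p3."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(vertex, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(vertex, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle undefined: a point coincides with the vertex")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def complex_geometry_angle(
    structure: Structure,
    d1: DomainDefinition,
    ligand: DomainDefinition,
    sd1: DomainDefinition,
    coords: np.ndarray | None = None,
) -> float:
    """D1–ligand–SD1 center-of-mass angle; the ligand COM is the vertex."""
    sets = [set(d.selection.resolved_indices) for d in (d1, ligand, sd1)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise SelectionError(
                    "geometry domains must be pairwise disjoint "
                    f"(overlap between domain {i} and {j})"
                )
    p1 = center_of_mass(structure, d1.selection, d1.mass_weighted, coords)
    v = center_of_mass(structure, ligand.selection, ligand.mass_weighted, coords)
    p3 = center_of_mass(structure, sd1.selection, sd1.mass_weighted, coords)
    return three_point_angle(p1, v, p3)


def receptor_rotation_angle(
    complex_a: Structure,
    complex_b: Structure,
    align_sel_a: Selection,
    align_sel_b: Selection,
    vertex_residue: tuple[str, int],
    probe_residue: tuple[str, int],
) -> float:
    """Static rotation (degrees) of one receptor chain between two complexes.

    ``complex_b`` is superposed onto ``complex_a`` using the paired
    alignment selections (typically the shared receptor chain's Cα atoms).
    The vertex is the midpoint of the two post-alignment Cα positions of
    ``vertex_residue`` (a residue sitting in nearly the same spot in both
    complexes, Tyr82 in the IL10Rβ case), and the returned value is the
    angle subtended at that vertex by the two Cα positions of
    ``probe_residue`` (an outer-loop residue, Ala46). Identical complexes
    give 0; the measure is symmetric in its two inputs.
    """
    transform = kabsch_superpose(complex_b, complex_a, align_sel_b, align_sel_a)

    def ca(structure: Structure, residue: tuple[str, int]) -> np.ndarray:
        chain, seq = residue[0], residue[1]
        icode = residue[2] if len(residue) > 2 else ""
        i = structure.find_atom(chain, seq, "CA", icode)
        return structure.coords[i]

    vert_a = ca(complex_a, vertex_residue)
    vert_b = transform.apply(ca(complex_b, vertex_residue))
    probe_a = ca(complex_a, probe_residue)
    probe_b = transform.apply(ca(complex_b, probe_residue))

    vertex = 0.5 * (vert_a + vert_b)
    if np.allclose(probe_a, probe_b, atol=1e-9):
        return 0.0
    return three_point_angle(probe_a, vertex, probe_b)
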