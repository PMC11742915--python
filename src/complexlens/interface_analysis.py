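"""Solvent-accessible and buried surface area, and interface polar contacts.

SASA follows the Shrake–Rupley construction: each atom's surface is the
sphere of radius r_vdw + r_probe, sampled on a deterministic Fibonacci
(golden-spiral) lattice, and a test point is buried when it falls inside
any neighbouring atom's probe-extended sphere. The buried surface area of
an interface A:B is

    BSA_twosided = SASA(A alone) + SASA(B alone) − SASA(A ∪ B)

with waters, ions and all other chains excluded from every computation, so
the number measures the pairwise interface only. The one-sided convention
(half the two-sided value, the "interface area" that PISA prints) is
reported alongside it. Per-residue BSA is the per-residue SASA loss, and
the burial fraction divides that loss by the residue's SASA in the
isolated group.

Polar contacts are a hydrogen-free proxy for hydrogen bonds: inter-group
nitrogen/oxygen heavy-atom pairs within a distance cutoff (default 3.5 Å),
with no angular term, because deposited cryoEM models carry no hydrogens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Selection, SelectionError, Structure

__all__ = [
    "SasaParams",
    "PolarContactParams",
    "PolarContact",
    "InterfaceReport",
    "fibonacci_sphere",
    "compute_sasa",
    "buried_surface_area",
    "find_polar_contacts",
    "residue_bsa_fold_change",
    "FoldChange",
]


@dataclass(frozen=True)
class SasaParams:
    """Parameters of the Shrake–Rupley surface computation.

    probe_radius : solvent probe radius in Å (1.4 ≈ water).
    sphere_points : quasi-uniform lattice points per atom; the lattice is
        deterministic, so results carry no random seed.
    include_hydrogens : when False (default) hydrogens neither contribute
        surface nor occlude it, matching heavy-atom-only deposited models.
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    include_hydrogens: bool = False

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.sphere_points < 12:
            raise ValueError("sphere_points must be >= 12")


@dataclass(frozen=True)
class PolarContactParams:
    max_distance: float = 3.5
    donor_acceptor_elements: frozenset = frozenset({"N", "O"})
    exclude_intra_residue: bool = True
    exclude_intra_group: bool = True

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


@dataclass(frozen=True)
class PolarContact:
    atom_a: int  # atom index in the structure
    atom_b: int
    distance: float
    label_a: str = ""
    label_b: str = ""


@dataclass
class InterfaceReport:
    """Buried-area accounting for one pairwise interface."""

    group_a: Selection
    group_b: Selection
    bsa_total_twosided: float
    bsa_total_onesided: float
    per_residue_bsa: dict
    per_residue_burial_fraction: dict
    polar_contacts: list = field(default_factory=list)
    params: SasaParams = field(default_factory=SasaParams)

    @property
    def n_polar_contacts(self) -> int:
        return len(self.polar_contacts)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice of ``n`` points."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _sasa_context(
    structure: Structure, indices: tuple[int, ...], params: SasaParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates, extended radii and kept-atom indices for a SASA run."""
    kept = []
    for i in indices:
        a = structure.atoms[i]
        if not params.include_hydrogens and a.element in ("H", "D"):
            continue
        kept.append(i)
    if not kept:
        raise SelectionError("SASA selection is empty (after hydrogen filtering)")
    coords = structure.coords[kept]
    radii = np.array(
        [structure.atoms[i].vdw_radius + params.probe_radius for i in kept]
    )
    return coords, radii, np.array(kept, dtype=int)


def compute_sasa(
    structure: Structure,
    selection: Selection,
    params: SasaParams | None = None,
) -> dict[int, float]:
    """Per-atom solvent-accessible surface area (Å²) of the selection.

    Only the selected atoms exist for the computation: everything outside
    the selection neither contributes surface nor occludes it. The result
    maps structure atom index -> area and is deterministic for a fixed
    ``sphere_points``.
    """
    params = params or SasaParams()
    coords, radii, kept = _sasa_context(structure, selection.resolved_indices, params)
    lattice = fibonacci_sphere(params.sphere_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(kept))
    for k in range(len(kept)):
        pts = coords[k] + radii[k] * lattice
        # neighbours whose extended sphere could cover any test point
        neigh = [j for j in tree.query_ball_point(coords[k], radii[k] + max_r) if j != k]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > radii[j] ** 2
        areas[k] = 4.0 * math.pi * radii[k] ** 2 * exposed.mean()
    return {int(i): float(a) for i, a in zip(kept, areas)}


def _per_residue(structure: Structure, atom_areas: dict[int, float]) -> dict:
    out: dict = {}
    for i, a in atom_areas.items():
        out[structure.atoms[i].residue_key] = out.get(structure.atoms[i].residue_key, 0.0) + a
    return out


def buried_surface_area(
    structure: Structure,
    group_a: Selection,
    group_b: Selection,
    params: SasaParams | None = None,
    contact_params: PolarContactParams | None = None,
    with_contacts: bool = True,
) -> InterfaceReport:
    """Buried surface area of the A:B interface, totals and per residue.

    The groups must be disjoint and non-empty. Three SASA runs are made
    (A alone, B alone, A ∪ B), each restricted to exactly those atoms.
    """
    params = params or SasaParams()
    set_a = set(group_a.resolved_indices)
    set_b = set(group_b.resolved_indices)
    shared = sorted(set_a & set_b)
    if shared:
        raise SelectionError(f"groups overlap on atom indices {shared[:10]}")
    if not set_a or not set_b:
        raise SelectionError("both interface groups must be non-empty")

    sasa_a = compute_sasa(structure, group_a, params)
    sasa_b = compute_sasa(structure, group_b, params)
    sasa_ab = compute_sasa(structure, group_a.union(group_b), params)

    alone = {**sasa_a, **sasa_b}
    total_alone = sum(alone.values())
    total_complex = sum(sasa_ab.values())
    bsa2 = max(0.0, total_alone - total_complex)

    res_alone = _per_residue(structure, alone)
    res_complex = _per_residue(structure, sasa_ab)
    per_res_bsa = {}
    per_res_frac = {}
    for key, a0 in res_alone.items():
        loss = a0 - res_complex.get(key, 0.0)
        loss = max(0.0, loss)
        per_res_bsa[key] = loss
        per_res_frac[key] = min(1.0, loss / a0) if a0 > 0 else 0.0

    contacts = (
        find_polar_contacts(structure, group_a, group_b, contact_params)
        if with_contacts
        else []
    )
    return InterfaceReport(
        group_a=group_a,
        group_b=group_b,
        bsa_total_twosided=bsa2,
        bsa_total_onesided=bsa2 / 2.0,
        per_residue_bsa=per_res_bsa,
        per_residue_burial_fraction=per_res_frac,
        polar_contacts=contacts,
        params=params,
    )


def find_polar_contacts(
    structure: Structure,
    group_a: Selection,
    group_b: Selection,
    params: PolarContactParams | None = None,
) -> list[PolarContact]:
    """Inter-group N/O heavy-atom pairs within the cutoff, sorted by distance."""
    params = params or PolarContactParams()
    if set(group_a.resolved_indices) & set(group_b.resolved_indices):
        raise SelectionError("polar-contact groups must be disjoint")

    def polar(indices):
        return [
            i
            for i in indices
            if structure.atoms[i].element in params.donor_acceptor_elements
        ]

    ia = polar(group_a.resolved_indices)
    ib = polar(group_b.resolved_indices)
    if not ia or not ib:
        return []
    ca = structure.coords[ia]
    cb = structure.coords[ib]
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), params.max_distance)
    out = []
    for k, js in enumerate(pairs):
        for j in js:
            i_a, i_b = ia[k], ib[j]
            aa, ab = structure.atoms[i_a], structure.atoms[i_b]
            if params.exclude_intra_residue and aa.residue_key == ab.residue_key:
                continue
            d = float(np.linalg.norm(aa.coords - ab.coords))
            if d <= params.max_distance:
                out.append(
                    PolarContact(
                        atom_a=i_a,
                        atom_b=i_b,
                        distance=d,
                        label_a=f"{aa.residue_label}:{aa.name}",
                        label_b=f"{ab.residue_label}:{ab.name}",
                    )
                )
    out.sort(key=lambda c: (c.distance, c.atom_a, c.atom_b))
    return out


@dataclass(frozen=True)
class FoldChange:
    fold: float
    infinite: bool = False


def residue_bsa_fold_change(
    report_x: InterfaceReport,
    report_y: InterfaceReport,
    residue_pairs: list[tuple],
) -> dict[tuple, FoldChange]:
    """Per-residue BSA ratio between two interface reports.

    ``residue_pairs`` pairs a residue key of ``report_x`` with its
    counterpart in ``report_y`` (the two complexes need not share
    numbering). A zero denominator is reported as an infinite fold with a
    flag rather than an exception.
    """
    out: dict[tuple, FoldChange] = {}
    for rx, ry in residue_pairs:
        if rx not in report_x.per_residue_bsa:
            raise KeyError(f"residue {rx} absent from first report")
        if ry not in report_y.per_residue_bsa:
            raise KeyError(f"residue {ry} absent from second report")
        bx = report_x.per_residue_bsa[rx]
        by = report_y.per_residue_bsa[ry]
        if by == 0.0:
            out[(rx, ry)] = FoldChange(fold=math.inf, infinite=True)
        else:
            out[(rx, ry)] = FoldChange(fold=bx / by, infinite=False)
    return out
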