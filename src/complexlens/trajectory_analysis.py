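"""Per-residue statistics over coordinate trajectories.

All observables follow the conventions of the underlying MD analysis
practice for this system:

* RMSF is measured against the *first frame* of the trajectory (not the
  time average): RMSF_i = sqrt(⟨|r_i(t) − r_i(0)|²⟩_t), optionally after
  superposing every frame onto frame 0 on the analysis selection so that
  rigid-body drift does not masquerade as fluctuation.
* The dynamic cross-correlation matrix normalises the covariance of
  displacement vectors about each atom's trajectory mean:
  C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) ∈ [−1, 1].
* Residue contact frequency counts, per inter-group residue pair, the
  fraction of frames with distance ≤ cutoff (10 Å default), with distance
  either the minimum heavy-atom distance or the residue-COM distance.
* Ion occupancy counts, per residue, the percentage of frames in which
  ANY selected ion lies within the cutoff (1.0 Å default) of the
  residue's per-frame center of mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DomainDefinition, GeometrySeries, superpose_coords
from .structure_io import Selection, SelectionError, Trajectory, resolve_selection

__all__ = [
    "RmsfProfile",
    "DccMatrix",
    "ContactParams",
    "ContactMap",
    "IonOccupancy",
    "rmsf",
    "dynamic_cross_correlation",
    "contact_frequency",
    "ion_occupancy",
    "angle_timeseries",
    "mean_angle_difference",
]


@dataclass
class RmsfProfile:
    residues: list  # residue keys, order of appearance
    labels: list  # human-readable residue labels
    rmsf: np.ndarray  # Å, one value per residue (its Cα / selected atom)
    reference: str = "first_frame"
    superposed: bool = True


@dataclass
class DccMatrix:
    residues: list
    labels: list
    matrix: np.ndarray  # square, symmetric, unit diagonal, entries in [-1, 1]


@dataclass(frozen=True)
class ContactParams:
    cutoff: float = 10.0
    distance_mode: str = "min-heavy-atom"  # or "residue-COM"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.distance_mode not in ("min-heavy-atom", "residue-COM"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


@dataclass
class ContactMap:
    """Per-residue-pair contact fractions over a trajectory."""

    fractions: dict  # (residue_key_a, residue_key_b) -> fraction in [0, 1]
    params: ContactParams

    def pairs_above(self, threshold: float) -> int:
        """Number of residue pairs in contact in more than ``threshold`` of frames."""
        return sum(1 for f in self.fractions.values() if f > threshold)


@dataclass
class IonOccupancy:
    residues: list
    labels: list
    percent_frames: np.ndarray  # [0, 100] per residue
    cutoff: float
    ion_selection: Selection


def _superpose_frames(traj: Trajectory, fit_indices: list[int]) -> np.ndarray:
    """All frames superposed onto frame 0 using the fit atoms; returns copies."""
    frames = traj.frames.copy()
    ref = frames[0, fit_indices]
    if len(fit_indices) < 3:  # rotation underdetermined: remove drift only
        for f in range(1, frames.shape[0]):
            frames[f] += ref.mean(axis=0) - frames[f, fit_indices].mean(axis=0)
        return frames
    for f in range(1, frames.shape[0]):
        rot, t, _ = superpose_coords(frames[f, fit_indices], ref)
        frames[f] = frames[f] @ rot.T + t
    return frames


def _default_calpha(traj: Trajectory, selection: Selection | None) -> Selection:
    if selection is not None:
        return selection
    return resolve_selection(traj.topology, {"calpha": True})


def rmsf(
    traj: Trajectory,
    selection: Selection | None = None,
    superpose: bool = True,
) -> RmsfProfile:
    """Root mean squared fluctuation per residue, referenced to frame 0.

    The default selection is all Cα atoms, so the profile has one value
    per amino-acid residue. With ``superpose`` each frame is first
    rigid-body fitted onto the first frame on the same selection.
    """
    if traj.frame_count < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _default_calpha(traj, selection)
    if len(sel) == 0:
        raise SelectionError("RMSF selection is empty")
    idx = list(sel.resolved_indices)
    frames = _superpose_frames(traj, idx) if superpose else traj.frames
    sub = frames[:, idx]  # (n_frames, n_sel, 3)
    disp2 = np.sum((sub - sub[0]) ** 2, axis=2)  # includes frame 0 (zero)
    values = np.sqrt(disp2.mean(axis=0))
    atoms = [traj.topology.atoms[i] for i in idx]
    return RmsfProfile(
        residues=[a.residue_key for a in atoms],
        labels=[a.residue_label for a in atoms],
        rmsf=values,
        reference="first_frame",
        superposed=superpose,
    )


def dynamic_cross_correlation(
    traj: Trajectory,
    selection: Selection | None = None,
    superpose: bool = True,
) -> DccMatrix:
    """Normalised displacement-vector covariance matrix over the trajectory.

    Deviations are taken from each atom's trajectory mean, after optional
    superposition of every frame onto frame 0. An atom with zero variance
    gets a zeroed row/column (diagonal kept at 1) and a warning.
    """
    if traj.frame_count < 3:
        raise ValueError("dynamic cross-correlation needs at least 3 frames")
    sel = _default_calpha(traj, selection)
    if len(sel) == 0:
        raise SelectionError("DCC selection is empty")
    idx = list(sel.resolved_indices)
    frames = _superpose_frames(traj, idx) if superpose else traj.frames
    sub = frames[:, idx]
    delta = sub - sub.mean(axis=0)  # (n_frames, n_sel, 3)
    # ⟨Δr_i · Δr_j⟩ summed over xyz, averaged over frames
    cov = np.einsum("tid,tjd->ij", delta, delta) / delta.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance atom(s) in DCC; rows zeroed",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.sqrt(np.where(zero, 1.0, var))
    mat = cov / denom[:, None] / denom[None, :]
    mat[zero, :] = 0.0
    mat[:, zero] = 0.0
    np.fill_diagonal(mat, 1.0)
    mat = np.clip(mat, -1.0, 1.0)
    atoms = [traj.topology.atoms[i] for i in idx]
    return DccMatrix(
        residues=[a.residue_key for a in atoms],
        labels=[a.residue_label for a in atoms],
        matrix=mat,
    )


def _heavy(traj: Trajectory, indices) -> list[int]:
    return [i for i in indices if traj.topology.atoms[i].element not in ("H", "D")]


def contact_frequency(
    traj: Trajectory,
    group_a: Selection,
    group_b: Selection,
    params: ContactParams | None = None,
) -> ContactMap:
    """Fraction of frames each inter-group residue pair spends within cutoff."""
    params = params or ContactParams()
    if set(group_a.resolved_indices) & set(group_b.resolved_indices):
        raise SelectionError("contact groups must be disjoint")

    top = traj.topology
    if params.distance_mode == "min-heavy-atom":
        ia = _heavy(traj, group_a.resolved_indices)
        ib = _heavy(traj, group_b.resolved_indices)
    else:
        ia = list(group_a.resolved_indices)
        ib = list(group_b.resolved_indices)
    res_a = top.atoms_by_residue(ia)
    res_b = top.atoms_by_residue(ib)
    keys_a = list(res_a)
    keys_b = list(res_b)
    counts = {(ka, kb): 0 for ka in keys_a for kb in keys_b}

    if params.distance_mode == "residue-COM":
        masses = top.masses
        for f in range(traj.frame_count):
            xyz = traj.frames[f]
            coms_a = {
                k: (xyz[v] * masses[v, None]).sum(0) / masses[v].sum()
                for k, v in ((k, np.array(v)) for k, v in res_a.items())
            }
            coms_b = {
                k: (xyz[v] * masses[v, None]).sum(0) / masses[v].sum()
                for k, v in ((k, np.array(v)) for k, v in res_b.items())
            }
            for ka, ca in coms_a.items():
                for kb, cb in coms_b.items():
                    if np.linalg.norm(ca - cb) <= params.cutoff:
                        counts[(ka, kb)] += 1
    else:
        atom_res_a = {i: k for k, v in res_a.items() for i in v}
        atom_res_b = {i: k for k, v in res_b.items() for i in v}
        for f in range(traj.frame_count):
            xyz = traj.frames[f]
            tree_a = cKDTree(xyz[ia])
            tree_b = cKDTree(xyz[ib])
            hit: set = set()
            neigh = tree_a.query_ball_tree(tree_b, params.cutoff)
            for p, js in enumerate(neigh):
                ka = atom_res_a[ia[p]]
                for j in js:
                    hit.add((ka, atom_res_b[ib[j]]))
            for pair in hit:
                counts[pair] += 1

    n = traj.frame_count
    fractions = {pair: c / n for pair, c in counts.items()}
    return ContactMap(fractions=fractions, params=params)


def ion_occupancy(
    traj: Trajectory,
    residue_set: Selection,
    ion_sel: Selection,
    cutoff: float = 1.0,
) -> IonOccupancy:
    """Percentage of frames with any ion within ``cutoff`` of each residue COM.

    The residue center of mass is recomputed every frame. The default
    1.0 Å cutoff is deliberately tight: it flags ions sitting essentially
    on top of a residue's mass center, which is how condensation of
    counter-ions onto a highly charged disordered segment is scored.
    """
    if len(ion_sel) == 0:
        raise SelectionError("ion selection is empty")
    if len(residue_set) == 0:
        raise SelectionError("residue selection is empty")
    top = traj.topology
    by_res = top.atoms_by_residue(residue_set.resolved_indices)
    keys = list(by_res)
    masses = top.masses
    ion_idx = list(ion_sel.resolved_indices)
    counts = np.zeros(len(keys), dtype=int)
    for f in range(traj.frame_count):
        xyz = traj.frames[f]
        ions = xyz[ion_idx]
        for k, key in enumerate(keys):
            v = np.array(by_res[key])
            com = (xyz[v] * masses[v, None]).sum(0) / masses[v].sum()
            d = np.linalg.norm(ions - com, axis=1)
            if (d <= cutoff).any():
                counts[k] += 1
    percent = 100.0 * counts / traj.frame_count
    label_of = {a.residue_key: a.residue_label for a in top.atoms}
    return IonOccupancy(
        residues=keys,
        labels=[label_of[k] for k in keys],
        percent_frames=percent,
        cutoff=cutoff,
        ion_selection=ion_sel,
    )


def angle_timeseries(
    traj: Trajectory,
    d1: DomainDefinition,
    ligand: DomainDefinition,
    sd1: DomainDefinition,
    bin_width_deg: float = 1.0,
) -> GeometrySeries:
    """The D1–ligand–SD1 COM angle evaluated at every frame.

    The histogram uses ``bin_width_deg`` bins spanning the observed range
    (a single bin when the series is constant).
    """
    from .geometry import complex_geometry_angle

    angles = np.array(
        [
            complex_geometry_angle(traj.topology, d1, ligand, sd1, coords=traj.frames[f])
            for f in range(traj.frame_count)
        ]
    )
    lo = np.floor(angles.min() / bin_width_deg) * bin_width_deg
    hi = np.ceil(angles.max() / bin_width_deg) * bin_width_deg
    if hi <= lo:
        hi = lo + bin_width_deg
    edges = np.arange(lo, hi + 0.5 * bin_width_deg, bin_width_deg)
    counts, edges = np.histogram(angles, bins=edges)
    return GeometrySeries(
        angles_deg=angles,
        mean_deg=float(angles.mean()),
        min_deg=float(angles.min()),
        max_deg=float(angles.max()),
        histogram_edges=edges,
        histogram_counts=counts,
        domain_names=(d1.name, ligand.name, sd1.name),
    )


def mean_angle_difference(series_a: GeometrySeries, series_b: GeometrySeries) -> float:
    """Absolute difference of the mean angles of two geometry series (degrees)."""
    return abs(series_a.mean_deg - series_b.mean_deg)
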