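"""Seeded synthetic structures and trajectories with exact ground truth.

Every generator here is a pure function of its :class:`SyntheticSpec`
(seed included): two calls with the same spec produce byte-identical
arrays. Randomness comes from a single counter-based bit generator
(numpy's Philox), so results are reproducible across platforms and
independent of call order. Each generator returns machine-readable ground
truth next to the data, and the analysis test-suite consumes only that
ground truth.

What the generators emulate:

* ``make_two_domain_complex`` — two complexes sharing a receptor chain,
  whose second chain differs by a known rigid rotation about an axis
  through a vertex residue: the fixture for the static receptor-rotation
  measurement.
* ``make_ternary_toy`` — three labelled domains placed so the
  D1–ligand–SD1 center-of-mass angle is exact by construction.
* ``make_gaussian_trajectory`` — isotropic Gaussian fluctuations with
  per-atom amplitudes and imposed pairwise correlations (Cholesky
  construction); frame 0 is pinned at each atom's mean, which gives the
  first-frame-referenced RMSF a closed form.
* ``make_ion_trajectory`` — labelled ions scripted to sit on chosen
  residues' centers of mass in chosen frames.
* ``make_sphere_interface`` — a few-sphere "complex" whose buried area
  has a closed-form spherical-cap value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "SyntheticSpec",
    "make_two_domain_complex",
    "make_ternary_toy",
    "make_gaussian_trajectory",
    "make_ion_trajectory",
    "make_sphere_interface",
    "two_sphere_buried_area",
    "two_sphere_sasa",
]


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic fixture.

    Only the fields a given generator reads need to be set; unused fields
    are ignored by that generator.
    """

    seed: int = 0
    n_frames: int = 1000
    atoms_per_domain: int = 8
    geometry_angle_deg: float = 100.0
    rotation_deg: float = 12.0
    per_atom_sigma: list = field(default_factory=lambda: [0.5])
    pair_correlations: dict = field(default_factory=dict)  # (i, j) -> rho
    ion_script: dict = field(default_factory=dict)  # residue_seq -> frame plan
    n_ions: int = 1
    ion_cutoff: float = 1.0
    sphere_layout: list = field(default_factory=list)  # (group, center, radius)
    probe_radius: float = 1.4

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.Philox(self.seed))


def _atom(
    serial, name, element, resname, resseq, chain, xyz, mass, vdw,
    is_ion=False, is_water=False,
) -> Atom:
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_seq=resseq, chain_id=chain, altloc="",
        coords=np.asarray(xyz, dtype=float), occupancy=1.0, mass=mass,
        vdw_radius=vdw, is_ion=is_ion, is_water=is_water,
    )


def _ca(serial, resseq, chain, xyz, resname="GLY") -> Atom:
    return _atom(serial, "CA", "C", resname, resseq, chain, xyz, 12.011, 1.70)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


# ---------------------------------------------------------------------------


def make_two_domain_complex(spec: SyntheticSpec) -> tuple[Structure, Structure]:
    """Base complex and a copy whose chain B is rotated by ``rotation_deg``.

    Chain R is a receptor stand-in, identical in both structures (so
    superposition on it is exact). Chain B carries a vertex residue
    (Tyr82-like, its Cα on the rotation axis, hence fixed) and a probe
    residue (Ala46-like, its Cα perpendicular to the axis), plus filler
    residues. Rotating chain B about the z-axis through the vertex by θ
    moves the probe Cα by exactly θ as seen from the vertex.
    """
    if not (0.0 <= spec.rotation_deg < 180.0):
        raise ValueError("rotation_deg must lie in [0, 180)")
    rng = spec.rng()
    n = max(4, spec.atoms_per_domain)

    # chain R: an irregular (non-degenerate) cloud away from the interface;
    # chain L: a small ligand stand-in between the two receptors, static
    r_coords = rng.normal(loc=(-20.0, 0.0, 0.0), scale=4.0, size=(n, 3))
    l_coords = rng.normal(loc=(-8.0, 2.0, 0.0), scale=2.0, size=(4, 3))
    atoms = [
        _ca(i + 1, 100 + i, "R", r_coords[i], resname="ALA") for i in range(n)
    ]
    atoms += [
        _ca(n + i + 1, 300 + i, "L", l_coords[i], resname="GLY") for i in range(4)
    ]

    vertex = np.array([0.0, 0.0, 0.0])
    probe = np.array([15.0, 0.0, 0.0])
    b_template = [
        ("TYR", 82, vertex),
        ("ALA", 46, probe),
    ]
    # filler residues on the rotation axis side, placed off-plane
    for k in range(n - 2):
        b_template.append(("GLY", 200 + k, np.array([5.0 + k, 3.0, 4.0 + 0.5 * k])))

    base_atoms = list(atoms)
    rot_atoms = list(atoms)
    rot = _rotation_about_axis([0.0, 0.0, 1.0], spec.rotation_deg)
    serial = len(atoms)
    for resname, resseq, xyz in b_template:
        serial += 1
        base_atoms.append(_ca(serial, resseq, "B", xyz, resname=resname))
        rot_atoms.append(
            _ca(serial, resseq, "B", rot @ (xyz - vertex) + vertex, resname=resname)
        )
    base = Structure(base_atoms, metadata={"ground_truth_rotation_deg": spec.rotation_deg})
    moved = Structure(rot_atoms, metadata={"ground_truth_rotation_deg": spec.rotation_deg})
    return base, moved


def make_ternary_toy(spec: SyntheticSpec) -> Structure:
    """Three-domain complex with an exact D1–ligand–SD1 COM angle.

    Each domain is a pair-symmetric equal-mass atom cluster, so its
    mass-weighted COM coincides with the placed center regardless of the
    random cluster shape. Domain centers: ligand at the origin (the
    vertex), D1 along +x, SD1 rotated by ``geometry_angle_deg`` in the
    xy-plane.
    """
    theta = spec.geometry_angle_deg
    if not (0.0 < theta < 180.0):
        raise ValueError("geometry_angle_deg must lie in (0, 180)")
    rng = spec.rng()
    n_half = max(2, spec.atoms_per_domain // 2)

    centers = {
        "L": np.zeros(3),
        "R": np.array([25.0, 0.0, 0.0]),
        "B": 30.0 * np.array([math.cos(math.radians(theta)), math.sin(math.radians(theta)), 0.0]),
    }
    atoms: list[Atom] = []
    serial = 0
    resseq = 0
    for chain in ("R", "L", "B"):
        offsets = rng.normal(scale=3.0, size=(n_half, 3))
        for off in offsets:
            for sign in (+1.0, -1.0):  # symmetric pair -> exact COM
                serial += 1
                resseq += 1
                atoms.append(_ca(serial, resseq, chain, centers[chain] + sign * off))
    return Structure(atoms, metadata={"ground_truth_angle_deg": theta})


def make_gaussian_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, dict]:
    """Gaussian-fluctuation trajectory with closed-form RMSF and DCC.

    Atom i fluctuates isotropically with amplitude ``per_atom_sigma[i]``
    per Cartesian component; requested pair correlations are imposed with
    a Cholesky factor applied identically to x, y and z, which makes the
    displacement-vector correlation equal the imposed scalar. Frame 0 is
    each atom's mean position, so

        E[RMSF_i] = σ_i · sqrt(3 · (n − 1) / n)

    including the zero frame-0 term in the average over n frames. Returns
    ``(trajectory, ground_truth)`` with ``expected_rmsf`` (Å) and
    ``expected_dcc`` (full matrix).
    """
    sigma = np.asarray(spec.per_atom_sigma, dtype=float)
    n_atoms = sigma.size
    n_frames = spec.n_frames
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    corr = np.eye(n_atoms)
    for (i, j), rho in spec.pair_correlations.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation {rho} out of [-1, 1]")
        corr[i, j] = corr[j, i] = rho
    # PSD check before factorisation
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"requested correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(n_atoms))

    rng = spec.rng()
    base = np.column_stack(
        [np.arange(n_atoms) * 10.0, np.zeros(n_atoms), np.zeros(n_atoms)]
    )
    frames = np.empty((n_frames, n_atoms, 3))
    frames[0] = base
    z = rng.standard_normal(size=(n_frames - 1, n_atoms, 3))
    corr_z = np.einsum("ij,tjd->tid", L, z)
    frames[1:] = base[None] + sigma[None, :, None] * corr_z

    topo = Structure(
        [_ca(i + 1, i + 1, "A", base[i]) for i in range(n_atoms)],
        metadata={"generator": "gaussian"},
    )
    traj = Trajectory(topology=topo, frames=frames)
    # zero-amplitude atoms have undefined DCC; the analysis zeroes them
    expected_dcc = corr.copy()
    dead = sigma == 0.0
    expected_dcc[dead, :] = 0.0
    expected_dcc[:, dead] = 0.0
    np.fill_diagonal(expected_dcc, 1.0)
    truth = {
        "expected_rmsf": sigma * math.sqrt(3.0 * (n_frames - 1) / n_frames),
        "expected_dcc": expected_dcc,
    }
    return traj, truth


def make_ion_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, dict]:
    """Trajectory with ions scripted onto residue centers frame by frame.

    ``ion_script`` maps residue_seq -> either a list of frame indices or a
    boolean list of length ``n_frames``; in a "contact" frame one of the
    ``n_ions`` chloride ions (rotating through them round-robin, so
    multi-ion alternation is exercised) is placed exactly on that
    residue's center of mass. Out-of-duty ions are parked hundreds of Å
    away. Ground truth is the exact occupancy percentage per residue.
    """
    n_frames = spec.n_frames
    residues = list(range(1, 6))
    for r in spec.ion_script:
        if r not in residues:
            residues.append(r)
    residues.sort()
    base = {r: np.array([10.0 * k, 0.0, 0.0]) for k, r in enumerate(residues)}

    atoms = [_ca(k + 1, r, "A", base[r]) for k, r in enumerate(base)]
    n_prot = len(atoms)

    def contact_frames(plan) -> set[int]:
        if all(isinstance(x, (bool, np.bool_)) for x in plan) and len(plan) == n_frames:
            return {f for f, flag in enumerate(plan) if flag}
        return {int(f) for f in plan}

    script = {r: contact_frames(plan) for r, plan in spec.ion_script.items()}
    # enough ions to serve every simultaneous contact in any single frame
    simultaneous = max(
        (sum(1 for when in script.values() if f in when) for f in range(n_frames)),
        default=0,
    )
    n_ions = max(1, spec.n_ions, simultaneous)
    park = np.array([[500.0 + 50.0 * i, 500.0, 500.0] for i in range(n_ions)])
    for i in range(n_ions):
        atoms.append(
            _atom(
                n_prot + i + 1, "CL", "Cl", "CL", 900 + i, "I", park[i],
                mass=35.45, vdw=1.75, is_ion=True,
            )
        )
    topo = Structure(atoms, metadata={"generator": "ions"})

    frames = np.empty((n_frames, len(atoms), 3))
    turn = 0
    for f in range(n_frames):
        frames[f, :n_prot] = [base[r] for r in base]
        frames[f, n_prot:] = park
        used: set[int] = set()
        for r, when in script.items():
            if f in when:
                # round-robin, skipping ions already on duty this frame
                while turn % n_ions in used:
                    turn += 1
                ion = turn % n_ions
                used.add(ion)
                turn += 1
                frames[f, n_prot + ion] = base[r]  # exactly on the residue COM
    truth = {
        "expected_percent": {
            r: 100.0 * len(script.get(r, ())) / n_frames for r in base
        },
        "protein_atom_count": n_prot,
    }
    return Trajectory(topology=topo, frames=frames), truth


# ---------------------------------------------------------------------------
# sphere-interface oracle


def two_sphere_buried_area(
    c1, r1: float, c2, r2: float, probe: float
) -> float:
    """Closed-form two-sided buried area of two probe-extended spheres (Å²).

    Uses the spherical-cap intersection formula on radii R = r + probe.
    Zero when the extended spheres do not intersect; full engulfment is
    rejected (the toy fixtures never construct it).
    """
    R1, R2 = r1 + probe, r2 + probe
    d = float(np.linalg.norm(np.asarray(c2, float) - np.asarray(c1, float)))
    if d >= R1 + R2:
        return 0.0
    if d <= abs(R1 - R2):
        raise ValueError("one extended sphere engulfs the other; no cap formula")
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d)
    return 2.0 * math.pi * (R1 * h1 + R2 * h2)


def two_sphere_sasa(c1, r1: float, c2, r2: float, probe: float) -> tuple[float, float]:
    """Analytic per-sphere SASA of an isolated two-sphere system (Å²)."""
    R1, R2 = r1 + probe, r2 + probe
    d = float(np.linalg.norm(np.asarray(c2, float) - np.asarray(c1, float)))
    a1 = 4.0 * math.pi * R1 * R1
    a2 = 4.0 * math.pi * R2 * R2
    if d >= R1 + R2:
        return a1, a2
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d)
    return a1 - 2.0 * math.pi * R1 * h1, a2 - 2.0 * math.pi * R2 * h2


def make_sphere_interface(spec: SyntheticSpec) -> tuple[Structure, float]:
    """Toy sphere complex plus its analytic two-sided buried area.

    ``sphere_layout`` entries are ``(group, center, radius)`` with group
    "A" or "B". The analytic BSA sums the pairwise inter-group cap areas,
    which is exact as long as no point is buried by two partners at once
    — the layouts used in testing are constructed that way (chains of
    spheres, not clusters).
    """
    if len(spec.sphere_layout) < 2:
        raise ValueError("sphere_layout needs at least two spheres")
    atoms = []
    for k, (group, center, radius) in enumerate(spec.sphere_layout):
        atoms.append(
            _atom(
                k + 1, "C", "C", "SPH", k + 1, group, center,
                mass=12.011, vdw=float(radius),
            )
        )
    bsa = 0.0
    for ga, ca_, ra in spec.sphere_layout:
        for gb, cb, rb in spec.sphere_layout:
            if ga == "A" and gb == "B":
                bsa += two_sphere_buried_area(ca_, ra, cb, rb, spec.probe_radius)
    return Structure(atoms, metadata={"analytic_bsa_twosided": bsa}), bsa
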