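"""Atomic structures, trajectories and declarative atom selections.

Structures are read with :mod:`gemmi` (PDB and mmCIF) and flattened into a
simple ordered atom list that keeps author residue numbering, insertion
codes, occupancies, element-resolved masses and van der Waals radii.
Alternate locations are collapsed to the highest-occupancy conformer
(ties resolved towards altloc ``A``). Trajectories are multi-model PDB
(read/written here), DCD or XTC (read through :mod:`mdtraj`'s low-level
format readers). All coordinates are Angstrom.

Selections are declarative: a small string grammar
(``"chain A, resi 1-10, calpha"``) or an equivalent dict, resolved once
against a structure into a strictly increasing atom-index tuple.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from ._radii import (
    AMINO_ACID_RESNAMES,
    MONATOMIC_ION_RESNAMES,
    WATER_RESNAMES,
    vdw_radius,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "StructureParseError",
    "SelectionError",
    "TrajectoryError",
    "parse_structure",
    "write_structure",
    "load_trajectory",
    "write_trajectory",
    "resolve_selection",
]


class StructureParseError(ValueError):
    """Raised when a structure source cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression cannot be resolved."""


class TrajectoryError(ValueError):
    """Raised for malformed trajectories (e.g. atom-count mismatch)."""


@dataclass(frozen=True)
class Atom:
    """One atom record with resolved element properties.

    ``residue_seq`` is the author residue number exactly as written in the
    source file; no renumbering is ever applied. ``icode`` is the PDB
    insertion code ('' when absent) and participates in residue identity.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    altloc: str
    coords: np.ndarray  # (3,) Å
    occupancy: float
    mass: float
    vdw_radius: float
    is_ion: bool
    is_water: bool
    icode: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_seq, icode) — the residue identity used in maps."""
        return (self.chain_id, self.residue_seq, self.icode)

    @property
    def residue_label(self) -> str:
        """Human-readable residue id, e.g. ``A:TYR82``."""
        return f"{self.chain_id}:{self.residue_name}{self.residue_seq}{self.icode.strip()}"


class Structure:
    """Ordered collection of atoms with stable (file-order) iteration."""

    def __init__(self, atoms: Sequence[Atom], metadata: dict | None = None):
        self.atoms: list[Atom] = list(atoms)
        self.metadata: dict = dict(metadata or {})
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def chains(self) -> list[str]:
        """Unique chain ids in first-appearance order."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å. Cached; atoms are immutable."""
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"atom count {len(self.atoms)}"
            )
        atoms = [
            Atom(
                serial=a.serial, name=a.name, element=a.element,
                residue_name=a.residue_name, residue_seq=a.residue_seq,
                chain_id=a.chain_id, altloc=a.altloc,
                coords=np.array(c, dtype=float), occupancy=a.occupancy,
                mass=a.mass, vdw_radius=a.vdw_radius, is_ion=a.is_ion,
                is_water=a.is_water, icode=a.icode,
            )
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, metadata=dict(self.metadata))

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Residue identities in first-appearance order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def atoms_by_residue(
        self, indices: Iterable[int] | None = None
    ) -> dict[tuple[str, int, str], list[int]]:
        """Map residue key -> atom indices (restricted to ``indices`` if given)."""
        idx = range(len(self.atoms)) if indices is None else indices
        out: dict[tuple[str, int, str], list[int]] = {}
        for i in idx:
            out.setdefault(self.atoms[i].residue_key, []).append(i)
        return out

    def find_atom(
        self, chain_id: str, residue_seq: int, atom_name: str, icode: str = ""
    ) -> int:
        """Index of the named atom, or raise SelectionError naming it."""
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_seq == residue_seq
                and a.icode.strip() == icode.strip()
                and a.name == atom_name
            ):
                return i
        raise SelectionError(
            f"atom {atom_name} of residue {chain_id}:{residue_seq}{icode} not found"
        )


@dataclass
class Selection:
    """A resolved atom subset: the original expression plus the index tuple.

    ``resolved_indices`` is strictly increasing. An empty selection is a
    valid, distinguishable object (``resolved_indices == ()``); an
    *unresolved* expression is simply never turned into a Selection.
    """

    expression: object
    resolved_indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_indices)

    def __post_init__(self):
        idx = tuple(int(i) for i in self.resolved_indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SelectionError("resolved_indices must be strictly increasing")
        self.resolved_indices = idx

    def union(self, other: "Selection") -> "Selection":
        merged = tuple(sorted(set(self.resolved_indices) | set(other.resolved_indices)))
        return Selection(("union", self.expression, other.expression), merged)

    def intersection(self, other: "Selection") -> "Selection":
        merged = tuple(sorted(set(self.resolved_indices) & set(other.resolved_indices)))
        return Selection(("intersection", self.expression, other.expression), merged)


@dataclass
class Trajectory:
    """Topology plus ordered coordinate frames (n_frames, n_atoms, 3) in Å."""

    topology: Structure
    frames: np.ndarray
    time_step: float | None = None  # ps per frame, None when unknown
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.topology):
            raise TrajectoryError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if self.frame_count < 1:
            raise TrajectoryError("a trajectory needs at least one frame")

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])


# ---------------------------------------------------------------------------
# parsing


def _infer_element(atom: gemmi.Atom, residue: gemmi.Residue) -> str:
    el = atom.element
    if el is not None and el.name not in ("X", ""):
        return el.name
    # fall back to PDB naming conventions: monatomic ions use the residue
    # name as the element; otherwise the first alphabetic character wins
    name = atom.name.strip()
    if residue.name.strip().upper() in MONATOMIC_ION_RESNAMES:
        guess = residue.name.strip().capitalize()
        if gemmi.Element(guess).is_metal or guess in ("Cl", "Br", "F", "I"):
            return guess
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Mg", "Zn", "Na", "Mn", "Ca", "Cu"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _gemmi_model_to_atoms(
    model: gemmi.Model, radii_override: dict[str, float] | None
) -> list[Atom]:
    # first pass: altloc resolution per (chain, seqid, icode, atom name)
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            for atom in res:
                key = (chain.name, res.seqid.num, icode, atom.name)
                altloc = atom.altloc.strip("\x00 ")  # gemmi uses NUL for no-altloc
                cand = (atom, res, chain, altloc)
                if key not in best:
                    best[key] = cand
                    order.append(key)
                else:
                    prev_atom, _, _, prev_alt = best[key]
                    if atom.occ > prev_atom.occ or (
                        atom.occ == prev_atom.occ and altloc < prev_alt
                    ):
                        best[key] = cand

    atoms: list[Atom] = []
    for key in order:
        gatom, gres, gchain, altloc = best[key]
        element = _infer_element(gatom, gres)
        if not element:
            raise StructureParseError(
                f"cannot resolve element for atom {gatom.name!r} in residue "
                f"{gres.name} {gchain.name}:{gres.seqid.num}"
            )
        radius = vdw_radius(element, radii_override)
        if radius is None:
            raise StructureParseError(
                f"no van der Waals radius for element {element!r} "
                f"(atom {gatom.name!r}, residue {gres.name} "
                f"{gchain.name}:{gres.seqid.num}); supply it via radii_override"
            )
        resname = gres.name.strip().upper()
        atoms.append(
            Atom(
                serial=gatom.serial,
                name=gatom.name,
                element=element,
                residue_name=resname,
                residue_seq=gres.seqid.num,
                chain_id=gchain.name,
                altloc=altloc,
                coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                occupancy=gatom.occ,
                mass=gemmi.Element(element).weight,
                vdw_radius=radius,
                is_ion=resname in MONATOMIC_ION_RESNAMES,
                is_water=resname in WATER_RESNAMES,
                icode=key[2],
            )
        )
    return atoms


def _read_gemmi(source: str | os.PathLike, fmt: str | None) -> gemmi.Structure:
    text: str | None = None
    if isinstance(source, (str,)) and ("\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "MODEL", "data_"))):
        text = source
    elif isinstance(source, os.PathLike) or os.path.exists(str(source)):
        pass
    else:
        raise StructureParseError(f"structure source not found: {source!r}")

    try:
        if text is not None:
            if fmt == "mmcif" or (fmt is None and text.lstrip().startswith("data_")):
                doc = gemmi.cif.read_string(text)
                return gemmi.make_structure_from_block(doc.sole_block())
            return gemmi.read_pdb_string(text)
        path = str(source)
        if fmt == "pdb":
            return gemmi.read_pdb(path)
        if fmt == "mmcif":
            doc = gemmi.cif.read(path)
            return gemmi.make_structure_from_block(doc.sole_block())
        return gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse structure: {exc}") from exc


def parse_structure(
    source: str | os.PathLike,
    format: str | None = None,
    *,
    model_index: int = 0,
    radii_override: dict[str, float] | None = None,
) -> Structure:
    """Read a PDB or mmCIF structure from a path or literal text.

    All ATOM and HETATM records are kept (hydrogens included when present);
    waters and monatomic ions are flagged; for alternate locations only the
    highest-occupancy conformer survives, ties going to altloc 'A'.

    Parameters
    ----------
    source : path or text
        File path, or the file content itself.
    format : {"pdb", "mmcif", None}
        Forced format; None auto-detects.
    model_index : int
        Which MODEL to take from a multi-model file (default: first).
    radii_override : dict
        Element symbol -> vdW radius (Å), overriding the bundled table.
    """
    st = _read_gemmi(source, format)
    if len(st) == 0:
        raise StructureParseError("no models found in structure source")
    atoms = _gemmi_model_to_atoms(st[model_index], radii_override)
    if not atoms:
        raise StructureParseError("structure contains no atoms")
    meta = {"source_id": st.name or "", "format": format or "auto"}
    return Structure(atoms, metadata=meta)


# ---------------------------------------------------------------------------
# writing


def _format_pdb_atom(atom: Atom, serial: int, coords: np.ndarray) -> str:
    record = "HETATM" if (atom.is_ion or atom.is_water) else "ATOM  "
    name = atom.name
    # PDB atom-name column alignment: 1/2-letter elements
    if len(name) < 4:
        name = (" " + name) if len(atom.element) == 1 else name
    resseq = atom.residue_seq
    icode = atom.icode[:1] if atom.icode else " "
    altloc = atom.altloc[:1] if atom.altloc else " "
    return (
        f"{record}{serial:>5d} {name:<4s}{altloc}{atom.residue_name:<3s} "
        f"{atom.chain_id[:1]:1s}{resseq:>4d}{icode}   "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_structure(structure: Structure, path: str | os.PathLike | None = None) -> str:
    """Write a single-model PDB. Returns the text; also writes ``path`` if given."""
    lines = [
        _format_pdb_atom(a, i + 1, a.coords) for i, a in enumerate(structure.atoms)
    ]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_trajectory(
    traj: Trajectory, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a trajectory as multi-model PDB or DCD (by extension or ``format``)."""
    fmt = format or os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt in ("pdb", "ent"):
        chunks = []
        for f in range(traj.frame_count):
            chunks.append(f"MODEL     {f + 1:>4d}")
            for i, a in enumerate(traj.topology.atoms):
                chunks.append(_format_pdb_atom(a, i + 1, traj.frames[f, i]))
            chunks.append("ENDMDL")
        chunks.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(chunks) + "\n")
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(np.asarray(traj.frames, dtype=np.float32))
    elif fmt == "xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path), "w") as fh:
            fh.write(np.asarray(traj.frames, dtype=np.float32) / 10.0)  # Å -> nm
    else:
        raise TrajectoryError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# trajectory reading


def load_trajectory(
    topology: Structure,
    source: str | os.PathLike,
    format: str | None = None,
    time_step: float | None = None,
) -> Trajectory:
    """Load a multi-model PDB, DCD or XTC trajectory against ``topology``.

    Every frame must carry exactly the topology's atom count; frames keep
    file order (frame 0 is the first frame in the file).
    """
    n_top = len(topology)
    fmt = format
    if fmt is None:
        ext = os.path.splitext(str(source))[1].lstrip(".").lower()
        fmt = {"pdb": "pdb", "ent": "pdb", "dcd": "dcd", "xtc": "xtc"}.get(ext)
    if fmt is None:
        raise TrajectoryError(f"cannot infer trajectory format from {source!r}")

    if fmt == "pdb":
        st = _read_gemmi(source, "pdb")
        frames = []
        for f, model in enumerate(st):
            atoms = _gemmi_model_to_atoms(model, None)
            if len(atoms) != n_top:
                raise TrajectoryError(
                    f"frame {f} has {len(atoms)} atoms but topology has {n_top}"
                )
            frames.append([a.coords for a in atoms])
        xyz = np.array(frames, dtype=float)
    elif fmt == "dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(source)) as fh:
            xyz, _, _ = fh.read()
        xyz = np.asarray(xyz, dtype=float)  # DCD stores Å
    elif fmt == "xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(source)) as fh:
            xyz, _, _, _ = fh.read()
        xyz = np.asarray(xyz, dtype=float) * 10.0  # nm -> Å
    else:
        raise TrajectoryError(f"unsupported trajectory format {fmt!r}")

    if xyz.shape[1] != n_top:
        raise TrajectoryError(
            f"frame 0 has {xyz.shape[1]} atoms but topology has {n_top}"
        )
    return Trajectory(topology=topology, frames=xyz, time_step=time_step)


# ---------------------------------------------------------------------------
# selections


def _parse_residue_ranges(token: str) -> list[tuple[int, int]]:
    ranges = []
    for part in token.replace("–", "-").split():
        for piece in part.split(","):
            if not piece:
                continue
            if "-" in piece[1:]:  # allow negative start
                head, tail = piece[1:].split("-", 1)
                lo = int(piece[0] + head)
                hi = int(tail)
            else:
                lo = hi = int(piece)
            if hi < lo:
                raise SelectionError(f"empty residue range {piece!r}")
            ranges.append((lo, hi))
    return ranges


_KEYWORDS = {
    "calpha", "ca", "cα", "heavy", "ions", "ion", "water", "waters",
    "protein", "all",
}


def _expression_to_dict(expression) -> dict:
    """Normalise a selection expression (string or dict) to dict form."""
    if isinstance(expression, Mapping):
        return dict(expression)
    if not isinstance(expression, str):
        raise SelectionError(f"unsupported selection expression: {expression!r}")
    spec: dict = {}
    for clause in expression.split(","):
        clause = clause.strip()
        if not clause:
            continue
        words = clause.split()
        head = words[0].lower()
        if head in ("chain", "chains"):
            if len(words) < 2:
                raise SelectionError(f"'chain' clause without a chain id: {clause!r}")
            spec.setdefault("chains", []).extend(words[1:])
        elif head in ("resi", "residue", "residues", "resid"):
            spec.setdefault("residues", []).extend(
                _parse_residue_ranges(" ".join(words[1:]))
            )
        elif head in ("name", "names"):
            spec.setdefault("names", []).extend(w.upper() for w in words[1:])
        elif head in ("calpha", "ca", "cα"):
            spec["calpha"] = True
        elif head == "heavy":
            spec["heavy"] = True
        elif head in ("ion", "ions"):
            spec["ions"] = True
        elif head in ("water", "waters"):
            spec["water"] = True
        elif head == "protein":
            spec["protein"] = True
        elif head == "all":
            pass
        elif len(words) == 1 and head.upper() == words[0].upper() and head not in _KEYWORDS:
            # bare token such as "CB": treat as an atom-name filter
            spec.setdefault("names", []).append(words[0].upper())
        else:
            raise SelectionError(f"cannot parse selection clause {clause!r}")
    return spec


def resolve_selection(
    structure: Structure, expression, *, allow_missing_chains: bool = False
) -> Selection:
    """Resolve a declarative selection expression against a structure.

    The result is deterministic and order-stable (file order). The Cα
    filter selects atoms named ``CA`` in amino-acid residues only, so
    calcium ions never leak into a ``calpha`` selection. Filters such as
    ``ions`` may legitimately match nothing; a *chain* reference to a
    chain the structure does not contain is an error unless
    ``allow_missing_chains`` is set.
    """
    spec = _expression_to_dict(expression)

    chains = spec.get("chains")
    if chains is not None and not allow_missing_chains:
        present = set(structure.chains)
        for c in chains:
            if c not in present:
                raise SelectionError(f"chain {c!r} not present in structure")
    chain_set = set(chains) if chains is not None else None

    residues = spec.get("residues")
    if residues is not None:
        residues = [tuple(r) for r in residues]
    names = {n.upper() for n in spec.get("names", [])} or None

    idx = []
    for i, a in enumerate(structure.atoms):
        if chain_set is not None and a.chain_id not in chain_set:
            continue
        if residues is not None and not any(
            lo <= a.residue_seq <= hi for lo, hi in residues
        ):
            continue
        if names is not None and a.name.upper() not in names:
            continue
        if spec.get("calpha") and not (
            a.name.upper() == "CA" and a.residue_name in AMINO_ACID_RESNAMES
        ):
            continue
        if spec.get("heavy") and a.element in ("H", "D"):
            continue
        if spec.get("ions") and not a.is_ion:
            continue
        if spec.get("water") and not a.is_water:
            continue
        if spec.get("protein") and a.residue_name not in AMINO_ACID_RESNAMES:
            continue
        idx.append(i)
    return Selection(expression=expression, resolved_indices=tuple(idx))
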