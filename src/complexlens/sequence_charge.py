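"""Sequence identity, net charge, isoelectric point and charge classes.

The charge model is the standard Henderson–Hasselbalch sum over ionizable
side chains (D, E, C, Y, H, K, R) and the two termini:

    Q(pH) = Σ_basic  1 / (1 + 10^(pH − pKa))
          − Σ_acidic 1 / (1 + 10^(pKa − pH))

The bundled default pKa table is the EMBOSS set; alternative published
tables can be registered, and the table used is always named in output
because a computed pI is only meaningful together with its table.

Pairwise identity is Needleman–Wunsch global alignment (BLOSUM62, affine
gaps, penalties config-exposed) through Biopython's ``PairwiseAligner``,
with the denominator being the full alignment length (gapped columns
included) unless a different denominator is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

__all__ = [
    "ProteinSequence",
    "PkaSet",
    "PKA_TABLES",
    "read_fasta",
    "pairwise_identity",
    "net_charge",
    "isoelectric_point",
    "classify_residue_charge",
]

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        seq = self.residues.upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard letters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values from one published table."""

    name: str
    side_chain: dict  # residue letter -> pKa for D,E,C,Y,H,K,R
    n_term: float
    c_term: float

    def __post_init__(self):
        vals = list(self.side_chain.values()) + [self.n_term, self.c_term]
        if not all(0.0 < v < 14.0 for v in vals):
            raise ValueError("all pKa values must lie in (0, 14)")


PKA_TABLES: dict[str, PkaSet] = {
    "EMBOSS": PkaSet(
        name="EMBOSS",
        side_chain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5},
        n_term=8.6,
        c_term=3.6,
    ),
    # Lehninger-style textbook values, as a sensitivity alternative
    "Lehninger": PkaSet(
        name="Lehninger",
        side_chain={"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07, "H": 6.0, "K": 10.53, "R": 12.48},
        n_term=9.69,
        c_term=2.34,
    ),
}

_BASIC = "KRH"
_ACIDIC = "DECY"


def read_fasta(path) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def pairwise_identity(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    mode: str = "global-align",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
    aligned: tuple[str, str] | None = None,
) -> float:
    """Percent identity between two protein sequences.

    ``global-align`` runs Needleman–Wunsch (BLOSUM62, affine gaps) and
    scores 100 × matches / denominator; ``aligned-columns`` instead scores
    a caller-supplied pair of equal-length gapped strings. The default
    denominator is the full alignment length including gapped columns;
    ``"shorter"`` divides by the shorter ungapped sequence instead.
    """
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("cannot compute identity of an empty sequence")
    if mode == "global-align":
        aln = _aligner(gap_open, gap_extend).align(seq_a.residues, seq_b.residues)[0]
        sa, sb = str(aln[0]), str(aln[1])
    elif mode == "aligned-columns":
        if aligned is None:
            raise ValueError("aligned-columns mode requires the `aligned` pair")
        sa, sb = aligned
        if len(sa) != len(sb):
            raise ValueError("aligned strings must have equal length")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    if denominator == "alignment":
        denom = len(sa)
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * matches / denom


def net_charge(seq: ProteinSequence, pH, pkas: PkaSet | None = None):
    """Modeled net charge (elementary charges) at a given pH.

    Accepts a scalar or an array of pH values (vectorised); strictly
    decreasing in pH.
    """
    pkas = pkas or PKA_TABLES["EMBOSS"]
    pH = np.asarray(pH, dtype=float)
    if np.any(pH <= 0.0) or np.any(pH >= 14.0):
        raise ValueError("pH must lie in (0, 14)")
    q = np.zeros_like(pH)

    def pos(pka):
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka):
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    q = pos(pkas.n_term) + neg(pkas.c_term)
    for letter, pka in pkas.side_chain.items():
        n = seq.residues.count(letter)
        if n == 0:
            continue
        q = q + n * (pos(pka) if letter in _BASIC else neg(pka))
    return float(q) if q.ndim == 0 else q


def isoelectric_point(
    seq: ProteinSequence,
    pkas: PkaSet | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the modeled net charge is zero, by bisection.

    Root-found on pH ∈ [0.1, 13.9]; a sequence whose charge never changes
    sign in that window (e.g. poly-lysine with a blocked C-terminus model)
    raises instead of extrapolating.
    """
    pkas = pkas or PKA_TABLES["EMBOSS"]
    has_ionizable = any(seq.residues.count(k) for k in pkas.side_chain) or len(seq) > 0
    if not has_ionizable:
        raise ValueError("sequence has no ionizable groups")
    lo, hi = 0.1, 13.9
    qlo = net_charge(seq, lo, pkas)
    qhi = net_charge(seq, hi, pkas)
    if qlo * qhi > 0:
        raise ValueError(
            f"net charge does not change sign on pH [{lo}, {hi}] "
            f"(Q({lo})={qlo:+.2f}, Q({hi})={qhi:+.2f}); no pI in range"
        )
    return float(brentq(lambda p: net_charge(seq, p, pkas), lo, hi, xtol=tol))


_CHARGE_CLASS = {
    **{r: "acidic" for r in ("ASP", "GLU")},
    **{r: "basic" for r in ("LYS", "ARG", "HIS")},
    **{
        r: "nonpolar"
        for r in ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY")
    },
    **{r: "polar-uncharged" for r in ("SER", "THR", "ASN", "GLN", "CYS", "TYR")},
}


def classify_residue_charge(residue_name: str) -> str:
    """Charge class of a 3-letter residue code (``"unknown"`` if nonstandard)."""
    return _CHARGE_CLASS.get(residue_name.strip().upper(), "unknown")
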