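"""All-atom peptide model: sequences, formulas, masses, and conformer geometry.

A capped peptide is described by a :class:`SequenceSpec` (residues plus the
N-terminal acetyl / C-terminal amide caps used to mimic a protein-interior
fragment) and a :class:`DihedralSet` of backbone torsions.  Conformers are
built by sequential internal-coordinate (NeRF) construction with a fixed
standard-geometry set, placing every heavy atom plus the protons needed for
NOE work (amide HN, Halpha, and proline Hdelta).

The builder is deterministic and vectorised: the same atom-placement plan is
applied to a whole batch of dihedral sets at once, which is what makes
pool-scale sampling cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

__all__ = [
    "SequenceSpec",
    "DihedralSet",
    "ChemFormula",
    "Conformer",
    "peptide_formula",
    "mass",
    "build_conformer",
    "build_coordinates",
    "clash_count",
    "wrap_angle",
    "dihedral_angle",
    "AA1TO3",
    "AA3TO1",
    "DEFAULT_CLASH_THRESHOLD",
]

DEFAULT_CLASH_THRESHOLD = 2.0  # Å between non-bonded heavy atoms

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}

# Residue formulas are for the residue *as polymerised* (free amino acid
# minus one water).  Element order is Hill convention when printed.
_RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "GLY": {"C": 2, "H": 3, "N": 1, "O": 1},
    "ALA": {"C": 3, "H": 5, "N": 1, "O": 1},
    "SER": {"C": 3, "H": 5, "N": 1, "O": 2},
    "CYS": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "THR": {"C": 4, "H": 7, "N": 1, "O": 2},
    "VAL": {"C": 5, "H": 9, "N": 1, "O": 1},
    "LEU": {"C": 6, "H": 11, "N": 1, "O": 1},
    "ILE": {"C": 6, "H": 11, "N": 1, "O": 1},
    "PRO": {"C": 5, "H": 7, "N": 1, "O": 1},
    "MET": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "PHE": {"C": 9, "H": 9, "N": 1, "O": 1},
    "TYR": {"C": 9, "H": 9, "N": 1, "O": 2},
    "TRP": {"C": 11, "H": 10, "N": 2, "O": 1},
    "ASP": {"C": 4, "H": 5, "N": 1, "O": 3},
    "GLU": {"C": 5, "H": 7, "N": 1, "O": 3},
    "ASN": {"C": 4, "H": 6, "N": 2, "O": 2},
    "GLN": {"C": 5, "H": 8, "N": 2, "O": 2},
    "HIS": {"C": 6, "H": 7, "N": 3, "O": 1},
    "LYS": {"C": 6, "H": 12, "N": 2, "O": 1},
    "ARG": {"C": 6, "H": 12, "N": 4, "O": 1},
}

# Most-abundant-isotope and standard-atomic-weight masses (Da).
_MONOISOTOPIC = {
    "H": 1.00782503207, "C": 12.0, "N": 14.0030740048,
    "O": 15.9949146196, "S": 31.97207100,
}
_AVERAGE = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
}


def wrap_angle(a):
    """Wrap an angle in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = ((-a + 180.0) % 360.0)
    out = -(wrapped - 180.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# sequence and chemistry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceSpec:
    """A peptide sequence with terminal capping.

    ``residues`` holds three-letter codes; ``n_cap`` is ``"acetyl"`` or
    ``"free"``, ``c_cap`` is ``"amide"`` or ``"free"``.  Residue numbering is
    1-based from the first non-cap residue throughout the package.
    """

    residues: tuple[str, ...]
    n_cap: str = "acetyl"
    c_cap: str = "amide"

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        for code in self.residues:
            if code not in _RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue code: {code!r}")
        if self.n_cap not in ("acetyl", "free"):
            raise ValueError(f"n_cap must be 'acetyl' or 'free', got {self.n_cap!r}")
        if self.c_cap not in ("amide", "free"):
            raise ValueError(f"c_cap must be 'amide' or 'free', got {self.c_cap!r}")

    @classmethod
    def from_string(cls, text: str) -> "SequenceSpec":
        """Parse names like ``Ac-PHNPGYPHNPGY-NH2`` or ``Ac-(PHNPGY)2-NH2``.

        A bare one-letter string (``"PHNPGY"``) gives free termini.
        """
        s = text.strip()
        n_cap, c_cap = "free", "free"
        if s.lower().startswith("ac-"):
            n_cap = "acetyl"
            s = s[3:]
        if s.lower().endswith("-nh2"):
            c_cap = "amide"
            s = s[:-4]
        # expand (SEQ)n repeats
        while "(" in s:
            open_i = s.index("(")
            close_i = s.index(")", open_i)
            unit = s[open_i + 1:close_i]
            j = close_i + 1
            digits = ""
            while j < len(s) and s[j].isdigit():
                digits += s[j]
                j += 1
            count = int(digits) if digits else 1
            s = s[:open_i] + unit * count + s[j:]
        residues = []
        for ch in s:
            if ch.upper() not in AA1TO3:
                raise ValueError(f"unknown residue code: {ch!r}")
            residues.append(AA1TO3[ch.upper()])
        return cls(tuple(residues), n_cap=n_cap, c_cap=c_cap)

    def __len__(self) -> int:
        return len(self.residues)

    def one_letter(self) -> str:
        return "".join(AA3TO1[r] for r in self.residues)

    def __str__(self) -> str:
        n = "Ac-" if self.n_cap == "acetyl" else ""
        c = "-NH2" if self.c_cap == "amide" else ""
        return f"{n}{self.one_letter()}{c}"


class ChemFormula(dict):
    """Element -> count map with element-wise addition."""

    def __init__(self, counts: Mapping[str, int] | None = None):
        super().__init__()
        if counts:
            for el, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative count for element {el}")
                if n:
                    self[el] = int(n)

    def __add__(self, other: "ChemFormula") -> "ChemFormula":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ChemFormula(out)

    def hill(self) -> str:
        """Hill-notation string, e.g. ``C33H44N10O9``."""
        parts = []
        for el in ("C", "H"):
            if el in self:
                parts.append(f"{el}{self[el] if self[el] > 1 else ''}")
        for el in sorted(k for k in self if k not in ("C", "H")):
            parts.append(f"{el}{self[el] if self[el] > 1 else ''}")
        return "".join(parts)


def peptide_formula(seq: SequenceSpec) -> ChemFormula:
    """Molecular formula of a capped peptide.

    Sum of residue formulas plus H2O for the free chain, plus C2H2O for an
    N-terminal acetyl, and -O +N +H for a C-terminal amide.
    """
    counts: dict[str, int] = {}

    def _add(f: Mapping[str, int], sign: int = 1):
        for el, n in f.items():
            counts[el] = counts.get(el, 0) + sign * n

    for code in seq.residues:
        _add(_RESIDUE_FORMULAS[code])
    _add({"H": 2, "O": 1})  # free chain termini
    if seq.n_cap == "acetyl":
        _add({"C": 2, "H": 2, "O": 1})
    if seq.c_cap == "amide":
        _add({"O": -1, "N": 1, "H": 1})
    return ChemFormula(counts)


def mass(formula: Mapping[str, int], kind: str = "monoisotopic") -> float:
    """Mass in Da of a formula: ``monoisotopic`` or ``average``."""
    table = {"monoisotopic": _MONOISOTOPIC, "average": _AVERAGE}.get(kind)
    if table is None:
        raise ValueError(f"kind must be 'monoisotopic' or 'average', got {kind!r}")
    total = 0.0
    for el, n in formula.items():
        if el not in table:
            raise ValueError(f"no tabulated {kind} mass for element {el!r}")
        total += n * table[el]
    return total


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

@dataclass
class DihedralSet:
    """Per-residue backbone torsions in degrees.

    ``omega[i]`` is the peptide bond *preceding* residue i (so ``omega[0]``
    is the cap-to-residue-1 bond when an acetyl cap is present).  All angles
    live in (-180, 180]; omega defaults to 180 (trans) everywhere.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        if self.omega is None:
            self.omega = np.full_like(self.phi, 180.0)
        else:
            self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if not (len(self.phi) == len(self.psi) == len(self.omega)):
            raise ValueError("phi, psi, omega must have equal length")
        self.phi = wrap_angle(self.phi)
        self.psi = wrap_angle(self.psi)
        self.omega = wrap_angle(self.omega)

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0):
        return cls(np.full(n, float(phi)), np.full(n, float(psi)),
                   np.full(n, float(omega)))


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (deg) for points of shape (..., 3), IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


# ---------------------------------------------------------------------------
# standard geometry and topology
# ---------------------------------------------------------------------------

# Bond lengths (Å) and angles (deg) follow standard small-molecule /
# protein-refinement values (Engh-Huber-like).
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "C-CH3": 1.505, "N-H": 0.980, "CA-HA": 1.090, "CA-CB": 1.530,
}
_A = {
    "C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8,
    "CH3-C-N": 116.5, "CH3-C-O": 121.5, "C-N-H": 119.3,
    "N-CA-CB": 110.5, "N-CA-HA": 107.5,
}
# Substituent torsions about the N-CA axis measured from the carbonyl C:
# dihedral(C, N, CA, CB) for an L residue, and the alpha proton opposite.
_TAU_CB = -122.6
_TAU_HA = 120.0

# Side-chain internal coordinates.  Each entry places one atom from a frame
# of three already-placed atoms of the same residue:
#   (name, element, (ref1, ref2, ref3), bond, angle, torsion)
# A torsion may reference a named default chi via a string.
_CHI_DEFAULTS = {"chi1": -65.0, "chi2": 90.0}
# Proline ring: chi1/chi2 chosen so the CD...N ring-closure distance lands at
# a bonded value (checked numerically; see tests).
_SIDECHAINS: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.495, 104.0, -21.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.507, 106.0, 10.0),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, "chi1"),
        ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, "chi2"),
        ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.2, "chi2+180"),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, "chi2"),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, "chi2+180"),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, "chi1"),
        ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, "chi2"),
        ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, "chi2+180"),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
}
# Extra bonds that close rings (both endpoints within the residue).
_RING_CLOSURES = {
    "PRO": [("CD", "N")],
    "HIS": [("CE1", "NE2")],
    "TYR": [("CZ", "CE2")],
}

_BUILDABLE = set(_SIDECHAINS)


@dataclass(frozen=True)
class _AtomOp:
    """One step of the placement plan (indices into the atom list)."""
    index: int
    refs: tuple[int, int, int]       # frame atoms A, B, C
    bond: float
    angle: float                     # angle(B, C, new) in degrees
    tau_kind: str                    # 'const' | 'phi' | 'psi' | 'psi180' | 'omega'
    tau_value: float                 # used when tau_kind == 'const'
    tau_residue: int                 # 0-based residue index for torsion lookup
    methylene: bool = False          # analytic H2/H3 placement instead of NeRF
    sign: int = 1                    # which methylene proton


@dataclass
class _BuildPlan:
    seq: SequenceSpec
    names: list[str]
    elements: list[str]
    resids: list[int]                # 0 = ACE cap, L+1 = NH2 cap
    resnames: list[str]
    ops: list[_AtomOp]
    bonds: list[tuple[int, int]]
    index: dict[tuple[int, str], int]
    heavy: np.ndarray = field(default=None)
    excluded_pairs: set = field(default=None)

    def finalise(self):
        self.heavy = np.array(
            [i for i, el in enumerate(self.elements) if el != "H"], dtype=int)
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.names))}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        excl = set()
        for a in range(len(self.names)):
            for b in adj[a]:
                excl.add((min(a, b), max(a, b)))
                for c in adj[b]:
                    if c != a:
                        excl.add((min(a, c), max(a, c)))
        self.excluded_pairs = excl


def _sequence_key(seq: SequenceSpec):
    return (seq.residues, seq.n_cap, seq.c_cap)


@lru_cache(maxsize=64)
def _plan_cached(key) -> _BuildPlan:
    residues, n_cap, c_cap = key
    return _make_plan(SequenceSpec(residues, n_cap=n_cap, c_cap=c_cap))


def _make_plan(seq: SequenceSpec) -> _BuildPlan:
    for code in seq.residues:
        if code not in _BUILDABLE:
            raise ValueError(
                f"no builder topology for residue {code}; available: "
                f"{sorted(_BUILDABLE)}")
    names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    ops: list[_AtomOp] = []
    bonds: list[tuple[int, int]] = []
    index: dict[tuple[int, str], int] = {}

    def add(resid, resname, name, element, refs=None, bond=None, angle=None,
            tau_kind="const", tau_value=0.0, tau_residue=0,
            methylene=False, sign=1, bond_to=()):
        i = len(names)
        names.append(name)
        elements.append(element)
        resids.append(resid)
        resnames.append(resname)
        index[(resid, name)] = i
        if refs is not None:
            ops.append(_AtomOp(i, refs, bond, angle, tau_kind, tau_value,
                               tau_residue, methylene, sign))
        for j in bond_to:
            bonds.append((j, i))
        return i

    L = len(seq)
    if seq.n_cap == "acetyl":
        i_ch3 = add(0, "ACE", "CH3", "C")            # bootstrap atom 0
        i_c = add(0, "ACE", "C", "C", bond_to=(i_ch3,))
        i_o = add(0, "ACE", "O", "O", bond_to=(i_c,))
        prev = {"N": i_o, "CA": i_ch3, "C": i_c}     # N slot only used as frame A
        first_frame = (i_o, i_ch3, i_c)
    else:
        prev = None
        first_frame = None

    prev_C = prev["C"] if prev else None
    prev_CA = prev["CA"] if prev else None
    prev_N = prev["N"] if prev else None

    for r, code in enumerate(seq.residues):
        resid = r + 1
        is_pro = code == "PRO"
        is_gly = code == "GLY"
        if r == 0 and seq.n_cap == "free":
            # bootstrap: N, CA placed directly; C via in-plane construction
            i_n = add(resid, code, "N", "N")
            i_ca = add(resid, code, "CA", "C", bond_to=(i_n,))
            i_c = add(resid, code, "C", "C", bond_to=(i_ca,))
        else:
            if r == 0:
                frame_n = first_frame
                ang_n = _A["CH3-C-N"]
                tau_kind_n, tau_res_n = "const", 0
                tau_val_n = 180.0
            else:
                frame_n = (prev_N, prev_CA, prev_C)
                ang_n = _A["CA-C-N"]
                tau_kind_n, tau_res_n, tau_val_n = "psi", r - 1, 0.0
            i_n = add(resid, code, "N", "N", refs=frame_n, bond=_B["C-N"],
                      angle=ang_n, tau_kind=tau_kind_n, tau_value=tau_val_n,
                      tau_residue=tau_res_n, bond_to=(prev_C,))
            i_ca = add(resid, code, "CA", "C", refs=(prev_CA, prev_C, i_n),
                       bond=_B["N-CA"], angle=_A["C-N-CA"],
                       tau_kind="omega", tau_residue=r, bond_to=(i_n,))
            i_c = add(resid, code, "C", "C", refs=(prev_C, i_n, i_ca),
                      bond=_B["CA-C"], angle=_A["N-CA-C"],
                      tau_kind="phi", tau_residue=r, bond_to=(i_ca,))
            if not is_pro:
                add(resid, code, "H", "H", refs=(prev_CA, prev_C, i_n),
                    bond=_B["N-H"], angle=_A["C-N-H"],
                    tau_kind="const", tau_value=0.0, bond_to=(i_n,))
        i_o = add(resid, code, "O", "O", refs=(i_n, i_ca, i_c),
                  bond=_B["C-O"], angle=_A["CA-C-O"],
                  tau_kind="psi180", tau_residue=r, bond_to=(i_c,))
        # alpha substituents
        if is_gly:
            add(resid, code, "HA2", "H", refs=(i_c, i_n, i_ca),
                bond=_B["CA-HA"], angle=_A["N-CA-HA"],
                tau_kind="const", tau_value=_TAU_HA, bond_to=(i_ca,))
            add(resid, code, "HA3", "H", refs=(i_c, i_n, i_ca),
                bond=_B["CA-HA"], angle=_A["N-CA-CB"],
                tau_kind="const", tau_value=_TAU_CB, bond_to=(i_ca,))
        else:
            i_cb = add(resid, code, "CB", "C", refs=(i_c, i_n, i_ca),
                       bond=_B["CA-CB"], angle=_A["N-CA-CB"],
                       tau_kind="const", tau_value=_TAU_CB, bond_to=(i_ca,))
            add(resid, code, "HA", "H", refs=(i_c, i_n, i_ca),
                bond=_B["CA-HA"], angle=_A["N-CA-HA"],
                tau_kind="const", tau_value=_TAU_HA, bond_to=(i_ca,))
            for entry in _SIDECHAINS[code]:
                name, el, refs, b, ang, tau = entry
                if isinstance(tau, str):
                    if tau.endswith("+180"):
                        tau_v = wrap_angle(_CHI_DEFAULTS[tau[:-4]] + 180.0)
                    else:
                        tau_v = _CHI_DEFAULTS[tau]
                else:
                    tau_v = float(tau)
                ref_idx = tuple(index[(resid, n)] for n in refs)
                parent = index[(resid, refs[2])]
                add(resid, code, name, el, refs=ref_idx, bond=b, angle=ang,
                    tau_kind="const", tau_value=tau_v, bond_to=(parent,))
            for a, b2 in _RING_CLOSURES.get(code, ()):
                bonds.append((index[(resid, a)], index[(resid, b2)]))
            if is_pro:
                i_cd = index[(resid, "CD")]
                i_cg = index[(resid, "CG")]
                for hname, sgn in (("HD2", 1), ("HD3", -1)):
                    add(resid, code, hname, "H", refs=(i_cg, i_n, i_cd),
                        bond=1.09, angle=0.0, tau_kind="const",
                        methylene=True, sign=sgn, bond_to=(i_cd,))
        prev_N, prev_CA, prev_C = i_n, i_ca, i_c

    if seq.c_cap == "amide":
        add(L + 1, "NH2", "N", "N", refs=(prev_N, prev_CA, prev_C),
            bond=_B["C-N"], angle=_A["CA-C-N"],
            tau_kind="psi", tau_residue=L - 1, bond_to=(prev_C,))
    elif seq.c_cap == "free":
        add(L, seq.residues[-1], "OXT", "O", refs=(prev_N, prev_CA, prev_C),
            bond=1.249, angle=_A["CA-C-O"],
            tau_kind="psi", tau_residue=L - 1, bond_to=(prev_C,))

    plan = _BuildPlan(seq, names, elements, resids, resnames, ops, bonds, index)
    plan.finalise()
    return plan


def get_plan(seq: SequenceSpec) -> _BuildPlan:
    return _plan_cached(_sequence_key(seq))


def _nerf_batch(A, B, C, bond, angle_deg, tau_deg):
    """Place D given frame atoms (batched, shape (n, 3))."""
    theta = np.radians(angle_deg)
    tau = np.radians(tau_deg)
    bc = C - B
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = B - A
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = (-np.cos(theta))[..., None] * bc \
        + (np.sin(theta) * np.cos(tau))[..., None] * m \
        + (np.sin(theta) * np.sin(tau))[..., None] * n
    return C + bond * d


def _methylene_batch(X, A, B, sign, bond=1.09, half_angle_deg=53.7):
    """Protons on a tetrahedral centre X with heavy neighbours A and B."""
    u = A - X
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v = B - X
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    bis = -(u + v)
    bis /= np.linalg.norm(bis, axis=-1, keepdims=True)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp, axis=-1, keepdims=True)
    half = np.radians(half_angle_deg)
    return X + bond * (np.cos(half) * bis + sign * np.sin(half) * perp)


def build_coordinates(seq: SequenceSpec, phi, psi, omega=None) -> np.ndarray:
    """Build coordinates for a batch of conformers.

    ``phi``, ``psi``, ``omega`` have shape (n, L) (or (L,) for a single
    conformer).  Returns an array of shape (n, n_atoms, 3) in Å.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if omega is None:
        omega = np.full_like(phi, 180.0)
    else:
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
    L = len(seq)
    if phi.shape[1] != L or psi.shape[1] != L or omega.shape[1] != L:
        raise ValueError(
            f"dihedral arrays must cover all {L} residues "
            f"(got {phi.shape[1]})")
    n = phi.shape[0]
    plan = get_plan(seq)
    coords = np.empty((n, len(plan.names), 3))

    # bootstrap first three atoms in a canonical frame
    if seq.n_cap == "acetyl":
        coords[:, 0] = 0.0                                    # CH3
        coords[:, 1] = (_B["C-CH3"], 0.0, 0.0)                # C
        a = np.radians(_A["CH3-C-O"])
        coords[:, 2] = coords[:, 1] + _B["C-O"] * np.array(
            [-np.cos(a), np.sin(a), 0.0])                     # O
    else:
        coords[:, 0] = 0.0                                    # N
        coords[:, 1] = (_B["N-CA"], 0.0, 0.0)                 # CA
        a = np.radians(_A["N-CA-C"])
        coords[:, 2] = coords[:, 1] + _B["CA-C"] * np.array(
            [-np.cos(a), np.sin(a), 0.0])                     # C

    tau_tables = {"phi": phi, "psi": psi, "omega": omega}
    for op in plan.ops:
        A = coords[:, op.refs[0]]
        Bm = coords[:, op.refs[1]]
        C = coords[:, op.refs[2]]
        if op.methylene:
            coords[:, op.index] = _methylene_batch(C, A, Bm, op.sign)
            continue
        if op.tau_kind == "const":
            tau = np.full(n, op.tau_value)
        elif op.tau_kind == "psi180":
            tau = psi[:, op.tau_residue] + 180.0
        else:
            tau = tau_tables[op.tau_kind][:, op.tau_residue]
        coords[:, op.index] = _nerf_batch(A, Bm, C, op.bond, op.angle, tau)
    return coords


# ---------------------------------------------------------------------------
# conformer container
# ---------------------------------------------------------------------------

class Conformer:
    """All-atom coordinates of one capped chain with derived dihedrals."""

    def __init__(self, seq: SequenceSpec, coords: np.ndarray,
                 provenance: str = "sampled"):
        plan = get_plan(seq)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(plan.names), 3):
            raise ValueError(
                f"expected coordinates of shape {(len(plan.names), 3)}, "
                f"got {coords.shape}")
        self.seq = seq
        self.coords = coords
        self.provenance = provenance
        self._plan = plan

    @property
    def atom_names(self) -> list[str]:
        return self._plan.names

    @property
    def elements(self) -> list[str]:
        return self._plan.elements

    @property
    def resids(self) -> list[int]:
        return self._plan.resids

    @property
    def resnames(self) -> list[str]:
        return self._plan.resnames

    @property
    def n_atoms(self) -> int:
        return len(self._plan.names)

    def atom_index(self, resid: int, name: str) -> int:
        try:
            return self._plan.index[(resid, name)]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} in residue {resid} of {self.seq}") from None

    def has_atom(self, resid: int, name: str) -> bool:
        return (resid, name) in self._plan.index

    def position(self, resid: int, name: str) -> np.ndarray:
        return self.coords[self.atom_index(resid, name)]

    def dihedrals(self) -> DihedralSet:
        """Recompute backbone phi/psi/omega from coordinates.

        Angles that require missing cap atoms (free termini) come back NaN.
        """
        d = _ensemble_dihedrals(self.seq, self.coords[None])
        return DihedralSet(d[0, :, 0], d[0, :, 1], d[0, :, 2])


def _ensemble_dihedrals(seq: SequenceSpec, coords: np.ndarray) -> np.ndarray:
    """Backbone dihedrals for a coordinate batch: (n, L, 3) = phi, psi, omega."""
    plan = get_plan(seq)
    L = len(seq)
    n = coords.shape[0]
    out = np.full((n, L, 3), np.nan)
    idx = plan.index
    for r in range(L):
        resid = r + 1
        i_n, i_ca, i_c = idx[(resid, "N")], idx[(resid, "CA")], idx[(resid, "C")]
        if r > 0:
            p_c, p_ca = idx[(resid - 1, "C")], idx[(resid - 1, "CA")]
        elif seq.n_cap == "acetyl":
            p_c, p_ca = idx[(0, "C")], idx[(0, "CH3")]
        else:
            p_c = p_ca = None
        if p_c is not None:
            out[:, r, 0] = dihedral_angle(coords[:, p_c], coords[:, i_n],
                                          coords[:, i_ca], coords[:, i_c])
            out[:, r, 2] = dihedral_angle(coords[:, p_ca], coords[:, p_c],
                                          coords[:, i_n], coords[:, i_ca])
        if r < L - 1:
            nxt = idx[(resid + 1, "N")]
        elif seq.c_cap == "amide":
            nxt = idx[(L + 1, "N")]
        else:
            nxt = None
        if nxt is not None:
            out[:, r, 1] = dihedral_angle(coords[:, i_n], coords[:, i_ca],
                                          coords[:, i_c], coords[:, nxt])
    return out


def build_conformer(seq: SequenceSpec, dihedrals: DihedralSet,
                    provenance: str = "ideal") -> Conformer:
    """Build one all-atom conformer from backbone dihedrals (deterministic)."""
    if len(dihedrals) != len(seq):
        raise ValueError(
            f"dihedral set covers {len(dihedrals)} residues but the sequence "
            f"has {len(seq)}")
    coords = build_coordinates(seq, dihedrals.phi, dihedrals.psi,
                               dihedrals.omega)
    return Conformer(seq, coords[0], provenance=provenance)


# ---------------------------------------------------------------------------
# clash detection
# ---------------------------------------------------------------------------

def clash_count(conf: Conformer, threshold: float = DEFAULT_CLASH_THRESHOLD) -> int:
    """Number of non-bonded heavy-atom pairs closer than ``threshold`` Å.

    Pairs separated by fewer than three bonds (directly bonded or sharing a
    bonded neighbour) are never counted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return int(clash_counts_batch(conf.seq, conf.coords[None], threshold)[0])


def clash_counts_batch(seq: SequenceSpec, coords: np.ndarray,
                       threshold: float = DEFAULT_CLASH_THRESHOLD) -> np.ndarray:
    """Vectorised clash counts for a coordinate batch of shape (n, A, 3)."""
    plan = get_plan(seq)
    heavy = plan.heavy
    sub = coords[:, heavy]
    k = len(heavy)
    iu, ju = np.triu_indices(k, 1)
    # mask out 1-2 and 1-3 pairs once
    excl = plan.excluded_pairs
    pair_ok = np.array(
        [(min(heavy[a], heavy[b]), max(heavy[a], heavy[b])) not in excl
         for a, b in zip(iu, ju)])
    d = np.linalg.norm(sub[:, iu] - sub[:, ju], axis=-1)
    return np.sum((d < threshold) & pair_ok[None, :], axis=1)


def chirality_volumes(conf: Conformer) -> dict[int, float]:
    """Signed volume det[N-CA, C-CA, CB-CA] per non-Gly residue.

    The sign is constant across residues for a homochiral chain; its value
    for L residues is asserted in the tests against an independent oracle.
    """
    out = {}
    for r in range(len(conf.seq)):
        resid = r + 1
        if conf.seq.residues[r] == "GLY":
            continue
        ca = conf.position(resid, "CA")
        v = np.stack([conf.position(resid, "N") - ca,
                      conf.position(resid, "C") - ca,
                      conf.position(resid, "CB") - ca])
        out[resid] = float(np.linalg.det(v))
    return out
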