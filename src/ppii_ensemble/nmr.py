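"""Forward calculation and analysis of peptide NMR observables.

Covers the solution-state diagnostics used to detect residual structure in
short disordered peptides:

* three-bond HN-Halpha J-couplings via the Karplus relation (and its
  inversion back to phi candidates);
* interproton distances and rigid-ensemble NOE intensities under the
  ``<r^-6>`` averaging convention, with the two classic sequential intensity
  ratios R1 = I[aH(i)-HN(i+1)]/I[HN(i)-HN(i+1)] and
  R2 = I[aH(i)-HN(i+1)]/I[aH(i)-HN(i)];
* secondary chemical shifts against an intrinsic statistical-coil reference;
* amide-proton temperature gradients and the Andersen hydrogen-bond screen;
* the Halpha(i-1)/proline Hdelta-vs-Halpha proximity test for cis/trans
  X-Pro peptide bonds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ensemble import Ensemble
from .peptide import Conformer, wrap_angle

__all__ = [
    "KarplusCoefficients",
    "VUISTER_BAX",
    "karplus_j",
    "invert_karplus",
    "proton_group",
    "proton_distance",
    "ensemble_noe_intensity",
    "effective_distance",
    "RatioProfile",
    "noe_ratio_profile",
    "classify_from_ratios",
    "secondary_shift",
    "secondary_shift_table",
    "amide_temp_gradient",
    "AndersenRegion",
    "hbond_flag",
    "proline_isomer_state",
]


# ---------------------------------------------------------------------------
# Karplus analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KarplusCoefficients:
    """J(phi) = A cos^2(phi - 60) + B cos(phi - 60) + C, in Hz."""

    A: float
    B: float
    C: float

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError("Karplus coefficient A must be positive")


#: HN-Halpha parameterisation of Vuister & Bax (Hz).
VUISTER_BAX = KarplusCoefficients(A=6.51, B=-1.76, C=1.60)


def karplus_j(phi, coeff: KarplusCoefficients = VUISTER_BAX):
    """Three-bond J-coupling (Hz) for backbone phi in degrees."""
    c = np.cos(np.radians(np.asarray(phi, dtype=float) - 60.0))
    out = coeff.A * c * c + coeff.B * c + coeff.C
    return out if out.ndim else float(out)


def invert_karplus(J: float, coeff: KarplusCoefficients = VUISTER_BAX
                   ) -> list[float]:
    """All phi in (-180, 180] with karplus_j(phi) == J, sorted ascending.

    Solves the quadratic in cos(phi - 60); roots outside [-1, 1] are
    discarded, so a J below the curve minimum (or above its maximum) yields
    an empty list.
    """
    if not np.isfinite(J):
        raise ValueError("J must be finite")
    roots = np.roots([coeff.A, coeff.B, coeff.C - J])
    sols: list[float] = []
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        c = float(r.real)
        if abs(c) > 1.0 + 1e-12:
            continue
        c = min(1.0, max(-1.0, c))
        theta = np.degrees(np.arccos(c))
        for t in {theta, -theta}:
            sols.append(float(wrap_angle(t + 60.0)))
    return sorted(set(sols))


# ---------------------------------------------------------------------------
# interproton distances and NOE intensities
# ---------------------------------------------------------------------------

_GROUPS = {"HN": ("H",), "HA": ("HA", "HA2", "HA3"), "HD": ("HD2", "HD3")}


def proton_group(obj: Ensemble | Conformer, resid: int, name: str
                 ) -> list[int]:
    """Atom indices for a proton selector.

    ``name`` may be a group label (``HN``, ``HA``, ``HD``) resolving to all
    equivalent protons present (e.g. Gly HA2/HA3, Pro HD2/HD3), or an
    explicit atom name.
    """
    candidates = _GROUPS.get(name, (name,))
    idx = [obj.atom_index(resid, n) for n in candidates
           if obj.has_atom(resid, n)]
    if not idx:
        raise KeyError(
            f"no proton {name!r} in residue {resid} of {obj.seq}")
    return idx


def _pair_r6(coords: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int]
             ) -> np.ndarray:
    """Per-member <r^-6> over all equivalent-proton combinations.

    ``coords`` has shape (M, n_atoms, 3); returns shape (M,).
    """
    vals = []
    for a in idx_a:
        for b in idx_b:
            if a == b:
                vals.append(np.full(coords.shape[0], np.inf))
                continue
            r = np.linalg.norm(coords[:, a] - coords[:, b], axis=-1)
            vals.append(r ** -6.0)
    return np.mean(vals, axis=0)


def proton_distance(conf: Conformer, sel_a: tuple[int, str],
                    sel_b: tuple[int, str]) -> float:
    """Effective interproton distance (Å) in a single conformer.

    For degenerate methylene/aromatic groups the value is the r^-6-averaged
    effective distance over the equivalent protons.  Identical selectors
    give 0.
    """
    ia = proton_group(conf, *sel_a)
    ib = proton_group(conf, *sel_b)
    if ia == ib:
        return 0.0
    r6 = _pair_r6(conf.coords[None], ia, ib)[0]
    return float(r6 ** (-1.0 / 6.0))


def ensemble_noe_intensity(ens: Ensemble, pair) -> float:
    """Relative NOE intensity I = (1/M) sum_m <r_m^-6> for a proton pair.

    ``pair`` is ``((resid, name), (resid, name))`` using proton selectors.
    """
    (ra, na), (rb, nb) = pair
    ia = proton_group(ens, ra, na)
    ib = proton_group(ens, rb, nb)
    return float(np.mean(_pair_r6(ens.coords, ia, ib)))


def effective_distance(ens: Ensemble, pair) -> float:
    """Ensemble-effective distance r_eff = I^(-1/6) in Å."""
    return ensemble_noe_intensity(ens, pair) ** (-1.0 / 6.0)


@dataclass
class RatioProfile:
    """Sequential NOE intensity ratios per position i (1-based).

    ``r1[i-1]`` is I[aH(i)-HN(i+1)]/I[HN(i)-HN(i+1)] and ``r2[i-1]`` is
    I[aH(i)-HN(i+1)]/I[aH(i)-HN(i)].  Positions where a required amide
    proton does not exist (prolines, chain ends) are NaN.
    """

    positions: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    def mean_r1(self) -> float:
        return float(np.nanmean(self.r1))

    def mean_r2(self) -> float:
        return float(np.nanmean(self.r2))


def noe_ratio_profile(ens: Ensemble) -> RatioProfile:
    """R1/R2 profiles from rigid-ensemble <r^-6> intensities."""
    L = len(ens.seq)
    positions = np.arange(1, L)
    r1 = np.full(L - 1, np.nan)
    r2 = np.full(L - 1, np.nan)
    for i in positions:
        if not (ens.has_atom(i, "H") and ens.has_atom(i + 1, "H")):
            continue
        i_an = ensemble_noe_intensity(ens, ((i, "HA"), (i + 1, "HN")))
        i_nn = ensemble_noe_intensity(ens, ((i, "HN"), (i + 1, "HN")))
        i_aii = ensemble_noe_intensity(ens, ((i, "HA"), (i, "HN")))
        r1[i - 1] = i_an / i_nn
        r2[i - 1] = i_an / i_aii
    return RatioProfile(positions, r1, r2)


def classify_from_ratios(r1: float, r2: float) -> str:
    """Coarse secondary-structure label from the sequential ratios.

    The discriminating statistic is R2: > 4 indicates beta-strand-like
    extension, 2.3 < R2 <= 4 indicates PPII leaning, anything lower is
    random-coil-like.  R1 is corroborating evidence only.
    """
    if not (np.isfinite(r1) and np.isfinite(r2)):
        raise ValueError("ratios must be finite")
    if r2 > 4.0:
        return "beta-leaning"
    if r2 > 2.3:
        return "PPII-leaning"
    return "random-coil-like"


# ---------------------------------------------------------------------------
# chemical shifts and temperature gradients
# ---------------------------------------------------------------------------

def secondary_shift(delta: float, delta_isc: float) -> float:
    """Secondary shift (ppm): observed minus intrinsic statistical coil."""
    return float(delta) - float(delta_isc)


def secondary_shift_table(observed, reference):
    """Secondary shifts for matching (residue_index, atom) records.

    Both arguments are DataFrames with at least ``residue_index``, ``atom``
    and ``shift_ppm`` columns (the shape produced by
    :func:`ppii_ensemble.io.read_shift_table`).  Rows present in only one
    table are dropped; a mismatching residue type raises.
    """
    import pandas as pd

    keys = ["residue_index", "atom"]
    merged = pd.merge(observed, reference, on=keys, suffixes=("", "_isc"))
    if "residue_isc" in merged and not (
            merged["residue"] == merged["residue_isc"]).all():
        bad = merged.loc[merged["residue"] != merged["residue_isc"], keys]
        raise ValueError(f"residue identity mismatch at rows:\n{bad}")
    merged["secondary_shift_ppm"] = (
        merged["shift_ppm"] - merged["shift_ppm_isc"])
    return merged[keys + ["secondary_shift_ppm"]]


def amide_temp_gradient(series) -> tuple[float, float]:
    """Least-squares amide shift temperature gradient in ppb/K.

    ``series`` is an iterable of (T_kelvin, delta_ppm) pairs; at least three
    points are required.  Returns (slope, standard error) in ppb/K.
    """
    pts = np.asarray(list(series), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (temperature, shift) points")
    t, d = pts[:, 0], pts[:, 1]
    if np.ptp(t) == 0:
        raise ValueError("temperatures must not be all identical")
    res = stats.linregress(t, d * 1e3)  # ppm -> ppb
    return float(res.slope), float(res.stderr)


@dataclass(frozen=True)
class AndersenRegion:
    """Linear acceptance region for hydrogen-bond-protected amides.

    A (csd, gradient) point is ``protected`` iff
    gradient >= slope * csd + intercept.  The default is the flat
    -4.6 ppb/K cut-off commonly drawn through the Andersen correlation plot.
    """

    slope: float = 0.0
    intercept: float = -4.6

    def contains(self, csd: float, gradient: float) -> bool:
        return gradient >= self.slope * csd + self.intercept


def hbond_flag(gradient: float, csd: float,
               region: AndersenRegion = AndersenRegion()) -> str:
    """Classify an amide as ``protected`` or ``exposed``.

    ``gradient`` in ppb/K, ``csd`` the HN chemical-shift deviation in ppm.
    """
    if not (np.isfinite(gradient) and np.isfinite(csd)):
        raise ValueError("gradient and csd must be finite")
    return "protected" if region.contains(csd, gradient) else "exposed"


# ---------------------------------------------------------------------------
# proline isomer diagnostics
# ---------------------------------------------------------------------------

def proline_isomer_state(conf: Conformer, pro_index: int) -> dict:
    """cis/trans state of the X-Pro bond preceding residue ``pro_index``.

    trans iff |omega| > 90 deg.  Also reports the two diagnostic distances
    d(Halpha(i-1), Hdelta(Pro)) and d(Halpha(i-1), Halpha(Pro)): for a trans
    bond the Hdelta contact is the shorter of the two, for cis the Halpha
    contact is.
    """
    residues = conf.seq.residues
    if not (1 <= pro_index <= len(residues)) or residues[pro_index - 1] != "PRO":
        raise ValueError(f"residue {pro_index} is not a proline")
    if pro_index == 1 and conf.seq.n_cap == "free":
        raise ValueError("proline 1 has no preceding residue")
    omega = conf.dihedrals().omega[pro_index - 1]
    state = "trans" if abs(omega) > 90.0 else "cis"
    if pro_index > 1:
        prev_sel = (pro_index - 1, "HA")
        d_ad = proton_distance(conf, prev_sel, (pro_index, "HD"))
        d_aa = proton_distance(conf, prev_sel, (pro_index, "HA"))
    else:  # acetyl cap has no Halpha; distances unavailable
        d_ad = d_aa = np.nan
    return {"state": state, "omega": float(omega),
            "d_ha_hd": float(d_ad), "d_ha_ha": float(d_aa)}
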