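"""File formats: multi-model PDB, shift tables, restraints, diffusion decays.

The PDB writer emits plain ATOM/MODEL/ENDMDL records (chain A, occupancy
1.00, B 0.00), with the caps recorded as ACE and NH2 residues; the reader is
deliberately strict, accepts only what the writer produces plus whitespace
variation, reports malformed records with their line number, and round-trips
bit-identically for files this package wrote.  Tabular data (shift tables,
restraints, J targets, diffusion decays) are plain CSV / columnar text read
through pandas.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .hydro import DiffusionSeries
from .peptide import AA3TO1, Conformer, SequenceSpec, get_plan
from .selector import NoeRestraint, RestraintSet

__all__ = [
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "read_shift_table",
    "packaged_shift_table",
    "write_noe_table",
    "read_noe_table",
    "write_j_table",
    "read_j_table",
    "write_shift_targets",
    "read_shift_targets",
    "write_diffusion_series",
    "read_diffusion_series",
]


# ---------------------------------------------------------------------------
# multi-model PDB
# ---------------------------------------------------------------------------

def _atom_line(serial, name, resname, resid, xyz, element):
    pdb_name = name if len(name) == 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {pdb_name}{'':1s}{resname:>3s} A{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def write_multimodel_pdb(path, conformers: Ensemble | list[Conformer]):
    """Write conformers as a multi-model PDB file (chain A)."""
    if isinstance(conformers, Ensemble):
        members = list(conformers)
    else:
        members = list(conformers)
    lines = []
    for m, conf in enumerate(members, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 0
        for i in range(conf.n_atoms):
            serial += 1
            lines.append(_atom_line(serial, conf.atom_names[i],
                                    conf.resnames[i], conf.resids[i],
                                    conf.coords[i], conf.elements[i]))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _infer_sequence(records) -> SequenceSpec:
    resnames = {}
    for resid, resname, _, _ in records:
        resnames.setdefault(resid, resname)
    n_cap = "acetyl" if resnames.get(0) == "ACE" else "free"
    max_resid = max(r for r in resnames if resnames[r] != "NH2" or r == 0)
    c_cap = "amide" if resnames.get(max(resnames)) == "NH2" else "free"
    last = max(r for r, n in resnames.items() if n not in ("ACE", "NH2"))
    residues = []
    for r in range(1, last + 1):
        if r not in resnames:
            raise ValueError(f"missing residue {r} in PDB file")
        if resnames[r] not in AA3TO1:
            raise ValueError(f"unknown residue name {resnames[r]!r}")
        residues.append(resnames[r])
    return SequenceSpec(tuple(residues), n_cap=n_cap, c_cap=c_cap)


def read_multimodel_pdb(path, chain: str = "A") -> list[Conformer]:
    """Read a multi-model PDB written by this package.

    One :class:`Conformer` per MODEL block; atoms are mapped back onto the
    sequence's canonical atom plan.  Records on chains other than ``chain``
    are rejected.  A file with zero models returns an empty list with a
    warning.
    """
    models: list[list] = []
    current: list | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                if current is None:
                    raise ValueError(f"line {lineno}: ENDMDL without MODEL")
                models.append(current)
                current = None
            elif line.startswith("ATOM") or line.startswith("HETATM"):
                if current is None:
                    current = []   # tolerate single-model files w/o MODEL
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    ch = line[21]
                    resid = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]),
                           float(line[46:54]))
                except (ValueError, IndexError) as exc:
                    raise ValueError(
                        f"line {lineno}: malformed ATOM record: {exc}"
                        ) from None
                if ch != chain:
                    raise ValueError(
                        f"line {lineno}: chain {ch!r} not accepted "
                        f"(only chain {chain!r} is read by default)")
                current.append((resid, resname, name, xyz))
    if current:
        models.append(current)
    if not models:
        warnings.warn(f"{path}: no models found", stacklevel=2)
        return []

    seq = _infer_sequence(models[0])
    plan = get_plan(seq)
    out = []
    for records in models:
        coords = np.full((len(plan.names), 3), np.nan)
        for resid, resname, name, xyz in records:
            key = (resid, name)
            if key not in plan.index:
                raise ValueError(
                    f"atom {name!r} of residue {resid} ({resname}) does not "
                    f"belong to the {seq} topology")
            coords[plan.index[key]] = xyz
        if np.isnan(coords).any():
            missing = [f"{plan.resids[i]}/{plan.names[i]}"
                       for i in np.where(np.isnan(coords).any(axis=1))[0]]
            raise ValueError(f"model missing atoms: {', '.join(missing[:8])}")
        out.append(Conformer(seq, coords, provenance="file"))
    return out


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------

_SHIFT_COLUMNS = ["residue_index", "residue", "atom", "shift_ppm",
                  "condition", "temperature_K"]


def read_shift_table(path) -> pd.DataFrame:
    """Read an assigned-shift CSV with the package's fixed columns.

    Validates column presence, numeric ppm values, and uniqueness of
    (residue_index, atom, condition, temperature_K) records.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty shift table") from None
    missing = [c for c in _SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ppm = pd.to_numeric(df["shift_ppm"], errors="coerce")
    if ppm.isna().any():
        rows = (df.index[ppm.isna()] + 2).tolist()   # header + 1-based
        raise ValueError(f"{path}: unparsable shift_ppm at file rows {rows}")
    df["shift_ppm"] = ppm
    key = ["residue_index", "atom", "condition", "temperature_K"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate shift records at rows {rows}")
    return df


def packaged_shift_table() -> pd.DataFrame:
    """The packaged water-condition assigned-shift table for 2-HexaPY."""
    ref = importlib.resources.files("ppii_ensemble") / "data" / \
        "hexapy_shifts_water.csv"
    with importlib.resources.as_file(ref) as p:
        return read_shift_table(p)


# ---------------------------------------------------------------------------
# restraints and observables
# ---------------------------------------------------------------------------

def write_noe_table(path, noes: list[NoeRestraint]):
    """Columnar NOE list: res_i atom_i res_j atom_j upper_A weight class."""
    with open(path, "w") as fh:
        fh.write("# res_i atom_i res_j atom_j upper_A weight class\n")
        for r in noes:
            fh.write(f"{r.res_i:4d} {r.atom_i:>4s} {r.res_j:4d} "
                     f"{r.atom_j:>4s} {r.bound:6.2f} {r.weight:6.3f} "
                     f"{r.klass}\n")


def read_noe_table(path) -> list[NoeRestraint]:
    noes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(
                    f"{path} line {lineno}: expected 7 columns, "
                    f"got {len(parts)}")
            noes.append(NoeRestraint(int(parts[0]), parts[1], int(parts[2]),
                                     parts[3], float(parts[4]),
                                     float(parts[5]), parts[6]))
    return noes


def write_j_table(path, j_targets: pd.DataFrame):
    """Per-residue J-coupling targets: residue, J (Hz), sigma (Hz)."""
    with open(path, "w") as fh:
        fh.write("# residue j_hz sigma_hz\n")
        for _, row in j_targets.iterrows():
            fh.write(f"{int(row.residue_index):4d} {row.j_hz:7.3f} "
                     f"{row.sigma_hz:6.3f}\n")


def read_j_table(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path} line {lineno}: expected at least "
                                 "residue and J columns")
            rows.append({"residue_index": int(parts[0]),
                         "j_hz": float(parts[1]),
                         "sigma_hz": float(parts[2]) if len(parts) > 2
                         else 0.2})
    return pd.DataFrame(rows)


def write_shift_targets(path, shift_targets: pd.DataFrame):
    shift_targets.to_csv(path, index=False)


def read_shift_targets(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"residue_index", "dshift_ppm", "sigma_ppm"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {need - set(df.columns)}")
    return df


def read_restraint_set(noe_path=None, j_path=None, shift_path=None
                       ) -> RestraintSet:
    return RestraintSet(
        noes=read_noe_table(noe_path) if noe_path else [],
        j_targets=read_j_table(j_path) if j_path else None,
        shift_targets=read_shift_targets(shift_path) if shift_path else None)


# ---------------------------------------------------------------------------
# diffusion decays
# ---------------------------------------------------------------------------

def write_diffusion_series(path, series: DiffusionSeries):
    """Two-column CSV with a commented header block of fit constants."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K: {series.temperature_K}\n")
        fh.write(f"# viscosity_mPas: {series.viscosity_mPas}\n")
        fh.write(f"# cal_const: {series.cal_const}\n")
        fh.write("gradient_G_cm,intensity\n")
        for g, i in zip(series.gradient, series.intensity):
            fh.write(f"{g:.6g},{i:.8g}\n")


def read_diffusion_series(path) -> DiffusionSeries:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
            body_start = k + 1
        else:
            break
    import io as _io
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return DiffusionSeries(df["gradient_G_cm"].to_numpy(),
                           df["intensity"].to_numpy(),
                           temperature_K=meta.get("temperature_K", 300.0),
                           viscosity_mPas=meta.get("viscosity_mPas", 0.851),
                           cal_const=meta.get("cal_const", 1.8e7))
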