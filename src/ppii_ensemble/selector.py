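"""Restraint-driven sub-ensemble selection from a conformer pool.

The selection objective is a pseudo-energy over ensemble-averaged
observables:

* flat-bottom quadratic NOE terms, ``weight * max(0, r_eff - bound)^2``
  with the ensemble-effective distance ``r_eff = <r^-6>^(-1/6)``;
* a chi-square J-coupling term on the linear ensemble mean of the Karplus
  curve;
* an optional chi-square term on coarse basin-level Halpha secondary-shift
  predictions (off by default).

Optimisation is stochastic exchange: starting from a random subset of the
requested size, single-member swaps against the pool are accepted by a
Metropolis rule under a geometrically decreasing temperature schedule.
Hydrodynamic data never enter the objective, so the Rh comparison afterwards
is an honest cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hydro, nmr, sampler
from .ensemble import Ensemble

__all__ = [
    "NoeRestraint",
    "RestraintSet",
    "Schedule",
    "SelectionResult",
    "restraint_score",
    "select_ensemble",
    "cross_validate_rh",
]


@dataclass(frozen=True)
class NoeRestraint:
    """An upper-bound distance restraint between two proton selectors."""

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    bound: float          # Å: 8 for the strong class, 10 for the weak class
    weight: float         # 1.0 strong, 0.1 weak
    klass: str = "strong"

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError("restraint bound must be positive")
        if self.weight <= 0:
            raise ValueError("restraint weight must be positive")


@dataclass
class RestraintSet:
    """NOE bounds plus per-residue J targets (and optional shift targets).

    ``j_targets`` and ``shift_targets`` are DataFrames with columns
    ``residue_index``, ``j_hz``/``dshift_ppm`` and ``sigma_hz``/``sigma_ppm``.
    """

    noes: list[NoeRestraint]
    j_targets: pd.DataFrame | None = None
    shift_targets: pd.DataFrame | None = None

    def __post_init__(self):
        n = len(self.noes)
        if self.j_targets is not None and len(self.j_targets) == 0:
            self.j_targets = None
        if self.shift_targets is not None and len(self.shift_targets) == 0:
            self.shift_targets = None
        if n == 0 and self.j_targets is None and self.shift_targets is None:
            raise ValueError("restraint set is empty")
        if self.j_targets is not None and (
                self.j_targets["sigma_hz"] <= 0).any():
            raise ValueError("J-coupling uncertainties must be positive")


@dataclass(frozen=True)
class Schedule:
    """Stochastic-exchange schedule: geometric cooling over fixed stages."""

    t_start: float = 1.0
    t_end: float = 1e-3
    stages: int = 20
    proposals_per_member: float = 50.0   # scaled by log(pool size)

    def n_proposals(self, size: int, pool: int) -> int:
        return max(200, int(self.proposals_per_member * size
                            * math.log(max(pool, 2))))

    def temperatures(self, n: int) -> np.ndarray:
        stage_t = np.geomspace(self.t_start, self.t_end, self.stages)
        return np.repeat(stage_t, int(np.ceil(n / self.stages)))[:n]


@dataclass
class SelectionResult:
    indices: np.ndarray
    ensemble: Ensemble
    score: float
    trace: np.ndarray                 # best score after each proposal block
    violations: pd.DataFrame
    seed: int | None = None
    schedule: Schedule | None = None


# ---------------------------------------------------------------------------
# precomputation
# ---------------------------------------------------------------------------

class _Terms:
    """Per-member contributions to every restraint term, for fast swaps."""

    def __init__(self, ens: Ensemble, rs: RestraintSet,
                 include_shifts: bool):
        M = len(ens)
        self.noe_bounds = np.array([r.bound for r in rs.noes])
        self.noe_weights = np.array([r.weight for r in rs.noes])
        cols = []
        for r in rs.noes:
            try:
                ia = nmr.proton_group(ens, r.res_i, r.atom_i)
                ib = nmr.proton_group(ens, r.res_j, r.atom_j)
            except KeyError as exc:
                raise KeyError(
                    f"unresolvable restraint {r.res_i}/{r.atom_i} - "
                    f"{r.res_j}/{r.atom_j}: {exc}") from None
            cols.append(nmr._pair_r6(ens.coords, ia, ib))
        self.r6 = (np.stack(cols, axis=1) if cols
                   else np.zeros((M, 0)))

        if rs.j_targets is not None:
            res = rs.j_targets["residue_index"].to_numpy(dtype=int)
            self.j_member = nmr.karplus_j(ens.phi[:, res - 1])
            self.j_target = rs.j_targets["j_hz"].to_numpy(dtype=float)
            self.j_sigma = rs.j_targets["sigma_hz"].to_numpy(dtype=float)
        else:
            self.j_member = np.zeros((M, 0))
            self.j_target = np.zeros(0)
            self.j_sigma = np.ones(0)

        if include_shifts and rs.shift_targets is not None:
            res = rs.shift_targets["residue_index"].to_numpy(dtype=int)
            pred = sampler.predicted_halpha_shifts(ens)
            self.s_member = pred[:, res - 1]
            self.s_target = rs.shift_targets["dshift_ppm"].to_numpy(float)
            self.s_sigma = rs.shift_targets["sigma_ppm"].to_numpy(float)
        else:
            self.s_member = np.zeros((M, 0))
            self.s_target = np.zeros(0)
            self.s_sigma = np.ones(0)

    def score_from_sums(self, r6_sum, j_sum, s_sum, size) -> float:
        total = 0.0
        if r6_sum.size:
            r_eff = (r6_sum / size) ** (-1.0 / 6.0)
            viol = np.maximum(0.0, r_eff - self.noe_bounds)
            total += float(np.sum(self.noe_weights * viol ** 2))
        if j_sum.size:
            total += float(np.sum(((j_sum / size - self.j_target)
                                   / self.j_sigma) ** 2))
        if s_sum.size:
            total += float(np.sum(((s_sum / size - self.s_target)
                                   / self.s_sigma) ** 2))
        return total

    def score_subset(self, idx) -> float:
        idx = np.asarray(idx, dtype=int)
        return self.score_from_sums(self.r6[idx].sum(axis=0),
                                    self.j_member[idx].sum(axis=0),
                                    self.s_member[idx].sum(axis=0), len(idx))


def restraint_score(ens: Ensemble, rs: RestraintSet,
                    include_shifts: bool = False) -> float:
    """Pseudo-energy of an ensemble under a restraint set (>= 0)."""
    terms = _Terms(ens, rs, include_shifts)
    return terms.score_subset(np.arange(len(ens)))


def violation_table(ens: Ensemble, rs: RestraintSet) -> pd.DataFrame:
    """Per-NOE effective distances and violations for a report."""
    rows = []
    for r in rs.noes:
        r_eff = nmr.effective_distance(
            ens, ((r.res_i, r.atom_i), (r.res_j, r.atom_j)))
        rows.append({
            "res_i": r.res_i, "atom_i": r.atom_i,
            "res_j": r.res_j, "atom_j": r.atom_j,
            "class": r.klass, "bound_A": r.bound, "weight": r.weight,
            "r_eff_A": r_eff, "violation_A": max(0.0, r_eff - r.bound)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stochastic exchange optimisation
# ---------------------------------------------------------------------------

def select_ensemble(pool: Ensemble, rs: RestraintSet, size: int = 100,
                    rng_seed=0, schedule: Schedule | None = None,
                    include_shifts: bool = False) -> SelectionResult:
    """Select a fixed-size sub-ensemble minimising the restraint score.

    Deterministic for a given seed.  Returns the best-scoring subset seen
    during the anneal (its member order follows the pool index order).
    """
    M = len(pool)
    if size > M:
        raise ValueError(f"requested size {size} exceeds pool size {M}")
    schedule = schedule or Schedule()
    rng = sampler._rng(rng_seed)
    terms = _Terms(pool, rs, include_shifts)

    idx = rng.choice(M, size=size, replace=False)
    in_subset = np.zeros(M, dtype=bool)
    in_subset[idx] = True
    r6_sum = terms.r6[idx].sum(axis=0)
    j_sum = terms.j_member[idx].sum(axis=0)
    s_sum = terms.s_member[idx].sum(axis=0)
    current = terms.score_from_sums(r6_sum, j_sum, s_sum, size)
    best = current
    best_idx = idx.copy()

    n_prop = schedule.n_proposals(size, M)
    temps = schedule.temperatures(n_prop)
    trace = []
    block = max(1, n_prop // 200)
    for step in range(n_prop):
        pos = rng.integers(size)
        out = idx[pos]
        cand = int(rng.integers(M))
        if in_subset[cand]:
            if step % block == 0:
                trace.append(best)
            continue
        new_r6 = r6_sum + terms.r6[cand] - terms.r6[out]
        new_j = j_sum + terms.j_member[cand] - terms.j_member[out]
        new_s = s_sum + terms.s_member[cand] - terms.s_member[out]
        new_score = terms.score_from_sums(new_r6, new_j, new_s, size)
        dE = new_score - current
        if dE <= 0 or rng.random() < math.exp(-dE / max(temps[step], 1e-12)):
            idx[pos] = cand
            in_subset[out] = False
            in_subset[cand] = True
            r6_sum, j_sum, s_sum = new_r6, new_j, new_s
            current = new_score
            if current < best:
                best = current
                best_idx = idx.copy()
        if step % block == 0:
            trace.append(best)
    trace.append(best)

    best_idx = np.sort(best_idx)
    selected = pool.subset(best_idx)
    selected.provenance = "selected"
    result = SelectionResult(
        indices=best_idx, ensemble=selected, score=float(best),
        trace=np.asarray(trace), violations=violation_table(selected, rs),
        seed=rng_seed if isinstance(rng_seed, int) else None,
        schedule=schedule)
    return result


# ---------------------------------------------------------------------------
# hydrodynamic cross-validation
# ---------------------------------------------------------------------------

def cross_validate_rh(sel: SelectionResult | Ensemble, experimental_rh: float,
                      bead_radius: float = hydro.DEFAULT_BEAD_RADIUS) -> dict:
    """Compare the selected ensemble's Kirkwood Rh with an experimental value.

    The ensemble passes when the experimental radius lies within
    mean +/- 2 sd of the per-member back-calculated radii.  Hydrodynamics is
    never part of the selection objective, so this is an independent check.
    """
    ens = sel.ensemble if isinstance(sel, SelectionResult) else sel
    mean, sd, values = hydro.ensemble_rh(ens, bead_radius)
    deviation = abs(mean - experimental_rh)
    return {
        "ensemble_rh_mean": mean,
        "ensemble_rh_sd": sd,
        "experimental_rh": float(experimental_rh),
        "deviation": deviation,
        "passes": bool(deviation <= 2.0 * sd),
        "bead_radius": bead_radius,
        "n_members": len(ens),
    }
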