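"""Hydrodynamics: diffusion decays, Stokes-Einstein, Kirkwood bead model.

The experimental route goes PG-SLED diffusion decay -> translational
diffusion coefficient -> hydrodynamic radius via Stokes-Einstein.  The
structural route back-calculates Rh per conformer from heavy-atom
coordinates with the Kirkwood double-sum approximation

    1/Rh = 1/(N a) + (1/N^2) sum_{i != j} 1/r_ij

over N beads of hydrated radius ``a``; ensembles are summarised by the
arithmetic mean and standard deviation over members.  The two routes never
mix, which is what makes the hydrodynamic comparison of a restraint-selected
ensemble a genuine cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .ensemble import Ensemble
from .peptide import Conformer, get_plan

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DEFAULT_BEAD_RADIUS",
    "DEFAULT_CAL_CONST",
    "DiffusionSeries",
    "HydroResult",
    "forward_diffusion_decay",
    "fit_diffusion_decay",
    "stokes_einstein_rh",
    "diffusion_coefficient_from_rh",
    "kirkwood_rh",
    "ensemble_rh",
]

BOLTZMANN_J_PER_K = 1.380649e-23

#: Hydrated heavy-atom bead radius (Å) of the atomic-level bead convention.
DEFAULT_BEAD_RADIUS = 2.9

#: Instrument calibration constant c in I(G) = I0 exp(-c D G^2), for D in
#: m^2/s and G in G/cm.  Corresponds to ordinary PG-SLED encode/decode
#: timings; synthetic decays and fits share it, so radii are c-independent.
DEFAULT_CAL_CONST = 1.8e7


@dataclass
class DiffusionSeries:
    """A pulsed-field-gradient decay: intensity vs gradient strength."""

    gradient: np.ndarray            # G/cm, strictly increasing
    intensity: np.ndarray           # normalised to (0, 1]
    temperature_K: float = 300.0
    viscosity_mPas: float = 0.851   # pure water at 300 K
    cal_const: float = DEFAULT_CAL_CONST

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.gradient.size != self.intensity.size:
            raise ValueError("gradient and intensity lengths differ")
        if self.gradient.size < 5:
            raise ValueError("need at least 5 gradient points")
        if not np.all(np.diff(self.gradient) > 0):
            raise ValueError("gradient strengths must be strictly increasing")
        if np.any(self.intensity <= 0) or np.any(self.intensity > 1.0 + 1e-9):
            raise ValueError("intensities must lie in (0, 1]")


@dataclass
class HydroResult:
    d_trans: float | None           # m^2/s (None for coordinate-based route)
    rh: float                       # Å
    uncertainty: float              # Å
    method: str                     # 'stokes-einstein' | 'kirkwood-bead'


def diffusion_coefficient_from_rh(rh_angstrom: float, temperature_K: float,
                                  viscosity_mPas: float) -> float:
    """Invert Stokes-Einstein: D (m^2/s) for a given Rh in Å."""
    if rh_angstrom <= 0 or temperature_K <= 0 or viscosity_mPas <= 0:
        raise ValueError("all inputs must be positive")
    eta = viscosity_mPas * 1e-3
    return BOLTZMANN_J_PER_K * temperature_K / (
        6.0 * np.pi * eta * rh_angstrom * 1e-10)


def forward_diffusion_decay(rh_angstrom: float, gradient=None,
                            temperature_K: float = 300.0,
                            viscosity_mPas: float = 0.851,
                            cal_const: float = DEFAULT_CAL_CONST,
                            noise: float = 0.0,
                            rng: np.random.Generator | None = None
                            ) -> DiffusionSeries:
    """Synthesize a PG-SLED decay for a target hydrodynamic radius.

    Gaussian noise of relative scale ``noise`` is added to the intensities
    and clipped into (0, 1].  The default gradient grid is 20 points over
    0.5-30 G/cm.
    """
    if gradient is None:
        gradient = np.linspace(0.5, 30.0, 20)
    gradient = np.asarray(gradient, dtype=float)
    D = diffusion_coefficient_from_rh(rh_angstrom, temperature_K,
                                      viscosity_mPas)
    I = np.exp(-cal_const * D * gradient ** 2)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        I = I + rng.normal(0.0, noise, size=I.shape)
        I = np.clip(I, 1e-6, 1.0)
    return DiffusionSeries(gradient, I, temperature_K, viscosity_mPas,
                           cal_const)


def fit_diffusion_decay(series: DiffusionSeries) -> tuple[float, float]:
    """Translational diffusion coefficient from a decay series.

    Nonlinear least-squares fit of I(G) = I0 exp(-c D G^2); returns (D,
    standard error) in m^2/s.  Fitting on the linear intensity scale keeps
    noisy near-zero tail points from dominating, which a log-linear fit
    would.  A series that does not decay is rejected.
    """
    from scipy.optimize import curve_fit

    g2 = series.gradient ** 2
    # initial guess from a log-linear fit restricted to the strong points
    strong = series.intensity > 0.05 * series.intensity.max()
    slope = stats.linregress(g2[strong],
                             np.log(series.intensity[strong])).slope
    if slope >= 0:
        raise ValueError("series does not decay")
    c = series.cal_const

    def model(g2_, i0, d):
        return i0 * np.exp(-c * d * g2_)

    p0 = (float(series.intensity[0]), -slope / c)
    popt, pcov = curve_fit(model, g2, series.intensity, p0=p0, maxfev=10000)
    D = float(popt[1])
    if D <= 0:
        raise ValueError("series does not decay: fitted D is non-positive")
    return D, float(np.sqrt(pcov[1, 1]))


def stokes_einstein_rh(d_trans: float, temperature_K: float,
                       viscosity_mPas: float) -> float:
    """Hydrodynamic radius (Å) via Rh = kB T / (6 pi eta D)."""
    if d_trans <= 0 or temperature_K <= 0 or viscosity_mPas <= 0:
        raise ValueError("all inputs must be positive")
    eta = viscosity_mPas * 1e-3
    rh_m = BOLTZMANN_J_PER_K * temperature_K / (6.0 * np.pi * eta * d_trans)
    return rh_m * 1e10


# ---------------------------------------------------------------------------
# Kirkwood bead model
# ---------------------------------------------------------------------------

def kirkwood_rh(conf: Conformer | np.ndarray,
                bead_radius: float = DEFAULT_BEAD_RADIUS,
                seq=None) -> float:
    """Kirkwood-approximation Rh (Å) from heavy-atom beads.

    Accepts a :class:`Conformer` or a raw (n_heavy, 3) coordinate array.
    """
    if isinstance(conf, Conformer):
        xyz = conf.coords[get_plan(conf.seq).heavy]
    else:
        xyz = np.asarray(conf, dtype=float)
    n = xyz.shape[0]
    if n == 0:
        raise ValueError("need at least one heavy atom")
    if n == 1:
        return float(bead_radius)
    inv_sum = np.sum(1.0 / pdist(xyz)) * 2.0   # both (i,j) and (j,i)
    inv_rh = 1.0 / (n * bead_radius) + inv_sum / n ** 2
    return float(1.0 / inv_rh)


def ensemble_rh(ens: Ensemble, bead_radius: float = DEFAULT_BEAD_RADIUS
                ) -> tuple[float, float, np.ndarray]:
    """Per-member Kirkwood Rh: (mean, sd, values) in Å."""
    heavy = get_plan(ens.seq).heavy
    vals = np.array([kirkwood_rh(ens.coords[m][heavy], bead_radius)
                     for m in range(len(ens))])
    return float(vals.mean()), float(vals.std()), vals
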