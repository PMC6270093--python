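"""Karplus analysis, NOE intensities/ratios, shifts, temperature gradients."""

import numpy as np
import pytest

from ppii_ensemble import nmr
from ppii_ensemble.ensemble import Ensemble
from ppii_ensemble.nmr import (
    AndersenRegion,
    KarplusCoefficients,
    VUISTER_BAX,
    amide_temp_gradient,
    classify_from_ratios,
    ensemble_noe_intensity,
    hbond_flag,
    invert_karplus,
    karplus_j,
    noe_ratio_profile,
    proline_isomer_state,
    proton_distance,
    secondary_shift,
)
from ppii_ensemble.peptide import DihedralSet, build_conformer


# ---------------------------------------------------------------------------
# Karplus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi,expected", [
    (-120.0, 9.87),   # cos(theta) = -1
    (60.0, 6.35),     # cos(theta) = +1
    (-60.0, 4.1075),  # cos(theta) = -1/2
])
def test_karplus_values(phi, expected):
    assert karplus_j(phi) == pytest.approx(expected, abs=1e-3)


def test_karplus_requires_positive_A():
    with pytest.raises(ValueError):
        KarplusCoefficients(A=-1.0, B=0.0, C=0.0)


def test_invert_karplus_round_trip_single():
    sols = invert_karplus(karplus_j(-85.0))
    assert any(abs(s + 85.0) < 0.1 for s in sols)


def test_invert_karplus_below_minimum_empty():
    # curve minimum sits near 1.48 Hz for the default coefficients
    assert invert_karplus(1.0) == []


def test_invert_karplus_grid_round_trip():
    """karplus_j and invert_karplus are mutual inverses on a 1-degree grid."""
    for phi in np.arange(-179.0, 181.0, 1.0):
        sols = invert_karplus(karplus_j(phi))
        assert sols, phi
        assert min(abs(phi - s) for s in sols) < 0.1


def test_extended_j_band_maps_to_ppii_phi_branch():
    """J in the extended 6.0-7.5 Hz band always has a root in (-90, -70)."""
    for j in np.arange(6.0, 7.51, 0.1):
        sols = invert_karplus(float(j))
        assert any(-90.0 < s < -70.0 for s in sols), j


# ---------------------------------------------------------------------------
# distances and intensities
# ---------------------------------------------------------------------------

def test_proton_distance_identity_and_symmetry(beta_conformer):
    assert proton_distance(beta_conformer, (2, "HA"), (2, "HA")) == 0.0
    ab = proton_distance(beta_conformer, (2, "HA"), (3, "HN"))
    ba = proton_distance(beta_conformer, (3, "HN"), (2, "HA"))
    assert ab == pytest.approx(ba, rel=1e-12)
    assert ab == pytest.approx(2.2, abs=0.15)


def test_proton_distance_missing_atom(beta_conformer):
    with pytest.raises(KeyError, match="residue 1"):
        proton_distance(beta_conformer, (1, "HN"), (2, "HN"))  # Pro1 has no HN


def test_methylene_pseudo_pair_r6_average(beta_conformer):
    """Pro Hdelta selector averages HD2/HD3 as r^-6."""
    d_eff = proton_distance(beta_conformer, (3, "HA"), (4, "HD"))
    r2 = np.linalg.norm(beta_conformer.position(3, "HA")
                        - beta_conformer.position(4, "HD2"))
    r3 = np.linalg.norm(beta_conformer.position(3, "HA")
                        - beta_conformer.position(4, "HD3"))
    expected = (0.5 * (r2 ** -6 + r3 ** -6)) ** (-1 / 6)
    assert d_eff == pytest.approx(expected, rel=1e-12)


def test_ensemble_intensity_r6_convention(two_hexapy, beta_conformer):
    ens = Ensemble.from_conformers([beta_conformer])
    pair = ((2, "HA"), (3, "HN"))
    r = proton_distance(beta_conformer, *pair)
    assert ensemble_noe_intensity(ens, pair) == pytest.approx(r ** -6)
    # doubling every distance divides the intensity by 64
    scaled = Ensemble(two_hexapy, ens.coords * 2.0)
    assert ensemble_noe_intensity(scaled, pair) == pytest.approx(
        r ** -6 / 64.0, rel=1e-9)


def test_ensemble_intensity_two_member_average(two_hexapy, beta_conformer,
                                               ppii_conformer):
    ens = Ensemble.from_conformers([beta_conformer, ppii_conformer])
    pair = ((2, "HA"), (3, "HN"))
    r1 = proton_distance(beta_conformer, *pair)
    r2 = proton_distance(ppii_conformer, *pair)
    assert ensemble_noe_intensity(ens, pair) == pytest.approx(
        0.5 * (r1 ** -6 + r2 ** -6), rel=1e-12)


def test_ensemble_intensity_permutation_invariant(coil_pool):
    pair = ((2, "HA"), (3, "HN"))
    i1 = ensemble_noe_intensity(coil_pool, pair)
    perm = coil_pool.subset(np.random.default_rng(0).permutation(
        len(coil_pool)))
    assert ensemble_noe_intensity(perm, pair) == pytest.approx(i1, rel=1e-12)


# ---------------------------------------------------------------------------
# ratio diagnostics
# ---------------------------------------------------------------------------

def test_beta_strand_r1_is_extended_signature(beta_conformer):
    prof = noe_ratio_profile(Ensemble.from_conformers([beta_conformer]))
    vals = prof.r1[np.isfinite(prof.r1)]
    # Gly positions sit lower (two-proton r^-6 average) but remain far
    # above any coil-like value; non-Gly positions show the full ~55
    assert np.all(vals > 25.0)
    assert vals.max() > 50.0


def test_ratio_profile_undefined_at_prolines(coil_pool):
    prof = noe_ratio_profile(coil_pool)
    # positions i where residue i or i+1 is Pro carry no HN-HN pair
    finite = set(prof.positions[np.isfinite(prof.r1)])
    assert finite == {2, 5, 8, 11}


def test_beta_vs_coil_r1_separation(coil_pool, beta_conformer):
    """The extended/coil R1 contrast spans more than an order of magnitude."""
    beta = noe_ratio_profile(Ensemble.from_conformers([beta_conformer]))
    coil = noe_ratio_profile(coil_pool)
    assert np.nanmean(beta.r1) >= 10.0 * np.nanmean(coil.r1)


@pytest.mark.parametrize("r2,label", [
    (5.0, "beta-leaning"),
    (3.0, "PPII-leaning"),
    (2.0, "random-coil-like"),
])
def test_classify_from_ratios(r2, label):
    assert classify_from_ratios(1.5, r2) == label


# ---------------------------------------------------------------------------
# shifts and temperature gradients
# ---------------------------------------------------------------------------

def test_secondary_shift_antisymmetric():
    assert secondary_shift(4.39, 4.41) == pytest.approx(-0.02)
    assert secondary_shift(4.41, 4.39) == pytest.approx(
        -secondary_shift(4.39, 4.41))
    assert secondary_shift(4.39, 4.39) == 0.0


def test_secondary_shift_table_mean():
    import pandas as pd
    obs = pd.DataFrame({"residue_index": [1, 2, 3], "residue": list("PHN"),
                        "atom": ["HA"] * 3, "shift_ppm": [4.18, 4.57, 4.83]})
    ref = obs.copy()
    ref["shift_ppm"] = [4.20, 4.55, 4.90]
    out = nmr.secondary_shift_table(obs, ref)
    assert out["secondary_shift_ppm"].mean() == pytest.approx(
        np.mean([-0.02, 0.02, -0.07]))


def test_temp_gradient_exact_line():
    t = np.array([300.0, 303.0, 306.0, 309.0])
    delta = 8.5 - 6.0e-3 * t
    slope, err = amide_temp_gradient(zip(t, delta))
    assert slope == pytest.approx(-6.0, abs=1e-9)
    assert err == pytest.approx(0.0, abs=1e-9)


def test_temp_gradient_constant_series():
    slope, _ = amide_temp_gradient([(300, 8.1), (305, 8.1), (310, 8.1)])
    assert slope == 0.0


def test_temp_gradient_needs_three_points():
    with pytest.raises(ValueError):
        amide_temp_gradient([(300, 8.1), (305, 8.0)])


def test_temp_gradient_noisy_recovery():
    """Monte-Carlo: the fitted slope is consistent with its standard error."""
    rng = np.random.default_rng(42)
    t = np.linspace(300, 311, 12)
    hits = 0
    for _ in range(100):
        delta = 8.5 - 6.0e-3 * t + rng.normal(0, 5e-3, size=t.size)
        slope, err = amide_temp_gradient(zip(t, delta))
        if abs(slope + 6.0) <= 2.0 * err:
            hits += 1
    assert hits >= 85


def test_hbond_flags():
    assert hbond_flag(-8.0, 0.0) == "exposed"
    assert hbond_flag(-1.0, 0.5) == "protected"
    # strongly negative gradients across the peptide all classify exposed
    for grad in (-6.0, -7.5, -9.0):
        assert hbond_flag(grad, 0.2) == "exposed"
    region = AndersenRegion(slope=-2.0, intercept=-5.0)
    assert hbond_flag(-5.5, 0.5, region) == "protected"


# ---------------------------------------------------------------------------
# proline isomer diagnostics
# ---------------------------------------------------------------------------

def _conformer_with_omega(seq, omega4):
    omega = np.full(12, 180.0)
    omega[3] = omega4
    return build_conformer(seq, DihedralSet(np.full(12, -75.0),
                                            np.full(12, 145.0), omega))


def test_trans_proline_diagnostic(two_hexapy):
    state = proline_isomer_state(_conformer_with_omega(two_hexapy, 180.0), 4)
    assert state["state"] == "trans"
    assert state["d_ha_hd"] < state["d_ha_ha"]


def test_cis_proline_diagnostic(two_hexapy):
    state = proline_isomer_state(_conformer_with_omega(two_hexapy, 0.0), 4)
    assert state["state"] == "cis"
    assert state["d_ha_ha"] < state["d_ha_hd"]


def test_omega_boundary_convention(two_hexapy):
    assert proline_isomer_state(
        _conformer_with_omega(two_hexapy, 90.1), 4)["state"] == "trans"
    assert proline_isomer_state(
        _conformer_with_omega(two_hexapy, 89.9), 4)["state"] == "cis"


def test_non_proline_rejected(two_hexapy, beta_conformer):
    with pytest.raises(ValueError, match="not a proline"):
        proline_isomer_state(beta_conformer, 2)
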