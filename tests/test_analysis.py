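"""Ramachandran classification, PPII profiles, superposition, clustering."""

import numpy as np
import pytest

from ppii_ensemble import analysis
from ppii_ensemble.analysis import (
    DEFAULT_REGIONS,
    RamaRegion,
    cluster_ensemble,
    cluster_stats,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    ppii_profile,
    rama_classify,
)
from ppii_ensemble.ensemble import Ensemble
from ppii_ensemble.peptide import DihedralSet, build_conformer


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi,psi,expected", [
    (-75.0, 145.0, "PPII"),
    (-65.0, -40.0, "alphaR"),
    (-139.0, 135.0, "beta"),
    (55.0, 45.0, "alphaL"),
    (0.0, 0.0, "other"),
    (-110.0, 145.0, "PPII"),       # closed lower bound belongs to PPII
    (-110.001, 145.0, "beta"),
    (-75.0, 180.0, "PPII"),        # domain edge +180 included
])
def test_rama_classification(phi, psi, expected):
    assert rama_classify(phi, psi) == expected


def test_overlapping_region_set_rejected():
    bad = (RamaRegion("A", (-100.0, 0.0), (0.0, 100.0)),
           RamaRegion("B", (-50.0, 50.0), (50.0, 150.0)))
    with pytest.raises(ValueError, match="overlap"):
        rama_classify(-20.0, 60.0, bad)


def _mixture_ensemble(seq, n_ppii, n_beta):
    confs = []
    for _ in range(n_ppii):
        confs.append(build_conformer(seq, DihedralSet.uniform(12, -75, 145)))
    for _ in range(n_beta):
        confs.append(build_conformer(seq, DihedralSet.uniform(12, -139, 135)))
    return Ensemble.from_conformers(confs)


def test_ppii_profile_counting(two_hexapy):
    """A 3:7 PPII/beta mixture gives exactly 0.30 at non-proline residues."""
    ens = _mixture_ensemble(two_hexapy, 3, 7)
    prof = ppii_profile(ens)
    # prolines have phi -65 under both mixtures -> PPII region membership
    # is decided purely by psi, identical for both: 3 PPII + 7 beta whose
    # psi 135 still lies in [110, 180] -> those count too
    assert prof.per_residue[1] == pytest.approx(0.30)      # His2
    assert prof.overall == pytest.approx(np.mean(prof.per_residue))


def test_all_ppii_profile_is_one(two_hexapy):
    ens = _mixture_ensemble(two_hexapy, 4, 0)
    assert np.all(ppii_profile(ens).per_residue == 1.0)


def test_overall_equals_mean_of_residues(coil_pool):
    prof = ppii_profile(coil_pool)
    assert prof.overall == pytest.approx(float(np.mean(prof.per_residue)))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_identity(beta_conformer):
    rmsd, _ = kabsch_superpose(beta_conformer, beta_conformer,
                               residue_range=(3, 10))
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_superpose_rotation_invariance(two_hexapy, beta_conformer):
    from ppii_ensemble.peptide import Conformer
    rng = np.random.default_rng(1)
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = Conformer(two_hexapy, beta_conformer.coords @ q.T + [5.0, -3.0, 2.0])
    rmsd, _ = kabsch_superpose(moved, beta_conformer, residue_range=(3, 10))
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_matches_scipy_oracle(beta_conformer, ppii_conformer):
    """Independent check against scipy's Kabsch (Rotation.align_vectors)."""
    from scipy.spatial.transform import Rotation

    sel = analysis._selection_indices(beta_conformer, (3, 10))
    P = beta_conformer.coords[sel]
    Q = ppii_conformer.coords[sel]
    rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    moved = rot.apply(P - P.mean(0)) + Q.mean(0)
    oracle = np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))
    rmsd, _ = kabsch_superpose(beta_conformer, ppii_conformer,
                               residue_range=(3, 10))
    assert rmsd == pytest.approx(oracle, rel=1e-6)


def test_superpose_postfit_rmsd_closed_form(two_hexapy, beta_conformer):
    """Displacing atoms post-fit: returned RMSD equals sqrt(sum d^2 / k)."""
    rmsd, (R, t) = kabsch_superpose(beta_conformer, beta_conformer,
                                    residue_range=(3, 10))
    from ppii_ensemble.peptide import Conformer
    sel = analysis._selection_indices(beta_conformer, (3, 10))
    # apply the optimal transform manually and displace nothing: rmsd 0;
    # then compare a perturbed pair against the brute-force evaluation
    rng = np.random.default_rng(3)
    other = beta_conformer.coords.copy()
    other[sel] += rng.normal(scale=0.3, size=(len(sel), 3))
    pert = Conformer(two_hexapy, other)
    rmsd, (R, t) = kabsch_superpose(beta_conformer, pert,
                                    residue_range=(3, 10))
    moved = beta_conformer.coords[sel] @ R.T + t
    brute = np.sqrt(np.mean(np.sum((moved - other[sel]) ** 2, axis=1)))
    assert rmsd == pytest.approx(brute, rel=1e-12)


def test_missing_selection_atom_reported(two_hexapy, beta_conformer):
    with pytest.raises(KeyError, match="CB"):
        analysis._selection_indices(beta_conformer, (5, 5), ("N", "CA", "CB"))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _jittered_group(seq, phi, psi, n, scale, rng):
    confs = []
    for _ in range(n):
        d = DihedralSet(phi + rng.normal(0, scale, 12),
                        psi + rng.normal(0, scale, 12))
        confs.append(build_conformer(seq, d))
    return confs


def test_two_separated_groups_give_two_clusters(two_hexapy):
    rng = np.random.default_rng(17)
    confs = (_jittered_group(two_hexapy, np.full(12, -75.0),
                             np.full(12, 145.0), 6, 2.0, rng)
             + _jittered_group(two_hexapy, np.full(12, -65.0),
                               np.full(12, -40.0), 6, 2.0, rng))
    ens = Ensemble.from_conformers(confs)
    tree = cluster_ensemble(ens, superpose_range=(3, 10))
    assert tree.n_clusters == 2
    assert len(set(tree.labels[:6])) == 1 and len(set(tree.labels[6:])) == 1
    assert tree.labels[0] != tree.labels[6]


def test_identical_ensemble_one_cluster(two_hexapy, beta_conformer):
    ens = Ensemble.from_conformers([beta_conformer] * 5)
    tree = cluster_ensemble(ens, superpose_range=(3, 10))
    assert tree.n_clusters == 1


def test_cluster_cut_matches_exhaustive_penalty_oracle(two_hexapy):
    """10-member toy: chosen cut equals brute-force penalty minimisation."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(23)
    confs = (_jittered_group(two_hexapy, np.full(12, -75.0),
                             np.full(12, 145.0), 4, 3.0, rng)
             + _jittered_group(two_hexapy, np.full(12, -65.0),
                               np.full(12, -40.0), 3, 3.0, rng)
             + _jittered_group(two_hexapy, np.full(12, -139.0),
                               np.full(12, 135.0), 3, 3.0, rng))
    ens = Ensemble.from_conformers(confs)
    tree = cluster_ensemble(ens, superpose_range=(3, 10))

    # independent re-computation of the penalty per candidate count
    D = tree.distance_matrix
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    M = 10
    spreads, labelings = [], []
    for c in range(M - 1, 0, -1):
        lab = hierarchy.fcluster(Z, t=c, criterion="maxclust")
        labelings.append(lab)
        per = []
        for cl in np.unique(lab):
            mem = np.where(lab == cl)[0]
            if len(mem) < 2:
                continue
            vals = [D[i, j] for k, i in enumerate(mem) for j in mem[k + 1:]]
            per.append(np.mean(vals))
        spreads.append(np.mean(per) if per else 0.0)
    spreads = np.array(spreads)
    if spreads.max() > spreads.min():
        norm = (spreads - spreads.min()) / (spreads.max() - spreads.min()) \
            * (M - 2) + 1
    else:
        norm = np.ones_like(spreads)
    penalty = norm + np.arange(M - 1, 0, -1)
    counts = np.arange(M - 1, 0, -1)
    best = min(zip(penalty, counts))    # ties -> fewer clusters
    assert tree.n_clusters == best[1]
    np.testing.assert_allclose(tree.penalties, penalty)


def test_clustering_member_order_invariant(two_hexapy):
    rng = np.random.default_rng(29)
    confs = (_jittered_group(two_hexapy, np.full(12, -75.0),
                             np.full(12, 145.0), 5, 2.0, rng)
             + _jittered_group(two_hexapy, np.full(12, -65.0),
                               np.full(12, -40.0), 5, 2.0, rng))
    ens = Ensemble.from_conformers(confs)
    perm = rng.permutation(10)
    shuffled = ens.subset(perm)
    t1 = cluster_ensemble(ens, superpose_range=(3, 10))
    t2 = cluster_ensemble(shuffled, superpose_range=(3, 10))
    parts1 = {frozenset(np.where(t1.labels == c)[0])
              for c in np.unique(t1.labels)}
    parts2 = {frozenset(perm[np.where(t2.labels == c)[0]])
              for c in np.unique(t2.labels)}
    assert {frozenset(int(i) for i in p) for p in parts1} == \
           {frozenset(int(i) for i in p) for p in parts2}


def test_cluster_stats_degenerate_and_pair(two_hexapy, beta_conformer,
                                           ppii_conformer):
    # duplicated members -> RMSD-to-mean 0
    ens = Ensemble.from_conformers(
        [beta_conformer, beta_conformer, ppii_conformer, ppii_conformer])
    tree = cluster_ensemble(ens, superpose_range=(3, 10))
    stats = cluster_stats(tree, ens)
    for vals in stats["within"].values():
        assert np.allclose(vals, 0.0, atol=1e-9)
    # two-member cluster: RMSD-to-mean is half the pairwise RMSD
    pair = Ensemble.from_conformers([beta_conformer, ppii_conformer])
    d, _, _ = analysis._cluster_rmsd_to_mean(
        pair, np.array([0, 1]), (3, 10), None, analysis.BACKBONE_ATOMS)
    rmsd_full = pairwise_rmsd_matrix(pair, superpose_range=(3, 10))[0, 1]
    assert d[0] == pytest.approx(rmsd_full / 2, rel=1e-6)
    assert d[1] == pytest.approx(rmsd_full / 2, rel=1e-6)


def test_representative_belongs_to_cluster(coil_pool):
    sub = coil_pool.subset(range(20))
    tree = cluster_ensemble(sub, superpose_range=(3, 10))
    for cl, rep in tree.representatives.items():
        assert tree.labels[rep] == cl
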