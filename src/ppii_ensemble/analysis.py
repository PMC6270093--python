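"""Ramachandran-region populations, superposition, and RMSD clustering.

The polyproline-II content of an ensemble is quantified as the fraction of
members whose (phi, psi) falls inside a configurable PPII region of
Ramachandran space, reported per residue and as the mean over residues.
Conformational subfamilies are extracted by average-linkage agglomerative
clustering of the pairwise backbone RMSD matrix with a Kelley-style
penalty choosing the cut level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ensemble import Ensemble
from .peptide import Conformer

__all__ = [
    "RamaRegion",
    "DEFAULT_REGIONS",
    "rama_classify",
    "rama_classify_batch",
    "PpiiProfile",
    "ppii_profile",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "ClusterTree",
    "cluster_ensemble",
    "cluster_stats",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class RamaRegion:
    """A rectangular (phi, psi) region; intervals are closed-lower/open-upper.

    The domain edge +180 is treated as belonging to an interval that touches
    it on either side, so wrapped angles never fall through the seam.
    """

    name: str
    phi: tuple[float, float]
    psi: tuple[float, float]

    def _in(self, val, lo, hi):
        val = np.asarray(val)
        inside = (val >= lo) & (val < hi)
        if hi == 180.0 or lo == -180.0:
            inside = inside | (val == 180.0)
        return inside

    def contains(self, phi, psi):
        return self._in(phi, *self.phi) & self._in(psi, *self.psi)


#: Default region set.  The PPII strip sits around the canonical
#: (-75, +145) basin; beta is the more extended phi range; alpha-L mirrors
#: alpha-R.  Boundaries are package configuration, recorded in every report.
DEFAULT_REGIONS = (
    RamaRegion("PPII", (-110.0, -50.0), (110.0, 180.0)),
    RamaRegion("beta", (-180.0, -110.0), (90.0, 180.0)),
    RamaRegion("alphaR", (-160.0, -20.0), (-90.0, 30.0)),
    RamaRegion("alphaL", (20.0, 160.0), (-30.0, 90.0)),
)


def _check_regions(regions):
    grid = np.arange(-179.5, 180.5, 1.0)
    pg, sg = np.meshgrid(grid, grid)
    cover = np.zeros(pg.shape, dtype=int)
    for reg in regions:
        cover += reg.contains(pg, sg).astype(int)
    if (cover > 1).any():
        raise ValueError("region set has overlapping regions")


def rama_classify(phi: float, psi: float, regions=DEFAULT_REGIONS) -> str:
    """Name of the unique region containing (phi, psi), else ``"other"``."""
    _check_regions(regions)
    for reg in regions:
        if bool(reg.contains(phi, psi)):
            return reg.name
    return "other"


def rama_classify_batch(phi, psi, regions=DEFAULT_REGIONS,
                        validate: bool = False) -> np.ndarray:
    """Region index array (-1 for "other") for angle arrays of any shape."""
    if validate:
        _check_regions(regions)
    phi = np.asarray(phi)
    out = np.full(phi.shape, -1, dtype=int)
    for k, reg in enumerate(regions):
        mask = reg.contains(phi, psi) & (out == -1)
        out[mask] = k
    return out


@dataclass
class PpiiProfile:
    """Per-residue and overall PPII fractions of an ensemble."""

    per_residue: np.ndarray
    overall: float
    n_members: int
    regions: tuple = DEFAULT_REGIONS


def ppii_profile(ens: Ensemble, regions=DEFAULT_REGIONS) -> PpiiProfile:
    """Fraction of members classified PPII at every residue.

    The overall fraction is the mean of the per-residue fractions over all
    residues (prolines are counted by the same region test as everything
    else).
    """
    ppii_idx = next(
        (k for k, r in enumerate(regions) if r.name.upper() == "PPII"), None)
    if ppii_idx is None:
        raise ValueError("region set must contain a region named 'PPII'")
    codes = rama_classify_batch(ens.phi, ens.psi, regions, validate=True)
    frac = np.mean(codes == ppii_idx, axis=0)
    return PpiiProfile(frac, float(np.mean(frac)), len(ens), tuple(regions))


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def _selection_indices(ens_or_conf, residue_range=None,
                       atom_set=BACKBONE_ATOMS) -> np.ndarray:
    L = len(ens_or_conf.seq)
    lo, hi = residue_range if residue_range is not None else (1, L)
    idx = []
    for resid in range(lo, hi + 1):
        for name in atom_set:
            if ens_or_conf.has_atom(resid, name):
                idx.append(ens_or_conf.atom_index(resid, name))
            else:
                raise KeyError(
                    f"selection atom {name!r} missing in residue {resid}")
    return np.asarray(idx, dtype=int)


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation R, translation t mapping P onto Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = qc - R @ pc
    return R, t


def kabsch_superpose(a: Conformer | np.ndarray, b: Conformer | np.ndarray,
                     residue_range=None, atom_set=BACKBONE_ATOMS,
                     seq=None):
    """Least-squares superposition of conformer ``a`` onto ``b``.

    Returns ``(rmsd, (R, t))`` where ``x @ R.T + t`` maps coordinates of
    ``a`` into the frame of ``b``; the RMSD is evaluated over the selection
    (a residue range and backbone atom set).
    """
    if isinstance(a, Conformer):
        sel = _selection_indices(a, residue_range, atom_set)
        P, Q = a.coords[sel], b.coords[sel]
    else:
        P, Q = np.asarray(a), np.asarray(b)
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=-1))))
    return rmsd, (R, t)


def pairwise_rmsd_matrix(ens: Ensemble, superpose_range=None,
                         rmsd_range=None, atom_set=BACKBONE_ATOMS
                         ) -> np.ndarray:
    """All-pairs RMSD: fit on one selection, measure on another.

    Mirrors the usual ensemble-family protocol where a structured core is
    superposed while the RMSD is evaluated over the full chain.
    """
    sup = _selection_indices(ens, superpose_range, atom_set)
    calc = _selection_indices(ens, rmsd_range, atom_set)
    M = len(ens)
    out = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            R, t = _kabsch(ens.coords[i][sup], ens.coords[j][sup])
            moved = ens.coords[i][calc] @ R.T + t
            d = np.sqrt(np.mean(np.sum((moved - ens.coords[j][calc]) ** 2,
                                       axis=-1)))
            out[i, j] = out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Average-linkage clustering with a Kelley-penalty cut."""

    linkage: np.ndarray
    distance_matrix: np.ndarray
    labels: np.ndarray              # cluster id per member, 0-based
    n_clusters: int
    penalties: np.ndarray           # penalty per candidate cluster count
    candidate_counts: np.ndarray
    superpose_range: tuple | None
    rmsd_range: tuple | None
    atom_set: tuple = BACKBONE_ATOMS
    representatives: dict = field(default_factory=dict)


def _level_penalties(Z: np.ndarray, D: np.ndarray):
    """Kelley-style penalty for every candidate cluster count.

    For each cut level the average spread (mean intra-cluster pairwise
    distance, averaged over clusters with >= 2 members) is normalised across
    levels onto [1, M-1] and added to the cluster count.
    """
    M = D.shape[0]
    counts = np.arange(M - 1, 0, -1)
    spreads = np.empty(len(counts))
    labelings = []
    for k, c in enumerate(counts):
        lab = hierarchy.fcluster(Z, t=c, criterion="maxclust") - 1
        labelings.append(lab)
        vals = []
        for cl in np.unique(lab):
            members = np.where(lab == cl)[0]
            if len(members) < 2:
                continue
            sub = D[np.ix_(members, members)]
            iu = np.triu_indices(len(members), 1)
            vals.append(float(np.mean(sub[iu])))
        spreads[k] = np.mean(vals) if vals else 0.0
    smin, smax = spreads.min(), spreads.max()
    if smax > smin:
        norm = (spreads - smin) / (smax - smin) * (M - 2) + 1.0
    else:
        norm = np.ones_like(spreads)
    penalties = norm + counts
    return counts, penalties, labelings


def cluster_ensemble(ens: Ensemble, superpose_range=None, rmsd_range=None,
                     atom_set=BACKBONE_ATOMS,
                     distance_matrix: np.ndarray | None = None) -> ClusterTree:
    """Cluster an ensemble on pairwise backbone RMSD.

    Average-linkage agglomeration; the cut level minimises the Kelley
    penalty (ties resolved toward fewer clusters).  Singletons are
    permitted.
    """
    if len(ens) < 2:
        raise ValueError("clustering needs an ensemble of size >= 2")
    D = (pairwise_rmsd_matrix(ens, superpose_range, rmsd_range, atom_set)
         if distance_matrix is None else np.asarray(distance_matrix))
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    counts, penalties, labelings = _level_penalties(Z, D)
    order = np.lexsort((counts, penalties))   # min penalty, then fewer clusters
    best = order[0]
    labels = labelings[best]
    tree = ClusterTree(Z, D, labels, int(counts[best]), penalties, counts,
                       superpose_range, rmsd_range, tuple(atom_set))
    tree.representatives = _representatives(ens, tree)
    return tree


def _cluster_rmsd_to_mean(ens: Ensemble, members: np.ndarray,
                          superpose_range, rmsd_range, atom_set):
    """Superpose members onto the first, return per-member RMSD to the mean."""
    sup = _selection_indices(ens, superpose_range, atom_set)
    calc = _selection_indices(ens, rmsd_range, atom_set)
    ref = ens.coords[members[0]]
    stack = []
    for m in members:
        R, t = _kabsch(ens.coords[m][sup], ref[sup])
        stack.append(ens.coords[m] @ R.T + t)
    stack = np.stack(stack)
    mean = stack.mean(axis=0)
    d = np.sqrt(np.mean(np.sum((stack[:, calc] - mean[calc]) ** 2, axis=-1),
                        axis=-1))
    return d, stack, mean


def _representatives(ens: Ensemble, tree: ClusterTree) -> dict[int, int]:
    reps = {}
    for cl in np.unique(tree.labels):
        members = np.where(tree.labels == cl)[0]
        d, _, _ = _cluster_rmsd_to_mean(
            ens, members, tree.superpose_range, tree.rmsd_range, tree.atom_set)
        reps[int(cl)] = int(members[np.argmin(d)])
    return reps


def cluster_stats(tree: ClusterTree, ens: Ensemble) -> dict:
    """Within/between-cluster RMSD summary.

    ``within`` maps cluster id to the member RMSD-to-mean distribution;
    ``between`` is the representative-to-representative RMSD matrix.
    """
    within = {}
    for cl in np.unique(tree.labels):
        members = np.where(tree.labels == cl)[0]
        d, _, _ = _cluster_rmsd_to_mean(
            ens, members, tree.superpose_range, tree.rmsd_range, tree.atom_set)
        within[int(cl)] = d
    rep_idx = [tree.representatives[c] for c in sorted(tree.representatives)]
    reps = ens.subset(rep_idx)
    between = pairwise_rmsd_matrix(reps, tree.superpose_range,
                                   tree.rmsd_range, tree.atom_set)
    return {"within": within, "between": between,
            "representatives": dict(tree.representatives)}
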