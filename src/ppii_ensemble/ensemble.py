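"""Ordered collections of conformers sharing one sequence/topology.

An :class:`Ensemble` stores the coordinate stack ``(M, n_atoms, 3)`` plus the
shared atom metadata, so per-member objects are cheap views.  Backbone
dihedrals are computed lazily once and cached; most analyses (Ramachandran
classification, NOE averaging, hydrodynamics) run directly on the stack.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .peptide import (
    Conformer,
    SequenceSpec,
    _ensemble_dihedrals,
    get_plan,
)

__all__ = ["Ensemble"]


class Ensemble:
    """An ordered collection of conformers of one capped peptide."""

    def __init__(self, seq: SequenceSpec, coords: np.ndarray,
                 provenance: str = "sampled", seed: int | None = None):
        coords = np.asarray(coords, dtype=float)
        plan = get_plan(seq)
        if coords.ndim != 3 or coords.shape[1] != len(plan.names):
            raise ValueError(
                f"expected coordinates of shape (M, {len(plan.names)}, 3)")
        self.seq = seq
        self.coords = coords
        self.provenance = provenance
        self.seed = seed
        self._plan = plan
        self._dihedrals: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_conformers(cls, conformers: Sequence[Conformer],
                        provenance: str = "collected") -> "Ensemble":
        if not conformers:
            raise ValueError("cannot build an ensemble from zero conformers")
        seq = conformers[0].seq
        for c in conformers:
            if c.seq != seq:
                raise ValueError("all conformers must share one sequence")
        return cls(seq, np.stack([c.coords for c in conformers]),
                   provenance=provenance)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.coords.shape[0]

    def member(self, i: int) -> Conformer:
        return Conformer(self.seq, self.coords[i], provenance=self.provenance)

    def __iter__(self):
        for i in range(len(self)):
            yield self.member(i)

    def subset(self, indices) -> "Ensemble":
        sub = Ensemble(self.seq, self.coords[np.asarray(indices, dtype=int)],
                       provenance=f"{self.provenance}/subset", seed=self.seed)
        return sub

    # -- cached derived quantities ----------------------------------------
    @property
    def dihedrals(self) -> np.ndarray:
        """Backbone dihedrals, shape (M, L, 3) = (phi, psi, omega) in deg."""
        if self._dihedrals is None:
            self._dihedrals = _ensemble_dihedrals(self.seq, self.coords)
        return self._dihedrals

    @property
    def phi(self) -> np.ndarray:
        return self.dihedrals[:, :, 0]

    @property
    def psi(self) -> np.ndarray:
        return self.dihedrals[:, :, 1]

    def atom_index(self, resid: int, name: str) -> int:
        try:
            return self._plan.index[(resid, name)]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} in residue {resid} of {self.seq}") from None

    def has_atom(self, resid: int, name: str) -> bool:
        return (resid, name) in self._plan.index
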