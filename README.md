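# ppii-ensemble

Conformational-ensemble analysis of residual polyproline-II (PPII) structure
in short disordered peptides, built around the avian prion hexarepeat:
chicken PrP carries N-terminal tandem PHNPGY repeats whose high proline
content hints at transient PPII helix rather than pure random coil.  The
package models the capped dodecapeptide Ac-PHNPGYPHNPGY-NH₂ ("2-HexaPY",
two hexarepeats) and the control hexapeptide Ac-YPHNPG-NH₂, and implements
the full restraint-driven ensemble workflow used to quantify such residual
structure:

* **peptide model** — all-atom conformers built from backbone dihedrals
  (φ, ψ, ω) by internal-coordinate construction with standard geometry;
  molecular formulas and monoisotopic/average masses for capped sequences.
* **statistical-coil sampler** — a residue-class basin library (generic,
  Gly, Pro, pre-Pro) over the Ramachandran basins PPII/β/α_R/α_L; clash-free
  conformer pools; ground-truth mixtures with prescribed per-residue PPII
  fractions; synthetic observables (J-couplings, NOE restraints, coarse Hα
  secondary shifts, PG-SLED diffusion decays).
* **NMR observables** — the Karplus relation
  ³J(φ) = A cos²(φ−60°) + B cos(φ−60°) + C (Vuister–Bax coefficients
  A = 6.51, B = −1.76, C = 1.60 Hz) and its inversion; rigid-ensemble NOE
  intensities I = ⟨r⁻⁶⟩ with the sequential diagnostics
  R1 = I[αH(i)–HN(i+1)]/I[HN(i)–HN(i+1)] and
  R2 = I[αH(i)–HN(i+1)]/I[αH(i)–HN(i)]; secondary shifts δ−δ_isc against an
  8 M urea intrinsic-coil reference; amide Δδ/ΔT temperature gradients with
  the Andersen hydrogen-bond screen; Hα–Hδ/Hα–Hα proximity as the cis/trans
  X-Pro diagnostic.
* **hydrodynamics** — PG-SLED decay fitting I(G) = I₀·exp(−c·D·G²), the
  Stokes–Einstein conversion R_h = k_B T/(6πηD), and the per-conformer
  Kirkwood bead estimate 1/R_h = 1/(Na) + (1/N²)·Σ_{i≠j} 1/r_ij over heavy
  atoms (hydrated bead radius a = 2.9 Å).
* **ensemble selection** — stochastic-exchange (Metropolis) selection of a
  fixed-size sub-ensemble minimising a pseudo-energy over ensemble-averaged
  observables: flat-bottom quadratic NOE terms (8 Å strong / 10 Å weak at
  10 % weight), a χ² term on ⟨J⟩, and an optional χ² term on coarse Hα
  shifts; hydrodynamics is excluded from the objective so the R_h comparison
  afterwards is a genuine cross-validation.
* **structure analysis** — Ramachandran-region PPII profiles (per residue
  and overall), Kabsch superposition, average-linkage RMSD clustering with a
  Kelley-penalty cut, and within/between-cluster statistics.

## Worked example

```python
import numpy as np
import ppii_ensemble as ppe
from ppii_ensemble import sampler, nmr, hydro

seq = ppe.TWO_HEXAPY                       # Ac-PHNPGYPHNPGY-NH2
f = ppe.peptide_formula(ppe.HEXA_YG)       # control peptide Ac-YPHNPG-NH2
print(f.hill(), round(ppe.mass(f, "monoisotopic"), 2))
# C33H44N10O9 724.33

pool = sampler.generate_pool(seq, 2000, rng_seed=11)
prof = nmr.noe_ratio_profile(pool)
print(round(prof.mean_r1(), 2), round(prof.mean_r2(), 2))
# 1.49 1.32        <- R1 matches the ~1.4 statistical-coil prediction

rh, sd, _ = hydro.ensemble_rh(pool.subset(range(500)))
print(round(rh, 1), "+/-", round(sd, 1), "A")
# 7.3 +/- 0.3 A    <- plain Kirkwood sum; systematically below the
#                     shell-model scale (~11 A) for a chain this short
```

A single ideal β-strand gives R1 ≈ 57 at a central position — the classic
order-of-magnitude separation from the coil value that makes the ratio a
secondary-structure diagnostic.

An end-to-end synthetic run (pool → restraint selection → PPII profile →
clustering → R_h cross-validation) is one call:

```bash
ppii-ensemble demo --seed 3 -o run-demo
```

which writes `selected.pdb`, `ppii_profile.csv`, `clusters.csv`,
`violations.csv` and `report.json` under `run-demo/`, all reproducible from
the seed.  The other subcommands (`genpool`, `observables`, `select`,
`analyze`, `hydrodynamics`, `run`, `report`, `formula`) expose the stages
individually.

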