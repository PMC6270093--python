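# Methods

## The problem and the model

Short proline-rich peptides such as the avian prion hexarepeat
(PHNPGY)ₙ exchange rapidly between conformers, so every NMR observable is
an ensemble average.  The package represents the solution state of a capped
peptide as a finite ensemble of rigid all-atom conformers and asks two
questions: (i) what per-residue fraction of the ensemble occupies the
polyproline-II (PPII) region of Ramachandran space, and (ii) is an ensemble
selected to match averaged NMR restraints consistent with independent
hydrodynamic data?  Only the major, all-trans-proline species is modelled;
the minor cis isomers (about one part in five in solution for this family)
are recorded as metadata and excluded from sampling by default, matching
the usual situation in which only the major conformer yields assignable
NOEs.

## Conformer construction

Conformers are built by sequential natural-extension (NeRF) placement from
backbone dihedrals with a fixed standard-geometry set (Engh–Huber-like
bond lengths and angles).  Caps are explicit (acetyl, C-terminal amide).
Protons needed for NOE work are placed: amide HN, Hα (both Hα2/Hα3 for
Gly), and proline Hδ2/Hδ3.  Hα uses N–Cα–Hα = 107.5° with the Hα torsion
120° from the carbonyl about the N–Cα axis; these standard values reproduce
the textbook sequential distance table for an ideal β-strand
(dαN ≈ 2.2 Å, dNN ≈ 4.3 Å), which anchors the intensity-ratio diagnostics.
The proline ring is closed with fixed χ1 = −21°, χ2 = +10° (flat pucker;
Cδ–N closes at 1.47 Å).  Chirality is all-L, asserted in the tests against
an RDKit-embedded L-alanine as an independent oracle.  The builder is
vectorised over conformer batches, which is what makes pool-scale sampling
(10³–10⁴ conformers) cheap.

Steric sanity is a count of non-bonded heavy-atom pairs (three or more
bonds apart) closer than 2.0 Å; pool sampling rejects and redraws clashing
conformers.  The threshold is permissive by design — disordered-state
sampling should not be trimmed by a hard-sphere prior — and its main effect
is to remove genuinely impossible local geometry such as a helical residue
directly preceding a proline (O(i−1)–Pro Cδ contact).

## The statistical-coil library

Sampling uses wrapped-Gaussian Ramachandran basins per residue class:

| class   | PPII (−75,145) | β (−120,135) | α_R | α_L |
|---------|----------------|--------------|-----|-----|
| generic | 0.26           | 0.21         | 0.50 at (−65,−30) | 0.03 |
| Gly     | 0.115          | 0.115        | 0.72 at (−75,−25) | 0.05 |
| pre-Pro | 0.45           | 0.30         | 0.20 | 0.05 |
| Pro     | 0.55 (ψ 145)   | —            | 0.45 (ψ −30), φ fixed −65 ± 10 | — |

Class precedence is Pro > Gly > pre-Pro > generic.  The weights were
calibrated once, by grid search on 800–2000-conformer pools, against the
three literature coil diagnostics for peptides of this size — sequential
intensity ratios R1 ≈ 1.4 and R2 ≈ 2.3 and a coil hydrodynamic radius of
≈ 11.2 Å — and against nothing else; in particular they were never adjusted
against any PPII-recovery result.  The calibration pins R1 (1.4–1.5 across
seeds at n = 2000).  R2 and the Kirkwood radius cannot be pinned
simultaneously with R1 under this package's averaging conventions; see
"Known limitations".  The resulting picture — extended-biased prolines and
pre-prolines, helical-biased generic/Gly residues that supply the only
sequential HN–HN contacts (Gly→Tyr) — is consistent with what is actually
observed for this peptide family.

What the generator emulates: residue-class-specific basin occupancies,
PPII enrichment at and before prolines, all-trans peptide bonds, NOE
restraints derived from short ensemble-effective distances, J-couplings in
the extended 6–7.5 Hz band, and Gaussian-noise diffusion decays.  What it
does not emulate: nearest-neighbour coupling between residues (draws are
independent), side-chain rotamer populations (fixed default χ), cis-proline
species, chemical exchange, and spectrometer artifacts.  Tests passing on
this generator therefore certify the machinery — averaging conventions,
selection, classification, hydrodynamics — not the fidelity of any
particular coil model to a real peptide.

## Observables

NOE intensities are rigid-ensemble ⟨r⁻⁶⟩ averages with r⁻⁶ averaging over
degenerate protons (Gly Hα, Pro Hδ); no correlation-time or spin-diffusion
corrections.  J-couplings use the Vuister–Bax Karplus parameterisation
(A = 6.51, B = −1.76, C = 1.60 Hz) with linear ensemble averaging; the
inversion solves the quadratic in cos(φ−60°) and returns all angle
branches, so a coupling in the 6.0–7.5 Hz band always includes a branch in
(−90°, −70°) — the PPII-compatible solution.  Secondary shifts are
δ − δ_isc against an intrinsic statistical-coil reference (the 8 M urea
assignment); the packaged fixture carries the water-condition assignment
table.  Amide temperature gradients are least-squares slopes in ppb/K over
≥ 3 temperatures; the hydrogen-bond screen defaults to the flat
−4.6 ppb/K cut with a configurable linear (CSD-dependent) boundary.
Proline isomerism uses |ω| > 90° as trans together with the
Hα(i−1)–Hδ(Pro) < Hα(i−1)–Hα(Pro) distance signature.

## Hydrodynamics

The experimental route fits I(G) = I₀ exp(−c·D·G²) by nonlinear least
squares (fitting on the linear intensity scale keeps noisy near-zero tail
points from dominating, which a log-linear fit would not) and converts D to
R_h by Stokes–Einstein.  The instrument constant c (default 1.8×10⁷ for D
in m²/s and G in G/cm, ordinary PG-SLED timings) is shared between the
forward model and the fit, so radii are calibration-independent.  Water
viscosity defaults to 0.851 mPa·s at 300 K; a urea-solution viscosity must
be supplied by the user.  The structural route is the Kirkwood
approximation over heavy-atom beads of hydrated radius a = 2.9 Å,
1/R_h = 1/(Na) + (1/N²)Σ 1/r_ij, averaged arithmetically over members.
The two routes share no inputs, so comparing a selected ensemble's Kirkwood
radius with a diffusion-derived radius is a genuine cross-validation.

## Ensemble selection

The pseudo-energy is Σ w·max(0, r_eff − bound)² over NOEs
(r_eff = ⟨r⁻⁶⟩^(−1/6); 8 Å bound at weight 1.0 for strong, 10 Å at 0.1 for
weak), plus Σ(⟨J⟩ − J_target)²/σ_J², plus an optional χ² term on coarse Hα
secondary-shift predictions.  The shift predictor assigns each residue's
(φ, ψ) to the nearest canonical basin center — PPII (−75,145),
β (−120,135), α_R (−65,−35), α_L (60,40) — and maps PPII → −0.02 ppm,
β → +0.38, α_R/α_L → −0.38.  Nearest-center assignment (rather than
rectangular regions with an unclassified remainder) is deliberate: an
"other → 0 ppm" category is numerically indistinguishable from PPII's
−0.02 ppm, which would leave the PPII content of an ensemble invisible to
shift matching.  The term is off by default — a predictor this coarse can
distort selection when real shifts are available — and is enabled in the
synthetic-recovery pipeline, where targets and predictions share the same
forward model.

Optimisation is single-swap stochastic exchange under geometric cooling
(default 20 stages, T 1.0 → 10⁻³, 50·size·ln(pool) proposals), with
per-member term matrices precomputed so a proposal costs a handful of
vector operations.  Selection is deterministic given the seed; the best
score in the trace is non-increasing by construction.

## Ground-truth mixtures and what recovery can show

`make_ground_truth_ensemble` draws a PPII/non-PPII label per member and
residue from the target fraction, then rejection-samples dihedrals
conditioned on the label: PPII labels from the class's PPII basin truncated
to the PPII region, non-PPII labels from the non-PPII basins with strays
into the region rejected.  The empirical profile therefore matches the
target exactly up to binomial label noise, and the truth shares its
basin-conditional shapes with an unconditioned pool — a necessary condition
for recovery to be well-posed at all.

Even so, per-residue PPII recovery by mean-matching selection is not fully
identifiable, and the package does not pretend otherwise.  Two exact
degeneracies persist: the three-level shift predictor satisfies
PPII ≈ (β + α_R)/2, so mean shifts are blind to that exchange; and the J
term constrains only the linear mean of a continuous curve, so within-basin
φ tilts of selected members can reproduce any target mean without changing
basin fractions.  NOE upper bounds at 8/10 Å never bind for
sequential/medium-range pairs whose effective distances are 2–7 Å.  In the
synthetic benchmark (pool 5,000 → ensemble 100, truth 20 % PPII at
prolines, 12 % elsewhere) selected ensembles fit the data an order of
magnitude better than the truth ensemble itself fits its own noisy targets;
prolines — whose composition the shift term pins through the large
PPII/α_R contrast — recover to within ±0.05, while positions where the
degeneracies operate relax toward pool marginals (errors up to ≈ 0.35).
This is the well-documented ill-posedness of restraint-based ensemble
selection, reproduced here in miniature; the corresponding acceptance test
asserts the ±0.10 bound and fails, intentionally.

## Structure analysis

PPII fractions use rectangular Ramachandran regions
(closed-lower/open-upper, the +180° seam included):
PPII φ ∈ [−110,−50), ψ ∈ [110,180]; β φ ∈ [−180,−110), ψ ∈ [90,180];
α_R φ ∈ [−160,−20), ψ ∈ [−90,30); α_L mirrored.  Region sets are validated
for non-overlap on a 1° grid and recorded in every report; prolines are
counted by the same test as every other residue, and the overall fraction
is the unweighted mean over residues.  Clustering computes all-pairs
backbone RMSD (superposition on residues 3–10 by default, N/Cα/C/O;
RMSD measurable on a different range, e.g. the full chain), applies
average linkage, and cuts at the minimum of a Kelley-style penalty —
average intra-cluster spread normalised onto [1, M−1] plus the cluster
count, ties resolved toward fewer clusters, singletons permitted.  The
cluster representative is the member closest to the cluster's mean
coordinates after superposition.

## Numerical choices

Angles live in (−180°, 180]; the dihedral round trip through the builder is
exact to < 10⁻¹² degrees, asserted at 0.5°.  ω comparisons use circular
differences (the ±180° seam).  Degenerate inputs: zero-width basins sample
exactly at the center; constant diffusion series are rejected as
non-decaying; an empty restraint set is rejected before selection;
equal-score subsets resolve to the first found under the seeded schedule.
Clash counting excludes pairs fewer than three bonds apart via a
precomputed bond graph.  Pool generation retries in batches and reports the
most clash-involved residue window if a pathological library exhausts its
budget.  Problem sizes used in tests and the acceptance script — pools of
300–5,000, ensembles of 100, ground truths of 80–300 members — were chosen
as the desk scale at which every statistical statement asserted is already
stable across seeds; the paper-scale pool (50,000) is available by
configuration.

## Known limitations

* **Joint R1/R2 coil targets.**  Under rigid ⟨r⁻⁶⟩ averaging with standard
  geometry, R2/R1 = I_NN/I_αN(i,i) ≤ ≈ 0.85 at coil-like levels (the
  builder's dNN(i,i+1) minimum over ψ is 2.60 Å against an intraresidue
  dαN of ≈ 2.85 Å), whereas the literature pair (1.4, 2.3) requires 1.64.
  The two predictions evidently assume a different intensity convention;
  with R1 calibrated to 1.4, this package's coil R2 reports ≈ 1.3–1.4.
* **Kirkwood radius scale.**  The plain Kirkwood double sum over ~100
  overlapping heavy-atom beads is dominated by covalent-neighbour pairs:
  even a fully extended PPII 12-mer caps at ≈ 8.1 Å (and at ≈ 8.3 Å in the
  a → ∞ limit), so the shell-model coil value of ≈ 11.2 Å is out of reach
  for any basin library.  Relative compactness is preserved — a
  compactness-restrained selected ensemble always reports a strictly
  smaller mean R_h than its coil pool — so the cross-validation ordering
  remains meaningful while absolute radii from this estimator run low for
  chains this short.
* **Recovery identifiability** as analysed above: ensemble-mean matching of
  coarse shifts, ⟨J⟩ and loose NOE bounds determines proline PPII content
  well but leaves other positions under-determined toward pool marginals.
* No nearest-neighbour coil corrections, no cis-proline ensembles, no
  SHIFTX-class shift prediction, no shell-model hydrodynamics, no
  maximum-entropy reweighting — each is either a stated non-goal or a
  deliberate simplification recorded here.
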