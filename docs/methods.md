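# Methods

This note records the models, conventions, and numerical choices behind
`hbshare`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem and model

Two short hydrogen bonds (O···O ≈ 2.5 Å) tie the phenolic oxygen of the PYP
chromophore (O_pCA) to E46 and Y42 in the dark state. The package implements
the two complementary diagnostics used to type such bonds:

1. **Proton dynamics.** The proton-sharing coordinate
   ξ = d(O_donor···H) − d(H···O_acceptor) is evaluated per frame
   (minimum-image when a box is present). Its sampled density P(ξ) is
   estimated by a histogram whose edges are aligned so ξ = 0 is a bin edge,
   fitted with a normal density by nonlinear least squares, and converted to
   a free-energy profile by Boltzmann inversion,
   A(ξ) = −k_B T ln P(ξ), shifted so min A = 0. Inverting the *fit* gives an
   exactly quadratic single-well profile with its minimum at the fitted mean;
   inverting the raw histogram instead reports only the occupied bins (empty
   bins are gaps, never ±∞ entries). The inversion assumes Boltzmann-sampled,
   unbiased dynamics along ξ — no umbrella reweighting is provided.
2. **Density topology.** Bond critical points of ρ are found by Newton
   iteration on ∇ρ and characterized by (ρ, ∇²ρ) plus energy densities from
   the Kirzhnits gradient-corrected semiclassical kinetic-energy functional
   with the local virial theorem (G, V, H = G + V). Classification uses the
   strict-sign taxonomy (weak / moderate / strong as the signs of ∇²ρ and H);
   exact zeros are reported `indeterminate` rather than forced into a class,
   because the taxonomy is defined on strict signs. At a critical point
   |∇ρ|² = 0, so the H column of a published BCP table follows from its
   printed ρ and ∇²ρ alone; the gradient term |∇ρ|²/(72ρ) matters only off
   critical points and is defined as 0 where ρ = 0.

An O···H···O motif is scored **LBHB-like** when both of its BCPs are
strong/covalent (∇²ρ < 0 and H < 0 on both sides), **SIHB-like** when one BCP
is strong/covalent and the other moderate/closed-shell, and **ordinary**
otherwise.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 303.15 | K | simulation temperature of the study conditions |
| k_B | 1.987204259e-3 | kcal/mol/K | CODATA value, single constant |
| ξ histogram bin width | 0.01 | Å | resolves σ ≈ 0.14 Å with ~30 bins per σ-interval |
| hop hysteresis | 0.05 | Å | Schmitt-trigger half-gap; suppresses noise recrossings while passing genuine transfers (≈ σ/3); a tool parameter, not a literature value |
| clustering cutoff | 0.6 | Å | package default for local active-site RMSDs (the typical local-RMSD scale); always reported with results |
| RDF bin width / r_max | 0.1 / 10 | Å | conventional water-structure resolution |
| bohr ↔ Å | 0.52917721 | — | single source for every conversion |
| promolecular ζ (H, C, N, O, S) | 1.0, 1.6, 1.95, 2.25, 1.85 | bohr⁻¹ | effective single-exponential valence decay; each atom integrates to its electron count analytically |
| CP search | gtol 1e−9, ≤100 iters, step ≤0.3 bohr | a.u. | damped Newton; |∇ρ| tolerance defines what "critical point" means downstream |
| nucleus exclusion | 0.2 | bohr | exponential densities have a cusp at nuclei, not a smooth maximum; searches entering the sphere return no record |
| Hessian zero threshold | 1e−6 | a.u. | rank/signature determination |

## Synthetic data: what it emulates and what it does not

The original classical-MD and QM/MM trajectories and the DFT electron
density are not public, so the generators reproduce the *reported summary
statistics* as study conditions:

* `build_toy_active_site` embeds O_E46, H1, O_pCA, H2, O_Y42 so the six
  published neutron-structure distances hold to 1e−6 Å. Those distances fix
  all intra-pair angles; the only free degree of freedom is the
  O_E46–O_pCA–O_Y42 inter-branch angle, set to 115° (a typical geometry for a
  phenolate oxygen accepting two HBs). Canonical embedding: O_pCA at the
  origin, O_E46 on +x, both branches in the xy-plane, hydrogens on the +y
  side by trilateration.
* `generate_xi_trajectory` (preset `pyp-dark-qmmm`) draws the O–O distance as
  N(2.5, 0.05) Å and places the hydrogen on the O–O axis so ξ follows
  N(−0.06, 0.14) Å — i.i.d. per frame, or an Ornstein–Uhlenbeck process
  (relaxation time 50 fs, integrated at 0.5 fs and subsampled to the 10 fs
  frame spacing) when correlated, sub-picosecond recrossing dynamics are
  wanted. The 50 fs relaxation time and the 20,000-frame default are package
  choices, documented as such. Geometry is emitted as coordinates so all
  downstream stages run on frames, not on pre-made ξ values.
* `generate_distance_trajectory` (preset `pyp-dark-classical`) draws the
  three reported HB distance channels (1.79 ± 0.07, 1.71 ± 0.05,
  1.00 ± 0.04 Å) as independent Gaussians embedded along fixed axes; no
  covariances are published, so none are modeled.
* `generate_water_fixture` places water oxygens uniformly (ideal gas) with an
  optional exclusion sphere for the dry-pocket case.

Every generator is a pure function of (parameters, seed). Passing the
recovery tests therefore shows that the *analysis stages* are unbiased and
correctly normalized on data satisfying their assumptions — Gaussian ξ,
uncorrelated channels, ideal-gas water. It does not validate force fields,
sampling convergence, anharmonic ξ distributions, or correlated solvent
structure in real systems.

Similarly, the **promolecular density** (a sum of spherical single-exponential
atoms) is the topology test substrate, not a stand-in for a DFT density: it
yields the correct number and signatures of critical points on HB paths, but
its ∇²ρ at BCPs is systematically positive (promolecular densities carry no
covalent charge accumulation), so promolecular BCP *values* are never
compared against the published DFT-density table. That table ships as a
package data file and is treated purely as input to the energy-density and
classification stages.

## Numerical choices

* **Kirzhnits energy densities.** The H column of the packaged reference
  table is reproduced from its printed (ρ, ∇²ρ) to within 0.5% — the printed
  inputs are themselves rounded to three significant figures, which bounds
  the achievable agreement; tests assert rtol = 5e−3 accordingly.
* **Grid densities.** Cube files are interpolated with a tricubic B-spline
  (`scipy.ndimage` prefilter + `map_coordinates`). Gradient and Hessian are
  symmetric central differences of the interpolant with step = half the grid
  spacing: differencing at the knot scale averages out sub-knot spline
  curvature error (at 0.05 bohr spacing this brings the BCP Laplacian from
  ~5% to ~0.2% of the analytic value) and keeps the Hessian exactly
  symmetric. Only axis-aligned (orthogonal) grids are supported.
* **Kabsch superposition** accepts N ≥ 2 points; for degenerate (collinear)
  sets the minimizing rotation is not unique but the minimum RMSD is, and one
  proper-rotation minimizer (det +1) is returned.
* **Clustering** is greedy neighbor-count on the pairwise aligned-RMSD matrix
  (O(n²) in frames); all ties break toward the lowest frame index, making
  results deterministic. Alignment uses the same selection as the RMSD — a
  local RMSD implies a local superposition.
* **Running averages** are centered moving means with hard edges (no
  padding): the smoothing matches a plotted time window, not a causal filter.
  The window is converted to a sample count by rounding window/Δt; an even
  count yields points halfway between input samples, and the reported times
  are the window centers.
* **Selections**: `within R of …` is inclusive (d ≤ R), measured as minimum
  atom-atom distance against the sub-selection in a reference frame (default
  frame 0), minimum-image when a box is present.
* **Cube conventions**: files are normalized to atomic units on read
  regardless of dialect (negative voxel counts and/or a negative atom count
  mark the Å variant; a negative atom count also implies the extra data-set
  id line). Writing always uses the canonical bohr, positive-count form with
  13 decimal digits so read→write→read round-trips are lossless to 1e−12.
* **Degenerate inputs** raise typed errors (`FeasibilityError` with the
  violated triangle inequality, `DegenerateDistributionError` for constant
  samples, `ParameterError` for invalid parameters) rather than producing
  NaNs; the Gaussian-fit error carries moment-based fallback estimates.

## Pipeline sizes

The packaged pipeline defaults (20,000 ξ frames, 10,000 distance frames,
50–100 RDF frames, clustering capped at 200 frames by `max_frames`) were
chosen so a full run completes in seconds on one CPU while keeping all
recovery tolerances at 3 standard errors; clustering is quadratic in frames,
hence the cap, which is a reported parameter rather than a hidden truncation.

## Known limitations

* No binary trajectory formats (DCD/XTC/TRR), no triclinic boxes, no mmCIF.
* No HB existence criterion (distance/angle cutoff) is imposed; raw distances
  are reported and binarization is left to the user.
* Boltzmann inversion assumes equilibrium sampling; no WHAM/umbrella support.
* Nuclear quantum effects are not modeled: ξ statistics are classical over
  the sampled frames.
* QTAIM coverage is limited to bond critical points on HB paths: no ring/cage
  points, atomic-basin integration, or bond-path tracing.
* Promolecular BCP-to-atom distances differ from DFT-density values by
  construction; they are reported but never asserted against the reference
  table.
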