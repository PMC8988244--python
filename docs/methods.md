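# Methods

## The model

`dimerfe` computes the absolute binding free energy of a protein homodimer
by the staged-restraint ("geometric route") decomposition. The binding
constant is written as a ratio of bound- and free-state configurational
integrals and split into tractable factors by serially imposing harmonic
restraints in the bound state and releasing them in the free state:

1. **Conformational restraints** on RMSD coordinates — loop backbone of
   each chain (SOD1's zinc-binding loop 4, residues 49–83, and
   electrostatic loop 7, residues 121–142), β-barrel backbone
   (1–48, 84–120, 143–153), and interface heavy atoms
   (5, 7, 50–54, 114, 148, 150–153) — imposed in the order
   u_LA → u_LB → u_BA → u_BB → u_IA → u_IB.
2. **Orientational restraints** u_o on the Euler-like angles (Θ, Φ, Ψ) and
   **axial restraints** u_a on the spherical angles (θ, ϕ) of the
   inter-monomer reference frame.
3. **Separation** of the partners along r to a far anchor r*, with all
   restraints active, contributing the combined term
   ΔG_dist+a = −kT ln(c° S\* I\*).
4. **Release** of the restraints on the now-independent monomers; the
   orientational release is analytic, and the three conformational releases
   are counted once per monomer (coefficient 2).

The total is

ΔG_bind = −Σ(11 bound terms) + ΔG_dist+a + ΔG_o^free
          + 2ΔG_I,c^free + 2ΔG_B,c^free + 2ΔG_L,c^free,

with ΔG_bind = −kT ln(K_eq/c°) at the 1 mol/L standard state
(v° = 10²⁷/N_A ≈ 1660.5 Å³ per molecule).

The reference frame uses three mass-weighted anchor points per chain (the
barrel center of mass P1, a β-sheet surface point P2, a barrel "lid" point
P3) from fixed residue groups; (r, θ, ϕ) locate the partner's P1′ in this
frame and (Θ, Φ, Ψ) orient it. Dihedrals follow the IUPAC atan2 sign
convention on (−π, π]. An open choice is whether the anchor centers of mass
use backbone-only or all atoms of the listed residues; all atoms is the
default, with a geometric-centroid flag for toy inputs.

## Assumptions

* Restraints are harmonic; angular restraints use the minimum-image
  difference wrap(x − x₀), so centers near ±π stay continuous across the
  seam.
* The free state is isotropic in (Θ, Φ, Ψ), which makes the orientational
  release a separable three-fold quadrature with normalization 1/8π².
* Component free energies are treated as statistically independent when
  propagating errors (covariances between stages are not available), and
  per-term errors report max(statistical, systematic).
* The monomer conformational releases are assumed identical for the two
  chains (hence the factor 2), as for a homodimer.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| T | 300 | K | simulation/quadrature temperature |
| kB | 0.0019872041 | kcal/mol/K | energy scale kT ≈ 0.596 kcal/mol |
| c° | 1 | mol/L | standard state; sets v° ≈ 1660.5 Å³ |
| angular k | 1000 | kcal/mol/rad² | stiff enough that the bound angular costs are small and the analytic releases well-conditioned |
| loop RMSD restraint | center 3.5 (apo) / 1.2 (holo) Å, k = 10 | kcal/mol/Å² | biases toward the ordered loop basin |
| barrel RMSD restraint | center 0.6 Å, k = 20 | kcal/mol/Å² | tight: the barrel is well ordered |
| interface RMSD restraint | center 1.1 Å, k = 15 | kcal/mol/Å² | heavy-atom sidechain ordering |
| r* | 38.8 (37.8 for the disulfide-reduced variant) | Å | last point of the separation PMF; the angular surface grows as r*², giving the kT ln(r²/r_ref²) sensitivity (+0.27/−0.35 kcal/mol for ±1 nm) |

Per-variant angular centers and the sixteen-term ledgers for the five SOD1
variants (WT apo with intact disulfide, WT apo disulfide-reduced, A4V apo,
D101N apo, WT holo) ship as packaged JSON reference data, as do the
reparametrized metal-coordinating histidine charges (reference only; their
QM targets are external data).

## Numerical choices

* **Analytic terms.** ΔG_o^free and S\* are products of 1-D Gauss–Legendre
  quadratures (401 nodes per factor) over the full stated domains; the sinΘ
  Jacobian attaches to the polar factor and dihedral factors are evaluated
  through the minimum-image wrap, so the exact k = 0 normalization and the
  stiff k = 1000 limit are both handled. Doubling the node count moves
  results by < 1e-6 kcal/mol. The stiff-Gaussian closed form
  −kT ln[sinΘ₀ (2πkT)^{3/2} / (8π² √(kΘkΦkΨ))] serves as an independent
  cross-check.
* **MBAR.** Per-window dimensionless free energies solve the
  self-consistency equations, gauge-fixed to f₁ = 0, by log-sum-exp
  stabilized iteration (up to 150 sweeps, tol max|Δf| < 1e-8) with a BFGS
  polish of the convex MBAR objective when iteration alone has not
  converged. Windows whose sampled ranges do not chain into one connected
  overlap graph raise an error; neighbor overlaps below 10 shared samples
  warn.
* **PMF reconstruction.** MBAR weights are histogrammed on a grid whose
  default bin width is half the median umbrella spacing. Bins holding
  fewer than 5 samples are reported as undefined: lone samples in barely
  visited regions carry very large reweighting factors and the density
  estimate there is noise, which would otherwise corrupt the min-zero
  anchor. Offset conventions are explicit (min-zero or value-at-r*).
* **I\*.** Trapezoid rule of e^{−β(W−W(r*))} over the occupied support up
  to r\*; Boltzmann weighting makes contributions far above the bound well
  negligible, so no explicit "bound region" cutoff is needed. When windows
  end at r\*, the anchor is the outermost occupied bin center — half a bin
  short of r\*, where the separation surface is already flat.
* **Statistical errors.** Moving-block bootstrap (default 50 resamples for
  exponential averages, 15–30 for MBAR pipelines), block length from an
  initial-positive-sequence integrated-autocorrelation estimate; bootstrap
  MBAR solves warm-start from the full-data solution.
* **Systematic (convergence) errors.** An estimate is recomputed on growing
  fractions of each series with the initial half of each truncation
  discarded; the systematic error is the largest deviation from the final
  estimate and the reported error is max(statistical, systematic).
* **Charge fitting.** The loss w_U(U−U°)² + w_g Σ(g−g°)², with U and the
  metal-site gradients affine in the fittable charges, is a convex QP. It
  is solved by scipy's trust-region constrained minimizer (analytic
  gradient and Hessian, curvature-scaled); box-only problems are then
  refined by bounded-variable least squares, and problems with extra
  linear constraints by solving the KKT system of the near-active set,
  which resolves active bounds to machine precision. The gradient
  convention is ∇U at the metal position (force = −∇U).
* **Report rounding** is two decimals, half away from zero.

## The synthetic data generator

The estimators cannot be validated against the µs-scale MD that produced
the published per-term values, so the package ships a generator whose
ground truth is exact:

* 1-D analytic potentials shaped like the study system's PMFs: double
  wells with an ordered minimum near 4 Å, a disordered minimum near 8 Å
  and a barrier inside 5.2–7.0 Å for loop-RMSD coordinates; Morse-type
  bound wells flattening at large r for the separation coordinate;
  harmonic wells for angles.
* i.i.d. Boltzmann samples by inverse-CDF on a dense grid (4001 points) —
  the estimators, not a sampler, are under test, so autocorrelation is
  removed as a confounder; an optional Gaussian-copula AR(1) mode restores
  serial correlation to exercise the block bootstrap.
* toy dimer point geometries realizing prescribed (r, θ, ϕ, Θ, Φ, Ψ)
  exactly (placement angles are calibrated against the package's own
  dihedral convention, then verified by round-trip), expanded into one
  marker atom per frame residue so the group centroids land on the
  constructed points even though the frame residue groups overlap;
* random charge-fit problems whose constrained optimum is known by
  construction (targets computed from charges drawn inside the bounds).

The default end-to-end scenario treats every restrained degree of freedom
as an independent 1-D coordinate. That factorization is what makes the
ground truth exactly computable by quadrature, and it is also the
generator's main departure from real data: it cannot represent coupling
between coordinates, staged-ensemble shifts (imposing one restraint does
not perturb another coordinate's ensemble), replica-exchange kinetics, or
force-field error. Passing tests therefore demonstrate that the
estimators — FEP exponential averaging, MBAR/PMF reconstruction, I\*, and
the assembly algebra — are correct and statistically calibrated, not that
the physical inputs of a real system are converged. Scenario problem
sizes (3000 samples per perturbation term; 25 separation windows of 200
samples with k = 2 kcal/mol/Å²) are chosen so a full end-to-end recovery
runs on a desk machine in tens of seconds with total statistical error a
few tenths of kcal/mol.

## Known limitations

* The sixteen per-variant component terms are shipped as reference data;
  recomputing them requires the original µs-scale restrained MD and is out
  of scope. The assembly, dissection and comparison layers operate on any
  user-supplied ledger in the same TSV/JSON schema.
* The published total uncertainty for the wild-type apo variant (±2.89)
  is not reproduced exactly by independent quadrature over the printed
  per-term errors with the assembly coefficients; the propagation rule
  here is plain quadrature with the doubled free-term errors doubled, and
  the total it produces is of the same order (≈3.5).
* FEP exponential averaging inherits its usual poor-overlap variance;
  the bootstrap error reflects but does not remove it.
* The charge-fitting module implements the generic constrained loss; the
  published fitted charges depend on external QM targets and subsystem
  geometry and are included as reference data only.
* Grouping note: the orientational dissection row subtracts all five bound
  angular terms (Θ, Φ, Ψ and the axial θ, ϕ) from the analytic free-state
  orientational term; that is the combination whose values match the
  published dissection table.
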