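# dimerfe

Absolute protein–protein dimer binding free energies by the
staged-restraint (geometric-route) decomposition, applied to Cu,Zn
superoxide dismutase (SOD1) and its ALS-associated variants.

SOD1 is an obligate homodimer whose monomerization is an early step toward
the misfolding and aggregation seen in familial ALS. Computing its dimer
binding free energy directly from a separation simulation fails to
converge: the disordered zinc-binding and electrostatic loops (residues
48–83 and 121–143) and the monomers' orientational tumbling relax on
microsecond timescales. The geometric route tames this by writing the
binding constant as a product of tractable ratios. Harmonic restraints —
conformational (loop, β-barrel and interface RMSD per chain),
orientational (Euler angles Θ, Φ, Ψ) and axial (spherical angles θ, ϕ) —
are imposed serially in the bound state, the restrained partners are
separated along r to a far anchor r\*, and the restraints are released on
the free monomers, several of them analytically:

```
ΔG_bind = −Σ ΔG_bound(11 restraints) + ΔG_dist+a + ΔG_o^free
          + 2ΔG_I,c^free + 2ΔG_B,c^free + 2ΔG_L,c^free

ΔG_dist+a      = −kT ln(c° S* I*)
S*             = r*² ∫ sinθ e^{−βu_a} dθ dϕ          (axial surface, Å²)
I*             = ∫ e^{−β(W(r) − W(r*))} dr            (separation PMF, Å)
ΔG_o^free      = −kT ln[(1/8π²) ∫ sinΘ e^{−βu_o} dΘ dΦ dΨ]
```

with c° the 1 mol/L standard state (one molecule per ~1661 Å³).

The package provides, as library modules plus a thin `dimerfe` CLI:

* `dimerfe.geometry` — the inter-monomer reference frame (anchor points
  P1, P2, P3 per chain from fixed residue groups), the six relative
  coordinates, Kabsch-superposition RMSD, harmonic restraint energies with
  periodic wrapping, PDB I/O;
* `dimerfe.analytic` — ΔG_o^free, S\*, the standard-state volume, and the
  kT ln(r²/r_ref²) sensitivity of the result to the choice of r\*;
* `dimerfe.pmf` — MBAR over umbrella windows, PMF reconstruction, free
  energy perturbation averages, I\*, block-bootstrap statistical errors and
  trailing-fraction convergence errors (the larger of the two is reported);
* `dimerfe.ledger` — assembly of ΔG_bind from the sixteen named terms,
  dissections (per-region nets, exclusion pathways), ΔΔG between variants,
  and the heterodimer relation ΔG_het = 2ΔG_WT-mut − ΔG_WT-WT − ΔG_mut-mut,
  with reference ledgers for five SOD1 variants packaged as data;
* `dimerfe.charges` — the constrained metal-site partial-charge fit
  (energy/gradient targets, box bounds and floor constraints, convex QP);
* `dimerfe.synthetic` — generators with exact quadrature ground truth:
  double-well loop potentials, Morse separation wells, Boltzmann samplers,
  toy dimer geometries, charge-fit problems, and an end-to-end scenario.

## Worked example

Assemble the wild-type apo (intact disulfide) ledger and dissect it:

```sh
$ python -c "from dimerfe.ledger import reference_ledger, save_ledger; \
             save_ledger(reference_ledger('WT_EE_SS'), 'wt_ee_ss.tsv')"
$ dimerfe assemble --ledger wt_ee_ss.tsv
{
 "loop_net": {"value": -0.07, "error": 3.3824},
 "barrel_net": {"value": 3.85, "error": 0.2112},
 "interface_net": {"value": 11.17, "error": 0.2975},
 "orientational_net": {"value": 4.86, "error": 0.1353},
 ...
 "dG_bind": {"value": -3.45, "error": 3.4998},
 "dG_bind_noL": {"value": -3.38, "error": 0.8986},
 ...
}
```

`dG_bind = −3.45 kcal/mol` is the assembled dimer binding free energy: the
wild-type apoprotein dimer is marginally stable. The `loop_net` of −0.07
says ordering the disordered loops costs essentially the same in monomer
and dimer for this variant, while `interface_net` = 11.17 kcal/mol shows
that ordering the interface sidechains is the largest conformational
penalty opposing binding. Deleting the loop terms entirely
(`dG_bind_noL` = −3.38) barely changes the total — the loop contribution,
not the rest of the cycle, is what distinguishes variants that modify
loop chemistry. The error field propagates the per-term uncertainties in
quadrature (doubled free-monomer terms doubled).

The analytic orientational release for the same variant's restraint set
(k = 1000 kcal/mol/rad², centers 1.37/1.80/−2.38 rad, 300 K):

```sh
$ dimerfe analytic dgofree --centers 1.37 1.80 -2.38
{
 "dG_o_free_kcal_mol": 7.613085877547077,
 "quadrature_refinement_delta": 3.3e-11
}
```

— a universal ~7.6 kcal/mol cost of restraining a free monomer's
orientation, identical across variants to within rounding.

Synthetic end-to-end recovery (everything from samples, compared to exact
quadrature ground truth):

```python
from dimerfe.ledger import assemble
from dimerfe.synthetic import make_scenario, estimate_scenario_ledger

scenario = make_scenario(seed=11)
truth = assemble(scenario.true_ledger())          # -> 0.6585 kcal/mol
estimate = assemble(estimate_scenario_ledger(scenario))
print(estimate.value, estimate.error)             # -> 0.6427 0.3194
```

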