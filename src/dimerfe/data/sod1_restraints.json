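{
  "_comment": "Per-variant restraint parameters. Angular centers in radians, all angular spring constants 1000 kcal/mol/rad2; r_star is the last point of each variant's separation PMF in Angstrom. Conformational restraints: center in Angstrom, k in kcal/mol/A2, 1-based inclusive residue ranges, atoms 'backbone' (N, CA, C) or 'heavy'.",
  "angular": {
    "WT_EE_SS":    {"Theta0": 1.37, "Phi0": 1.80, "Psi0": -2.38, "theta0": 1.31, "phi0": 1.76, "k": 1000.0, "r_star": 38.8},
    "WT_EE_SH":    {"Theta0": 1.39, "Phi0": 1.65, "Psi0": -2.58, "theta0": 1.36, "phi0": 1.71, "k": 1000.0, "r_star": 37.8},
    "A4V_EE_SS":   {"Theta0": 1.32, "Phi0": 1.77, "Psi0": -2.43, "theta0": 1.31, "phi0": 1.78, "k": 1000.0, "r_star": 38.8},
    "D101N_EE_SS": {"Theta0": 1.32, "Phi0": 1.77, "Psi0": -2.40, "theta0": 1.30, "phi0": 1.79, "k": 1000.0, "r_star": 38.8},
    "WT_CuZn_SS":  {"Theta0": 1.35, "Phi0": 1.78, "Psi0": -2.45, "theta0": 1.35, "phi0": 1.77, "k": 1000.0, "r_star": 38.8}
  },
  "conformational": {
    "u_LA_c": {"coordinate": "chain A loop backbone RMSD", "center": 3.5, "center_holo": 1.2, "k": 10.0,
               "residues": [[49, 83], [121, 142]], "atoms": "backbone", "chain": "A"},
    "u_LB_c": {"coordinate": "chain B loop backbone RMSD", "center": 3.5, "center_holo": 1.2, "k": 10.0,
               "residues": [[49, 83], [121, 142]], "atoms": "backbone", "chain": "B"},
    "u_BA_c": {"coordinate": "chain A barrel backbone RMSD", "center": 0.6, "k": 20.0,
               "residues": [[1, 48], [84, 120], [143, 153]], "atoms": "backbone", "chain": "A"},
    "u_BB_c": {"coordinate": "chain B barrel backbone RMSD", "center": 0.6, "k": 20.0,
               "residues": [[1, 48], [84, 120], [143, 153]], "atoms": "backbone", "chain": "B"},
    "u_IA_c": {"coordinate": "chain A interface sidechain RMSD", "center": 1.1, "k": 15.0,
               "residues": [[5, 5], [7, 7], [50, 54], [114, 114], [148, 148], [150, 153]], "atoms": "heavy", "chain": "A"},
    "u_IB_c": {"coordinate": "chain B interface sidechain RMSD", "center": 1.1, "k": 15.0,
               "residues": [[5, 5], [7, 7], [50, 54], [114, 114], [148, 148], [150, 153]], "atoms": "heavy", "chain": "B"}
  }
}
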