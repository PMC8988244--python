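{
  "_comment": "Per-variant free-energy ledgers for the five SOD1 variants: each of the 16 staged-restraint terms as [value, error] in kcal/mol, plus the study's own assembled total (dG_bind) as printed.",
  "WT_EE_SS": {
    "terms": {
      "dG_LA_c_bound": [4.08, 1.90],
      "dG_LB_c_bound": [3.79, 0.32],
      "dG_BA_c_bound": [1.12, 0.11],
      "dG_BB_c_bound": [0.43, 0.01],
      "dG_IA_c_bound": [0.37, 0.01],
      "dG_IB_c_bound": [0.80, 0.10],
      "dG_Theta_o_bound": [0.45, 0.01],
      "dG_Phi_o_bound": [0.91, 0.06],
      "dG_Psi_o_bound": [0.82, 0.12],
      "dG_theta_a_bound": [0.33, 0.01],
      "dG_phi_a_bound": [0.25, 0.01],
      "dG_dist_a_restr": [-23.26, 0.81],
      "dG_o_free": [7.62, 0.0],
      "dG_I_c_free": [6.17, 0.14],
      "dG_B_c_free": [2.70, 0.09],
      "dG_L_c_free": [3.90, 1.39]
    },
    "dG_bind": [-3.45, 2.89]
  },
  "WT_EE_SH": {
    "terms": {
      "dG_LA_c_bound": [1.73, 0.51],
      "dG_LB_c_bound": [2.63, 0.29],
      "dG_BA_c_bound": [0.53, 0.05],
      "dG_BB_c_bound": [1.32, 0.06],
      "dG_IA_c_bound": [1.65, 0.04],
      "dG_IB_c_bound": [0.58, 0.03],
      "dG_Theta_o_bound": [0.33, 0.02],
      "dG_Phi_o_bound": [0.67, 0.03],
      "dG_Psi_o_bound": [0.45, 0.01],
      "dG_theta_a_bound": [0.68, 0.02],
      "dG_phi_a_bound": [0.34, 0.07],
      "dG_dist_a_restr": [-18.81, 0.63],
      "dG_o_free": [7.62, 0.0],
      "dG_I_c_free": [4.31, 0.04],
      "dG_B_c_free": [2.73, 0.05],
      "dG_L_c_free": [4.55, 0.24]
    },
    "dG_bind": [1.04, 0.94]
  },
  "A4V_EE_SS": {
    "terms": {
      "dG_LA_c_bound": [4.74, 0.94],
      "dG_LB_c_bound": [2.48, 0.25],
      "dG_BA_c_bound": [1.36, 0.02],
      "dG_BB_c_bound": [2.17, 0.02],
      "dG_IA_c_bound": [0.47, 0.02],
      "dG_IB_c_bound": [0.21, 0.01],
      "dG_Theta_o_bound": [0.30, 0.01],
      "dG_Phi_o_bound": [0.42, 0.05],
      "dG_Psi_o_bound": [0.61, 0.02],
      "dG_theta_a_bound": [0.29, 0.01],
      "dG_phi_a_bound": [0.37, 0.03],
      "dG_dist_a_restr": [-18.97, 0.90],
      "dG_o_free": [7.63, 0.0],
      "dG_I_c_free": [4.41, 0.07],
      "dG_B_c_free": [4.76, 0.27],
      "dG_L_c_free": [4.34, 0.66]
    },
    "dG_bind": [2.26, 1.67]
  },
  "D101N_EE_SS": {
    "terms": {
      "dG_LA_c_bound": [2.73, 0.67],
      "dG_LB_c_bound": [4.40, 0.88],
      "dG_BA_c_bound": [0.50, 0.02],
      "dG_BB_c_bound": [1.90, 0.03],
      "dG_IA_c_bound": [0.86, 0.05],
      "dG_IB_c_bound": [0.64, 0.19],
      "dG_Theta_o_bound": [0.66, 0.11],
      "dG_Phi_o_bound": [0.35, 0.01],
      "dG_Psi_o_bound": [0.51, 0.01],
      "dG_theta_a_bound": [0.37, 0.04],
      "dG_phi_a_bound": [0.75, 0.13],
      "dG_dist_a_restr": [-22.69, 0.49],
      "dG_o_free": [7.63, 0.0],
      "dG_I_c_free": [5.96, 0.41],
      "dG_B_c_free": [0.67, 0.02],
      "dG_L_c_free": [4.35, 0.27]
    },
    "dG_bind": [-6.74, 1.42]
  },
  "WT_CuZn_SS": {
    "terms": {
      "dG_LA_c_bound": [0.13, 0.01],
      "dG_LB_c_bound": [0.21, 0.03],
      "dG_BA_c_bound": [0.73, 0.01],
      "dG_BB_c_bound": [0.27, 0.03],
      "dG_IA_c_bound": [0.49, 0.03],
      "dG_IB_c_bound": [0.41, 0.04],
      "dG_Theta_o_bound": [0.27, 0.01],
      "dG_Phi_o_bound": [0.36, 0.02],
      "dG_Psi_o_bound": [0.44, 0.02],
      "dG_theta_a_bound": [0.26, 0.01],
      "dG_phi_a_bound": [0.67, 0.05],
      "dG_dist_a_restr": [-22.29, 1.58],
      "dG_o_free": [7.62, 0.0],
      "dG_I_c_free": [2.85, 0.07],
      "dG_B_c_free": [0.50, 0.05],
      "dG_L_c_free": [3.62, 1.32]
    },
    "dG_bind": [-4.97, 2.46]
  }
}
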