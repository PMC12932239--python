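{
  "name": "I-125 model 6711",
  "description": "Consensus-style TG-43 1D dosimetry parameters for the model 6711 iodine-125 seed: dose-rate constant, radial dose function g(r) and 1D anisotropy factor phi_an(r) tabulated against radial distance in cm. All values are overridable at load time.",
  "dose_rate_constant_cGy_per_hU": 0.965,
  "half_life_days": 59.4,
  "u_per_mci": 1.27,
  "radial_dose_function": {
    "r_cm":  [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
    "g":     [1.055, 1.000, 0.925, 0.842, 0.764, 0.693, 0.625, 0.558, 0.496, 0.439, 0.349, 0.273, 0.211, 0.163, 0.125]
  },
  "anisotropy_factor": {
    "r_cm":  [0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0],
    "phi_an": [0.973, 0.944, 0.941, 0.942, 0.943, 0.944, 0.947, 0.949]
  }
}
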