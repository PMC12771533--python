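{
  "version": "1.0",
  "description": "Bundled constitutive-law coefficients for TiO2-doped agarose hydrogels with standard errors, units and characterised domains.",
  "absorption": {
    "tag": "lorentzian_absorption",
    "model": "mu_a = (a*C_agarose + b) * c / (c^2 + (lambda_nm - 500)^2)",
    "a": 67.731, "a_se": 0.426, "a_units": "nm cm^-1 (% w/w)^-1",
    "b": 0.099, "b_se": 0.588, "b_units": "nm cm^-1",
    "c": 207.0, "c_se": 5.0, "c_units": "nm",
    "lambda_domain_nm": [490, 835],
    "c_agarose_domain_pct": [0.5, 2.0]
  },
  "scattering": {
    "tag": "mie_power_law_scattering",
    "model": "mu_s_prime = C_tio2 * x * (lambda_nm/1000)^(-y)",
    "x": 9.629, "x_se": 0.365, "x_units": "cm^-1 mL mg^-1",
    "y": 0.775, "y_se": 0.057, "y_units": "dimensionless",
    "a_rm": 0.0, "a_rm_units": "dimensionless (Rayleigh-to-Mie ratio)",
    "lambda_domain_nm": [590, 815],
    "c_tio2_domain_mg_ml": [0.25, 1.0]
  },
  "attenuation": {
    "tag": "agarose_attenuation_power_law",
    "model": "alpha = (a2*C_agarose^a3 + a1) * f_mhz^(b2*C_agarose + b1)",
    "a1": 0.0072, "a1_se": 0.0010, "a1_units": "dB cm^-1 MHz^-b",
    "a2": 0.0026, "a2_se": 0.0005, "a2_units": "dB cm^-1 MHz^-b (% w/w)^-a3",
    "a3": 2.636, "a3_se": 0.145, "a3_units": "dimensionless",
    "b1": 1.897, "b1_se": 0.039, "b1_units": "dimensionless",
    "b2": -0.132, "b2_se": 0.019, "b2_units": "(% w/w)^-1",
    "f_domain_mhz": [15, 35],
    "c_agarose_domain_pct": [0.75, 4.0]
  },
  "linear_laws": {
    "density": {
      "tag": "density_vs_agarose",
      "anchors": [[0.5, 1000.0], [3.0, 1018.0]],
      "units": "kg m^-3", "regressor": "c_agarose",
      "note": "reconstructed from the published range endpoints, not a released fit"
    },
    "sound_speed": {
      "tag": "sound_speed_vs_agarose",
      "anchors": [[0.5, 1482.0], [3.0, 1493.0]],
      "units": "m s^-1", "regressor": "c_agarose",
      "note": "reconstructed from the published range endpoints, not a released fit"
    },
    "heat_capacity": {
      "tag": "heat_capacity_vs_tio2",
      "anchors": [[0.0, 4100.0], [1.0, 3870.0]],
      "units": "J K^-1 kg^-1", "regressor": "c_tio2",
      "note": "reconstructed from the published range endpoints, not a released fit"
    }
  },
  "tio2_dispersion": {
    "tag": "tio2_single_pole_dispersion",
    "model": "n^2 = A + B / (lambda_um^2 - C)",
    "A": 5.913, "B": 0.2441, "C": 0.0803
  },
  "beta_gel_interval_per_K": [0.000207, 0.000231]
}
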