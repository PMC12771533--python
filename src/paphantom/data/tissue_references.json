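{
  "version": "1.0",
  "description": "Reference property intervals: healthy intervertebral-disc optical envelopes, porcine annulus fibrosus measurements and compiled soft-tissue mechanics. Intervals are closed; point values have lo == hi.",
  "tissues": {
    "ivd": {
      "mu_a": {"lo": 0.1, "hi": 0.6, "units": "cm^-1", "source": "compiled literature envelope, visible band, blood-stained outliers excluded"},
      "mu_s_prime": {"lo": 5.0, "hi": 20.0, "units": "cm^-1", "source": "compiled literature envelope, visible band"}
    },
    "water": {
      "cp": {"lo": 4180.0, "hi": 4180.0, "units": "J K^-1 kg^-1", "source": "standard reference value"},
      "rho": {"lo": 998.0, "hi": 998.0, "units": "kg m^-3", "source": "standard reference value"},
      "cs": {"lo": 1482.0, "hi": 1482.0, "units": "m s^-1", "source": "standard reference value, 20 C"},
      "Z": {"lo": 1.48, "hi": 1.48, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 0.85, "hi": 0.85, "units": "dB cm^-1 at 20 MHz", "source": "standard reference value"}
    },
    "brain": {
      "cp": {"lo": 3450.0, "hi": 3750.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 1030.0, "hi": 1041.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1525.0, "hi": 1573.0, "units": "m s^-1", "source": "compiled literature values"},
      "Z": {"lo": 1.57, "hi": 1.64, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 0.2, "hi": 4.5, "units": "dB cm^-1 at 1-5 MHz", "source": "compiled literature values"}
    },
    "liver": {
      "cp": {"lo": 3600.0, "hi": 3600.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 1050.0, "hi": 1070.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1525.0, "hi": 1639.0, "units": "m s^-1", "source": "compiled literature values"},
      "Z": {"lo": 1.60, "hi": 1.75, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 0.5, "hi": 0.7, "units": "dB cm^-1 at 1-10 MHz", "source": "compiled literature values"}
    },
    "breast": {
      "cp": {"lo": 2960.0, "hi": 2960.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 990.0, "hi": 1060.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1430.0, "hi": 1570.0, "units": "m s^-1", "source": "compiled literature values"},
      "Z": {"lo": 1.42, "hi": 1.66, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 0.5, "hi": 12.6, "units": "dB cm^-1 at 1.76-7 MHz", "source": "compiled literature values"}
    },
    "prostate": {
      "cp": {"lo": 3740.0, "hi": 3780.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 1045.0, "hi": 1045.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1614.0, "hi": 1614.0, "units": "m s^-1", "source": "compiled literature values"},
      "Z": {"lo": 1.69, "hi": 1.69, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 0.2, "hi": 0.2, "units": "dB cm^-1 at 1-10 MHz", "source": "compiled literature values"}
    },
    "tendon": {
      "cp": {"lo": 3360.0, "hi": 3360.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 1110.0, "hi": 1220.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1595.0, "hi": 1667.0, "units": "m s^-1", "source": "compiled literature values, 1631 +/- 36"},
      "Z": {"lo": 1.77, "hi": 2.03, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 3.7, "hi": 19.3, "units": "dB cm^-1 at 1-5 MHz", "source": "compiled literature values"}
    },
    "skin": {
      "cp": {"lo": 3150.0, "hi": 3710.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 1093.0, "hi": 1190.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1503.0, "hi": 1630.0, "units": "m s^-1", "source": "compiled literature values"},
      "Z": {"lo": 1.64, "hi": 1.94, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 2.3, "hi": 11.4, "units": "dB cm^-1 at 1-5 MHz", "source": "compiled literature values"}
    },
    "cartilage": {
      "cp": {"lo": 3500.0, "hi": 3600.0, "units": "J K^-1 kg^-1", "source": "compiled literature values"},
      "rho": {"lo": 1100.0, "hi": 1100.0, "units": "kg m^-3", "source": "compiled literature values"},
      "cs": {"lo": 1627.0, "hi": 1650.0, "units": "m s^-1", "source": "compiled literature values"},
      "Z": {"lo": 1.79, "hi": 1.82, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 5.0, "hi": 19.0, "units": "dB cm^-1 at 1-5 MHz", "source": "compiled literature values"}
    },
    "annulus_fibrosus": {
      "cp": {"lo": 3390.0, "hi": 3390.0, "units": "J K^-1 kg^-1", "source": "porcine annulus fibrosus calorimetry, 3.39 +/- 0.26 J K^-1 g^-1"},
      "rho": {"lo": 1047.0, "hi": 1047.0, "units": "kg m^-3", "source": "porcine annulus fibrosus pycnometry, 1047 +/- 10"},
      "cs": {"lo": 1489.0, "hi": 1652.0, "units": "m s^-1", "source": "derived from published impedance measurements"},
      "Z": {"lo": 1.557, "hi": 1.710, "units": "MRayl", "source": "published impedance measurements"}
    },
    "nucleus_pulposus": {
      "cp": {"lo": 4000.0, "hi": 4100.0, "units": "J K^-1 kg^-1", "source": "water-fraction estimate"},
      "rho": {"lo": 923.0, "hi": 1238.0, "units": "kg m^-3", "source": "derived from published sound-speed and impedance measurements"},
      "cs": {"lo": 1408.0, "hi": 1661.0, "units": "m s^-1", "source": "published porcine measurements, 25 C"},
      "Z": {"lo": 1.533, "hi": 1.743, "units": "MRayl", "source": "published impedance measurements"}
    },
    "tmm": {
      "cp": {"lo": 3870.0, "hi": 4100.0, "units": "J K^-1 kg^-1", "source": "phantom characterisation"},
      "rho": {"lo": 1000.0, "hi": 1018.0, "units": "kg m^-3", "source": "phantom characterisation"},
      "cs": {"lo": 1482.0, "hi": 1493.0, "units": "m s^-1", "source": "phantom characterisation, 19.9 C"},
      "Z": {"lo": 1.48, "hi": 1.52, "units": "MRayl", "source": "rho*cs"},
      "alpha": {"lo": 1.8, "hi": 4.4, "units": "dB cm^-1 at 20 MHz", "source": "phantom characterisation"}
    }
  },
  "gruneisen": {
    "nucleus_pulposus": {"temperature_c": 25, "cp_J_K_g": [4.0, 4.1], "cs_m_s": [1408, 1661], "beta_per_K": [0.000258, 0.000258], "Gamma": [0.125, 0.178], "source": "corner-combination estimate"},
    "annulus_fibrosus": {"temperature_c": 20, "cp_J_K_g": [3.13, 3.65], "cs_m_s": [1489, 1652], "beta_per_K": [0.0002, 0.00038], "Gamma": [0.121, 0.331], "source": "corner-combination estimate"},
    "tmm_20C": {"temperature_c": 20, "cp_J_K_g": [3.87, 4.1], "cs_m_s": [1482, 1493], "beta_per_K": [0.000207, 0.000231], "Gamma": [0.111, 0.133], "source": "corner-combination estimate"},
    "tmm_37C": {"temperature_c": 37, "Gamma": [0.178, 0.213], "source": "20 C estimate scaled by the literature factor 1.6 for agar hydrogels"}
  }
}
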