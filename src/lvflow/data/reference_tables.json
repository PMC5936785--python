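{
  "description": "Published constant-inflow and porous-layer outcome tables for the five human left-ventricle models (A-E; E is the control anatomy carrying papillary muscles only). Units: areas m^2, d m, alpha degrees, pressure drops kPa, WSS Pa, vortex surfaces m^2.",
  "table1": {
    "hearts": ["A", "B", "C", "D", "E"],
    "area_inlet_m2": [6e-4, 10.2e-4, 5.7e-4, 9.4e-4, 13.9e-4],
    "area_outlet_m2": [2.5e-4, 2.4e-4, 3e-4, 1.8e-4, 4.9e-4],
    "alpha_deg": [49.0, 72.2, 58.8, 43.3, 73.7],
    "d_m": [2.1e-2, 1.9e-2, 2.3e-2, 2.3e-2, 2.3e-2],
    "trabeculae_pct": [21.4, 26.6, 19.6, 21.3, 10.9],
    "reynolds_inlet": [6004, 4605, 4477, 5764, 7009],
    "dp_kpa": {
      "smoothed": [1.3, 3.8, 0.7, 2.2, 2.3],
      "smoothed_sd": [0.1, 0.04, 0.06, 0.1, null],
      "detailed": [1.5, 4.1, 0.8, 4.9, 2.5],
      "detailed_sd": [0.1, 0.1, 0.05, 0.2, 0.1]
    },
    "dp_diff_kpa": [0.2, 0.3, 0.1, 2.7, 0.2],
    "wss_mode_pa": {
      "smoothed": [0.35, 0.06, 0.75, 0.45, 0.15],
      "detailed": [0.05, 0.05, 0.05, 0.05, 0.25]
    },
    "wss_median_pa": {
      "smoothed": [0.51, 1.02, 1.23, 0.63, 0.84],
      "detailed": [0.39, 0.34, 0.67, 0.66, 0.52]
    },
    "vortex_surface_m2": {
      "smoothed": [29.1e-3, 33.8e-3, 20.4e-3, 45e-3, 29.4e-3],
      "detailed": [35.6e-3, 60.4e-3, 37.7e-3, 48.4e-3, 35.3e-3]
    }
  },
  "table2": {
    "hearts": ["A", "B", "C", "D"],
    "porous_layer": {"thickness_m": 1.2e-2, "sigma_kg_m2": 20},
    "dp_kpa": [1.5, 3.9, 0.78, 2.6],
    "dp_sd_kpa": [0.04, 0.4, 0.04, 0.3],
    "wss_mode_pa": [0.003, 0.47, 0.23, 0.25],
    "wss_median_pa": [0.36, 0.32, 0.51, 0.55],
    "vortex_surface_m2": [36.8e-3, 61.3e-3, 40e-3, 54.6e-3]
  },
  "table3": {
    "heart": "D",
    "instants": [1, 2, 3, 4, 5, 6],
    "vortex_surface_m2": {
      "smoothed": [9.4e-3, 16.7e-3, 17.4e-3, 25.5e-3, 22.5e-3, 23.7e-3],
      "detailed": [14.9e-3, 18.1e-3, 24.4e-3, 29.2e-3, 25.9e-3, 26.6e-3]
    }
  },
  "table4": {
    "heart": "A",
    "thickness_m": [1e-2, 1.2e-2],
    "sigma_kg_m2": [7, 20, 40, 70],
    "dp_kpa": [[1.46, 1.45, 1.45, 1.44], [1.56, 1.5, 1.47, 1.45]],
    "wss_median_pa": [[1.3, 1.26, 1.11, 1.1], [1.27, 1.32, 1.2, 1.18]],
    "vortex_surface_m2": [[38.5e-3, 36.4e-3, 32e-3, 31.4e-3],
                          [36.3e-3, 36.8e-3, 35.7e-3, 32.9e-3]]
  }
}
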