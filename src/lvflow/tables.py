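"""Packaged published outcome tables and the derived statistics over them.

The JSON data file carries the printed per-ventricle results digit-for-digit
(constant-inflow outcomes, the porous-layer runs, the E-A-wave vortex
surfaces and the thickness x sigma sensitivity grid).  ``table_stats``
recomputes, from the packaged values alone, the headline derived numbers:
per-model pressure-drop differences, group means/SDs of the vortex surfaces,
and the per-model WSS median reduction percentages.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

_DATA = None


def load_tables() -> dict:
    """Raw packaged table content (cached)."""
    global _DATA
    if _DATA is None:
        with resources.files("lvflow.data").joinpath(
                "reference_tables.json").open() as fh:
            _DATA = json.load(fh)
    return _DATA


def table1_frame() -> pd.DataFrame:
    """Constant-inflow outcome table as a tidy DataFrame (hearts as index)."""
    t1 = load_tables()["table1"]
    idx = t1["hearts"]
    return pd.DataFrame({
        "area_inlet_m2": t1["area_inlet_m2"],
        "area_outlet_m2": t1["area_outlet_m2"],
        "alpha_deg": t1["alpha_deg"],
        "d_m": t1["d_m"],
        "trabeculae_pct": t1["trabeculae_pct"],
        "reynolds_inlet": t1["reynolds_inlet"],
        "dp_smoothed_kpa": t1["dp_kpa"]["smoothed"],
        "dp_detailed_kpa": t1["dp_kpa"]["detailed"],
        "dp_diff_kpa": t1["dp_diff_kpa"],
        "wss_median_smoothed_pa": t1["wss_median_pa"]["smoothed"],
        "wss_median_detailed_pa": t1["wss_median_pa"]["detailed"],
        "vortex_smoothed_m2": t1["vortex_surface_m2"]["smoothed"],
        "vortex_detailed_m2": t1["vortex_surface_m2"]["detailed"],
    }, index=idx)


def table_stats() -> dict:
    """Derived statistics recomputed from the packaged tables.

    * per-model dP_diff = dP(detailed) - dP(smoothed), kPa;
    * the mean dP_diff over the four models excluding the outlier D;
    * smoothed/detailed vortex-surface means and sample SDs, m^2;
    * per-model WSS median reduction (smoothed -> detailed), %, and the
      min/max over the models that show a reduction.
    """
    t1 = table1_frame()
    dp_diff = t1["dp_detailed_kpa"] - t1["dp_smoothed_kpa"]
    others = dp_diff.drop("D")
    red = 100.0 * (t1["wss_median_smoothed_pa"] - t1["wss_median_detailed_pa"]) \
        / t1["wss_median_smoothed_pa"]
    reducing = red[red > 0]
    vs, vd = t1["vortex_smoothed_m2"], t1["vortex_detailed_m2"]
    return {
        "dp_diff_kpa": dp_diff.to_dict(),
        "dp_diff_model_d_kpa": float(dp_diff["D"]),
        "mean_dp_diff_abce_kpa": float(others.mean()),
        "vortex_mean_smoothed_m2": float(vs.mean()),
        "vortex_sd_smoothed_m2": float(vs.std(ddof=1)),
        "vortex_mean_detailed_m2": float(vd.mean()),
        "vortex_sd_detailed_m2": float(vd.std(ddof=1)),
        "wss_reduction_pct": red.to_dict(),
        "wss_reduction_min_pct": float(reducing.min()),
        "wss_reduction_max_pct": float(reducing.max()),
    }


def porous_reference_errors() -> dict:
    """Relative errors of the porous runs vs the detailed references.

    Signed as (detailed - porous) / detailed, from the packaged per-model
    values (pressure drop, WSS median, total vortex surface).
    """
    t1 = table1_frame()
    t2 = load_tables()["table2"]
    out = {}
    for i, heart in enumerate(t2["hearts"]):
        det = t1.loc[heart]
        out[heart] = {
            "delta_p": (det["dp_detailed_kpa"] - t2["dp_kpa"][i])
            / det["dp_detailed_kpa"],
            "wss_median": (det["wss_median_detailed_pa"]
                           - t2["wss_median_pa"][i])
            / det["wss_median_detailed_pa"],
            "total_vortex_surface": (det["vortex_detailed_m2"]
                                     - t2["vortex_surface_m2"][i])
            / det["vortex_detailed_m2"],
        }
    return out
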