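"""Cohort-level endpoint studies: simulate seeded CONT/MCT cohorts, run the
protocol analyses per muscle, and collect group endpoint statistics.

These runners back both the ``atriomech reproduce`` CLI command and the
acceptance script; every number they report is computed from a fresh
simulate-then-analyze pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MuscleGeometry
from .params import FL_GRID, REFERENCE_ENDPOINTS
from .protocols import analyze_fl, analyze_prp, analyze_sfr
from .simulate import FLProtocol, PRPProtocol, SFRProtocol, make_cohort, \
    simulate_protocol
from .stats import mann_whitney

__all__ = ["run_sfr_study", "run_fl_study", "run_prp_study",
           "run_endpoint_study", "COHORT_N"]

#: per-group cohort sizes of the functional study
COHORT_N = {"CONT": 12, "MCT": 11}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) deterministically from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _cohort_runs(protocol, seed, n_cont, n_mct, sampling_rate):
    """Simulate both cohorts; yields (group, muscle index, recording)."""
    sizes = {"CONT": n_cont, "MCT": n_mct}
    seeds = _spawn_seeds(seed, 2 + n_cont + n_mct)
    cohorts = {"CONT": make_cohort("CONT", n_cont, seeds[0]),
               "MCT": make_cohort("MCT", n_mct, seeds[1])}
    k = 2
    for group in ("CONT", "MCT"):
        for i in range(sizes[group]):
            rec = simulate_protocol(cohorts[group][i], protocol,
                                    seed=seeds[k],
                                    sampling_rate=sampling_rate)
            k += 1
            yield group, i, rec


def run_sfr_study(seed: int, n_cont: int = COHORT_N["CONT"],
                  n_mct: int = COHORT_N["MCT"],
                  sampling_rate: float = 1000.0,
                  protocol: SFRProtocol | None = None) -> pd.DataFrame:
    """Slow-force-response endpoints per muscle (tidy, one row per muscle)."""
    protocol = protocol or SFRProtocol()
    rows = []
    for group, i, rec in _cohort_runs(protocol, seed, n_cont, n_mct,
                                      sampling_rate):
        res = analyze_sfr(rec)
        rows.append({
            "group": group, "muscle": i,
            "sfr_magnitude_pct": res.sfr_magnitude,
            "sfr_cat_amp_end_pct": res.end_values["cat_amplitude"],
            "sfr_cat_dia_end_pct": res.end_values["cat_diastolic"],
        })
    return pd.DataFrame(rows)


def run_prp_study(seed: int, n_cont: int = COHORT_N["CONT"],
                  n_mct: int = COHORT_N["MCT"],
                  sampling_rate: float = 1000.0,
                  protocol: PRPProtocol | None = None) -> pd.DataFrame:
    """Post-rest-potentiation endpoints per muscle."""
    protocol = protocol or PRPProtocol()
    rows = []
    for group, i, rec in _cohort_runs(protocol, seed, n_cont, n_mct,
                                      sampling_rate):
        res = analyze_prp(rec)
        rows.append({
            "group": group, "muscle": i,
            "prp_extent_pct": res.prp_extent,
            "prp_cat_first_pct": res.cat_first_beat_pct,
            "recovery_beats": res.recovery_beats,
        })
    return pd.DataFrame(rows)


def run_fl_study(seed: int, n_cont: int = COHORT_N["CONT"],
                 n_mct: int = COHORT_N["MCT"],
                 sampling_rate: float = 1000.0,
                 protocol: FLProtocol | None = None) -> pd.DataFrame:
    """Force-length characteristics per muscle per preload (tidy)."""
    protocol = protocol or FLProtocol()
    rows = []
    for group, i, rec in _cohort_runs(protocol, seed, n_cont, n_mct,
                                      sampling_rate):
        res = analyze_fl(rec, geometry=MuscleGeometry(rec.diameter_um))
        tab = res.table.copy()
        tab.insert(0, "group", group)
        tab.insert(1, "muscle", i)
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def _grid_contrast(fl: pd.DataFrame, col: str):
    """Per-preload group means and the MCT-vs-CONT contrast, averaged over
    the preload grid.  Returns (excess %, absolute difference)."""
    means = fl.groupby(["group", "preload_pct"])[col].mean().unstack(0)
    excess = 100.0 * (means["MCT"] - means["CONT"]) / means["CONT"]
    diff = means["MCT"] - means["CONT"]
    return float(excess.mean()), float(diff.mean())


def run_endpoint_study(seed: int, n_cont: int = COHORT_N["CONT"],
                       n_mct: int = COHORT_N["MCT"],
                       sampling_rate: float = 1000.0) -> pd.DataFrame:
    """Full endpoint study over all three protocols.

    Returns one row per endpoint with group means/SDs, the between-group
    Mann-Whitney p-value where the endpoint is per-muscle, and the
    reference value the calibration targeted.
    """
    s1, s2, s3 = _spawn_seeds(seed, 3)
    sfr = run_sfr_study(s1, n_cont, n_mct, sampling_rate)
    prp = run_prp_study(s2, n_cont, n_mct, sampling_rate)
    fl = run_fl_study(s3, n_cont, n_mct, sampling_rate)

    rows = []

    def per_muscle(df, col, name, ref_key, units="%"):
        g = {k: v[col].to_numpy() for k, v in df.groupby("group")}
        cmp_res = mann_whitney(g["CONT"], g["MCT"])
        ref = REFERENCE_ENDPOINTS.get(ref_key, {})
        rows.append({
            "endpoint": name, "units": units,
            "cont_mean": float(np.mean(g["CONT"])),
            "cont_sd": float(np.std(g["CONT"], ddof=1)),
            "mct_mean": float(np.mean(g["MCT"])),
            "mct_sd": float(np.std(g["MCT"], ddof=1)),
            "p_value": cmp_res.p_value,
            "reference_cont": ref.get("CONT", (np.nan,))[0] if ref else np.nan,
            "reference_mct": ref.get("MCT", (np.nan,))[0] if ref else np.nan,
        })

    per_muscle(sfr, "sfr_magnitude_pct", "SFR magnitude (force)",
               "sfr_force_end_pct")
    per_muscle(sfr, "sfr_cat_amp_end_pct", "SFR CaT amplitude at end",
               "sfr_cat_amp_end_pct")
    per_muscle(prp, "prp_extent_pct", "PRP extent (force)",
               "prp_force_extent_pct")
    per_muscle(prp, "prp_cat_first_pct", "PRP first-beat CaT amplitude",
               "prp_cat_first_pct")

    contrasts = (
        ("force_ttp_ms", "Force TTP excess, MCT vs CONT", "%",
         "force_ttp_excess_pct", 0),
        ("cat_ttp_ms", "CaT TTP excess, MCT vs CONT", "%",
         "cat_ttp_excess_pct", 0),
        ("cat_ttp_ms", "CaT TTP prolongation, MCT - CONT", "ms",
         "cat_ttp_prolongation_ms", 1),
        ("cat_t50_ms", "CaT T50 prolongation, MCT - CONT", "ms",
         "cat_t50_prolongation_ms", 1),
    )
    for col, name, units, ref_key, which in contrasts:
        excess, diff = _grid_contrast(fl, col)
        rows.append({
            "endpoint": name, "units": units,
            "cont_mean": np.nan, "cont_sd": np.nan,
            "mct_mean": np.nan, "mct_sd": np.nan,
            "p_value": np.nan,
            "reference_cont": REFERENCE_ENDPOINTS[ref_key],
            "reference_mct": np.nan,
            "value": excess if which == 0 else diff,
        })
    out = pd.DataFrame(rows)
    return out
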