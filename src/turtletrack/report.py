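"""Report assembly: study summary tables and their aggregate statistics.

The packaged CSVs under ``turtletrack/data`` transcribe the per-animal
summary tables of a published multi-year Fastloc-GPS telemetry study of
immature green turtles resident on the Bermuda Platform (the raw tracking
data were never deposited, so per-animal values are inputs here, not
recomputable).  This module loads them, recomputes every aggregate from the
per-row values, and writes the report tables as delimited text.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .detectability import (DetectabilityEstimate, ResidencyRecord,
                            detectability_summary, detection_rate, round_half_up)
from .homerange import summarize_home_ranges

USE_AREA_KINDS = ("foraging_f", "rest_day_r", "rest_night_r", "cool_refuge_c")


def _data_path(name: str):
    return resources.files("turtletrack.data").joinpath(name)


def load_deployments() -> pd.DataFrame:
    """Per-deployment tag summary: size, dates, fix counts, UD and MCP areas."""
    with resources.as_file(_data_path("deployments.csv")) as p:
        df = pd.read_csv(p)
    df["post_migration"] = df["post_migration"].astype(bool)
    df["departed"] = df["departed"].astype(bool)
    return df


def load_use_areas() -> pd.DataFrame:
    """Distinct use areas (kind, depth, size) per animal."""
    with resources.as_file(_data_path("use_areas.csv")) as p:
        return pd.read_csv(p)


def load_detectability() -> pd.DataFrame:
    """Residency and net-set/capture counts per animal."""
    with resources.as_file(_data_path("detectability.csv")) as p:
        df = pd.read_csv(p)
    df["single_site"] = df["single_site"].astype(bool)
    return df


def load_migrations() -> pd.DataFrame:
    """Per-track migration metrics (pelagic portion)."""
    with resources.as_file(_data_path("migrations.csv")) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# Aggregates (always recomputed from per-row values)
# ---------------------------------------------------------------------------

def detectability_estimates(df: Optional[pd.DataFrame] = None):
    if df is None:
        df = load_detectability()
    ests = []
    for _, r in df.iterrows():
        n_sets = None if pd.isna(r["n_sets"]) else int(r["n_sets"])
        n_caps = None if pd.isna(r["n_captures"]) else int(r["n_captures"])
        rec = ResidencyRecord(
            turtle_id=str(r["ptt"]),
            first_capture=r["first_capture"],
            last_observation=r["last_observation"],
            residency_months=float(r["residency_months"]),
            single_site=bool(r["single_site"]),
            n_sets=n_sets, n_captures=n_caps,
        )
        est = detection_rate(rec)
        if est is not None:
            ests.append(est)
    return ests


def study_aggregates() -> Dict[str, float]:
    """Every study-level mean recomputed from the packaged per-row tables."""
    dep = load_deployments()
    animals = dep[~dep["post_migration"]]
    out: Dict[str, float] = {}
    for col, key in (("ud25_km2", "mean_ud25_km2"), ("ud50_km2", "mean_ud50_km2"),
                     ("ud90_km2", "mean_ud90_km2"), ("mcp_km2", "mean_mcp_km2"),
                     ("scl_min_cm", "mean_scl_cm"),
                     ("days_deployed", "mean_days_deployed"),
                     ("n_fixes", "mean_fixes_per_animal")):
        out[key] = float(animals[col].mean())
    out["n_animals"] = int(len(animals))
    out["mean_scl_departing_cm"] = float(
        animals.loc[animals["departed"], "scl_min_cm"].mean())

    ua = load_use_areas()
    for kind, tag in (("foraging_f", "foraging"), ("rest_day_r", "day_rest"),
                      ("rest_night_r", "night_rest"), ("cool_refuge_c", "cool_refuge")):
        sub = ua[ua["kind"] == kind]
        out[f"mean_{tag}_size_km2"] = float(sub["size_km2"].mean())
        out[f"mean_{tag}_depth_m"] = float(sub["depth_m"].mean())
        out[f"n_{tag}_areas"] = int(len(sub))

    ests = detectability_estimates()
    mean, sd, n = detectability_summary(ests)
    out["detectability_mean_pct"] = mean
    out["detectability_sd_pct"] = sd
    out["n_detectability_animals"] = n

    mig = load_migrations()
    out["migration_straightness_mean"] = float(mig["straightness"].mean())
    out["migration_rate_mean_kmh"] = float(mig["rate_kmh"].mean())
    out["migration_current_mean_ms"] = float(mig["current_ms"].mean())
    out["n_migrations"] = int(len(mig))
    return out


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def build_report(outdir, deployments: Optional[pd.DataFrame] = None,
                 use_areas: Optional[pd.DataFrame] = None,
                 detect: Optional[pd.DataFrame] = None,
                 migrations: Optional[pd.DataFrame] = None) -> Dict[str, Path]:
    """Write the four report tables as CSV; returns the written paths.

    Missing inputs default to the packaged study tables; an explicitly empty
    frame yields a headers-only table.  Column means are recomputed from the
    per-row values on every call, excluding rows flagged ``post_migration``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    dep = load_deployments() if deployments is None else deployments
    if len(dep):
        rows = dep.rename(columns={"ptt": "tag_id"}).to_dict("records")
        table1 = summarize_home_ranges(rows)
    else:
        table1 = pd.DataFrame(columns=["tag_id", "ud25_km2", "ud50_km2",
                                       "ud90_km2", "mcp_km2"])
    paths["home_ranges"] = outdir / "home_ranges.csv"
    table1.to_csv(paths["home_ranges"], index=False, float_format="%.4g")

    ua = load_use_areas() if use_areas is None else use_areas
    if len(ua):
        pieces = [ua]
        mean_rows = []
        for kind in USE_AREA_KINDS:
            sub = ua[ua["kind"] == kind]
            if len(sub):
                mean_rows.append({"ptt": "Mean", "kind": kind,
                                  "depth_m": round_half_up(sub["depth_m"].mean(), 1),
                                  "size_km2": round_half_up(sub["size_km2"].mean(), 2)})
        table2 = pd.concat([ua, pd.DataFrame(mean_rows)], ignore_index=True)
    else:
        table2 = pd.DataFrame(columns=["ptt", "kind", "depth_m", "size_km2"])
    paths["use_areas"] = outdir / "use_areas.csv"
    table2.to_csv(paths["use_areas"], index=False)

    det = load_detectability() if detect is None else detect
    if len(det):
        ests = {e.turtle_id: e for e in detectability_estimates(det)}
        det = det.copy()
        det["rate_percent"] = [
            ests[str(p)].rate_percent_display if str(p) in ests else np.nan
            for p in det["ptt"]]
        if sum(e.eligible for e in ests.values()) >= 2:
            mean, sd, n = detectability_summary(list(ests.values()))
            footer = {c: "" for c in det.columns}
            footer.update({"ptt": "Mean (eligible)",
                           "rate_percent": round_half_up(mean, 1)})
            det = pd.concat([det, pd.DataFrame([footer])], ignore_index=True)
    paths["detectability"] = outdir / "detectability.csv"
    det.to_csv(paths["detectability"], index=False)

    mig = load_migrations() if migrations is None else migrations
    if len(mig):
        mean_row = {c: "" for c in mig.columns}
        mean_row.update({
            "ptt": "Mean",
            "straightness": round_half_up(float(mig["straightness"].mean()), 3),
            "rate_kmh": round_half_up(float(mig["rate_kmh"].mean()), 3),
            "current_ms": round_half_up(float(mig["current_ms"].mean()), 3),
        })
        mig = pd.concat([mig, pd.DataFrame([mean_row])], ignore_index=True)
    paths["migrations"] = outdir / "migrations.csv"
    mig.to_csv(paths["migrations"], index=False)
    return paths
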