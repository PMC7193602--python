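"""Pulmonary-artery morphometry from per-vessel perimeter/area tables.

Histology slides are measured upstream (e.g. in ImageJ); this module takes
the tabulated external/internal media perimeters and total/lumen areas of
muscular arteries and computes medial wall thickness and the medial-area
ratio, with the 20-80 um external-diameter vessel filter and the >= 5
vessels-per-sample rule applied before summarising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DIAMETER_WINDOW_UM = (20.0, 80.0)

REQUIRED_COLUMNS = ("sample_id", "group", "ext_perimeter_um", "int_perimeter_um",
                    "total_area_um2", "lumen_area_um2")


@dataclass
class VesselMeasure:
    sample_id: str
    group: str
    ext_perimeter_um: float
    int_perimeter_um: float
    total_area_um2: float
    lumen_area_um2: float

    def __post_init__(self) -> None:
        if not self.ext_perimeter_um > self.int_perimeter_um > 0:
            raise ValueError("need ext_perimeter > int_perimeter > 0")
        if not self.total_area_um2 > self.lumen_area_um2 >= 0:
            raise ValueError("need total_area > lumen_area >= 0")


def radius_from_perimeter(perimeter_um):
    """Effective circular radius r = P / (2*pi)."""
    p = np.asarray(perimeter_um, dtype=float)
    if np.any(p <= 0):
        raise ValueError("perimeter must be positive")
    r = p / (2.0 * math.pi)
    return float(r) if np.isscalar(perimeter_um) else r


def medial_wall_thickness(r_ext, r_int, mode: str = "absolute"):
    """Medial wall thickness from external/internal media radii.

    ``fraction`` mode: (r_ext - r_int) / r_ext; ``absolute`` mode: the
    difference in um (the convention used for cohort summary tables).
    """
    re_ = np.asarray(r_ext, dtype=float)
    ri = np.asarray(r_int, dtype=float)
    if np.any(ri <= 0) or np.any(re_ < ri):
        raise ValueError("need r_ext >= r_int > 0")
    if mode == "fraction":
        out = (re_ - ri) / re_
    elif mode == "absolute":
        out = re_ - ri
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.isscalar(r_ext) else out


def medial_area_ratio(total_area, lumen_area):
    """(total vascular area - lumen area) / total vascular area, in (0, 1]."""
    ta = np.asarray(total_area, dtype=float)
    la = np.asarray(lumen_area, dtype=float)
    if np.any(la < 0) or np.any(ta <= la):
        raise ValueError("need total_area > lumen_area >= 0")
    out = (ta - la) / ta
    return float(out) if np.isscalar(total_area) else out


def sample_summary(vessels: pd.DataFrame, min_n: int = 5,
                   mode: str = "absolute",
                   diameter_window_um: tuple[float, float] = DIAMETER_WINDOW_UM,
                   ) -> tuple[pd.DataFrame, dict]:
    """Per-sample mean +/- SD of medial wall thickness and medial-area ratio.

    Vessels whose external diameter (2 * r_ext) falls outside
    ``diameter_window_um`` are excluded and counted.  Samples left with
    fewer than ``min_n`` vessels are flagged and excluded from group-level
    statistics.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in vessels.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = vessels.copy()
    df["r_ext_um"] = radius_from_perimeter(df["ext_perimeter_um"].to_numpy())
    df["r_int_um"] = radius_from_perimeter(df["int_perimeter_um"].to_numpy())
    diam = 2.0 * df["r_ext_um"]
    lo, hi = diameter_window_um
    keep = (diam >= lo) & (diam <= hi)
    n_filtered = int((~keep).sum())
    df = df[keep].copy()
    df["thickness"] = medial_wall_thickness(df["r_ext_um"].to_numpy(),
                                            df["r_int_um"].to_numpy(), mode=mode)
    df["area_ratio"] = medial_area_ratio(df["total_area_um2"].to_numpy(),
                                         df["lumen_area_um2"].to_numpy())
    rows, flagged = [], []
    for (sid, grp), sub in df.groupby(["sample_id", "group"], sort=False):
        n = len(sub)
        if n < min_n:
            flagged.append(sid)
            continue
        rows.append({
            "sample_id": sid, "group": grp, "n_vessels": n,
            "thickness_mean": float(sub["thickness"].mean()),
            "thickness_sd": float(sub["thickness"].std(ddof=1)),
            "area_ratio_mean": float(sub["area_ratio"].mean()),
            "area_ratio_sd": float(sub["area_ratio"].std(ddof=1)),
        })
    info = {"n_filtered_vessels": n_filtered, "flagged_samples": flagged,
            "mode": mode, "diameter_window_um": diameter_window_um}
    return pd.DataFrame(rows), info
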