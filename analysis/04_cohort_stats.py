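#!/usr/bin/env python
"""Cohort statistics over the imaging metrics and histology summaries.

Control vs pooled-MCT Mann-Whitney tests for each metric, the three-group
Kruskal-Wallis with gated post-hoc pairs, the morphometry sample summary,
and the RBC:barrier vs RBC_defect% correlation.  Alpha = 0.05 two-sided,
uncorrected.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from xegas.morphometry import sample_summary
from xegas.stats import kruskal_wallis, mann_whitney, pearson


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--metrics", type=Path, default=Path("results/imaging_metrics.csv"))
    ap.add_argument("--vessels", type=Path, default=Path("results/histology_vessels.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    metrics = pd.read_csv(args.metrics)
    vessels = pd.read_csv(args.vessels)
    morpho, info = sample_summary(vessels)
    morpho.to_csv(args.out / "morphometry_summary.csv", index=False)

    is_ctrl = metrics.group == "control"
    results = {}
    for col in ("rbc_barrier_spectro", "vdp_pct", "rbc_defect_pct", "barrier_high_pct"):
        res = mann_whitney(metrics.loc[is_ctrl, col], metrics.loc[~is_ctrl, col])
        results[f"mw_control_vs_mct_{col}"] = {"U": res.u, "p": res.p,
                                               "method": res.method}
        groups = [g[col].to_numpy() for _, g in metrics.groupby("group")]
        kw = kruskal_wallis(groups)
        results[f"kw_{col}"] = {"H": kw.h, "p": kw.p,
                                "n_posthoc_pairs": len(kw.posthoc)}

    thick = morpho.set_index("sample_id")["thickness_mean"]
    merged = metrics.join(thick, on="animal_id")
    mct = merged[~is_ctrl].dropna(subset=["thickness_mean"])
    corr = pearson(mct["rbc_barrier_spectro"], mct["rbc_defect_pct"])
    results["pearson_mct_rbcbarrier_vs_rbcdefect"] = {
        "r": corr.r, "p": corr.p, "slope": corr.slope, "n": corr.n}

    with open(args.out / "cohort_stats.json", "w") as fh:
        json.dump(results, fh, indent=2)
    for key, val in results.items():
        print(key, {k: (round(v, 4) if isinstance(v, float) else v)
                    for k, v in val.items()})
    print(f"flagged morphometry samples: {info['flagged_samples']}")
    print(f"-> {args.out / 'cohort_stats.json'}")


if __name__ == "__main__":
    main()
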