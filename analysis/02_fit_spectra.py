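#!/usr/bin/env python
"""Fit the three-resonance spectral model to each animal's FID.

Synthesises one steady-state dissolved-phase FID per cohort animal from its
drawn RBC:barrier ratio, decomposes it into gas/barrier/RBC Lorentzians,
and tabulates the fitted ratios and chemical shifts per group.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from xegas.params import AcqParams
from xegas.phantom import synth_fid, truth_resonances
from xegas.spectro import fit_spectrum


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--noise-sd", type=float, default=0.3)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(args.cohort)
    acq = AcqParams()
    rng = np.random.default_rng(args.seed)
    rows = []
    for _, rec in cohort.iterrows():
        res = truth_resonances(rec["rbc_barrier"], acq)
        fid = synth_fid(res, acq, noise_sd=args.noise_sd,
                        seed=int(rng.integers(2**31)))
        fit = fit_spectrum(fid, acq)
        rows.append({
            "animal_id": rec["animal_id"], "group": rec["group"],
            "rbc_barrier_true": rec["rbc_barrier"],
            "rbc_barrier_fit": fit.rbc_barrier,
            "shift_rbc_ppm": fit.rbc.shift_ppm,
            "shift_barrier_ppm": fit.barrier.shift_ppm,
            "converged": fit.converged,
        })
    fits = pd.DataFrame(rows)
    fits.to_csv(args.out / "spectro_fits.csv", index=False)
    summary = fits.groupby("group")[["rbc_barrier_fit"]].agg(["mean", "std"]).round(3)
    print("fitted RBC:barrier by group")
    print(summary)
    err = (fits["rbc_barrier_fit"] - fits["rbc_barrier_true"]).abs()
    print(f"max |fit - truth| over {len(fits)} animals: {err.max():.4f}")
    print(f"-> {args.out / 'spectro_fits.csv'}")


if __name__ == "__main__":
    main()
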