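"""Box-Cox reference distributions, linear binning, and defect metrics.

Healthy-population histograms of ventilation and the two gas-exchange ratio
maps are right-skewed, so thresholds cannot be set directly at mean +/- k*SD.
The one-parameter Box-Cox transform

    y = (x^lambda - 1) / lambda     (lambda != 0;  ln x at lambda = 0)

renders the pooled healthy histogram approximately Gaussian; thresholds are
placed at mu_t + k*sigma_t in the transformed domain and mapped back,
producing uneven bin edges in original units.  Ventilation and RBC:gas use
6 bins (k = -2..+2: red defect bin, orange low bin, two green normal bins,
two blue high bins); barrier:gas uses 8 bins (k = -2..+4) to span its wider
dynamic range, the top three (purple) bins marking elevated barrier uptake.

Summary metrics: VDP = % of thorax voxels in ventilation bin 1;
low-ventilation cluster = % in bin 2; RBC_defect% = % of analysed voxels in
RBC:gas bin 1; barrier_high% = % in the three purple barrier bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import special, stats

from .volume import VolumeImage

#: threshold multiples of sigma_t per map type
K_MULTIPLES = {
    "ventilation": (-2, -1, 0, 1, 2),
    "rbc": (-2, -1, 0, 1, 2),
    "barrier": (-2, -1, 0, 1, 2, 3, 4),
}
SIX_BIN_PALETTE = ("red", "orange", "green", "green", "blue", "blue")
# 8-bin barrier palette: top three bins purple
BARRIER_PALETTE = ("red", "orange", "green", "green", "blue", "purple", "purple", "purple")


class BinningError(RuntimeError):
    pass


def boxcox_lambda(samples: np.ndarray, bracket: tuple[float, float] = (-3.0, 3.0)) -> float:
    """Profile-likelihood Box-Cox exponent for strictly positive samples."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise BinningError("need at least two samples")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise BinningError(
            "Box-Cox requires strictly positive samples; pre-mask zeros/negatives")
    lam = float(stats.boxcox_normmax(x, brack=bracket, method="mle"))
    return float(np.clip(lam, bracket[0], bracket[1]))


def boxcox_transform(x, lam: float):
    return special.boxcox(np.asarray(x, dtype=float), lam)


def boxcox_inverse(y, lam: float):
    return special.inv_boxcox(np.asarray(y, dtype=float), lam)


@dataclass
class ReferenceDistribution:
    map_type: str
    lam: float
    mu_t: float
    sigma_t: float
    thresholds: list[float]
    n_bins: int
    k_multiples: list[float]
    palette: tuple[str, ...]
    n_pooled: int = 0
    n_excluded_nonpositive: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) != self.n_bins - 1:
            raise BinningError("need n_bins - 1 thresholds")
        if np.any(np.diff(t) <= 0):
            raise BinningError("thresholds must be strictly increasing")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["palette"] = list(d["palette"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ReferenceDistribution":
        with open(path) as fh:
            d = json.load(fh)
        d["palette"] = tuple(d["palette"])
        return cls(**d)


@dataclass
class BinnedMap:
    labels: VolumeImage          # integer bins 1..n_bins, 0 outside mask
    percentages: np.ndarray      # per-bin % of masked voxels, sums to 100
    map_type: str
    n_bins: int

    def bin_pct(self, b: int) -> float:
        return float(self.percentages[b - 1])


def build_reference(healthy_maps: list[tuple[VolumeImage, np.ndarray | VolumeImage]],
                    map_type: str, lam: float | None = None,
                    equal_animal_weight: bool = False) -> ReferenceDistribution:
    """Pool masked voxels across healthy animals and derive bin thresholds.

    By default voxels pool with equal weight (aggregate histogram);
    ``equal_animal_weight`` resamples each animal's voxels to a common count
    first.  Non-positive voxels are excluded (counted); ``lam`` may be
    forced (e.g. 1.0 makes the transform a pure shift for testing).
    """
    if map_type not in K_MULTIPLES:
        raise BinningError(f"unknown map type {map_type!r}")
    if len(healthy_maps) == 0:
        raise BinningError("need at least one healthy subject")
    pools = []
    for vol, mask in healthy_maps:
        m = (mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)).astype(bool)
        v = vol.data[m]
        pools.append(v[np.isfinite(v)])
    if equal_animal_weight:
        n_common = min(len(p) for p in pools)
        rng = np.random.default_rng(0)
        pools = [rng.choice(p, n_common, replace=False) for p in pools]
    pooled = np.concatenate(pools)
    n_nonpos = int((pooled <= 0).sum())
    pooled = pooled[pooled > 0]
    if pooled.size < 1000:
        warnings.warn(f"only {pooled.size} pooled voxels; reference may be unstable")
    if lam is None:
        lam = boxcox_lambda(pooled)
    t = boxcox_transform(pooled, lam)
    mu_t, sigma_t = float(t.mean()), float(t.std(ddof=0))
    ks = K_MULTIPLES[map_type]
    y = mu_t + sigma_t * np.asarray(ks, dtype=float)
    # inverse transform must stay in the Box-Cox domain (lambda*y + 1 > 0)
    if lam != 0 and np.any(lam * y + 1 <= 0):
        raise BinningError("threshold outside the Box-Cox domain; "
                           "distribution too narrow or lambda extreme")
    thresholds = boxcox_inverse(y, lam)
    n_bins = len(ks) + 1
    palette = BARRIER_PALETTE if map_type == "barrier" else SIX_BIN_PALETTE
    return ReferenceDistribution(
        map_type=map_type, lam=float(lam), mu_t=mu_t, sigma_t=sigma_t,
        thresholds=[float(v) for v in thresholds], n_bins=n_bins,
        k_multiples=[float(k) for k in ks], palette=palette,
        n_pooled=int(pooled.size), n_excluded_nonpositive=n_nonpos)


def bin_map(vol: VolumeImage, mask, reference: ReferenceDistribution,
            map_type: str | None = None) -> BinnedMap:
    """Assign each masked voxel to a bin: label = 1 + #(thresholds <= value)
    with half-open intervals [t_k, t_{k+1}); a voxel exactly at a threshold
    goes to the higher bin."""
    if map_type is not None and map_type != reference.map_type:
        raise BinningError(
            f"reference is for {reference.map_type!r}, map is {map_type!r}")
    m = (mask.data if isinstance(mask, VolumeImage) else np.asarray(mask)).astype(bool)
    vals = vol.data[m]
    if not np.all(np.isfinite(vals)):
        raise BinningError("undefined (non-finite) voxels inside the mask")
    t = np.asarray(reference.thresholds)
    labels_in = 1 + np.searchsorted(t, vals, side="right")
    labels = np.zeros(vol.shape, dtype=np.int16)
    labels[m] = labels_in
    counts = np.bincount(labels_in, minlength=reference.n_bins + 1)[1:]
    pct = 100.0 * counts / counts.sum()
    return BinnedMap(labels=vol.with_data(labels), percentages=pct,
                     map_type=reference.map_type, n_bins=reference.n_bins)


def metrics(binned: dict[str, BinnedMap]) -> dict:
    """Summary metrics from the binned maps.

    Expects keys from {"ventilation", "barrier", "rbc"}; missing map types
    are flagged rather than failing.
    """
    out: dict[str, float | list[str]] = {}
    missing = []
    if "ventilation" in binned:
        b = binned["ventilation"]
        out["vdp_pct"] = b.bin_pct(1)
        out["low_vent_pct"] = b.bin_pct(2)
    else:
        missing.append("ventilation")
    if "rbc" in binned:
        out["rbc_defect_pct"] = binned["rbc"].bin_pct(1)
    else:
        missing.append("rbc")
    if "barrier" in binned:
        b = binned["barrier"]
        out["barrier_high_pct"] = float(sum(b.bin_pct(k) for k in (6, 7, 8)))
    else:
        missing.append("barrier")
    if missing:
        out["missing_maps"] = missing
    return out
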