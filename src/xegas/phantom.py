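"""Digital rat-thorax phantoms, synthetic FIDs and whole cohorts.

No public gas-exchange MRI data exist for the monocrotaline (MCT) rat model,
so the pipeline is exercised end to end on simulated inputs.  The generator
emulates the study conditions:

* a supine rat thorax (axis 0 left-right, axis 1 anterior-posterior with
  anterior at low index, axis 2 superior-inferior) with an ellipsoidal lung
  pair, a heart notch, and conducting airways;
* compartment signal maps (ventilation/gas, barrier, RBC) whose healthy
  RBC:barrier totals default to the control-group value 0.47;
* MCT lesion geography — RBC-transfer defects in the anterior (dependent)
  lung, elevated barrier uptake and ventilation defects at the lung
  periphery, proton-bright unventilated edema in the posterior lung;
* three-resonance FIDs via the exact forward model of the spectral fit;
* cohorts whose per-animal metrics are drawn from group means/SDs (defaults
  are the published control / MCT-wk1 / MCT-wk2 values).

Volumes are generated directly in image space; k-space sampling and radial
reconstruction artifacts are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .params import AcqParams
from .spectro import ResonanceFit
from .volume import VolumeImage

LESION_KINDS = ("rbc_defect", "barrier_high", "vent_defect", "edema")
REGIONS = ("anterior", "posterior", "peripheral")

#: group means/SDs of the cohort metrics (medial wall thickness um,
#: spectroscopic RBC:barrier, VDP %, barrier_high %, RBC_defect %)
TABLE1_GROUPS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "medial_wall_um": (4.6, 2.5),
        "rbc_barrier": (0.47, 0.03),
        "vdp_pct": (2.5, 0.9),
        "barrier_high_pct": (3.5, 1.9),
        "rbc_defect_pct": (11.8, 3.6),
    },
    "PH": {
        "medial_wall_um": (10.3, 6.7),
        "rbc_barrier": (0.40, 0.06),
        "vdp_pct": (3.3, 2.6),
        "barrier_high_pct": (7.9, 6.3),
        "rbc_defect_pct": (17.1, 5.3),
    },
    "MCT-wk1": {
        "medial_wall_um": (3.9, 2.0),
        "rbc_barrier": (0.41, 0.04),
        "vdp_pct": (1.5, 0.5),
        "barrier_high_pct": (7.3, 8.1),
        "rbc_defect_pct": (17.6, 6.3),
    },
    "MCT-wk2": {
        "medial_wall_um": (12.6, 6.3),
        "rbc_barrier": (0.40, 0.08),
        "vdp_pct": (4.7, 2.7),
        "barrier_high_pct": (8.3, 5.4),
        "rbc_defect_pct": (16.7, 5.0),
    },
}

# physical truncation ranges for cohort draws
_METRIC_BOUNDS = {
    "medial_wall_um": (0.2, 60.0),
    "rbc_barrier": (0.05, 1.5),
    "vdp_pct": (0.0, 100.0),
    "barrier_high_pct": (0.0, 100.0),
    "rbc_defect_pct": (0.0, 100.0),
}


@dataclass
class Lesion:
    """A contiguous pathological sub-region.

    ``multiplier`` scales the affected channel inside the lesion: in [0, 1)
    for ``rbc_defect``/``vent_defect``, > 1 for ``barrier_high``.  For
    ``edema`` it scales the proton signal (> 1); edema regions additionally
    lose all ventilation and dissolved signal.
    """

    kind: str
    region: str
    volume_fraction: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must be in [0, 1]")
        if self.kind in ("rbc_defect", "vent_defect"):
            if not 0.0 <= self.multiplier < 1.0:
                raise ValueError(f"{self.kind} multiplier must be in [0, 1)")
        elif self.multiplier <= 1.0:
            raise ValueError(f"{self.kind} multiplier must be > 1")


@dataclass
class PhantomConfig:
    grid_size: int = 64
    fov_mm: float = 50.0
    vent_mean: float = 1.0
    vent_cv: float = 0.10
    barrier_to_gas: float = 0.010
    rbc_to_gas: float = 0.0047        # healthy RBC:barrier 0.47
    barrier_cv: float = 0.15
    rbc_cv: float = 0.15
    lesions: list[Lesion] = field(default_factory=list)
    noise_sd: dict = field(default_factory=dict)
    dissolved_phase_deg: float = 37.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        for name in ("vent_mean", "barrier_to_gas", "rbc_to_gas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("vent_cv", "barrier_cv", "rbc_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.lesions = [l if isinstance(l, Lesion) else Lesion(**l) for l in self.lesions]
        defaults = {"proton": 0.02, "ventilation": 0.02, "dissolved": 5e-4, "fid": 0.05}
        self.noise_sd = {**defaults, **dict(self.noise_sd)}


@dataclass
class PhantomTruth:
    """Noiseless ground truth for one simulated animal."""

    proton: VolumeImage
    ventilation: VolumeImage
    barrier: VolumeImage
    rbc: VolumeImage
    thorax_mask: VolumeImage
    airway_mask: VolumeImage
    edema_mask: VolumeImage
    true_rbc_barrier: float
    lesion_masks: list[np.ndarray] = field(default_factory=list)
    config: PhantomConfig | None = None


def _ellipsoid(u, center, semi) -> np.ndarray:
    return sum(((ui - c) / s) ** 2 for ui, c, s in zip(u, center, semi)) <= 1.0


def _segment_mask(u, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` (normalised units) of segment p0-p1."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    pts = np.stack([ui - c for ui, c in zip(u, p0)], axis=-1)
    tt = np.clip(pts @ d / (d @ d), 0.0, 1.0)
    closest = tt[..., None] * d
    return np.linalg.norm(pts - closest, axis=-1) <= radius


def _smooth_field(rng, shape, mask, cv, sigma=2.0) -> np.ndarray:
    """Multiplicative heterogeneity 1 + cv*G, G smooth unit-variance noise
    (clipped at 3 sigma to keep the field positive)."""
    if cv == 0:
        return np.ones(shape)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    g = (g - g[mask].mean()) / max(g[mask].std(), 1e-12)
    return 1.0 + cv * np.clip(g, -3.0, 3.0)


def _zone_mask(region: str, thorax: np.ndarray, frac_needed: float) -> np.ndarray:
    idx = np.argwhere(thorax)
    if region == "anterior":
        cut = np.quantile(idx[:, 1], max(0.4, frac_needed))
        zone = np.zeros_like(thorax)
        zone[thorax] = idx[:, 1] <= cut
        return zone & thorax
    if region == "posterior":
        cut = np.quantile(idx[:, 1], min(0.6, 1.0 - frac_needed))
        zone = np.zeros_like(thorax)
        zone[thorax] = idx[:, 1] >= cut
        return zone & thorax
    # peripheral: thinnest shell (by Euclidean depth) holding enough voxels
    edt = ndimage.distance_transform_edt(thorax)
    cut = np.quantile(edt[thorax], min(0.95, max(0.35, 1.2 * frac_needed)))
    return thorax & (edt <= cut)


def _grow_lesion(rng, thorax: np.ndarray, zone: np.ndarray, n_target: int,
                 taken: np.ndarray) -> np.ndarray:
    """Spherical region grown from a deep seed voxel of the zone, filling the
    zone first, spilling into the rest of the thorax only if the zone is
    exhausted."""
    avail_zone = zone & ~taken
    if avail_zone.sum() == 0:
        raise ValueError("lesion zone exhausted")
    edt = ndimage.distance_transform_edt(avail_zone)
    deep = np.argwhere(edt >= 0.8 * edt.max())
    seed = deep[rng.integers(len(deep))]
    avail = thorax & ~taken
    coords = np.argwhere(avail)
    dist = np.linalg.norm(coords - seed, axis=1)
    in_zone = avail_zone[tuple(coords.T)]
    order = np.lexsort((dist, ~in_zone))  # zone voxels first, each by distance
    chosen = coords[order[:n_target]]
    out = np.zeros_like(thorax)
    out[tuple(chosen.T)] = True
    return out


def make_phantom(config: PhantomConfig) -> PhantomTruth:
    """Build the noiseless ground-truth volumes for one animal.

    Deterministic for a given ``(config, seed)``.  Compartment totals are
    calibrated so that sum(rbc)/sum(barrier) over the thorax equals
    ``rbc_to_gas / barrier_to_gas`` exactly before lesions are applied;
    lesions then move the realised ratio, which is reported as
    ``true_rbc_barrier``.
    """
    total_vf = sum(l.volume_fraction for l in config.lesions)
    if total_vf > 0.9:
        raise ValueError("total lesion volume fraction exceeds 0.9 of the lung")

    rng = np.random.default_rng(config.seed)
    n = config.grid_size
    shape = (n, n, n)
    ax = [np.linspace(-0.5, 0.5, n)] * 3
    u = np.meshgrid(*ax, indexing="ij")

    lungs = _ellipsoid(u, (+0.18, 0.02, 0.02), (0.17, 0.27, 0.33))
    lungs |= _ellipsoid(u, (-0.18, 0.02, 0.02), (0.17, 0.27, 0.33))
    lungs |= _ellipsoid(u, (0.0, 0.17, 0.02), (0.24, 0.11, 0.14))  # retrocardiac bridge
    heart = _ellipsoid(u, (0.02, -0.12, 0.10), (0.13, 0.13, 0.13))
    thorax = lungs & ~heart

    trachea = _segment_mask(u, (0.0, -0.02, -0.38), (0.0, -0.02, -0.06), 0.022)
    bronchi = _segment_mask(u, (0.0, -0.02, -0.06), (0.16, 0.0, 0.10), 0.018)
    bronchi |= _segment_mask(u, (0.0, -0.02, -0.06), (-0.16, 0.0, 0.10), 0.018)
    airways = trachea | bronchi

    body = _ellipsoid(u, (0.0, 0.0, 0.0), (0.42, 0.38, 0.47))
    proton = np.full(shape, 0.02)
    proton[body] = 1.0
    proton[lungs] = 0.15
    proton[airways & body] = 0.10

    vent = np.zeros(shape)
    vent[thorax] = config.vent_mean * _smooth_field(rng, shape, thorax, config.vent_cv)[thorax]
    vent[airways & body] = 1.3 * config.vent_mean  # conducting airways hold gas

    parenchyma = thorax & ~airways
    gas_w = np.where(parenchyma, vent, 0.0)
    barrier = gas_w * _smooth_field(rng, shape, parenchyma, config.barrier_cv)
    rbc = gas_w * _smooth_field(rng, shape, parenchyma, config.rbc_cv)
    barrier *= config.barrier_to_gas * gas_w[thorax].sum() / barrier[thorax].sum()
    rbc *= config.rbc_to_gas * gas_w[thorax].sum() / rbc[thorax].sum()

    # carve lesions
    edema_mask = np.zeros(shape, bool)
    lesion_masks: list[np.ndarray] = []
    taken = np.zeros(shape, bool)
    for lesion in config.lesions:
        n_target = int(round(lesion.volume_fraction * thorax.sum()))
        zone = _zone_mask(lesion.region, thorax, lesion.volume_fraction)
        region = _grow_lesion(rng, thorax, zone, n_target, taken)
        taken |= region
        lesion_masks.append(region)
        if lesion.kind == "rbc_defect":
            rbc[region] *= lesion.multiplier
        elif lesion.kind == "barrier_high":
            barrier[region] *= lesion.multiplier
        elif lesion.kind == "vent_defect":
            for vol in (vent, barrier, rbc):  # unventilated -> no xenon
                vol[region] *= lesion.multiplier
        elif lesion.kind == "edema":
            edema_mask |= region
            proton[region] = np.clip(0.85 * lesion.multiplier / 2.0, 0.5, 1.2)
            for vol in (vent, barrier, rbc):
                vol[region] = 0.0

    proton = ndimage.gaussian_filter(proton, 0.7)

    fov = (config.fov_mm,) * 3
    denom = barrier[thorax].sum()
    truth = PhantomTruth(
        proton=VolumeImage(proton, fov),
        ventilation=VolumeImage(vent, fov),
        barrier=VolumeImage(barrier, fov),
        rbc=VolumeImage(rbc, fov),
        thorax_mask=VolumeImage(thorax, fov),
        airway_mask=VolumeImage(airways, fov),
        edema_mask=VolumeImage(edema_mask, fov),
        true_rbc_barrier=float(rbc[thorax].sum() / denom),
        lesion_masks=lesion_masks,
        config=config,
    )
    return truth


# --------------------------------------------------------------------- FIDs

def synth_fid(resonances: list[ResonanceFit], acq: AcqParams,
              noise_sd: float = 0.0, seed: int | None = None) -> np.ndarray:
    """Exact forward model of the spectral fit:

        s(t) = sum_k A_k exp(i phi_k) exp(i 2 pi f_k t) exp(-pi w_k t)

    with ``w_k`` the Lorentzian FWHM in Hz, plus circularly-symmetric
    complex Gaussian noise of per-channel SD ``noise_sd``.
    """
    for r in resonances:
        if abs(r.freq_hz) >= acq.nyquist_hz:
            raise ValueError(
                f"resonance at {r.freq_hz} Hz aliases (Nyquist {acq.nyquist_hz} Hz)"
            )
    t = np.arange(acq.n_points) * acq.dwell_s
    s = np.zeros(acq.n_points, dtype=complex)
    for r in resonances:
        s += r.amplitude * np.exp(1j * math.radians(r.phase_deg)) * np.exp(
            (2j * np.pi * r.freq_hz - np.pi * r.fwhm_hz) * t
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + noise_sd * (rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points))
    return s


def truth_resonances(rbc_barrier: float, acq: AcqParams,
                     gas_amplitude: float = 100.0, barrier_amplitude: float = 30.0,
                     shift_barrier_ppm: float = 196.9, shift_rbc_ppm: float = 210.5,
                     phase_deg: float = 0.0) -> list[ResonanceFit]:
    """Ground-truth three-resonance set for a subject with a given
    RBC:barrier ratio, referenced to the dissolved-phase carrier (gas +
    17.51 kHz).  Dissolved linewidths follow T2* ~ 0.5 ms; gas follows
    ``acq.t2star_gas_ms``."""
    f_gas = -acq.carrier_offset_hz
    mhz = acq.spectrometer_freq_MHz
    w_dissolved = 1.0 / (np.pi * acq.t2star_dissolved_ms * 1e-3)
    w_gas = 1.0 / (np.pi * acq.t2star_gas_ms * 1e-3)
    return [
        ResonanceFit(gas_amplitude, f_gas, w_gas, phase_deg, 0.0),
        ResonanceFit(barrier_amplitude, f_gas + shift_barrier_ppm * mhz,
                     w_dissolved, phase_deg, shift_barrier_ppm),
        ResonanceFit(rbc_barrier * barrier_amplitude, f_gas + shift_rbc_ppm * mhz,
                     w_dissolved, phase_deg, shift_rbc_ppm),
    ]


# ---------------------------------------------------------- measured subject

@dataclass
class SubjectData:
    """What the scanner would hand the pipeline for one animal."""

    proton: VolumeImage
    ventilation: VolumeImage
    dissolved: VolumeImage        # complex
    fid: np.ndarray
    acq: AcqParams
    truth: PhantomTruth


def simulate_measurement(truth: PhantomTruth, acq: AcqParams | None = None,
                         seed: int | None = None,
                         dissolved_fov_factor: float = 1.0) -> SubjectData:
    """Add measurement noise and compose the complex dissolved-phase volume
    ``exp(i phi0) * (barrier + i * rbc)`` the Dixon stage must unmix.

    ``dissolved_fov_factor`` > 1 re-grids the dissolved volume onto a larger
    field of view (the in vivo protocol used 2x) at the same matrix size.
    """
    cfg = truth.config or PhantomConfig()
    acq = acq or AcqParams()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    sd = cfg.noise_sd
    shape = truth.proton.shape

    proton = truth.proton.with_data(truth.proton.data + sd["proton"] * rng.standard_normal(shape))
    vent = truth.ventilation.with_data(
        np.abs(truth.ventilation.data + sd["ventilation"] * rng.standard_normal(shape))
    )
    phi0 = math.radians(cfg.dissolved_phase_deg)
    dis = np.exp(1j * phi0) * (truth.barrier.data + 1j * truth.rbc.data)
    if dissolved_fov_factor != 1.0:
        from .volume import resample_to_grid
        big = VolumeImage(np.zeros(shape, complex),
                          tuple(f * dissolved_fov_factor for f in truth.proton.fov_mm))
        dis = resample_to_grid(VolumeImage(dis, truth.proton.fov_mm), big).data
        fov = big.fov_mm
    else:
        fov = truth.proton.fov_mm
    dis = dis + sd["dissolved"] * (rng.standard_normal(dis.shape) + 1j * rng.standard_normal(dis.shape))

    res = truth_resonances(truth.true_rbc_barrier, acq, phase_deg=cfg.dissolved_phase_deg)
    fid = synth_fid(res, acq, noise_sd=sd["fid"], seed=int(rng.integers(2**31)))
    return SubjectData(proton=proton, ventilation=vent,
                       dissolved=VolumeImage(dis, fov), fid=fid, acq=acq, truth=truth)


# -------------------------------------------------------------------- cohort

def _draw_truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if sd == 0:
        return np.full(size, mean) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def synth_cohort(group_specs: dict[str, dict[str, tuple[float, float]]] | None = None,
                 n_per_group: dict[str, int] | int | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Draw per-animal generator parameters for each group.

    ``group_specs`` maps group name -> {metric: (mean, sd)}; defaults to the
    published control / PH / MCT-wk1 / MCT-wk2 values.  Draws are truncated
    normal within physical ranges and reproducible by seed.  Returns a tidy
    DataFrame (one row per animal) of generator-truth metrics.
    """
    specs = group_specs or {k: TABLE1_GROUPS[k] for k in ("control", "MCT-wk1", "MCT-wk2")}
    default_n = {"control": 8, "PH": 9, "MCT-wk1": 4, "MCT-wk2": 5}
    rng = np.random.default_rng(seed)
    rows = []
    for group, spec in specs.items():
        if isinstance(n_per_group, dict):
            n = n_per_group[group]
        elif n_per_group is not None:
            n = int(n_per_group)
        else:
            n = default_n.get(group, 5)
        if n < 2:
            raise ValueError("need n >= 2 animals per group")
        for i in range(n):
            row = {"animal_id": f"{group}-{i + 1:02d}", "group": group}
            for metric, (mean, sd) in spec.items():
                lo, hi = _METRIC_BOUNDS.get(metric, (-np.inf, np.inf))
                row[metric] = float(_draw_truncnorm(rng, mean, sd, lo, hi))
            rows.append(row)
    return pd.DataFrame(rows)


#: baseline bin-1 fraction of a Gaussianised reference (percent);
#: lesion sizes for materialised animals are set on top of this floor
NORMAL_BIN1_PCT = 100.0 * float(stats.norm.cdf(-2.0))


def config_for_animal(record: dict | pd.Series, base: PhantomConfig | None = None,
                      seed: int | None = None) -> PhantomConfig:
    """Translate one cohort row into a phantom configuration.

    The drawn RBC:barrier sets the compartment totals; drawn defect
    percentages in excess of the healthy binning floor (~2.3%) are injected
    as lesions in their characteristic zones (RBC defects anterior, high
    barrier and ventilation defects peripheral).
    """
    base = base or PhantomConfig()
    lesions = list(base.lesions)
    vf_rbc = max(0.0, (float(record["rbc_defect_pct"]) - NORMAL_BIN1_PCT) / 100.0)
    if vf_rbc > 0.005:
        lesions.append(Lesion("rbc_defect", "anterior", vf_rbc, 0.2))
    vf_bar = max(0.0, (float(record["barrier_high_pct"]) - NORMAL_BIN1_PCT) / 100.0)
    if vf_bar > 0.005:
        lesions.append(Lesion("barrier_high", "peripheral", vf_bar, 2.5))
    vf_vent = max(0.0, (float(record["vdp_pct"]) - NORMAL_BIN1_PCT) / 100.0)
    if vf_vent > 0.005:
        lesions.append(Lesion("vent_defect", "peripheral", vf_vent, 0.05))
    return replace(
        base,
        rbc_to_gas=base.barrier_to_gas * float(record["rbc_barrier"]),
        lesions=lesions,
        seed=base.seed if seed is None else seed,
    )


def synth_histology(cohort: pd.DataFrame, vessels_per_sample: int = 8,
                    seed: int = 0) -> pd.DataFrame:
    """Per-vessel perimeter/area table consistent with each animal's drawn
    medial wall thickness (µm).  External radii are drawn in the muscular-
    artery range; perimeters follow r = P / (2 pi) exactly, areas are those
    of concentric circles."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in cohort.iterrows():
        thickness = float(rec["medial_wall_um"])
        for v in range(vessels_per_sample):
            r_ext = rng.uniform(14.0, 38.0)
            t = max(0.3, rng.normal(thickness, 0.15 * thickness + 0.1))
            r_int = max(0.2, r_ext - t)
            if r_int >= r_ext:
                r_int = 0.95 * r_ext
            rows.append({
                "sample_id": rec["animal_id"],
                "group": rec["group"],
                "ext_perimeter_um": 2 * np.pi * r_ext,
                "int_perimeter_um": 2 * np.pi * r_int,
                "total_area_um2": np.pi * r_ext**2,
                "lumen_area_um2": np.pi * r_int**2,
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- FID I/O

def save_fid_csv(fid: np.ndarray, acq: AcqParams, csv_path, sidecar_path=None) -> None:
    """Two-column (real, imaginary) CSV plus a JSON sidecar with AcqParams."""
    pd.DataFrame({"real": fid.real, "imag": fid.imag}).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        acq.to_json(sidecar_path)


def load_fid_csv(csv_path, sidecar_path=None):
    df = pd.read_csv(csv_path)
    fid = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    if sidecar_path is None:
        return fid
    return fid, AcqParams.from_json(sidecar_path)
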