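"""Complex Lorentzian decomposition of dissolved-phase 129Xe spectra.

A dissolved-phase free induction decay (FID) acquired with the carrier near
the RBC resonance contains three resonances: gas (airspaces), barrier
(septal tissue and plasma, ~197 ppm downfield of gas) and RBC (~211 ppm).
Each contributes a complex exponential

    s_k(t) = A_k * exp(i*phi_k) * exp(i*2*pi*f_k*t) * exp(-pi*w_k*t)

where ``w_k`` is the Lorentzian full width at half maximum in Hz.  Fitting
is nonlinear least squares on the complex time-domain signal (real and
imaginary parts stacked), which keeps the noise model Gaussian and avoids
the Rician bias of magnitude-spectrum fits.  Initialisation is automatic by
peak-picking the magnitude spectrum.

The amplitude ratio RBC:barrier is the package's global index of
gas-exchange efficiency (0.47 in healthy control rats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .params import AcqParams

# label guard bands in ppm relative to the gas resonance
PPM_BANDS = {"rbc": (205.0, 218.0), "barrier": (190.0, 202.0), "gas": (-5.0, 5.0)}


class SpectralFitError(RuntimeError):
    """Raised when a spectrum cannot be decomposed (too few resolvable
    peaks, non-finite input, ...)."""


def wrap_phase_deg(phi: float) -> float:
    """Wrap a phase in degrees into (-180, 180]."""
    phi = (float(phi) + 180.0) % 360.0 - 180.0
    if phi == -180.0:
        phi = 180.0
    return phi


@dataclass
class ResonanceFit:
    """One fitted (or ground-truth) resonance."""

    amplitude: float
    freq_hz: float
    fwhm_hz: float
    phase_deg: float
    shift_ppm: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.fwhm_hz < 0:
            raise ValueError("fwhm_hz must be >= 0")
        self.phase_deg = wrap_phase_deg(self.phase_deg)


@dataclass
class SpectrumFitResult:
    gas: ResonanceFit
    barrier: ResonanceFit
    rbc: ResonanceFit
    rbc_barrier: float
    residual_norm: float
    converged: bool
    label_warnings: list[str] = field(default_factory=list)

    @property
    def resonances(self) -> tuple[ResonanceFit, ResonanceFit, ResonanceFit]:
        return (self.gas, self.barrier, self.rbc)


def ppm_shift(freq_hz: float, gas_freq_hz: float, spectrometer_freq_MHz: float) -> float:
    """Chemical shift in ppm relative to the gas resonance.

    Hz offset divided by the spectrometer frequency in MHz is ppm.
    """
    if spectrometer_freq_MHz <= 0:
        raise ValueError("spectrometer frequency must be positive")
    return (freq_hz - gas_freq_hz) / spectrometer_freq_MHz


def lorentzian_fid(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Forward model: sum of decaying complex exponentials.

    ``params`` is flat ``[A, f, w, phi_deg] * k``.
    """
    p = np.asarray(params, dtype=float).reshape(-1, 4)
    s = np.zeros_like(t, dtype=complex)
    for amp, f, w, phi in p:
        s += amp * np.exp(1j * math.radians(phi)) * np.exp((2j * np.pi * f - np.pi * w) * t)
    return s


def _peak_pick(fid: np.ndarray, dwell_s: float, n_resonances: int):
    """Initial (freq, amp, fwhm) guesses from the magnitude spectrum."""
    n = len(fid)
    spec = np.fft.fftshift(np.fft.fft(fid))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=dwell_s))
    mag = np.abs(spec)
    # broad dissolved lines sit ~1 kHz apart: allow close peaks, rank by
    # prominence so the tall narrow gas line does not mask them
    min_dist = max(2, int(0.004 * n))
    idx, props = signal.find_peaks(mag, distance=min_dist,
                                   prominence=0.002 * mag.max())
    if len(idx) < n_resonances:
        raise SpectralFitError(
            f"only {len(idx)} resolvable peaks found, need {n_resonances}; "
            "check SNR or reduce n_resonances"
        )
    order = np.argsort(props["prominences"])[::-1][:n_resonances]
    idx = idx[order]
    widths_bins = signal.peak_widths(mag, idx, rel_height=0.5)[0]
    df = freqs[1] - freqs[0]
    out = []
    for i, wb in zip(idx, widths_bins):
        fwhm = max(wb * df, df)
        # Lorentzian peak height = A / (pi * (fwhm/2)) per unit time; with a
        # DFT the peak magnitude is approximately A / (1 - exp(-pi*fwhm*dwell))
        amp = mag[i] * (1.0 - np.exp(-np.pi * fwhm * dwell_s))
        out.append((freqs[i], amp, fwhm))
    out.sort(key=lambda x: x[0])
    return out


def fit_spectrum(
    fid: np.ndarray,
    acq: AcqParams,
    n_resonances: int = 3,
    init: list[tuple[float, float, float]] | None = None,
) -> SpectrumFitResult:
    """Fit ``n_resonances`` complex Lorentzians to a time-domain FID.

    Parameters
    ----------
    fid : complex ndarray
        Time-domain signal sampled at ``acq.dwell_us``; at least 64 points.
    init : optional list of (freq_hz, amplitude, fwhm_hz)
        Overrides the automatic magnitude-spectrum peak picking.

    Returns
    -------
    SpectrumFitResult
        With components labelled by chemical-shift ordering
        (RBC > barrier > gas) and ppm shifts referenced to the gas line.
        For ``n_resonances != 3`` the labelled result is not defined; use
        :func:`fit_resonances` instead.
    """
    resonances, res_norm, ok = fit_resonances(fid, acq, n_resonances, init)
    if n_resonances != 3:
        raise ValueError("fit_spectrum labels gas/barrier/RBC and needs n_resonances=3")
    # gas is the most upfield line (most negative offset from the dissolved
    # carrier); RBC the most downfield
    resonances.sort(key=lambda r: r.freq_hz)
    gas, barrier, rbc = resonances
    warnings = []
    for name, r in (("gas", gas), ("barrier", barrier), ("rbc", rbc)):
        r.shift_ppm = ppm_shift(r.freq_hz, gas.freq_hz, acq.spectrometer_freq_MHz)
        lo, hi = PPM_BANDS[name]
        if not (lo <= r.shift_ppm <= hi):
            warnings.append(
                f"{name} shift {r.shift_ppm:.1f} ppm outside guard band [{lo}, {hi}]"
            )
    if barrier.amplitude == 0:
        raise SpectralFitError("barrier amplitude fitted to zero; ratio undefined")
    return SpectrumFitResult(
        gas=gas,
        barrier=barrier,
        rbc=rbc,
        rbc_barrier=rbc.amplitude / barrier.amplitude,
        residual_norm=res_norm,
        converged=ok,
        label_warnings=warnings,
    )


def fit_resonances(
    fid: np.ndarray,
    acq: AcqParams,
    n_resonances: int,
    init: list[tuple[float, float, float]] | None = None,
) -> tuple[list[ResonanceFit], float, bool]:
    """Unlabelled k-resonance complex time-domain fit."""
    fid = np.asarray(fid)
    if fid.ndim != 1 or len(fid) < 64:
        raise SpectralFitError("need a 1D FID with at least 64 points")
    if not np.all(np.isfinite(fid)):
        raise SpectralFitError("non-finite samples in FID")
    t = np.arange(len(fid)) * acq.dwell_s

    if init is None:
        guesses = _peak_pick(fid, acq.dwell_s, n_resonances)
    else:
        if len(init) != n_resonances:
            raise ValueError("init length must equal n_resonances")
        guesses = [(f, a, w) for (f, a, w) in init]

    # Variable projection: the complex amplitudes A_k e^{i phi_k} enter the
    # model linearly, so for any (f_k, w_k) they have a closed-form least-
    # squares solution.  The nonlinear search runs only over frequencies and
    # widths, which is markedly more robust than the full 4K-parameter fit.
    nyq = acq.nyquist_hz
    x0, lb, ub = [], [], []
    for f, _a, w in guesses:
        x0 += [f, max(min(w, 0.5 * nyq), 1.0)]
        lb += [-nyq, 1e-3]
        ub += [nyq, nyq]

    def basis(x):
        p = np.asarray(x).reshape(-1, 2)
        return np.exp((2j * np.pi * p[:, 0] - np.pi * p[:, 1])[None, :] * t[:, None])

    def solve_linear(x):
        B = basis(x)
        c, *_ = np.linalg.lstsq(B, fid, rcond=None)
        return B, c

    def resid(x):
        B, c = solve_linear(x)
        r = B @ c - fid
        return np.concatenate([r.real, r.imag])

    sol = optimize.least_squares(
        resid, x0, bounds=(lb, ub), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
        x_scale=[50.0, 20.0] * n_resonances,
        diff_step=1e-6,
    )
    _B, c = solve_linear(sol.x)
    fitted = []
    for (f, w), amp in zip(sol.x.reshape(-1, 2), c):
        fitted.append(ResonanceFit(
            amplitude=float(np.abs(amp)), freq_hz=float(f), fwhm_hz=float(w),
            phase_deg=wrap_phase_deg(math.degrees(np.angle(amp)))))
    res_norm = float(np.linalg.norm(sol.fun))
    return fitted, res_norm, bool(sol.success)


def steady_state_ratio(fits: list[SpectrumFitResult]) -> dict:
    """Mean and dispersion of RBC:barrier across repeat steady-state spectra.

    With a single spectrum the SD is reported as NaN and flagged.
    """
    if len(fits) == 0:
        raise ValueError("need at least one spectrum fit")
    ratios = np.array([f.rbc_barrier for f in fits], dtype=float)
    single = len(ratios) == 1
    return {
        "mean": float(ratios.mean()),
        "sd": float("nan") if single else float(ratios.std(ddof=1)),
        "n": len(ratios),
        "sd_defined": not single,
    }
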