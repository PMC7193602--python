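"""Acquisition parameters shared across the simulation and fitting stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json


@dataclass
class AcqParams:
    """MR acquisition settings for the dissolved-phase spectroscopy/imaging
    protocol on a 7 T small-animal system.

    Frequencies are for the 129Xe channel; the dissolved-phase carrier sits
    17.51 kHz above the gas resonance, i.e. close to the RBC resonance.
    The breath cycle is 250 ms inspiration / 250 ms breath-hold / 500 ms
    exhalation (60 breaths per minute).
    """

    spectrometer_freq_MHz: float = 83.06
    tr_ms: float = 15.0
    flip_gas_deg: float = 15.0
    flip_dissolved_deg: float = 20.0
    te_us: float = 248.0          # operational TE90 used in vivo
    dwell_us: float = 10.0        # 100 kHz spectral bandwidth
    n_points: int = 512
    nex: int = 200
    rays_total: int = 2073
    rays_per_breathhold: int | None = None
    breath_cycle_ms: tuple[float, float, float] = (250.0, 250.0, 500.0)
    t2star_dissolved_ms: float = 0.5
    t2star_gas_ms: float = 15.0
    carrier_offset_hz: float = 17510.0  # dissolved carrier relative to gas

    def __post_init__(self) -> None:
        for name in ("spectrometer_freq_MHz", "tr_ms", "flip_gas_deg",
                     "flip_dissolved_deg", "te_us", "dwell_us",
                     "t2star_dissolved_ms", "t2star_gas_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_points <= 0 or self.nex <= 0:
            raise ValueError("n_points and nex must be positive")
        self.breath_cycle_ms = tuple(float(p) for p in self.breath_cycle_ms)
        if any(p <= 0 for p in self.breath_cycle_ms):
            raise ValueError("breath cycle phases must be positive")

    @property
    def dwell_s(self) -> float:
        return self.dwell_us * 1e-6

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.dwell_s

    @property
    def breath_cycle_s(self) -> float:
        return sum(self.breath_cycle_ms) / 1000.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AcqParams":
        with open(path) as fh:
            d = json.load(fh)
        d["breath_cycle_ms"] = tuple(d["breath_cycle_ms"])
        if d.get("rays_per_breathhold") is not None:
            d["rays_per_breathhold"] = int(d["rays_per_breathhold"])
        return cls(**d)
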