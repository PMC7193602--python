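# xegas — quantitative hyperpolarized ¹²⁹Xe gas-exchange MRI analysis

Hyperpolarized ¹²⁹Xe MRI images inhaled xenon in three compartments of the
lung: the airspaces (gas phase), the alveolar septal tissue and plasma
("barrier", ~197 ppm downfield of the gas resonance), and red blood cells
(RBC, ~211 ppm). Because the RBC signal reports xenon that actually crossed
the air–blood interface, the ratio of RBC to barrier signal and the regional
RBC-transfer map are sensitive, non-invasive probes of gas-exchange
impairment — for example in preclinical rat models of pulmonary hypertension,
where reduced RBC transfer appears before histology shows vascular
remodeling.

`xegas` implements the complete analysis chain for such preclinical studies,
for imaging scientists who have (or want to simulate) reconstructed volumes
and dissolved-phase spectroscopy:

* **Spectral decomposition** (`xegas.spectro`): the complex FID is fit in the
  time domain to three Lorentzians,
  `s(t) = Σₖ Aₖ e^{iφₖ} e^{i2πfₖt} e^{−πwₖt}` (wₖ = FWHM in Hz), by variable
  projection; components are labelled gas/barrier/RBC by chemical-shift
  ordering and the amplitude ratio RBC:barrier is reported (≈0.47 in healthy
  control rats).
* **1-point Dixon separation** (`xegas.dixon`): at the echo time TE₉₀ the RBC
  and barrier magnetizations are 90° apart, so a single global phase rotation
  — solved in closed form from the spectroscopic ratio — puts barrier on the
  real channel and RBC on the imaginary channel of the complex dissolved
  image.
* **Quantitative maps** (`xegas.maps`): Otsu-based thoracic segmentation,
  rigid registration (SimpleITK), flip-angle/T2* signal correction
  (divide by `sin α · e^{−TE/T2*}`), top-percentile ventilation
  normalisation to [0, 1], and voxelwise barrier:gas and RBC:gas ratio maps.
* **Box-Cox reference binning** (`xegas.binning`): healthy-cohort histograms
  are Gaussianised with a one-parameter Box-Cox transform; thresholds at
  μ ± k·σ in the transformed domain are mapped back to define 6 bins
  (ventilation, RBC:gas) or 8 bins (barrier:gas), yielding VDP,
  low-ventilation %, RBC_defect % and barrier_high %.
* **Morphometry** (`xegas.morphometry`): medial wall thickness and
  medial-area ratio of 20–80 µm muscular arteries from per-vessel
  perimeter/area tables (r = P/2π).
* **Cohort statistics** (`xegas.stats`): exact-permutation Mann-Whitney U
  (enumeration with mid-rank ties for combined n ≤ 20), Kruskal-Wallis with
  gated post-hoc pairs, Pearson correlation; α = 0.05, uncorrected.
* **Protocol arithmetic** (`xegas.acquisition`): RF-limited effective T1
  (−TR/ln cos α), TE₉₀ = 1/(4Δf), scan-time/resolution bookkeeping, and the
  small-tip off-resonance profile of the selective sinc pulse.
* **Digital phantom generator** (`xegas.phantom`): because no public
  preclinical dataset exists, a rat-thorax phantom (ellipsoidal lung pair,
  heart notch, airways, disease lesions in their characteristic zones) plus
  FID and cohort generators make every stage testable end to end.

The numbered scripts in `analysis/` run the study workflow over a synthetic
cohort: `01_simulate_cohort.py`, `02_fit_spectra.py`,
`03_gas_exchange_maps.py`, `04_cohort_stats.py`, `05_protocol_check.py`.
Each writes small CSV/JSON tables under `results/`.

## Worked example

```python
import numpy as np
from xegas.params import AcqParams
from xegas.phantom import PhantomConfig, make_phantom, simulate_measurement
from xegas.pipeline import build_references, process_subject
from xegas.spectro import fit_spectrum

# five healthy animals define the reference distributions
healthy = [simulate_measurement(make_phantom(PhantomConfig(seed=s)))
           for s in range(5)]
refs = build_references(healthy)

sub = healthy[0]
fit = fit_spectrum(sub.fid, sub.acq)
res = process_subject(sub, refs)
print(f"spectroscopic RBC:barrier {fit.rbc_barrier:.3f} "
      f"(truth {sub.truth.true_rbc_barrier:.2f})")
print(f"shifts: RBC {fit.rbc.shift_ppm:.1f} ppm, "
      f"barrier {fit.barrier.shift_ppm:.1f} ppm")
md = np.nanmedian(res.rbc_to_gas.data) / np.nanmedian(res.barrier_to_gas.data)
print(f"median-map RBC:barrier {md:.3f}")
print({k: round(v, 2) for k, v in res.metrics.items()})
```

prints

```
spectroscopic RBC:barrier 0.468 (truth 0.47)
shifts: RBC 210.5 ppm, barrier 196.9 ppm
median-map RBC:barrier 0.467
{'vdp_pct': 2.39, 'low_vent_pct': 14.76, 'rbc_defect_pct': 2.36, 'barrier_high_pct': 2.49}
```

The spectroscopic ratio matches the generator truth to better than 1%, the
Dixon/map route agrees to ~0.5%, and a defect-free animal shows the ~2.3%
bin-1 floor expected of a Gaussianised reference (Φ(−2)), not zero. A
ventilation defect carved over 10% of the lung raises VDP by ~10 points.

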