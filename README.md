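# cnetvna

Single-molecule analysis of distance-dependent energy transfer from organic
fluorophores to single-walled carbon nanotubes (SWCNTs).

Semiconducting SWCNTs are one-dimensional excitonic quenchers: a dye held at
height *d* above the tube surface loses a fraction

    eta(d) = 1 / (1 + (d/d0)^n)

of its excitations to the tube, where *d0* is the characteristic distance of
50% energy transfer and *n* is set by the acceptor's dimensionality — *n* = 6
for a point acceptor (classical FRET), *n* = 5 for a line of transition
dipoles such as a nanotube, *n* = 4 for a plane, *n* = 3 for a bulk metal.
Experimentally, *eta* is read out from single-molecule fluorescence lifetimes
as `eta = 1 - tau/tau0`, and *d* is set by rigid dsDNA duplexes of 12–24 base
pairs (0.34 nm/bp) standing on the tube, plus a ~1.1 nm dye/linker extension.

The package is aimed at single-molecule spectroscopists and modellers who
want a tested, reusable version of that analysis chain:

* **`cnetvna.synthdata`** — simulators with ground truth: TCSPC photon
  streams (Gaussian IRF, Poisson background, single-step photobleaching),
  lifetime cohorts from Gaussian subpopulations, a geometric forward model
  (tilt → height → efficiency → lifetime), rigid duplex-on-cylinder
  trajectories, and toy spectra.
* **`cnetvna.lifetimes`** — intensity traces, Poisson changepoint detection
  of photobleaching steps (single-step molecules only are accepted), TCSPC
  decay histograms, and a monoexponential maximum-likelihood fit with
  analytic IRF reconvolution (`MonoexponentialFitter`, scikit-learn style).
* **`cnetvna.populations`** — Gaussian-mixture decomposition of lifetime
  histograms with component widths constrained to 0.05–0.5 ns and AIC-based
  selection of the component count (`LifetimeMixture`), plus physical labels
  (unquenched / perpendicular / tilted).
* **`cnetvna.cnet_model`** — efficiency/distance conversions, the one-
  parameter d^-n scaling fit (`DistanceScalingLaw`), SSR comparison across
  exponents, the point-to-line transfer-rate integral that grounds the d^-5
  law, and the Förster overlap/radius-ratio calculation.
* **`cnetvna.geometry`** — duplex tilt angles and 5'-tip-to-surface distances
  from multi-frame XYZ trajectories (MD formats via an MDAnalysis adapter).
* **`cnetvna` CLI** — `simulate`, `fit-lifetimes`, `fit-populations`,
  `fit-cnet`, `geometry`, `overlap`, and `run` for the full pipeline with a
  YAML config and a reproducibility manifest.

## Worked example

Fit the distance law to five quenching points (duplex heights 4.6–7.7 nm
from trajectory means, + 1.1 nm linker) generated from a d0 = 7.4 nm, n = 5
law with 3% efficiency noise:

```python
import numpy as np
from cnetvna.cnet_model import QuenchingPoint, cnet_efficiency, compare_exponents

d = np.array([4.6, 5.0, 5.8, 6.2, 7.7]) + 1.1
rng = np.random.default_rng(1)
eta = np.clip(cnet_efficiency(d, 7.4, 5) + rng.normal(0, 0.03, 5), 0, 1)
pts = [QuenchingPoint(f"{b}bp", di, ei, 0.03)
       for b, di, ei in zip((12, 15, 18, 20, 24), d, eta)]
print(compare_exponents(pts).round(4).to_string(index=False))
```

prints

```
 exponent  d0_nm  d0_se_nm    ssr  rank
        5 7.4316    0.0842 0.0030     1
        6 7.3582    0.1075 0.0065     2
        4 7.5451    0.1687 0.0080     3
        3 7.7455    0.3856 0.0240     4
```

The d^-5 law attains the smallest sum of squared residuals and recovers the
generating characteristic distance (7.43 ± 0.08 nm vs 7.4 nm true); the
neighbouring exponents fit measurably worse.  The same table is produced from
the shell by `cnetvna fit-cnet --points quenching_points.csv`, and
`cnetvna run --seed 1 --out out/` executes the whole synthetic study
(photon streams → lifetimes → populations → scaling fits).

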