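# chambervol

In-vivo volumetry of the anterior and posterior chambers of the mouse eye
from multi-view anterior-segment OCT, with the downstream re-analysis of
aqueous humor dynamics that the chamber volumes enable.

## The problem

Aqueous inflow in the mouse is measured by fluorophotometry through

&nbsp;&nbsp;&nbsp;&nbsp; *Q* = (d ln *C*<sub>c</sub>/d*t*) · (*V*<sub>a</sub> + (*C*<sub>c</sub>/*C*<sub>a</sub>)·*V*<sub>c</sub>),

where *V*<sub>a</sub> is the anterior-chamber volume. Mouse studies have
assumed *V*<sub>a</sub> ≈ total aqueous volume (5.9 µL), as in humans —
but the mouse lens is proportionally enormous and the posterior chamber
holds a comparable share of the aqueous. If the true volume is
*V*<sub>a</sub>\*, the reported inflow must be rescaled by

&nbsp;&nbsp;&nbsp;&nbsp; *Q*\*/*Q* = (*V*<sub>a</sub>\* + (*C*<sub>c</sub>/*C*<sub>a</sub>)·*V*<sub>c</sub>) / (*V*<sub>a</sub> + (*C*<sub>c</sub>/*C*<sub>a</sub>)·*V*<sub>c</sub>),

which propagates through Goldmann's balance
*Q* − *Q*<sub>u</sub> = *C*·(IOP − EVP) into the fraction of aqueous
leaving by the pressure-independent (unconventional) route.

Measuring both chambers in vivo requires (1) montaging eight OCT
sub-volumes acquired around the eye with the beam normal to the limbus
(surface point clouds + vessel-branch landmarks + MSAC, chained into a
common frame and intensity-fused), (2) segmenting each chamber per B-scan
from interpolated guide points (deterministic seeded region growing here),
and (3) correcting the posterior chamber's posterior boundary, because the
anterior hyaloid membrane cannot be imaged: an axis-aligned ellipsoid is
fitted to the anterior lens surface and the chamber is extended to (and
cut at) the equatorial plane through the lens center.

The package implements this pipeline end-to-end and validates it on
synthetic eyes and phantoms with analytically known volumes: a parametric
axisymmetric mouse eye (AC 1.533 µL, PC 1.719 µL, AC fraction 0.47 by
construction) rasterized into overlapping tilted views with speckle, and a
3 mm hemispherical phantom with a 2.99 µL cavity. It is aimed at
researchers building or auditing OCT volumetry pipelines and at anyone who
needs the corrected AHD arithmetic.

## Worked example

Full synthetic study (simulate → register/fuse → segment → correct →
quantify → AHD), noiseless, default 160³ views:

```python
from chambervol.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(preset="eye", seed=1729, noise=False))
print(res["report"])
```

prints (values in µL and mm):

```
ac_volume_ul              1.5193   # truth 1.5330  (-0.9 %)
pc_volume_ul              1.7536   # truth 1.7188  (+2.0 %)
pc_volume_uncorrected_ul  0.9384   # the raw segmentation stops at a
                                   # spurious lens-to-ciliary interface:
                                   # -45 % before the hyaloid correction
total_volume_ul           3.2729
ac_pc_ratio               0.8664
ac_fraction               0.4642
angle_apex_separation_mm  2.8371   # truth 2.8700
```

The uncorrected value shows the failure mode the correction exists for;
after extending the chamber to the lens-center plane the estimate is
within 2 % of the analytic truth.

The AHD chain from the published mouse inputs
(*Q* = 90 nl/min, *V*<sub>a</sub> = 5.9 µL, *V*<sub>c</sub> = 0.5 µL,
*C*<sub>c</sub>/*C*<sub>a</sub> = 4.0, *C* = 5.89 nl/min/mmHg at an
8 mmHg pressure drop):

```bash
chambervol ahd --q 90 --va 5.9 --vc 0.5 --ratio 4.0 \
               --facility 5.89 --dp 8
```

reports correction factors 0.45–0.61 for true AC volumes of 1.55–2.8 µL,
corrected inflow *Q*\* = 40–55 nl/min against a conventional outflow of
47 nl/min, hence an unconventional outflow fraction of 0–14 % — where the
uncorrected inflow would have implied 48 %.

Other subcommands: `chambervol simulate|fuse|segment|correct|quantify|run-all`
(see `--help`); `run-all --preset phantom` reproduces the phantom
validation, recovering the 2.99 µL design cavity as 2.9845 µL (0.18 %
relative error) at the default grid.

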