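# plumewake

Wind-rotated satellite NO₂ composites around point facilities, gridded
truck traffic, and demographic exposure disparities — with a synthetic
scenario generator so every stage is validated by parameter recovery.

## The problem

Warehouses and similar logistics facilities attract heavy-duty truck
traffic whose NOx emissions appear as tropospheric-column NO₂ in
satellite retrievals, typically peaking a few kilometers *downwind* of
the facility. Quantifying that signal, linking it to facility
characteristics (loading docks, parking, co-located facilities) and to
observed truck activity, and asking who lives near these facilities,
requires a chain of spatial and statistical operations that is easy to
get subtly wrong. `plumewake` implements that chain as a tested
library for researchers in environmental health and exposure
assessment.

## The core statistic

Daily NO₂ fields on a 0.01° (~1 km) grid are sampled in a ±R-cell
window around each facility (R = 7). Each daily window is rotated into
a common wind frame in which the prevailing wind (the vector-mean flow
over the satellite-overpass hours, interpolated to the facility) blows
toward +x, then averaged per facility and across facilities. On the composite
C the **enhancement** is

    enhancement % = 100 · (max C − ū) / ū

where ū is the mean over the upwind (left) edge column, and the
**displacement** is the downwind component of the peak offset in km.
Population-weighted exposure per demographic subgroup g is

    NO₂_pw(g) = Σᵢ NO₂ᵢ · popᵢ(g) / Σᵢ popᵢ(g)

over facilities i, with NO₂ᵢ the spatial mean of facility i's window
and popᵢ(g) the subgroup population of its census tract. Truck
activity is VKT = AADT × segment length, gridded by exact
length-in-cell apportionment and regressed on facility characteristics
within decile bins of total near-facility VKT.

## Worked example

```python
import plumewake as pw
from plumewake import synthetic as ps

cfg = ps.ScenarioConfig(domain_bounds=(0, 0, 1.5, 1.5), n_facilities=40,
                        n_days=10, tract_nx=8, tract_ny=8, seed=0)
scn = ps.generate_scenario(cfg)
res = pw.PlumeCompositeModel(scn.no2_daily, scn.facilities, scn.winds).fit()
print(res.summary())
```

prints

```
Wind-rotated NO2 composite results
==================================
facilities:            40
facility-days used:    400
calm facility-days:    0
window radius (cells): 7
upwind-edge mean:      4.4747
composite peak:        5.3170
enhancement:           18.8 %
peak offset (E, N):    (5, 0)
downwind displacement: 5.0 km
```

The scenario planted Gaussian plumes displaced 4 km downwind with a
noise-free composite enhancement of 18.5% (`scn.truth.enhancement_pct`);
from 10 noisy, 30%-masked days the composite recovers 18.8% with the
peak one cell off — the small-sample wobble the full-size recovery
test quantifies. `TruckTrafficModel` and `ExposureDisparityModel`
follow the same fit/results pattern for the traffic regressions and
the demographic tables, and every `Results` object has a `summary()`.

A complete run (simulate → composite → enhance → traffic → equity →
report) is one command:

```sh
plumewake run-all --outdir demo_run --seed 0
```

which writes tidy CSV tables, `report.md`/`report.json` and a
`manifest.json` with the config hash, seed, versions and timings.

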