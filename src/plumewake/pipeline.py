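"""End-to-end orchestration: simulate -> composite -> traffic -> equity -> report.

A run is driven by a single :class:`RunConfig` (usually loaded from
YAML) containing either a simulation block (a :class:`ScenarioConfig`)
or paths to previously written scenario files — never neither, never
both.  Every run writes tidy CSV tables, a human-readable markdown
report, a JSON report with the same numbers, and a manifest recording
the config hash, seed, library versions, stage timings, accumulated
warnings and every output file.  Identical config + seed yields
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import composite as pcomposite
from . import equity as pequity
from . import stats as pstats
from . import synthetic as psynth
from . import traffic as ptraffic
from .composite import PlumeCompositeModel
from .equity import ExposureDisparityModel
from .traffic import TruckTrafficModel


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    simulation: dict | None = None  # ScenarioConfig keyword arguments
    inputs: dict | None = None  # paths to scenario files
    radius: int = 7
    qa_threshold: float = 0.75
    edge_cells: list | None = None
    hours: tuple = pcomposite.DEFAULT_OVERPASS_HOURS
    cell_km: float = 1.0
    density_mode: str = "fixed"
    n_boot: int = 1000
    seed: int = 0
    write_rasters: bool = False

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulation block or real-input paths must be given"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def canonical(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["hours"] = list(self.hours)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def demo_config(outdir, seed: int = 0) -> RunConfig:
    """A small scenario that runs end to end in well under a minute."""
    return RunConfig(
        outdir=str(outdir),
        simulation=dict(
            domain_bounds=(0.0, 0.0, 1.5, 1.5),
            n_facilities=40,
            n_days=10,
            tract_nx=8,
            tract_ny=8,
            seed=seed,
        ),
        n_boot=200,
        seed=seed,
    )


@dataclass
class PipelineResult:
    """Tables, report dict and manifest of a completed run."""

    tables: dict
    report: dict
    manifest: dict
    outdir: Path


def _load_scenario(cfg: RunConfig) -> psynth.Scenario:
    if cfg.simulation is not None:
        sim = dict(cfg.simulation)
        sim.setdefault("seed", cfg.seed)
        if "domain_bounds" in sim:
            sim["domain_bounds"] = tuple(sim["domain_bounds"])
        return psynth.generate_scenario(psynth.ScenarioConfig(**sim))
    raise NotImplementedError(
        "real-input runs require the scenario files written by write_scenario; "
        "use plumewake.synthetic.read_* and the library API directly"
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute all stages in order and write the result bundle.

    Any stage failure raises with the stage name attached.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    collected: list[str] = []
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            t0 = time.time()
            scn = _load_scenario(cfg)
            timings[stage] = round(time.time() - t0, 3)

            stage = "composite"
            t0 = time.time()
            model = PlumeCompositeModel(
                scn.no2_daily, scn.facilities, scn.winds,
                radius=cfg.radius, hours=cfg.hours,
                edge_cells=cfg.edge_cells, cell_km=cfg.cell_km,
            )
            comp_res = model.fit()
            timings[stage] = round(time.time() - t0, 3)

            stage = "enhance"
            t0 = time.time()
            tracts_ix = scn.tracts.set_index("tract_id")
            dens_class = pequity.density_class(scn.tracts, mode=cfg.density_mode)
            fac_density = scn.facilities["tract_id"].map(
                pd.Series(dens_class.to_numpy(), index=scn.tracts["tract_id"])
            )
            labels = dict(zip(scn.facilities["id"], fac_density))
            strat = comp_res.stratified(labels)
            total_emis = psynth.total_emissions(scn.emissions)
            iy, ix = scn.grid.cell_of(
                scn.facilities["lon"].to_numpy(), scn.facilities["lat"].to_numpy()
            )
            sector_stack = np.stack([scn.emissions[s].values for s in psynth.SECTORS])
            dominant = np.array(psynth.SECTORS)[
                np.argmax(sector_stack[:, iy, ix], axis=0)
            ]
            strat_sector = comp_res.stratified(dict(zip(scn.facilities["id"], dominant)))
            strat_sector["kind"] = "dominant_sector"
            strat["kind"] = "density_class"
            enh_overall = pd.DataFrame([comp_res.enhancement_.as_dict()])
            tables["enhancement"] = enh_overall
            tables["enhancement_stratified"] = pd.concat(
                [strat, strat_sector], ignore_index=True
            )
            timings[stage] = round(time.time() - t0, 3)

            stage = "traffic"
            t0 = time.time()
            ref = (
                (scn.roads["aadt_total"] * scn.roads["length_km"])
                .groupby(scn.roads["state"]).sum().to_dict()
            )
            roads = ptraffic.scale_to_reference(scn.roads, ref)
            vkt_total, vkt_truck = ptraffic.rasterize_vkt(roads, scn.grid)
            near = ptraffic.near_facility_traffic(
                vkt_total, vkt_truck, scn.facilities, cfg.radius
            )
            traffic_res = TruckTrafficModel(scn.facilities, near).fit()
            tables["traffic_slopes"] = traffic_res.table()
            timings[stage] = round(time.time() - t0, 3)

            stage = "equity"
            t0 = time.time()
            fac_no2 = pcomposite.facility_mean_no2(
                scn.no2_daily, scn.facilities, cfg.radius
            )
            eq_res = ExposureDisparityModel(
                scn.tracts, scn.facilities, fac_no2
            ).fit()
            tables["equity_disparity"] = eq_res.disparity
            tables["pw_exposure"] = eq_res.pw_exposure
            dens = (
                tracts_ix.loc[scn.facilities["tract_id"], "population_total"]
                / tracts_ix.loc[scn.facilities["tract_id"], "area_km2"]
            ).to_numpy()
            hisp = (
                tracts_ix.loc[scn.facilities["tract_id"], "pop_hispanic"]
                / tracts_ix.loc[scn.facilities["tract_id"], "population_total"].clip(lower=1)
            ).to_numpy()
            flags = pd.DataFrame({
                "loading_docks_missing": scn.facilities["loading_docks"].isna(),
                "parking_spaces_missing": scn.facilities["parking_spaces"].isna(),
            })
            covs = pd.DataFrame({
                "no2_near": fac_no2.reindex(scn.facilities["id"]).to_numpy(),
                "total_vkt": near.set_index("id")["total_vkt"].reindex(scn.facilities["id"]).to_numpy(),
                "truck_vkt": near.set_index("id")["truck_vkt"].reindex(scn.facilities["id"]).to_numpy(),
                "population_density": dens,
                "hispanic_share": hisp,
            })
            tables["missingness_correlation"] = pstats.missingness_correlation(flags, covs)
            timings[stage] = round(time.time() - t0, 3)

            collected = [str(w.message) for w in wrec]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "report"
    rep = build_report(tables, truth=scn.truth)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    (out / "report.json").write_text(json.dumps(rep, indent=2, sort_keys=True))
    (out / "report.md").write_text(render_report_md(rep))
    if cfg.write_rasters:
        psynth.write_scenario(scn, out / "scenario", write_rasters=True)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "plumewake": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": timings,
        "warnings": collected,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(tables=tables, report=rep, manifest=manifest, outdir=out)


def build_report(tables: dict, truth=None) -> dict:
    """Headline quantities of a result bundle as one JSON-able dict.

    Missing tables are flagged as gaps rather than fabricated.
    """
    rep: dict = {"gaps": []}
    if "enhancement" in tables and len(tables["enhancement"]):
        e = tables["enhancement"].iloc[0]
        rep["enhancement_pct"] = float(e["enhancement_pct"])
        rep["displacement_km"] = float(e["displacement_km"])
        rep["upwind_edge_mean"] = float(e["upwind_edge_mean"])
        rep["composite_peak"] = float(e["peak_value"])
    else:
        rep["gaps"].append("enhancement")
    if "enhancement_stratified" in tables:
        rep["enhancement_by_stratum"] = {
            f"{r.kind}:{r.stratum}": float(r.enhancement_pct)
            for r in tables["enhancement_stratified"].itertuples()
        }
    else:
        rep["gaps"].append("enhancement_stratified")
    if "traffic_slopes" in tables:
        t = tables["traffic_slopes"]
        rep["mean_truck_vkt_slope"] = {
            c: float(t.loc[(t["characteristic"] == c) & t["defined"], "slope"].mean())
            for c in t["characteristic"].unique()
        }
    else:
        rep["gaps"].append("traffic_slopes")
    if "equity_disparity" in tables:
        d = tables["equity_disparity"]
        any_rows = d[d["stratum"] == "Any"]
        rep["demographic_relative_difference_pct"] = {
            r.subgroup: float(r.relative_difference_pct) for r in any_rows.itertuples()
        }
    else:
        rep["gaps"].append("equity_disparity")
    if "pw_exposure" in tables:
        rep["pw_no2_relative_difference_pct"] = {
            r.subgroup: float(r.relative_difference_pct)
            for r in tables["pw_exposure"].itertuples()
        }
    else:
        rep["gaps"].append("pw_exposure")
    if truth is not None:
        rep["truth"] = {
            "enhancement_pct": float(truth.enhancement_pct),
            "displacement_km": float(truth.displacement_km),
            "vkt_slopes": {k: float(v) for k, v in truth.vkt_slopes.items()},
        }
    return rep


def render_report_md(rep: dict) -> str:
    """Markdown rendering carrying exactly the numbers of the JSON report."""
    lines = ["# Near-facility NO2 / traffic / equity report", ""]
    if "enhancement_pct" in rep:
        lines += [
            "## Composite enhancement",
            f"- enhancement: {rep['enhancement_pct']} %",
            f"- downwind peak displacement: {rep['displacement_km']} km",
            f"- upwind-edge mean: {rep['upwind_edge_mean']}",
            f"- composite peak: {rep['composite_peak']}",
            "",
        ]
    if "enhancement_by_stratum" in rep:
        lines.append("## Enhancement by stratum")
        for k, v in rep["enhancement_by_stratum"].items():
            lines.append(f"- {k}: {v} %")
        lines.append("")
    if "mean_truck_vkt_slope" in rep:
        lines.append("## Mean truck-VKT slopes across total-VKT deciles")
        for k, v in rep["mean_truck_vkt_slope"].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    if "demographic_relative_difference_pct" in rep:
        lines.append("## Demographic composition of facility tracts vs national medians")
        for k, v in rep["demographic_relative_difference_pct"].items():
            lines.append(f"- {k}: {v} %")
        lines.append("")
    if "pw_no2_relative_difference_pct" in rep:
        lines.append("## Population-weighted NO2 relative differences")
        for k, v in rep["pw_no2_relative_difference_pct"].items():
            lines.append(f"- {k}: {v} %")
        lines.append("")
    if rep.get("truth"):
        lines.append("## Scenario truth (synthetic runs)")
        lines.append(f"- true enhancement: {rep['truth']['enhancement_pct']} %")
        lines.append(f"- true displacement: {rep['truth']['displacement_km']} km")
        lines.append("")
    if rep.get("gaps"):
        lines.append("## Gaps")
        for g in rep["gaps"]:
            lines.append(f"- missing: {g}")
    return "\n".join(lines)
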