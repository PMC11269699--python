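"""Demographic exposure disparities around facilities.

Census tracts carry a total population and six non-mutually-exclusive
race/ethnicity subgroup populations (white; non-Hispanic; Hispanic;
Black or African American; Asian, Native Hawaiian, or Pacific Islander;
some other race or two or more races).  The module compares the
demographic composition of facility-hosting tracts against the national
tract-median composition (overall and by clustering decile, with a
two-sample KS test), and computes population-weighted near-facility NO2
per subgroup,

    NO2_pw = sum_i(NO2_i * pop_i) / sum_i(pop_i),

over facilities i, where pop_i is the subgroup population of facility
i's tract, reported as a percent difference against the total-population
value.  Per the study design, no significance test is attached to the
population-weighted comparison (it compares two single numbers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as pstats

SUBGROUPS = (
    "white",
    "non_hispanic",
    "hispanic",
    "black",
    "asian_nhpi",
    "other",
)

# fixed population-density class bounds, people per km^2
DENSITY_LOW_MAX = 267.0
DENSITY_MED_MAX = 1501.0


def density_class(tracts: pd.DataFrame, mode: str = "fixed") -> pd.Series:
    """Classify tracts into Low/Medium/High population density.

    Fixed mode uses the bounds <267 (Low), 267-1501 (Medium), >1501
    (High) people/km² with boundaries assigned upward; tertile mode
    computes the 1/3 and 2/3 empirical density quantiles of the supplied
    tracts.
    """
    if (tracts["area_km2"] <= 0).any():
        raise ValueError("tract areas must be positive")
    dens = tracts["population_total"] / tracts["area_km2"]
    if mode == "fixed":
        lo, hi = DENSITY_LOW_MAX, DENSITY_MED_MAX
    elif mode == "tertile":
        lo, hi = np.quantile(dens, [1 / 3, 2 / 3])
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    out = pd.Series("Medium", index=tracts.index, name="density_class")
    out[dens < lo] = "Low"
    out[dens > hi] = "High"
    return out


def subgroup_share(tracts: pd.DataFrame, subgroup: str) -> pd.Series:
    pop = tracts["population_total"].to_numpy(dtype=float)
    sub = tracts[f"pop_{subgroup}"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(pop > 0, sub / pop, np.nan)
    return pd.Series(share, index=tracts.index, name=f"share_{subgroup}")


def clustering_decile_strata(tracts: pd.DataFrame) -> dict:
    """Strata of facility-hosting tracts: 'Any' plus clustering deciles.

    Deciles are deciles of the per-tract facility count among tracts
    that contain at least one facility (ties to the lower bin).
    """
    hosting = tracts.index[tracts["facility_count"] >= 1]
    strata = {"Any": hosting}
    if len(hosting) >= 10:
        bins = pstats.assign_deciles(tracts.loc[hosting, "facility_count"].to_numpy(float))
        for d in range(10):
            idx = hosting[bins == d]
            # heavy ties can leave middle deciles empty; skip those
            if len(idx):
                strata[f"decile_{d + 1}"] = idx
    return strata


def demographic_disparity(
    tracts: pd.DataFrame,
    subgroups=SUBGROUPS,
    strata: dict | None = None,
) -> pd.DataFrame:
    """Relative difference of stratum vs national median subgroup shares.

    For each subgroup and each stratum of tracts (default: 'Any'
    facility-hosting tract plus clustering deciles), reports
    100*(median share in stratum - national median share)/(national
    median share), the two-sample KS statistic between the stratum and
    national share distributions, and its significance at 0.05.
    Single-tract strata are flagged low-n.
    """
    if strata is None:
        strata = clustering_decile_strata(tracts)
    rows = []
    for sg in subgroups:
        share = subgroup_share(tracts, sg)
        national = share.dropna()
        nat_med = float(national.median())
        for name, idx in strata.items():
            s = share.loc[idx].dropna()
            if len(s) == 0:
                warnings.warn(f"stratum {name!r} empty for {sg}; omitted", stacklevel=2)
                continue
            if nat_med == 0:
                rows.append({"subgroup": sg, "stratum": name, "n": len(s),
                             "relative_difference_pct": np.nan, "ks_stat": np.nan,
                             "ks_p": np.nan, "significant": False, "defined": False,
                             "low_n": len(s) < 2})
                continue
            ks, p = pstats.ks_two_sample(s.to_numpy(), national.to_numpy())
            rows.append({
                "subgroup": sg,
                "stratum": name,
                "n": len(s),
                "relative_difference_pct": 100.0 * (float(s.median()) - nat_med) / nat_med,
                "ks_stat": ks,
                "ks_p": p,
                "significant": bool(p < pstats.ALPHA),
                "defined": True,
                "low_n": len(s) < 2,
            })
    return pd.DataFrame(rows)


def population_weighted_no2(facility_no2, facility_pops) -> float:
    """Population-weighted mean of per-facility NO2.

    ``facility_no2`` and ``facility_pops`` are aligned vectors over
    facilities; the result is sum(no2*pop)/sum(pop).
    """
    no2 = np.asarray(facility_no2, dtype=float)
    pop = np.asarray(facility_pops, dtype=float)
    if no2.shape != pop.shape:
        raise ValueError("NO2 and population vectors must align")
    if (pop < 0).any():
        raise ValueError("negative populations")
    tot = pop.sum()
    if tot <= 0:
        raise ValueError("total population is zero: weighted mean undefined")
    return float(np.sum(no2 * pop) / tot)


def pw_exposure_table(
    facilities: pd.DataFrame,
    tracts: pd.DataFrame,
    facility_no2: pd.Series,
    subgroups=SUBGROUPS,
) -> pd.DataFrame:
    """Population-weighted NO2 per subgroup with percent difference vs the
    total-population value.  Facility populations come from the hosting
    tract (column ``tract_id`` links facilities to ``tracts`` rows)."""
    t = tracts.set_index("tract_id") if "tract_id" in tracts.columns else tracts
    fac = facilities.set_index("id")
    no2 = facility_no2.reindex(fac.index).to_numpy(dtype=float)
    pops_total = t.loc[fac["tract_id"], "population_total"].to_numpy(dtype=float)
    base = population_weighted_no2(no2, pops_total)
    rows = [{"subgroup": "total", "no2_population_weighted": base,
             "relative_difference_pct": 0.0}]
    for sg in subgroups:
        pops = t.loc[fac["tract_id"], f"pop_{sg}"].to_numpy(dtype=float)
        val = population_weighted_no2(no2, pops)
        rows.append({
            "subgroup": sg,
            "no2_population_weighted": val,
            "relative_difference_pct": 100.0 * (val - base) / base,
        })
    return pd.DataFrame(rows)


def state_level_exposure(
    facilities: pd.DataFrame,
    tracts: pd.DataFrame,
    facility_no2: pd.Series,
    subgroups=SUBGROUPS,
) -> pd.DataFrame:
    """Per-state population-weighted exposure table.

    States with no facilities are omitted with a warning.
    """
    t = tracts.set_index("tract_id") if "tract_id" in tracts.columns else tracts
    fac = facilities.copy()
    fac["state"] = t.loc[fac["tract_id"], "state"].to_numpy()
    frames = []
    for state in sorted(t["state"].unique()):
        sel = fac[fac["state"] == state]
        if len(sel) == 0:
            warnings.warn(f"state {state!r} has no facilities; omitted", stacklevel=2)
            continue
        tab = pw_exposure_table(sel, tracts, facility_no2, subgroups)
        tab.insert(0, "state", state)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def leave_states_out(
    facilities: pd.DataFrame,
    tracts: pd.DataFrame,
    facility_no2: pd.Series,
    states_to_drop,
    subgroups=SUBGROUPS,
) -> pd.DataFrame:
    """National population-weighted table after excluding named states."""
    t = tracts.set_index("tract_id") if "tract_id" in tracts.columns else tracts
    fac = facilities.copy()
    fac["state"] = t.loc[fac["tract_id"], "state"].to_numpy()
    keep = fac[~fac["state"].isin(set(states_to_drop))]
    if len(keep) == 0:
        raise ValueError("no facilities left after the leave-out")
    return pw_exposure_table(keep, tracts, facility_no2, subgroups)


class ExposureDisparityModel:
    """Demographic siting and exposure disparity model.

    Parameters
    ----------
    tracts : DataFrame
        One row per tract with ``tract_id``, ``state``, ``area_km2``,
        ``population_total``, ``pop_<subgroup>`` columns and
        ``facility_count``.
    facilities : DataFrame
        One row per facility with ``id`` and ``tract_id``.
    facility_no2 : Series
        Per-facility near-facility NO2 (spatial mean of the ±R window),
        indexed by facility id.
    """

    def __init__(
        self,
        tracts: pd.DataFrame,
        facilities: pd.DataFrame,
        facility_no2: pd.Series,
        subgroups=SUBGROUPS,
    ) -> None:
        self.tracts = tracts
        self.facilities = facilities
        self.facility_no2 = facility_no2
        self.subgroups = tuple(subgroups)

    def fit(self) -> "ExposureDisparityResults":
        disparity = demographic_disparity(self.tracts, self.subgroups)
        pw = pw_exposure_table(self.facilities, self.tracts, self.facility_no2, self.subgroups)
        return ExposureDisparityResults(self, disparity, pw)


@dataclass
class ExposureDisparityResults:
    model: ExposureDisparityModel
    disparity: pd.DataFrame
    pw_exposure: pd.DataFrame

    def state_table(self) -> pd.DataFrame:
        return state_level_exposure(
            self.model.facilities, self.model.tracts,
            self.model.facility_no2, self.model.subgroups,
        )

    def leave_out(self, states) -> pd.DataFrame:
        return leave_states_out(
            self.model.facilities, self.model.tracts,
            self.model.facility_no2, states, self.model.subgroups,
        )

    def summary(self) -> str:
        any_rows = self.disparity[self.disparity["stratum"] == "Any"]
        lines = [
            "Demographic disparity (facility tracts vs national medians)",
            "subgroup        rel.diff %   KS stat     KS p",
        ]
        for row in any_rows.itertuples():
            sig = "*" if row.significant else " "
            lines.append(
                f"{row.subgroup:14s} {row.relative_difference_pct:9.1f}  {row.ks_stat:8.3f}  {row.ks_p:9.3g}{sig}"
            )
        lines.append("")
        lines.append("Population-weighted near-facility NO2")
        lines.append("subgroup        NO2_pw       rel.diff %")
        for row in self.pw_exposure.itertuples():
            lines.append(
                f"{row.subgroup:14s} {row.no2_population_weighted:9.4f}  {row.relative_difference_pct:9.2f}"
            )
        return "\n".join(lines)
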