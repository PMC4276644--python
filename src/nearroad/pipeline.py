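"""End-to-end orchestration: scenario -> chi -> emissions -> exposure.

Thin glue over the stage modules, used by the command-line interface
and anywhere a full run is needed programmatically. The chi matrix is
computed once per scenario; emissions scenarios (base case and adjusted)
scale it without re-running dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .adjustments import reassign_diesel, relabel_cohorts, rescale_aadt
from .config import Constants
from .dispersion import ChiMatrix, build_chi_matrix
from .emissions import compute_emissions
from .exposure import classify_receptors, combine, period_average
from .network import DEFAULT_PERIODS
from .synthetic import Scenario


@dataclass
class RunResult:
    """Outputs of one emissions-and-exposure pass over a chi matrix."""

    labels: pd.DataFrame
    emissions: pd.DataFrame
    concentrations: dict[str, pd.DataFrame]  # pollutant -> long frame
    cells: dict[str, pd.DataFrame]  # pollutant -> day x period cells


def run_chi(scenario: Scenario, constants: Constants | None = None) -> ChiMatrix:
    constants = constants or Constants()
    return build_chi_matrix(
        scenario.links, scenario.receptors, scenario.met, constants.dispersion
    )


def run_exposure(
    scenario: Scenario,
    chi: ChiMatrix,
    constants: Constants | None = None,
    links=None,
    pollutants: list[str] | None = None,
) -> RunResult:
    """Emissions, combination, and period summaries for one link set.

    Pass adjusted `links` to rescore an adjustment scenario against the
    unchanged chi matrix.
    """
    constants = constants or Constants()
    links = scenario.links if links is None else links
    pollutants = pollutants or list(scenario.ef_table.pollutants)
    labels = classify_receptors(
        scenario.receptors,
        links,
        ht_aadt_min=constants.exposure.ht_aadt_min,
        near_m=constants.exposure.near_m,
        verynear_m=constants.exposure.verynear_m,
    )
    emissions = compute_emissions(
        links, scenario.ef_table, scenario.mixes, scenario.tafs,
        scenario.met, pollutants, DEFAULT_PERIODS,
    )
    concentrations = {}
    cells = {}
    for pol in pollutants:
        conc = combine(chi, emissions, pol)
        concentrations[pol] = conc
        cells[pol] = period_average(
            conc, DEFAULT_PERIODS, completeness=constants.exposure.completeness
        )
    return RunResult(labels=labels, emissions=emissions,
                     concentrations=concentrations, cells=cells)


def apply_adjustments(
    scenario: Scenario,
    base_labels: pd.DataFrame,
    constants: Constants | None = None,
):
    """The measurement-driven adjustment pair plus cohort relabeling.

    Returns (adjusted links, new labels, combined adjustment log frame).
    """
    constants = constants or Constants()
    adj = constants.adjustment
    links1, log1 = rescale_aadt(scenario.links, adj.interstate_factor)
    links2, log2 = reassign_diesel(
        links1, scenario.ptrs, scenario.mixes, study_year=adj.study_year
    )
    labels, log3 = relabel_cohorts(
        scenario.receptors, links2, base_labels,
        ht_aadt_min=constants.exposure.ht_aadt_min,
        near_m=constants.exposure.near_m,
        verynear_m=constants.exposure.verynear_m,
    )
    log = pd.concat([log1.to_frame(), log2.to_frame(), log3.to_frame()],
                    ignore_index=True)
    return links2, labels, log


def cohort_period_stats(
    conc: pd.DataFrame, labels: pd.DataFrame, periods=DEFAULT_PERIODS
) -> pd.DataFrame:
    """Distribution stats of pooled valid hourly concentrations per
    cohort and time period (plus an all-hours row per cohort)."""
    df = conc[conc["valid"]].merge(
        labels[["receptor_id", "label"]], on="receptor_id"
    )
    hours = pd.DatetimeIndex(df["timestamp"]).hour
    df = df.assign(period=[periods.period_of(h) for h in hours])
    def stats(sub: pd.DataFrame) -> pd.Series:
        v = sub["c"]
        return pd.Series(
            {"median": v.median(), "mean": v.mean(), "p95": v.quantile(0.95),
             "n": len(v)}
        )
    per_period = (
        df.groupby(["label", "period"], observed=True)
        .apply(stats, include_groups=False)
        .reset_index()
    )
    overall = (
        df.groupby("label", observed=True)
        .apply(stats, include_groups=False)
        .reset_index()
        .assign(period="all")
    )
    return pd.concat([per_period, overall], ignore_index=True)
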