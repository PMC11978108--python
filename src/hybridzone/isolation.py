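"""Premating reproductive isolation between ancestry cohorts.

Three statistics, each on the -1 (complete disassortative) to 1 (complete
assortative) scale with 0 = random mating:

* mating-system RI: the ovule cohort's selfing rate (selfing isolates a
  maternal plant perfectly, outcrossing not at all);
* phenological RI = 1 - 2P, where P is the season-summed relative probability
  of between- vs within-cohort potential matings, each open flower mating
  with same-day open flowers in proportion to their counts;
* combined RI = RI_M + (1 - RI_M) * RI_P, the sequential (order-independent)
  action of the two barriers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_half_up(x: float, digits: int = 3) -> float:
    """Displayed values are rounded half-up to 3 decimals; internal values
    stay unrounded."""
    if not np.isfinite(x):
        return x
    factor = 10 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class PlotCohortMap:
    """Plot -> cohort assignment with an explicit exclusion list for plots
    whose residents span multiple cohorts (bimodal hybrid indices)."""

    assignment: dict[str, str]
    excluded: set[str] = field(default_factory=set)

    def resolve(self, plot: str) -> str | None:
        """Cohort for ``plot``; None when excluded; KeyError when unknown."""
        if plot in self.excluded:
            return None
        if plot not in self.assignment:
            raise KeyError(f"census plot {plot!r} is neither assigned nor excluded")
        return self.assignment[plot]

    def cohort_counts(self, census: pd.DataFrame) -> pd.DataFrame:
        """Daily flower totals per cohort (plot, day, count) -> (cohort, day, count)."""
        sub = census[~census["plot"].isin(self.excluded)].copy()
        sub["cohort"] = [self.resolve(p) for p in sub["plot"]]
        return sub.groupby(["cohort", "day"], as_index=False)["count"].sum()


def mating_system_ri(selfing_rate: float) -> float:
    """RI_M equals the ovule cohort's selfing rate (any pollen partner)."""
    if not np.isfinite(selfing_rate):
        return float("nan")
    if not 0 <= selfing_rate <= 1:
        raise ValueError(f"selfing rate outside [0, 1]: {selfing_rate}")
    return float(selfing_rate)


def potential_mating_totals(census: pd.DataFrame, plot_map: PlotCohortMap,
                            ovule: str, pollen: str,
                            include_focal: bool = False) -> tuple[float, float]:
    """Season totals (T_within, T_between) of potential matings.

    For each focal ovule-cohort flower on day d with A same-cohort and B
    pollen-cohort flowers open that day, the within- and between-cohort
    mating probabilities are A/(A+B) and B/(A+B); with ``include_focal=False``
    (default) the focal flower is removed from A — a flower is not its own
    potential mate. Totals are count-weighted sums over all focal flowers.
    A focal flower with no potential mates contributes nothing.
    """
    daily = plot_map.cohort_counts(census)
    table = daily.pivot_table(index="day", columns="cohort", values="count",
                              aggfunc="sum", fill_value=0)
    if ovule not in table.columns or table[ovule].sum() == 0:
        return float("nan"), float("nan")
    n_focal = table[ovule].to_numpy(float)
    b = table[pollen].to_numpy(float) if pollen in table.columns else np.zeros(len(table))
    a = n_focal if include_focal else n_focal - 1
    total = a + b
    usable = (n_focal > 0) & (total > 0)
    if not usable.any():
        logger.info("every %s flower was alone on its day; totals undefined", ovule)
        return 0.0, 0.0
    t_within = float(np.sum(n_focal[usable] * a[usable] / total[usable]))
    t_between = float(np.sum(n_focal[usable] * b[usable] / total[usable]))
    return t_within, t_between


def phenological_ri(census: pd.DataFrame, plot_map: PlotCohortMap,
                    ovule: str, pollen: str,
                    include_focal: bool = False) -> float:
    """RI_P = 1 - 2P with P = T_between / (T_within + T_between).

    Missing (NaN) when the ovule cohort never flowers; 1 when the pollen
    cohort never overlaps it (including a pollen cohort absent all season).
    """
    t_within, t_between = potential_mating_totals(
        census, plot_map, ovule, pollen, include_focal)
    if not np.isfinite(t_within) or t_within + t_between == 0:
        return float("nan")
    if t_between == 0:
        return 1.0
    p = t_between / (t_within + t_between)
    return 1.0 - 2.0 * p


def combined_ri(ri_m: float, ri_p: float) -> float:
    """RI_M + (1 - RI_M) * RI_P; missing when either component is missing.

    Equals 1 whenever RI_M = 1 regardless of RI_P, and reduces to RI_P at
    RI_M = 0. Monotone nondecreasing in each argument on [0, 1]^2.
    """
    if not (np.isfinite(ri_m) and np.isfinite(ri_p)):
        return float("nan")
    return float(ri_m + (1.0 - ri_m) * ri_p)


COHORT_LETTER = {"guttatus": "G", "admixed": "A", "nasutus": "N"}


def ri_table(rates: pd.DataFrame, censuses: pd.DataFrame | None,
             plot_map: PlotCohortMap, pairs: list[tuple[str, str]] | None = None,
             include_focal: bool = False) -> pd.DataFrame:
    """Assemble the per-year, per-direction RI table.

    ``rates`` needs columns (cohort, year, rate) plus optionally stream;
    ``censuses`` columns (year, plot, day, count) plus optionally stream.
    Missing components are preserved as NaN and the combined value is present
    only when both components are.
    """
    group_cols = [c for c in ("stream", "year") if c in rates.columns or
                  (censuses is not None and c in censuses.columns)]
    rate_key_cols = [c for c in group_cols if c in rates.columns]
    rate_lookup = {
        (tuple(np.atleast_1d(k)) if rate_key_cols else ()) + (rec["cohort"],):
        rec["rate"]
        for k, grp in (rates.groupby(rate_key_cols) if rate_key_cols
                       else [((), rates)])
        for _, rec in grp.iterrows()}
    cohorts = sorted(set(rates["cohort"])) if pairs is None else None
    if not group_cols:
        keys = [()]
    elif all(c in rates.columns for c in group_cols):
        keys = list(rates.groupby(group_cols).groups)
    else:
        keys = list(censuses.groupby(group_cols).groups)
    rows = []
    for key in keys:
        key_t = key if isinstance(key, tuple) else (key,)
        census = None
        if censuses is not None:
            mask = np.ones(len(censuses), dtype=bool)
            for col, val in zip(group_cols, key_t):
                if col in censuses.columns:
                    mask &= censuses[col] == val
            census = censuses[mask]
        iter_pairs = pairs if pairs is not None else [
            (o, p) for o in cohorts for p in cohorts if o != p]
        for ovule, pollen in iter_pairs:
            rate_key = tuple(v for c, v in zip(group_cols, key_t)
                             if c in rates.columns) + (ovule,)
            raw = rate_lookup.get(rate_key, float("nan"))
            ri_m = mating_system_ri(float(raw)) if np.isfinite(raw) else float("nan")
            ri_p = (phenological_ri(census, plot_map, ovule, pollen, include_focal)
                    if census is not None and len(census) else float("nan"))
            rows.append(dict(zip(group_cols, key_t)) | {
                "direction": f"{COHORT_LETTER.get(ovule, ovule[0].upper())} <- "
                             f"{COHORT_LETTER.get(pollen, pollen[0].upper())}",
                "ovule": ovule, "pollen": pollen,
                "ri_mating": ri_m, "ri_phenology": ri_p,
                "ri_combined": combined_ri(ri_m, ri_p)})
    return pd.DataFrame(rows)
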