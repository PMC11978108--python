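"""Realized assortative mating from paired maternal-offspring ancestry.

Offspring HI deviation (offspring HI minus maternal HI, positive = more
N ancestry than the mother) is averaged per fruit separately for selfed and
outcrossed offspring; selfed deviations should centre on zero (meiotic
sampling only), while outcrossed deviations shift toward the pollen-pool
mean. For an outcrossed offspring the implied pollen-parent HI is
``2 * offspring HI - maternal HI`` (unbiased under Mendelian expectation),
which lets cross-cohort matings be counted without paternity assignment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ancestry import DEFAULT_COHORT_CUTS, classify_cohort

logger = logging.getLogger(__name__)


def fruit_deviation(summaries: pd.DataFrame, mate_types: pd.DataFrame,
                    extra_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-fruit mean offspring HI deviation, split by mate-type class.

    ``summaries`` is indexed by sample with an ``hi`` column (mothers and
    offspring); ``mate_types`` needs (offspring, family, fruit, call).
    Ambiguous offspring are excluded; a fruit with only ambiguous offspring
    yields no rows.
    """
    extra_cols = extra_cols or [c for c in ("year", "stream")
                                if c in mate_types.columns]
    hi = summaries["hi"]
    called = mate_types[mate_types["call"].isin(["selfed", "outcrossed"])].copy()
    called = called[called["offspring"].isin(hi.index) &
                    called["family"].isin(hi.index)]
    called["deviation"] = (hi.loc[called["offspring"]].to_numpy()
                           - hi.loc[called["family"]].to_numpy())
    rows = []
    for (fruit, call), grp in called.groupby(["fruit", "call"]):
        mother = grp["family"].iloc[0]
        rows.append({"fruit": fruit, "family": mother,
                     "maternal_hi": float(hi.loc[mother]), "mate_class": call,
                     "mean_deviation": float(grp["deviation"].mean()),
                     "n_offspring": len(grp)}
                    | {c: grp[c].iloc[0] for c in extra_cols})
    return pd.DataFrame(rows)


def yearly_shift(deviations: pd.DataFrame, mate_class: str,
                 by: list[str] | None = None) -> pd.DataFrame:
    """Mean fruit-level deviation with its standard error per group.

    The uncertainty is the standard error over fruits (one observation per
    fruit); it is reported missing for single-fruit groups.
    """
    by = by or [c for c in ("year", "stream") if c in deviations.columns]
    sub = deviations[deviations["mate_class"] == mate_class]
    if sub.empty:
        return pd.DataFrame(columns=by + ["mean_shift", "se", "n_fruits"])

    def _agg(grp: pd.DataFrame) -> pd.Series:
        n = len(grp)
        dev = grp["mean_deviation"]
        se = float(dev.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return pd.Series({"mean_shift": float(dev.mean()), "se": se,
                          "n_fruits": n})

    if not by:
        out = _agg(sub).to_frame().T
    else:
        out = sub.groupby(by).apply(_agg, include_groups=False).reset_index()
    out["n_fruits"] = out["n_fruits"].astype(int)
    return out


def implied_pollen_hi(offspring_hi: np.ndarray,
                      maternal_hi: np.ndarray) -> np.ndarray:
    """Estimated pollen-parent HI for outcrossed offspring: 2*O - M,
    clipped to the feasible [0, 1] range."""
    return np.clip(2 * np.asarray(offspring_hi, float)
                   - np.asarray(maternal_hi, float), 0.0, 1.0)


def cross_cohort_rates(summaries: pd.DataFrame, mate_types: pd.DataFrame,
                       focal_cohort: str = "nasutus",
                       cuts: tuple[float, float, float] = DEFAULT_COHORT_CUTS,
                       ) -> dict:
    """Rates of mating across the focal cohort's boundary, both directions.

    maternal side: among called offspring of focal-cohort mothers, the
    fraction whose implied pollen parent lies outside the cohort;
    paternal side: among called offspring of other-cohort mothers, the
    fraction whose implied pollen parent is focal-cohort. Selfed offspring
    have their mother as pollen parent; outcrossed offspring use the implied
    pollen HI classified with the standard cohort cutoffs, and borderline
    (unassigned) implied parents are excluded from the cross-cohort counts
    but kept in the denominators.
    """
    hi = summaries["hi"]
    called = mate_types[mate_types["call"].isin(["selfed", "outcrossed"])].copy()
    called = called[called["offspring"].isin(hi.index) &
                    called["family"].isin(hi.index)]
    mat_hi = hi.loc[called["family"]].to_numpy()
    off_hi = hi.loc[called["offspring"]].to_numpy()
    maternal_cohort = classify_cohort(mat_hi, cuts)
    pollen_hi = np.where(called["call"] == "selfed", mat_hi,
                         implied_pollen_hi(off_hi, mat_hi))
    pollen_cohort = classify_cohort(pollen_hi, cuts)
    n_unassigned = int(np.sum(pollen_cohort == "unassigned"))
    if n_unassigned:
        logger.info("%d implied pollen parents fell in the unassigned HI gap "
                    "and were excluded from cross-cohort counts", n_unassigned)

    focal_mother = maternal_cohort == focal_cohort
    mat_n = int(focal_mother.sum())
    mat_cross = int(np.sum(focal_mother & (pollen_cohort != focal_cohort)
                           & (pollen_cohort != "unassigned")))
    pat_n = int((~focal_mother).sum())
    pat_cross = int(np.sum(~focal_mother & (pollen_cohort == focal_cohort)))
    return {
        "maternal_cross": mat_cross, "maternal_total": mat_n,
        "maternal_pct": 100.0 * mat_cross / mat_n if mat_n else float("nan"),
        "paternal_cross": pat_cross, "paternal_total": pat_n,
        "paternal_pct": 100.0 * pat_cross / pat_n if pat_n else float("nan"),
    }
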