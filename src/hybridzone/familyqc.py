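"""Maternal-offspring validation via the ancestry-incompatibility ratio.

A site is incompatible with a maternal-offspring relationship when mother and
offspring are hard-called homozygous for opposite ancestries (GG vs NN). The
ratio of such sites to all homozygous-maternal sites with any offspring call
flags mismatched pairs and high-error samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ancestry import MISSING

logger = logging.getLogger(__name__)

DEFAULT_OFFSPRING_THRESHOLD = 0.05


def incompatibility_ratio(maternal_calls: np.ndarray,
                          offspring_calls: np.ndarray) -> float:
    """Opposite-homozygote fraction among homozygous-maternal called sites.

    Heterozygous maternal sites are never informative here and enter neither
    numerator nor denominator; the offspring call in the denominator may be
    any non-missing genotype. Returns NaN when the denominator is zero.
    """
    mat = np.asarray(maternal_calls)
    off = np.asarray(offspring_calls)
    mat_hom = (mat == 0) | (mat == 2)
    denom = int(np.sum(mat_hom & (off != MISSING)))
    if denom == 0:
        return float("nan")
    opposite = int(np.sum((mat_hom & (off != MISSING)) &
                          ((mat == 0) & (off == 2) | (mat == 2) & (off == 0))))
    return opposite / denom


def pair_ratios(calls: np.ndarray, samples: list[str],
                families: pd.DataFrame) -> pd.DataFrame:
    """Incompatibility ratio for every maternal-offspring pair.

    ``families`` needs columns (sample, family, fruit) for offspring rows,
    with ``family`` naming the maternal sample. Returns one row per offspring
    with its ratio (NaN when unevaluable).
    """
    index = {s: i for i, s in enumerate(samples)}
    rows = []
    for _, rec in families.iterrows():
        mother, off = rec["family"], rec["sample"]
        if mother not in index or off not in index:
            continue
        ratio = incompatibility_ratio(calls[index[mother]], calls[index[off]])
        rows.append((mother, rec.get("fruit", ""), off, ratio))
    return pd.DataFrame(rows, columns=["family", "fruit", "offspring", "ratio"])


def apply_family_filters(ratios: pd.DataFrame,
                         offspring_threshold: float = DEFAULT_OFFSPRING_THRESHOLD,
                         ) -> pd.DataFrame:
    """Offspring- and family-level exclusions from incompatibility ratios.

    An offspring is excluded when its ratio is at least ``offspring_threshold``
    (inclusive) or could not be evaluated; a family is dropped when strictly
    more than half of its offspring (counting the excluded ones) are excluded.
    The operation is idempotent and order-independent across families.

    Returns ``ratios`` with ``offspring_status`` ({kept, excluded}),
    ``reason`` and ``family_status`` ({kept, dropped}) columns added.
    """
    out = ratios.copy()
    ratio = out["ratio"].to_numpy(float)
    unevaluable = ~np.isfinite(ratio)
    excluded = unevaluable | (ratio >= offspring_threshold)
    out["offspring_status"] = np.where(excluded, "excluded", "kept")
    out["reason"] = np.select(
        [unevaluable, excluded],
        ["no evaluable sites", f"incompatibility >= {offspring_threshold:g}"],
        default="")
    fam_excluded = out.groupby("family")["offspring_status"].apply(
        lambda s: (s == "excluded").sum() > len(s) / 2)
    out["family_status"] = np.where(
        out["family"].map(fam_excluded), "dropped", "kept")
    for fam in fam_excluded.index[fam_excluded]:
        logger.info("family %s dropped: majority of offspring excluded", fam)
    return out


def retained_offspring(qc: pd.DataFrame) -> pd.DataFrame:
    """Offspring surviving both the individual and family filters."""
    return qc[(qc["offspring_status"] == "kept") &
              (qc["family_status"] == "kept")]
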