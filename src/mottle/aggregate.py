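"""Specimen metrics -> species-level trait table of means and cv.

The comparative analysis works on two summaries per species x wing x
metric: the mean (x), capturing interspecific variation, and the
coefficient of variation (cv = sample s.d. / mean), capturing
intraspecific variability.  Morphs and sexes are pooled within species.
A configurable minimum sample size flags (but does not drop) thinly
sampled species, mirroring a sampling floor of ~14 specimens per
species in well-curated museum datasets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six colour/pattern metrics of the core analysis.
CORE_METRICS = ("hue", "saturation", "brightness", "dominance", "marking_size", "contrast")

#: Default minimum specimens per species before a low-n flag is raised.
DEFAULT_MIN_N = 14


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    Requires at least two values and a mean bounded away from zero
    (|mean| > 1e-12), since cv is undefined for zero-mean data.
    """
    x = np.asarray(values, float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 2:
        raise ValueError("cv requires at least 2 values")
    mean = x.mean()
    if abs(mean) <= 1e-12:
        raise ValueError("cv undefined: mean is within 1e-12 of zero")
    return float(x.std(ddof=1) / mean)


def aggregate(
    records: pd.DataFrame,
    min_n: int = DEFAULT_MIN_N,
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Collapse specimen metric rows into the species trait table.

    ``records`` is a tidy frame with columns ``specimen_id``, ``species``,
    ``wing`` and one column per metric (by default the six core metrics
    plus ``wing_area`` when present).  Rows with any metric missing are
    excluded with a logged reason.  The result has one row per
    (species, wing, metric) with columns ``x`` (mean), ``cv``, ``n`` and
    ``flag_low_n``; species/wing cells with fewer than two specimens are
    excluded from the table (no cv is defined), also logged.

    The table is invariant to the order of the input rows, and cv is
    scale-invariant: rescaling a metric rescales x and leaves cv alone.
    """
    if metrics is None:
        metrics = tuple(m for m in CORE_METRICS if m in records.columns)
        if "wing_area" in records.columns:
            metrics = metrics + ("wing_area",)
    missing_cols = [m for m in metrics if m not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack metric columns: {missing_cols}")
    if records.empty or records["species"].nunique() < 1:
        raise ValueError("records must span at least one species")

    complete = records.dropna(subset=list(metrics))
    n_dropped = len(records) - len(complete)
    if n_dropped:
        bad = records.loc[records[list(metrics)].isna().any(axis=1), "specimen_id"]
        logger.warning(
            "excluded %d specimen rows with missing metrics: %s",
            n_dropped, ", ".join(map(str, bad.head(10))),
        )

    rows = []
    for (species, wing), grp in complete.groupby(["species", "wing"], sort=True):
        n = len(grp)
        if n < 2:
            logger.warning(
                "species %r %s has %d specimen(s); cv undefined, cell excluded",
                species, wing, n,
            )
            continue
        if n < min_n:
            logger.info("species %r %s below min_n=%d (n=%d)", species, wing, min_n, n)
        for metric in metrics:
            vals = grp[metric].to_numpy(float)
            mean = vals.mean()
            cv = np.nan if abs(mean) <= 1e-12 else float(vals.std(ddof=1) / mean)
            rows.append(
                {
                    "species": species,
                    "wing": wing,
                    "metric": metric,
                    "x": float(mean),
                    "cv": cv,
                    "n": n,
                    "flag_low_n": n < min_n,
                }
            )
    table = pd.DataFrame(rows, columns=["species", "wing", "metric", "x", "cv", "n", "flag_low_n"])
    return table.sort_values(["species", "wing", "metric"], ignore_index=True)


def trait_vector(
    table: pd.DataFrame, wing: str, metric: str, stat: str
) -> dict[str, float]:
    """Pull one species -> value map out of the trait table.

    ``stat`` is ``"x"`` or ``"cv"``.  Species whose value is NaN are
    dropped (e.g. cv of a zero-mean metric).
    """
    if stat not in ("x", "cv"):
        raise ValueError("stat must be 'x' or 'cv'")
    sel = table[(table["wing"] == wing) & (table["metric"] == metric)]
    out = {
        str(r["species"]): float(r[stat])
        for _, r in sel.iterrows()
        if np.isfinite(r[stat])
    }
    return out
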