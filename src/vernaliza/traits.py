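"""Extraction of the four vernalization/flowering traits from replicated
response measurements.

Traits per accession:

* ``mtd_weeks`` — shortest cold duration permissive for flowering;
* ``days_after_mtd`` — mean post-return days to flower at that duration;
* ``saturation_weeks`` — shortest permissive duration beyond which longer
  cold gives no further reduction (within a tolerance) in days to flower;
* ``days_after_saturation`` — days from entering the cold chamber to
  flowering at saturation, i.e. ``7 * saturation_weeks`` plus the mean
  post-return days at saturation.

A treatment cell is *permissive* when at least ``min_flowered`` of its
replicates flowered (default: a majority).  Accessions with no permissive
cell are flagged ``never_flowered`` and excluded from trait analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FloweringTraits",
    "summarize_replicates",
    "extract_traits",
    "trait_correlations",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ["mtd_weeks", "days_after_mtd", "saturation_weeks", "days_after_saturation"]


@dataclass
class FloweringTraits:
    accession: str
    mtd_weeks: float | None
    days_after_mtd: float | None
    saturation_weeks: float | None
    days_after_saturation: float | None
    never_flowered: bool = False
    mtd_left_censored: bool = False
    saturation_right_censored: bool = False


def _validate_response(vr: pd.DataFrame) -> pd.DataFrame:
    required = {"accession", "duration_weeks", "replicate", "days_after_return", "flowered"}
    missing = required - set(vr.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    bad = vr["flowered"] & (vr["days_after_return"] < 0)
    if bad.any():
        raise ValueError("negative days_after_return on flowered replicates")
    return vr


def summarize_replicates(vr: pd.DataFrame, min_flowered: int | None = None) -> pd.DataFrame:
    """Per (accession, duration) summary of the replicated measurements.

    Returns columns: accession, duration_weeks, mean_days (over flowered
    replicates only; NaN if none), n_flowered, n_total, permissive.
    ``min_flowered`` defaults to a strict majority of replicates in the cell.
    """
    vr = _validate_response(vr)
    out = []
    for (acc, dur), cell in vr.groupby(["accession", "duration_weeks"], sort=True):
        n_total = len(cell)
        flowered = cell.loc[cell["flowered"], "days_after_return"]
        n_flowered = len(flowered)
        need = min_flowered if min_flowered is not None else n_total // 2 + 1
        out.append((
            acc, dur,
            flowered.mean() if n_flowered else np.nan,
            n_flowered, n_total,
            n_flowered >= need,
        ))
    return pd.DataFrame(
        out,
        columns=["accession", "duration_weeks", "mean_days", "n_flowered",
                 "n_total", "permissive"],
    )


def extract_traits(
    vr: pd.DataFrame,
    saturation_tol_days: float = 2.0,
    min_flowered: int | None = None,
) -> pd.DataFrame:
    """Extract the four traits per accession from a long-format response table.

    Saturation is the smallest permissive duration ``d*`` such that no
    tested duration ``d >= d*`` has a mean more than ``saturation_tol_days``
    below the mean at ``d*`` (the scoring cadence motivates the default
    tolerance of 2 days).  Degenerate cases are carried as flags, never as
    errors.
    """
    if saturation_tol_days < 0:
        raise ValueError("saturation_tol_days must be >= 0")
    cells = summarize_replicates(vr, min_flowered=min_flowered)
    rows = []
    for acc, sub in cells.groupby("accession", sort=True):
        sub = sub.sort_values("duration_weeks")
        durations = sub["duration_weeks"].to_numpy()
        means = sub["mean_days"].to_numpy()
        permissive = sub["permissive"].to_numpy()
        if not permissive.any():
            rows.append(FloweringTraits(acc, None, None, None, None,
                                        never_flowered=True))
            continue
        i_mtd = int(np.argmax(permissive))
        mtd = float(durations[i_mtd])
        days_after_mtd = float(means[i_mtd])
        mtd_left_censored = i_mtd == 0

        perm_idx = np.flatnonzero(permissive)
        i_sat = None
        for i in perm_idx:
            later = perm_idx[perm_idx >= i]
            if np.all(means[later] >= means[i] - saturation_tol_days):
                i_sat = int(i)
                break
        if i_sat is None:  # can only happen if the last permissive cell fails its own check
            i_sat = int(perm_idx[-1])
        sat = float(durations[i_sat])
        sat_right_censored = i_sat == len(durations) - 1
        days_after_sat = 7.0 * sat + float(means[i_sat])
        rows.append(FloweringTraits(
            acc, mtd, days_after_mtd, sat, days_after_sat,
            never_flowered=False,
            mtd_left_censored=mtd_left_censored,
            saturation_right_censored=sat_right_censored,
        ))
    return pd.DataFrame([vars(r) for r in rows])


def trait_correlations(traits: pd.DataFrame, columns: list[str] | None = None):
    """Pairwise-complete Pearson correlations among traits with t-test p-values.

    Returns (r, p) DataFrames.  Pairs involving a zero-variance trait are
    NaN (flagged by the caller inspecting the matrix).
    """
    columns = columns or TRAIT_COLUMNS
    if "never_flowered" in traits.columns:
        data = traits.loc[~traits["never_flowered"].astype(bool), columns]
    else:
        data = traits[columns]
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for i in range(k):
        for j in range(i + 1, k):
            pair = data[[columns[i], columns[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete pairs for {columns[i]} vs {columns[j]}"
                )
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = res.statistic, res.pvalue
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p
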