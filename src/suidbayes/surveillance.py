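"""Regional SUID-classification variability and exact contingency tests.

A region table has one row per region with live births and death counts in
the three SUID subcategories (SIDS, accidental asphyxia, unknown cause).
The variability summary reports, per subcategory, the across-region mean
and SD of the rate per 1000 live births and the coefficient of variation
CV = SD / mean x 100 — a measure of how consistently regions apply the
diagnostic subcategories.

Also here: Fisher's exact test for 2x2 tables and the Freeman-Halton
extension to RxC tables (exact enumeration with a seeded Monte-Carlo
fallback for large tables), as used for the cohort contingency analyses.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUBCATEGORIES = ("sids", "asphyxia", "unknown")

#: Largest table total for exact Freeman-Halton enumeration.
ENUMERATION_BOUND = 200


def region_rates(regions: pd.DataFrame) -> pd.DataFrame:
    """Per-region rates per 1000 live births, plus the SUID total."""
    _check_regions(regions)
    out = regions[["region"]].copy()
    for sub in SUBCATEGORIES:
        out[sub] = regions[sub] / regions["live_births"] * 1000.0
    out["suid"] = out[list(SUBCATEGORIES)].sum(axis=1)
    return out


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, in percent."""
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return sd / mean * 100.0


def variability_table(rates: pd.DataFrame, decimals: tuple[int, int] = (2, 1)) -> pd.DataFrame:
    """Across-region mean, SD (sample, n-1) and CV per subcategory.

    ``decimals`` gives the rounding for (mean/SD, CV); pass ``None`` to
    skip rounding.
    """
    if len(rates) < 2:
        raise ValueError("need at least 2 regions")
    rows = []
    for sub in (*SUBCATEGORIES, "suid"):
        vals = rates[sub].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        cv = cv_percent(mean, sd) if mean > 0 else 0.0
        if decimals is not None:
            mean, sd = round(mean, decimals[0]), round(sd, decimals[0])
            cv = round(cv, decimals[1])
        rows.append({"subcategory": sub, "mean": mean, "sd": sd, "cv": cv})
    return pd.DataFrame(rows)


def subcategory_ratios(regions: pd.DataFrame) -> pd.DataFrame:
    """Per-region proportions of total SUID by subcategory.

    Regions with zero SUID deaths are flagged (``defined = False``) with
    missing proportions rather than NaN arithmetic downstream.
    """
    _check_regions(regions)
    totals = regions[list(SUBCATEGORIES)].sum(axis=1)
    out = regions[["region"]].copy()
    out["defined"] = totals > 0
    for sub in SUBCATEGORIES:
        out[sub] = np.where(totals > 0, regions[sub] / totals.replace(0, np.nan), np.nan)
    return out


def _check_regions(regions: pd.DataFrame) -> None:
    required = {"region", "live_births", *SUBCATEGORIES}
    missing = required - set(regions.columns)
    if missing:
        raise ValueError(f"region table missing columns {sorted(missing)}")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    if (regions["live_births"] <= 0).any():
        raise ValueError("live_births must be positive")
    if (regions[list(SUBCATEGORIES)] < 0).to_numpy().any():
        raise ValueError("death counts must be non-negative")


# --- exact tests --------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value (point-probability rule)."""
    arr = _check_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def freeman_halton(table: Sequence[Sequence[int]],
                   bound: int = ENUMERATION_BOUND) -> float:
    """Exact RxC test (Freeman-Halton generalization of Fisher's test).

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one.  Tables with total above ``bound`` raise; use
    :func:`freeman_halton_mc` for those.
    """
    arr = _check_table(table)
    n = int(arr.sum())
    if n == 0:
        return 1.0
    if n > bound:
        raise ValueError(
            f"table total {n} exceeds enumeration bound {bound}; "
            "use freeman_halton_mc (seeded Monte-Carlo) instead")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    log_obs = _log_table_prob(arr, row_sums, col_sums)
    p = 0.0
    tol = 1e-9
    for cand in _tables_with_margins(tuple(row_sums), tuple(col_sums)):
        lp = _log_table_prob(cand, row_sums, col_sums)
        if lp <= log_obs + tol:
            p += math.exp(lp)
    return min(p, 1.0)


def freeman_halton_mc(table: Sequence[Sequence[int]], n_samples: int = 100_000,
                      seed: int = 0) -> float:
    """Seeded Monte-Carlo estimate of the Freeman-Halton p-value.

    Samples tables from the fixed-margin null by random pairing of row and
    column labels.
    """
    arr = _check_table(table)
    n = int(arr.sum())
    if n == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    log_obs = _log_table_prob(arr, row_sums, col_sums)
    rows = np.repeat(np.arange(arr.shape[0]), row_sums)
    cols = np.repeat(np.arange(arr.shape[1]), col_sums)
    hits = 0
    for _ in range(n_samples):
        perm = rng.permutation(cols)
        cand = np.zeros_like(arr)
        np.add.at(cand, (rows, perm), 1)
        if _log_table_prob(cand, row_sums, col_sums) <= log_obs + 1e-9:
            hits += 1
    # add-one correction keeps the estimate in (0, 1]
    return (hits + 1) / (n_samples + 1)


def _check_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def _log_table_prob(arr: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    n = int(arr.sum())
    lg = math.lgamma
    num = sum(lg(r + 1) for r in row_sums) + sum(lg(c + 1) for c in col_sums)
    den = lg(n + 1) + sum(lg(x + 1) for x in arr.ravel())
    return num - den


def _tables_with_margins(row_sums: tuple[int, ...], col_sums: tuple[int, ...]):
    """Yield all non-negative integer tables with the given margins."""
    n_rows = len(row_sums)

    def rec(row_idx: int, remaining_cols: tuple[int, ...], acc: list):
        if row_idx == n_rows - 1:
            if all(c >= 0 for c in remaining_cols):
                yield np.array(acc + [list(remaining_cols)])
            return
        target = row_sums[row_idx]
        for cells in _compositions(target, remaining_cols):
            rest = tuple(c - x for c, x in zip(remaining_cols, cells))
            yield from rec(row_idx + 1, rest, acc + [list(cells)])

    yield from rec(0, col_sums, [])


def _compositions(total: int, caps: tuple[int, ...]):
    """All ways to write ``total`` as a sum over cells bounded by ``caps``."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    for x in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - x, caps[1:]):
            yield (x,) + rest
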