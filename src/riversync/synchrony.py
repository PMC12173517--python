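"""Pairwise population synchrony.

Synchrony between two sampling sites is the Spearman rank correlation of
their density time series over the years both were sampled. Pairs with
too few matching years, with no shared year of positive density, or with
a constant (rank-degenerate) series are excluded. Between-fragment pairs
farther apart than the longest within-fragment pair of their catchment
are removed before modelling so that the two groups cover comparable
distance ranges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairSynchrony",
    "spearman",
    "pair_synchrony",
    "synchrony_table",
    "truncate_between_fragment_pairs",
    "fragment_mean_synchrony",
]


def _avg_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based, ties share the mean rank)."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    np.not_equal(xs[1:], xs[:-1], out=new_group[1:])
    starts = np.flatnonzero(new_group)
    counts = np.diff(np.append(starts, n))
    group_rank = starts + 1 + (counts - 1) / 2.0  # mean rank of each tie group
    ranks = np.empty(n)
    ranks[order] = np.repeat(group_rank, counts)
    return ranks


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = _avg_ranks(x)
    ry = _avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0.0:
        return float("nan")
    return float((rx @ ry) / denom)


@dataclass(frozen=True)
class PairSynchrony:
    rho: float | None
    n_matching_years: int
    excluded: str | None = None  # reason code, None when retained


def pair_synchrony(
    series_a: pd.Series,
    series_b: pd.Series,
    min_years: int = 6,
    require_positive: str = "both",
) -> PairSynchrony:
    """Synchrony of one site pair from two year-indexed density series.

    Exclusion reason codes: ``too_few_years`` (fewer than ``min_years``
    matching sampled years), ``no_positive_match`` (no matching year with
    positive density — at both sites by default, at either site with
    ``require_positive='either'``), ``constant_series`` (zero rank
    variance at one of the sites).
    """
    if require_positive not in ("both", "either"):
        raise ValueError("require_positive must be 'both' or 'either'")
    years = series_a.index.intersection(series_b.index)
    n = len(years)
    if n < min_years:
        return PairSynchrony(None, n, "too_few_years")
    a = series_a.loc[years].to_numpy(dtype=float)
    b = series_b.loc[years].to_numpy(dtype=float)
    if require_positive == "both":
        ok = bool(np.any((a > 0) & (b > 0)))
    else:
        ok = bool(np.any((a > 0) | (b > 0)))
    if not ok:
        return PairSynchrony(None, n, "no_positive_match")
    rho = spearman(a, b)
    if np.isnan(rho):
        return PairSynchrony(None, n, "constant_series")
    return PairSynchrony(rho, n)


def synchrony_table(
    density: pd.DataFrame,
    pair_table: pd.DataFrame,
    min_years: int = 6,
    require_positive: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synchrony records for every geometry pair with retained data.

    Parameters
    ----------
    density : long DataFrame with columns ``site, year, density``.
    pair_table : pair geometry table from ``pair_geometry_table``.

    Returns
    -------
    (records, exclusions) : records carry ``rho`` and ``n_matching_years``
    plus all geometry columns; exclusions log one row per dropped pair.
    """
    wide = density.pivot_table(index="year", columns="site", values="density")
    mat = wide.to_numpy()
    col = {s: i for i, s in enumerate(wide.columns)}
    finite = np.isfinite(mat)

    kept, dropped = [], []
    for row in pair_table.itertuples(index=False):
        ia = col.get(row.site_a)
        ib = col.get(row.site_b)
        if ia is None or ib is None:
            dropped.append({"site_a": row.site_a, "site_b": row.site_b,
                            "n_matching_years": 0, "reason": "too_few_years"})
            continue
        mask = finite[:, ia] & finite[:, ib]
        n = int(mask.sum())
        if n < min_years:
            dropped.append({"site_a": row.site_a, "site_b": row.site_b,
                            "n_matching_years": n, "reason": "too_few_years"})
            continue
        a = mat[mask, ia]
        b = mat[mask, ib]
        if require_positive == "both":
            ok = bool(np.any((a > 0) & (b > 0)))
        else:
            ok = bool(np.any((a > 0) | (b > 0)))
        if not ok:
            dropped.append({"site_a": row.site_a, "site_b": row.site_b,
                            "n_matching_years": n, "reason": "no_positive_match"})
            continue
        rho = spearman(a, b)
        if np.isnan(rho):
            dropped.append({"site_a": row.site_a, "site_b": row.site_b,
                            "n_matching_years": n, "reason": "constant_series"})
            continue
        rec = row._asdict()
        rec["rho"] = rho
        rec["n_matching_years"] = n
        kept.append(rec)

    records = pd.DataFrame(kept)
    exclusions = pd.DataFrame(dropped,
                              columns=["site_a", "site_b", "n_matching_years", "reason"])
    return records, exclusions


def truncate_between_fragment_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Drop between-fragment pairs beyond the catchment's maximum
    within-fragment watercourse distance.

    Within-fragment records are untouched. A catchment with no
    within-fragment pair loses all its between-fragment pairs (warning).
    Idempotent and order-invariant.
    """
    if records.empty:
        return records.copy()
    out = []
    for catchment, grp in records.groupby("catchment", sort=True):
        within = grp.loc[~grp["barrier_crossed"]]
        if within.empty:
            warnings.warn(
                f"catchment {catchment!r} has no within-fragment pair; "
                "all its between-fragment pairs dropped",
                stacklevel=2,
            )
            continue
        dmax = within["d_w_m"].max()
        out.append(grp.loc[~grp["barrier_crossed"] | (grp["d_w_m"] <= dmax)])
    return pd.concat(out, ignore_index=True) if out else records.iloc[0:0].copy()


def fragment_mean_synchrony(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean synchrony over within-fragment pairs, per fragment.

    Columns: ``fragment, mean_rho, n_pairs, catchment``. Fragments with no
    valid within-fragment pair are omitted.
    """
    within = records.loc[records["fragment_a"] == records["fragment_b"]]
    if within.empty:
        return pd.DataFrame(columns=["fragment", "mean_rho", "n_pairs", "catchment"])
    agg = (
        within.groupby("fragment_a", sort=True)
        .agg(mean_rho=("rho", "mean"), n_pairs=("rho", "size"),
             catchment=("catchment", "first"))
        .reset_index()
        .rename(columns={"fragment_a": "fragment"})
    )
    return agg
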