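"""Normalized per-7-mer expression from reporter and plasmid count tables.

Expression of a 7-mer is its mean reporter reads-per-million divided by its
plasmid-library RPM; the plasmid division also corrects the mild synthesis
composition bias of the randomized cassette.  Detection follows the
read-count filter convention: a 7-mer is detected when its raw count exceeds
a threshold in every replicate (the +1 G sub-universe is excluded upstream
by the classifier, and can be excluded here for externally supplied tables).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import KmerCountTable


def to_rpm(table: KmerCountTable) -> pd.Series:
    """Reads per million assigned reads: count * 1e6 / total assigned."""
    total = table.total_assigned
    if total <= 0:
        raise ValueError("empty count table")
    return (table.counts * 1e6 / total).rename(table.sample_id)


def detection_filter(
    tables: Sequence[KmerCountTable],
    min_reads: int = 50,
    require_all_replicates: bool = True,
    plus1: str | None = "ACT",
) -> pd.Index:
    """7-mers with raw count strictly greater than ``min_reads`` in every
    (or, with ``require_all_replicates=False``, any) table, optionally
    restricted to the given +1 nucleotides."""
    if not tables:
        raise ValueError("need at least one count table")
    universe = tables[0].counts.index
    for t in tables[1:]:
        universe = universe.union(t.counts.index)
    passing = None
    for t in tables:
        ok = t.counts.reindex(universe, fill_value=0) > min_reads
        passing = ok if passing is None else (passing & ok if require_all_replicates else passing | ok)
    detected = universe[passing]
    if plus1 is not None:
        detected = detected[[s[0] in plus1 for s in detected]]
    return detected


def normalize_expression(
    reporter_tables: Sequence[KmerCountTable],
    plasmid_table: KmerCountTable,
    min_reads: int = 50,
    require_all_replicates: bool = True,
    plus1: str | None = "ACT",
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-7-mer normalized expression table.

    Columns: ``reporter_rpm`` (mean over replicates; ``aggregate='gmean'``
    for the geometric mean), ``plasmid_rpm``, ``normalized`` (their ratio)
    and ``detected``.  Undetected 7-mers are flagged, not dropped.  A
    detected 7-mer with zero plasmid count is excluded with a warning.
    """
    rpms = pd.concat([to_rpm(t) for t in reporter_tables], axis=1).fillna(0.0)
    if aggregate == "mean":
        reporter_rpm = rpms.mean(axis=1)
    elif aggregate == "gmean":
        with np.errstate(divide="ignore"):
            reporter_rpm = np.exp(np.log(rpms).mean(axis=1))
    else:
        raise ValueError("aggregate must be 'mean' or 'gmean'")
    plasmid_rpm = to_rpm(plasmid_table).reindex(reporter_rpm.index, fill_value=0.0)
    detected = detection_filter(
        reporter_tables, min_reads, require_all_replicates, plus1
    )
    df = pd.DataFrame(
        {
            "reporter_rpm": reporter_rpm,
            "plasmid_rpm": plasmid_rpm,
            "detected": reporter_rpm.index.isin(detected),
        }
    )
    bad = df["detected"] & (df["plasmid_rpm"] <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} detected 7-mer(s) with zero plasmid counts"
        )
        df = df[~bad]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["normalized"] = df["reporter_rpm"] / df["plasmid_rpm"]
    df.loc[df["plasmid_rpm"] <= 0, "normalized"] = np.nan
    df.index.name = "sevenmer"
    return df.sort_index()


def expression_range(
    values: pd.Series | pd.DataFrame, lo_q: float = 0.0, hi_q: float = 1.0
) -> float:
    """Fold range of normalized expression: the hi_q quantile divided by the
    lo_q quantile (defaults: max over min, the full span).  Accepts a
    normalized-expression table, using its detected entries."""
    if isinstance(values, pd.DataFrame):
        values = values.loc[values["detected"], "normalized"]
    vals = values.dropna().values
    if len(vals) < 2:
        raise ValueError("need >= 2 detected entries")
    if not 0 <= lo_q < hi_q <= 1:
        raise ValueError("need 0 <= lo_q < hi_q <= 1")
    lo = np.quantile(vals, lo_q)
    hi = np.quantile(vals, hi_q)
    if lo <= 0:
        raise ValueError("lower quantile is not positive")
    return float(hi / lo)


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient b = (skew^2 + 1) / (kurt + 3(n-1)^2 /
    ((n-2)(n-3))); values above ~0.555 (the uniform) suggest bimodality."""
    n = len(values)
    if n < 4:
        raise ValueError("need >= 4 values")
    g = stats.skew(values, bias=False)
    k = stats.kurtosis(values, bias=False)  # excess kurtosis
    return float((g**2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def plus1_stratified_summary(table: pd.DataFrame) -> dict:
    """Summaries of detected normalized expression per +1 nucleotide.

    Returns ``{'strata': DataFrame, 'bimodality': float}``: per-stratum n,
    mean, geometric mean and quantiles of normalized expression, plus the
    bimodality coefficient of the pooled log10 distribution.
    """
    det = table.loc[table["detected"] & table["normalized"].notna()]
    if det.empty:
        raise ValueError("no detected entries")
    rows = []
    for nt, grp in det.groupby(det.index.str[0]):
        v = grp["normalized"].values
        rows.append(
            {
                "plus1": nt,
                "n": len(v),
                "mean": float(np.mean(v)),
                "gmean": float(np.exp(np.mean(np.log(v)))),
                "q05": float(np.quantile(v, 0.05)),
                "q25": float(np.quantile(v, 0.25)),
                "median": float(np.median(v)),
                "q75": float(np.quantile(v, 0.75)),
                "q95": float(np.quantile(v, 0.95)),
            }
        )
    strata = pd.DataFrame(rows).set_index("plus1")
    pooled = np.log10(det["normalized"].values)
    return {"strata": strata, "bimodality": bimodality_coefficient(pooled)}


def positional_frequency_matrix(
    sevenmers: Iterable[str],
    weights: pd.Series | None = None,
    plasmid_correction: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-position nucleotide frequencies of a 7-mer subset (logo matrix).

    Rows are positions +1..+7, columns A/C/G/T, each row summing to 1.
    ``weights`` weights each 7-mer (e.g. by expression); ``plasmid_correction``
    is a like-shaped positional frequency matrix to divide by (frequencies are
    renormalized per row afterwards).
    """
    sevenmers = list(sevenmers)
    if not sevenmers:
        raise ValueError("empty 7-mer subset")
    w = (
        np.ones(len(sevenmers))
        if weights is None
        else weights.reindex(sevenmers).fillna(0.0).values
    )
    mat = np.zeros((7, 4))
    cols = {b: j for j, b in enumerate("ACGT")}
    for s, wi in zip(sevenmers, w):
        for i, b in enumerate(s):
            mat[i, cols[b]] += wi
    df = pd.DataFrame(mat, index=range(1, 8), columns=list("ACGT"))
    df = df.div(df.sum(axis=1), axis=0)
    if plasmid_correction is not None:
        df = df / plasmid_correction.values
        df = df.div(df.sum(axis=1), axis=0)
    df.index.name = "position"
    return df
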