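"""Degenerate 5'-sequence motif classes and motif-level statistics.

Motif patterns are IUPAC-degenerate strings anchored at the +1 position of
the transcript (pattern position 0 = +1 nucleotide).  Patterns are stored in
DNA space; U on input is handled at ingest.  Built-in classes cover the
initiator-like (Inr) and pyrimidine-initiator (TCT) 5' sequence classes, the
key dinucleotides, and terminal oligopyrimidine (TOP) motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


@dataclass(frozen=True)
class MotifClass:
    """A +1-anchored degenerate 5'-sequence pattern."""

    name: str
    pattern: str
    description: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("U", "T")
        object.__setattr__(self, "pattern", pat)
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"unknown IUPAC code(s) {sorted(bad)} in {pat!r}")
        if not 1 <= len(pat) <= 7:
            raise ValueError("pattern length must be 1..7")


#: Built-in 5'-sequence classes.
BUILTIN_CLASSES: dict[str, MotifClass] = {
    c.name: c
    for c in [
        MotifClass("Inr", "ABW", "initiator-like +1 A starts (B=C/G/T, W=A/T)"),
        MotifClass("TCT", "CTYTYY", "pyrimidine-initiator +1 C starts (Y=C/T)"),
        MotifClass("AG", "AG", "+1 A +2 G dinucleotide (optimal Inr-type start)"),
        MotifClass("CT", "CT", "+1 C +2 T dinucleotide (optimal TCT-type start)"),
        MotifClass("CU", "CT", "alias of CT in RNA spelling"),
        MotifClass("TOP", "CYYYY", "terminal oligopyrimidine: +1 C then pyrimidines"),
        MotifClass("TOP_scan", "CYYYYNN", "TOP background for substitution scans"),
    ]
}


def match_class(kmer: str, motif: MotifClass | str) -> bool:
    """True iff every pattern position's code contains the k-mer's base.

    Pattern positions beyond the k-mer (or vice versa) are unconstrained;
    matching is anchored at position 0 (+1).
    """
    pattern = motif.pattern if isinstance(motif, MotifClass) else motif
    kmer = kmer.upper().replace("U", "T")
    for code, base in zip(pattern, kmer):
        try:
            allowed = IUPAC[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r}") from None
        if base not in allowed:
            return False
    return True


def match_mask(index: pd.Index, motif: MotifClass | str) -> np.ndarray:
    """Boolean mask over a k-mer index for one pattern."""
    return np.fromiter(
        (match_class(k, motif) for k in index), dtype=bool, count=len(index)
    )


def leading_pyrimidine_run(kmer: str) -> int:
    """Length of the maximal C/T prefix starting at +1."""
    n = 0
    for b in kmer:
        if b in PYRIMIDINES:
            n += 1
        else:
            break
    return n


# ---------------------------------------------------------------------
# statistics


def class_value_test(values: pd.Series, motif: MotifClass | str) -> dict:
    """Welch test of a motif class's per-7-mer values against the
    all-sequence background (the figure convention: class mean compared with
    the mean over every sequence, shown as a dashed line)."""
    mask = match_mask(values.index, motif)
    members = values.values[mask]
    if len(members) < 2 or (~mask).sum() < 2:
        raise ValueError("need >= 2 members and >= 2 non-members")
    t, p = stats.ttest_ind(members, values.values, equal_var=False)
    if np.isnan(t):  # zero variance everywhere -> no difference
        t, p = 0.0, 1.0
    return {
        "n_class": int(len(members)),
        "class_mean": float(np.mean(members)),
        "background_mean": float(values.mean()),
        "t": float(t),
        "p": float(p),
    }


def yrun_profile(
    delta: pd.Series,
    require_plus1C: bool = True,
    nested: bool = False,
) -> pd.DataFrame:
    """Mean regulation by leading pyrimidine-run length.

    Groups 7-mers by the maximal C/T run starting at +1 (``k`` = 0..7); with
    the default disjoint grouping a 7-mer belongs to exactly the run length it
    has (run terminated by a purine, or k = 7), while ``nested=True`` assigns
    a 7-mer to every k up to its run length.  ``require_plus1C`` restricts
    k >= 1 groups to +1 C starts (TOP semantics).  The k = 0 row (purine +1,
    any continuation) is the comparator; Welch statistics against it are
    reported per k.
    """
    runs = np.fromiter(
        (leading_pyrimidine_run(s) for s in delta.index), dtype=int, count=len(delta)
    )
    first_c = np.fromiter((s[0] == "C" for s in delta.index), dtype=bool, count=len(delta))
    baseline = delta.values[runs == 0]
    rows = []
    for k in range(8):
        if k == 0:
            sel = runs == 0
        else:
            sel = (runs >= k) if nested else (runs == k)
            if require_plus1C:
                sel = sel & first_c
        vals = delta.values[sel]
        row = {
            "k": k,
            "n": int(sel.sum()),
            "mean_delta": float(np.mean(vals)) if sel.any() else np.nan,
            "sd": float(np.std(vals, ddof=1)) if sel.sum() > 1 else np.nan,
        }
        if k > 0 and sel.sum() > 1 and len(baseline) > 1:
            t, p = stats.ttest_ind(vals, baseline, equal_var=False)
            row["t_vs_baseline"], row["p_vs_baseline"] = float(t), float(p)
        else:
            row["t_vs_baseline"], row["p_vs_baseline"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


def substitution_scan(
    values: pd.Series,
    base_pattern: str = "CYYYYNN",
    substitutions: str = "ACGT",
) -> pd.DataFrame:
    """Effect of single-position substitutions within a motif background.

    For each pattern position p and nucleotide (class) c, the effect is
    mean(values over k-mers matching the pattern with position p forced to c)
    minus mean(values over the unmodified pattern).  Forcing a position to a
    code it already matches reproduces a subset of the background; forcing it
    to its exact original code gives effect 0 by construction.  Empty cells
    are NaN.
    """
    base = MotifClass("base", base_pattern)
    base_mask = match_mask(values.index, base)
    if not base_mask.any():
        raise ValueError(f"no k-mer matches base pattern {base_pattern!r}")
    base_mean = float(values.values[base_mask].mean())
    out = {}
    for p in range(len(base.pattern)):
        row = {}
        for c in substitutions:
            forced = base.pattern[:p] + c + base.pattern[p + 1 :]
            mask = match_mask(values.index, forced)
            row[c] = float(values.values[mask].mean() - base_mean) if mask.any() else np.nan
        out[p + 1] = row  # 1-based: the paper's +1..+7 positions
    df = pd.DataFrame(out).T
    df.index.name = "position"
    return df


def aggregate_to_kmer(
    values: pd.Series, k: int, weights: pd.Series | None = None
) -> pd.Series:
    """Aggregate per-7-mer values to their first-k-nucleotide prefix.

    Unweighted mean by default; ``weights`` (e.g. plasmid frequencies per
    7-mer) gives a weighted mean within each prefix group.
    """
    if not 1 <= k <= 7:
        raise ValueError("k must be in 1..7")
    prefixes = values.index.str[:k]
    if weights is None:
        return values.groupby(prefixes).mean().rename(values.name)
    w = weights.reindex(values.index)
    num = (values * w).groupby(prefixes).sum()
    den = w.groupby(prefixes).sum()
    return (num / den).rename(values.name)


def pareto_front(df: pd.DataFrame, cols: tuple[str, str]) -> pd.Series:
    """Boolean mask of Pareto-optimal rows (maximal in both columns)."""
    a = df[cols[0]].values
    b = df[cols[1]].values
    n = len(df)
    optimal = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (a >= a[i]) & (b >= b[i]) & ((a > a[i]) | (b > b[i]))
        if dominated.any():
            optimal[i] = False
    return pd.Series(optimal, index=df.index)


def hybrid_ranking(
    expression: pd.Series, delta_psp: pd.Series
) -> pd.DataFrame:
    """Rank 5' 3-mers jointly on high expression and strong growth-regulated
    translational repression (large negative Torin-control P/SP delta).

    Returns one row per shared 3-mer with Pareto-front flags (over all +1
    A/C/T 3-mers and within the +1 C subset) and a rank product (lower =
    jointly better).  The paper-level question -- which +1 C starts maximize
    both transcription and mTOR-regulated translation -- is answered by the
    +1 C Pareto front.
    """
    shared = expression.index.intersection(delta_psp.index)
    df = pd.DataFrame(
        {
            "expression": expression.reindex(shared),
            "repression": -delta_psp.reindex(shared),  # higher = more repressed
        }
    ).dropna()
    df = df[~df.index.str.startswith("G")]
    df["pareto_all"] = pareto_front(df, ("expression", "repression"))
    c_sub = df[df.index.str.startswith("C")]
    front_c = pareto_front(c_sub, ("expression", "repression"))
    df["pareto_plus1C"] = front_c.reindex(df.index, fill_value=False)
    ranks = df[["expression", "repression"]].rank(ascending=False)
    df["rank_product"] = (ranks["expression"] * ranks["repression"]) ** 0.5
    return df.sort_values("rank_product")
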