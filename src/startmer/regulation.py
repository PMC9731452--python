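"""Per-7-mer translation (polysome/sub-polysome) and stability (ActD+/ActD-)
log2 ratios, condition deltas and the translation-stability correlation.

The log2 ratio estimator is a pseudocount ratio of normalized abundances:
per replicate pair, l2fc = log2((num + a) / (den + a)) where abundances are
reads-per-million or spike-in-scaled counts and ``a`` is a small pseudocount
(default 0.5 RPM); replicate values are averaged.  This keeps the pipeline
self-contained and fully specified; when externally computed fold changes
(e.g. shrinkage-based) are supplied for validation, agreement is assessed by
rank correlation, not value equality.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import motifs
from .expression import to_rpm
from .quantify import KmerCountTable

DEFAULT_PSEUDOCOUNT = 0.5


def _normalized_abundance(table: KmerCountTable, spikein_scaled: bool) -> pd.Series:
    if not spikein_scaled:
        return to_rpm(table)
    if table.spikein_count <= 0:
        raise ValueError(
            f"spike-in scaling requested but sample {table.sample_id!r} has no "
            "spike-in counts"
        )
    # per-spike-in-read units, on an RPM-like scale
    return (table.counts * 1e6 / table.spikein_count).rename(table.sample_id)


def log2_ratio(
    numerator: KmerCountTable | Sequence[KmerCountTable],
    denominator: KmerCountTable | Sequence[KmerCountTable],
    universe: pd.Index | None = None,
    spikein_scaled: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Mean per-7-mer log2 ratio over paired replicate tables.

    ``numerator`` and ``denominator`` are single tables or equal-length
    replicate lists paired in order.  ``universe`` restricts the index (e.g.
    the detection-passing set); by default the union of observed 7-mers is
    used in both tables of each pair.
    """
    nums = [numerator] if isinstance(numerator, KmerCountTable) else list(numerator)
    dens = [denominator] if isinstance(denominator, KmerCountTable) else list(denominator)
    if len(nums) != len(dens):
        raise ValueError("numerator and denominator replicate lists differ in length")
    reps = []
    for num, den in zip(nums, dens):
        idx = universe
        if idx is None:
            idx = num.counts.index.union(den.counts.index)
        a = _normalized_abundance(num, spikein_scaled).reindex(idx, fill_value=0.0)
        b = _normalized_abundance(den, spikein_scaled).reindex(idx, fill_value=0.0)
        if universe is not None and (idx.difference(num.counts.index.union(den.counts.index))).size == idx.size:
            raise ValueError("universe shares no 7-mers with the tables")
        reps.append(np.log2((a + pseudocount) / (b + pseudocount)))
    return pd.concat(reps, axis=1).mean(axis=1).rename("l2fc")


def psp_translation(
    polysome: KmerCountTable | Sequence[KmerCountTable],
    subpolysome: KmerCountTable | Sequence[KmerCountTable],
    universe: pd.Index | None = None,
    spikein_scaled: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2 polysome / sub-polysome ratio (translation proxy).

    Spike-in scaling is the default because equal spike-in amounts are added
    to each fraction, making the ratio comparable across fractions of very
    different total RNA content; ``spikein_scaled=False`` falls back to RPM.
    """
    return log2_ratio(
        polysome, subpolysome, universe=universe,
        spikein_scaled=spikein_scaled, pseudocount=pseudocount,
    ).rename("l2_psp")


def build_regulation_table(
    l2_psp_control: pd.Series,
    l2_psp_torin: pd.Series,
    l2_decay_control: pd.Series,
    l2_decay_torin: pd.Series,
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """Assemble the per-7-mer regulation table.

    Entries are restricted to 7-mers present in all four inputs (and in
    ``universe`` when given -- typically the detection-passing set);
    ``delta_psp`` and ``delta_decay`` are the Torin-minus-control differences.
    """
    parts = {
        "l2_psp_control": l2_psp_control,
        "l2_psp_torin": l2_psp_torin,
        "l2_decay_control": l2_decay_control,
        "l2_decay_torin": l2_decay_torin,
    }
    df = pd.DataFrame(parts).dropna()
    if universe is not None:
        df = df.loc[df.index.intersection(universe)]
    df["delta_psp"] = df["l2_psp_torin"] - df["l2_psp_control"]
    df["delta_decay"] = df["l2_decay_torin"] - df["l2_decay_control"]
    df.index.name = "sevenmer"
    return df.sort_index()


def condition_delta(
    reg_table: pd.DataFrame,
    metric: str = "psp",
    strata: tuple[str, str] = ("AG", "CT"),
) -> dict:
    """Torin-vs-control delta with a Welch test between two 5'-start strata.

    ``metric`` is ``'psp'`` or ``'decay'``; ``strata`` are +1-anchored
    patterns (e.g. the AG vs CT/CU dinucleotide classes).  Returns the
    per-7-mer delta series plus group means and the Welch statistic/p-value.
    """
    col = f"delta_{metric}"
    if col not in reg_table:
        raise KeyError(f"no column {col!r}; metric must be 'psp' or 'decay'")
    delta = reg_table[col]
    groups = []
    for pattern in strata:
        mask = motifs.match_mask(delta.index, pattern)
        vals = delta.values[mask]
        if len(vals) < 2:
            raise ValueError(f"stratum {pattern!r} has fewer than 2 members")
        groups.append(vals)
    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    if np.isnan(t):
        t, p = 0.0, 1.0
    return {
        "delta": delta,
        "strata": dict(zip(strata, (float(np.mean(g)) for g in groups))),
        "n": dict(zip(strata, (len(g) for g in groups))),
        "t": float(t),
        "p": float(p),
    }


def translation_stability_correlation(
    reg_table: pd.DataFrame, condition: str
) -> dict:
    """Pearson/Spearman correlation between translation (l2 P/SP) and
    stability (l2 ActD+/ActD-) for one condition, overall and per +1
    nucleotide stratum."""
    condition = condition.lower()
    x = reg_table[f"l2_psp_{condition}"]
    y = reg_table[f"l2_decay_{condition}"]
    paired = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(paired) < 10:
        raise ValueError("need >= 10 paired entries")

    def _corr(sub: pd.DataFrame) -> dict:
        if sub["x"].std() == 0 or sub["y"].std() == 0:
            raise ValueError("degenerate variance")
        r, p_r = stats.pearsonr(sub["x"], sub["y"])
        rho, p_rho = stats.spearmanr(sub["x"], sub["y"])
        return {
            "n": int(len(sub)),
            "pearson_r": float(r),
            "pearson_p": float(p_r),
            "spearman_rho": float(rho),
            "spearman_p": float(p_rho),
        }

    out = _corr(paired)
    out["by_plus1"] = {
        nt: _corr(grp)
        for nt, grp in paired.groupby(paired.index.str[0])
        if len(grp) >= 10 and grp["x"].std() > 0 and grp["y"].std() > 0
    }
    return out


def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (for exploratory motif scans)."""
    adj = stats.false_discovery_control(pvalues.values, method="bh")
    return pd.Series(adj, index=pvalues.index, name="padj")


def read_supplementary_l2fc(path: str | Path) -> pd.DataFrame:
    """Read an externally supplied per-7-mer fold-change table for
    validation (columns: 7-mer sequence, l2fc, optional padj; tab-separated,
    with or without a header).  U is converted to T."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0].upper().replace("U", "T").isalpha() and len(df.columns[0]) == 7:
        # headerless file: first row was data
        df = pd.read_csv(path, sep="\t", header=None)
    df = df.rename(
        columns={df.columns[0]: "sevenmer", df.columns[1]: "l2fc"}
    )
    df["sevenmer"] = df["sevenmer"].astype(str).str.upper().str.replace("U", "T")
    return df.set_index("sevenmer")


def rank_agreement(values: pd.Series, reference: pd.Series) -> dict:
    """Spearman rank agreement between this pipeline's estimates and an
    external reference (e.g. shrinkage-based fold changes)."""
    shared = values.index.intersection(reference.index)
    if len(shared) < 10:
        raise ValueError("fewer than 10 shared 7-mers")
    rho, p = stats.spearmanr(values.reindex(shared), reference.reindex(shared))
    return {"n": int(len(shared)), "spearman_rho": float(rho), "spearman_p": float(p)}
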