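"""Endogenous transcription start site analysis from CAGE-style 5' tags.

Inputs are alignment-free: strand-aware genomic 5'-tag positions with counts
(CTSS 4-column text or single-base BED6), a genome FASTA and a transcript
annotation giving one annotated TSS per gene.  Coordinates are 0-based
half-open throughout.  The analysis extracts tags within a promoter window
around each annotated TSS, reads the genomic k-mer at each tag's 5' end in
transcript orientation, excludes +1 G tags (mirroring the reporter-library
exclusion), and compares k-mer frequencies with library-derived values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CageTagSet:
    """Strand-aware genomic 5'-tag positions with counts.

    ``df`` has columns ``chrom, pos, strand, count``; ``pos`` is the 0-based
    genomic coordinate of the tag's 5' end, one row per (chrom, pos, strand).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "strand", "count"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing tag columns: {missing}")
        df = self.df[required].copy()
        df = df.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
        if (df["count"] < 1).any():
            raise ValueError("tag counts must be >= 1")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be + or -")
        self.df = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)

    @property
    def total(self) -> int:
        return int(self.df["count"].sum())

    @classmethod
    def from_ctss(cls, path: str | Path) -> "CageTagSet":
        """Read CTSS-style text: chrom, pos, strand, count (tab-separated)."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "strand", "count"]
        )
        return cls(df)

    @classmethod
    def from_bed6(cls, path: str | Path) -> "CageTagSet":
        """Read single-base BED6 intervals; score column carries the count.
        For a minus-strand tag the 5' end is ``end - 1`` (= start for a
        single-base interval)."""
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        if ((bed["end"] - bed["start"]) != 1).any():
            raise ValueError("tag BED must contain single-base intervals")
        return cls(
            pd.DataFrame(
                {
                    "chrom": bed["chrom"],
                    "pos": bed["start"],
                    "strand": bed["strand"],
                    "count": bed["score"].astype(int),
                }
            )
        )

    def to_ctss(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class TranscriptAnnotation:
    """Per-gene annotated TSS: columns ``gene_id, chrom, strand, tss`` and an
    optional ``gene_class`` tag (e.g. ``RP`` for ribosomal protein genes)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "strand", "tss"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing annotation columns: {missing}")
        df = self.df.copy()
        if "gene_class" not in df.columns:
            df["gene_class"] = ""
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be + or -")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_bed6(cls, path: str | Path) -> "TranscriptAnnotation":
        """Gene TSSs as single-base BED6 intervals; the name column is the
        gene id, optionally suffixed ``|<gene_class>``."""
        bed = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        if ((bed["end"] - bed["start"]) != 1).any():
            raise ValueError("annotation BED must contain single-base TSS intervals")
        name = bed["name"].astype(str).str.split("|")
        return cls(
            pd.DataFrame(
                {
                    "gene_id": name.str[0],
                    "chrom": bed["chrom"],
                    "strand": bed["strand"],
                    "tss": bed["start"],
                    "gene_class": name.str[1].fillna(""),
                }
            )
        )

    def to_bed6(self, path: str | Path) -> None:
        df = self.df
        name = df["gene_id"] + np.where(
            df["gene_class"].astype(bool), "|" + df["gene_class"].astype(str), ""
        )
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["tss"],
                "end": df["tss"] + 1,
                "name": name,
                "score": 0,
                "strand": df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------
# genome access


def load_genome(source) -> dict[str, str]:
    """Return a chrom -> sequence dict from a FASTA path, a pyfaidx.Fasta, or
    an already-loaded dict."""
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(source))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    # pyfaidx.Fasta or similar mapping of records
    return {name: str(source[name][:]).upper() for name in source.keys()}


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------
# operations


def extract_promoter_tags(
    tags: CageTagSet, annotation: TranscriptAnnotation, window: int = 1000
) -> pd.DataFrame:
    """Tags within the promoter window of each gene, with gene assignment.

    A gene's promoter is the symmetric half-open window
    ``|pos - tss| < window/2`` on the gene's strand.  A tag inside several
    genes' windows appears once per containing gene (per-gene analyses);
    global frequency computations deduplicate on (chrom, pos, strand).
    Returns columns ``chrom, pos, strand, count, gene_id, gene_class,
    offset`` where ``offset`` is the tag position in transcript orientation
    (annotated TSS = 0, positive downstream).
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be a positive even integer")
    half = window // 2
    ann = annotation.df.sort_values("tss")
    close = ann.groupby(["chrom", "strand"])["tss"].diff().dropna()
    if (close < window).any():
        warnings.warn("some same-strand genes are closer than the window width")
    out = []
    for _, gene in annotation.df.iterrows():
        sel = tags.df[
            (tags.df["chrom"] == gene["chrom"])
            & (tags.df["strand"] == gene["strand"])
            & ((tags.df["pos"] - gene["tss"]).abs() < half)
        ].copy()
        if sel.empty:
            continue
        sel["gene_id"] = gene["gene_id"]
        sel["gene_class"] = gene["gene_class"]
        sign = 1 if gene["strand"] == "+" else -1
        sel["offset"] = sign * (sel["pos"] - gene["tss"])
        out.append(sel)
    if not out:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "count", "gene_id", "gene_class", "offset"]
        )
    return pd.concat(out, ignore_index=True)


def _tag_kmer(genome: dict[str, str], chrom: str, pos: int, strand: str, k: int) -> str | None:
    seq = genome[chrom]
    if strand == "+":
        if pos + k > len(seq):
            return None
        return seq[pos : pos + k]
    if pos - k + 1 < 0:
        return None
    return revcomp(seq[pos - k + 1 : pos + 1])


def tag_kmer_frequencies(
    tags: CageTagSet | pd.DataFrame,
    genome,
    k: int = 3,
    exclude_plus1G: bool = True,
    count_weighted: bool = True,
) -> pd.Series:
    """k-mer frequencies at tag 5' ends in transcript orientation.

    For each tag the genomic k-mer beginning at its 5' end is read on the
    tag's strand (reverse-complemented for minus-strand tags).  Tags whose +1
    base is G are dropped when ``exclude_plus1G``; tags within ``k`` of a
    contig end are dropped with a warning.  Frequencies are count-weighted
    (``count_weighted=False`` collapses each tag position to weight 1) and
    sum to 1 over retained tags.
    """
    genome = load_genome(genome)
    df = tags.df if isinstance(tags, CageTagSet) else tags
    df = df.drop_duplicates(subset=["chrom", "pos", "strand"])
    weights: dict[str, float] = {}
    n_edge = 0
    for chrom, pos, strand, count in zip(df["chrom"], df["pos"], df["strand"], df["count"]):
        kmer = _tag_kmer(genome, chrom, int(pos), strand, k)
        if kmer is None:
            n_edge += 1
            continue
        if exclude_plus1G and kmer[0] == "G":
            continue
        weights[kmer] = weights.get(kmer, 0.0) + (count if count_weighted else 1)
    if n_edge:
        warnings.warn(f"dropped {n_edge} tag(s) within {k} nt of a contig end")
    if not weights:
        raise ValueError("no retained tags")
    freq = pd.Series(weights, dtype=float).sort_index()
    return freq / freq.sum()


def compare_library_to_cage(
    library_values: pd.Series, cage_freqs: pd.Series
) -> dict:
    """Correlate library-derived per-k-mer values with CAGE k-mer frequencies.

    Both vectors are log10-scaled with a floor at each vector's smallest
    positive observation (the comparison spans orders of magnitude).  Returns
    Pearson r and Spearman rho with p-values over the shared k-mer universe.
    """
    shared = library_values.index.intersection(cage_freqs.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared k-mers; need >= 10")
    x = library_values.reindex(shared).astype(float)
    y = cage_freqs.reindex(shared).astype(float)

    def _log(v: pd.Series) -> np.ndarray:
        pos = v[v > 0]
        if pos.empty:
            raise ValueError("degenerate values: nothing positive")
        return np.log10(v.clip(lower=pos.min()).values)

    lx, ly = _log(x), _log(y)
    if np.std(lx) == 0 or np.std(ly) == 0:
        raise ValueError("degenerate variance")
    r, p_r = stats.pearsonr(lx, ly)
    rho, p_rho = stats.spearmanr(lx, ly)
    return {
        "n": int(len(shared)),
        "pearson_r": float(r),
        "pearson_p": float(p_r),
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
    }


def gene_subset_frequencies(
    tags: CageTagSet,
    annotation: TranscriptAnnotation,
    gene_list,
    genome,
    k: int = 3,
    window: int = 1000,
    exclude_plus1G: bool = True,
) -> pd.Series:
    """k-mer frequencies over tags assigned to a gene subset (e.g. ribosomal
    protein genes).  Tags assigned to several listed genes count once."""
    gene_list = list(gene_list)
    known = set(annotation.df["gene_id"])
    missing = [g for g in gene_list if g not in known]
    if missing:
        warnings.warn(f"{len(missing)} gene id(s) not in the annotation: {missing[:5]}")
    keep = [g for g in gene_list if g in known]
    if not keep:
        raise ValueError("no listed gene is present in the annotation")
    sub_ann = TranscriptAnnotation(
        annotation.df[annotation.df["gene_id"].isin(keep)].copy()
    )
    assigned = extract_promoter_tags(tags, sub_ann, window=window)
    if assigned.empty:
        raise ValueError("no tags fall in the listed genes' promoter windows")
    return tag_kmer_frequencies(
        assigned, genome, k=k, exclude_plus1G=exclude_plus1G
    )


def bam_to_tags(bam_path: str | Path, min_mapq: int = 0) -> CageTagSet:
    """Collapse a coordinate-sorted BAM into 5'-tag counts.

    The tag position is the aligned 5' end of each read: ``reference_start``
    on the plus strand, ``reference_end - 1`` on the minus strand.  Soft-
    clipped bases (e.g. removed non-templated 5' Gs) are outside the aligned
    span and therefore never shift the tag.
    """
    import pysam

    tally: dict[tuple, int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_reverse:
                key = (read.reference_name, read.reference_end - 1, "-")
            else:
                key = (read.reference_name, read.reference_start, "+")
            tally[key] = tally.get(key, 0) + 1
    df = pd.DataFrame(
        [(c, p, s, n) for (c, p, s), n in tally.items()],
        columns=["chrom", "pos", "strand", "count"],
    )
    return CageTagSet(df)
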