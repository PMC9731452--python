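"""Classification of 5'-end reads against the reporter construct.

Each sequencing read is the 5' terminus of one library mRNA, possibly
prefixed by one or more non-templated G nucleotides introduced when reverse
transcriptase appends an extra cytidine opposite the cap.  Classification
anchors the read on the construct via a constant seed sequence, then asks
which origins (start position, number of artifact Gs) are consistent with the
template:

* a read whose leading Gs all mismatch known template bases has a single
  consistent origin -- the Gs are stripped and the start is definitive;
* a read whose first retained base would be a G inside the randomized
  cassette can always be explained both as a genuine +1..+7 G start and as a
  shorter start plus an artifact G, so it is irreducibly ambiguous (the
  ``ambiguous_plus1G`` category; such reads are excluded from 7-mer counts);
* reads starting upstream or downstream of the cassette are recorded with
  their start position but contribute no 7-mer.

``classify_read`` reports the full origin analysis for one read;
``quantify_fastq`` streams a FASTQ file into a :class:`KmerCountTable`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from .construct import ConstructTemplate

CATEGORIES = (
    "cassette_start",
    "upstream_start",
    "downstream_start",
    "ambiguous_plus1G",
    "no_seed",
    "truncated",
    "spikein",
)

DEFAULT_MAX_SCAN = 60
DEFAULT_MAX_ARTIFACT_G = 2
DEFAULT_SPIKEIN_MATCH_LEN = 15
BASE5_LEN = 30


@dataclass(frozen=True)
class FivePrimeCall:
    """Origin classification of a single 5'-end read."""

    read_id: str
    category: str
    align_offset: int | None = None  # construct coord of first templated base
    n_stripped_G: int = 0
    base5: str = ""  # inferred templated 5' sequence (<= 30 nt window)
    sevenmer: str | None = None  # present iff category == cassette_start
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if (self.sevenmer is not None) != (self.category == "cassette_start"):
            raise ValueError("sevenmer defined iff category == cassette_start")


@dataclass
class KmerCountTable:
    """Per-sample 7-mer counts with category tallies.

    ``counts`` maps each observed 7-mer to a non-negative integer;
    ``excluded`` tallies every read that did not yield a definitive cassette
    start, keyed by category.
    """

    sample_id: str
    counts: pd.Series
    condition: dict = field(default_factory=dict)
    replicate: int | None = None
    excluded: dict = field(default_factory=dict)
    spikein_count: int = 0

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts, dtype="int64").sort_index()
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total_assigned(self) -> int:
        return int(self.counts.sum())

    @property
    def total_reads(self) -> int:
        return self.total_assigned + sum(self.excluded.values()) + self.spikein_count

    def to_tsv(self, path: str | Path, sidecar: dict | None = None) -> None:
        df = self.counts.rename("count").rename_axis("sevenmer").reset_index()
        df.to_csv(path, sep="\t", index=False)
        side = {
            "sample_id": self.sample_id,
            "condition": self.condition,
            "replicate": self.replicate,
            "excluded": self.excluded,
            "spikein_count": self.spikein_count,
        }
        if sidecar:
            side.update(sidecar)
        Path(str(path) + ".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "KmerCountTable":
        df = pd.read_csv(path, sep="\t")
        meta_path = Path(str(path) + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            sample_id=sample_id or meta.get("sample_id", Path(path).stem),
            counts=pd.Series(df["count"].values, index=df["sevenmer"].values),
            condition=meta.get("condition", {}),
            replicate=meta.get("replicate"),
            excluded=meta.get("excluded", {}),
            spikein_count=meta.get("spikein_count", 0),
        )


# ---------------------------------------------------------------------
# seed search


def find_seed(
    read_seq: str,
    template: ConstructTemplate,
    max_scan: int = DEFAULT_MAX_SCAN,
    max_mismatches: int = 0,
) -> int | None:
    """Offset of the first occurrence of the anchoring seed within the first
    ``max_scan`` start positions of the read, or ``None`` if absent.

    ``max_mismatches`` > 0 enables a tolerant scan (first position with at
    most that many mismatches); the default exact search is used throughout
    the pipeline because the seed lies in a constant region.
    """
    seed = template.seed
    if max_mismatches <= 0:
        pos = read_seq.find(seed, 0, max_scan + len(seed))
        return pos if pos >= 0 else None
    k = len(seed)
    limit = min(max_scan, len(read_seq) - k)
    for pos in range(limit + 1):
        window = read_seq[pos : pos + k]
        mismatches = sum(a != b for a, b in zip(window, seed))
        if mismatches <= max_mismatches:
            return pos
    return None


# ---------------------------------------------------------------------
# per-read origin analysis


class _TemplateCtx:
    """Precomputed lookups for fast per-read classification."""

    __slots__ = (
        "template", "seed", "seed_index", "tss", "cassette_len",
        "full_known", "known_mask", "max_scan", "max_artifact_g",
        "spikein_prefixes", "length",
    )

    def __init__(
        self,
        template: ConstructTemplate,
        max_scan: int = DEFAULT_MAX_SCAN,
        max_artifact_g: int = DEFAULT_MAX_ARTIFACT_G,
        spikein_match_len: int = DEFAULT_SPIKEIN_MATCH_LEN,
    ) -> None:
        self.template = template
        self.seed = template.seed
        self.seed_index = template.seed_index
        self.tss = template.expected_tss_index
        self.cassette_len = template.cassette_len
        self.length = template.length
        self.max_scan = max_scan
        self.max_artifact_g = max_artifact_g
        # template with cassette marked unknown ('?'), for O(1) base lookups
        self.full_known = (
            template.promoter_seq + "?" * template.cassette_len + template.downstream_seq
        )
        # spike-in 5' prefixes with 0..max_artifact_g leading artifact Gs
        self.spikein_prefixes: tuple[str, ...] = ()
        if template.spikein_seq is not None:
            prefix = template.spikein_seq[:spikein_match_len]
            self.spikein_prefixes = tuple(
                "G" * g + prefix for g in range(max_artifact_g + 1)
            )


def _classify(ctx: _TemplateCtx, read_seq: str):
    """Classify one read.  Returns ``(category, start, n_stripped, sevenmer)``
    where ``start`` is the construct coordinate of the first templated base
    (``None`` when undefined)."""
    for pref in ctx.spikein_prefixes:
        if read_seq.startswith(pref):
            return "spikein", None, None, None

    s = find_seed(read_seq, ctx.template, ctx.max_scan)
    if s is None:
        return "no_seed", None, None, None

    p0 = ctx.seed_index - s  # construct coord aligned with read position 0
    if p0 < 0:
        # more 5' sequence than the construct can hold upstream of the seed
        return "no_seed", None, None, None

    # leading G run (cannot extend into the seed match)
    m = 0
    while m < s and read_seq[m] == "G":
        m += 1

    # read bases beyond the G run must match every known template base
    # (independent of how many leading Gs are artifacts)
    full = ctx.full_known
    n_check = min(len(read_seq), ctx.length - p0)
    for i in range(m, n_check):
        b = full[p0 + i]
        if b != "?" and b != read_seq[i]:
            return "no_seed", None, None, None

    # consistent artifact-G counts: g leading Gs are non-templated, the
    # remaining Gs of the run must each sit on a cassette position or a
    # templated G
    interpretations: list[tuple[int, int, str | None]] = []  # (g, start, sevenmer)
    seen: set[tuple[int, str | None]] = set()
    for g in range(min(m, ctx.max_artifact_g) + 1):
        start = p0 + g
        if start < 0 or start >= ctx.length:
            continue
        ok = True
        for i in range(g, m):
            b = full[p0 + i]
            if b != "?" and b != "G":
                ok = False
                break
        if not ok:
            continue
        sevenmer = None
        if start == ctx.tss and read_seq[g] != "G":
            if s - g < ctx.cassette_len:
                return "truncated", None, None, None
            sevenmer = read_seq[g : g + ctx.cassette_len]
        key = (start, sevenmer)
        if key not in seen:
            seen.add(key)
            interpretations.append((g, start, sevenmer))

    if not interpretations:
        return "no_seed", None, None, None
    if len(interpretations) > 1:
        # >= 2 consistent origins differing in TSS or 7-mer: the leading G(s)
        # cannot be resolved (the paper's +1 G ambiguity)
        return "ambiguous_plus1G", None, None, None

    g, start, sevenmer = interpretations[0]
    if sevenmer is not None:
        return "cassette_start", start, g, sevenmer
    if ctx.tss <= start < ctx.tss + ctx.cassette_len:
        if read_seq[g] == "G":
            # definitive +1..+7 G start (artifact budget exhausted): still
            # excluded, because +1 G 7-mer counts are unreliable
            return "ambiguous_plus1G", None, None, None
        return "downstream_start", start, g, None
    if start < ctx.tss:
        return "upstream_start", start, g, None
    return "downstream_start", start, g, None


def classify_read(
    read_seq: str,
    template: ConstructTemplate,
    read_id: str = "",
    max_scan: int = DEFAULT_MAX_SCAN,
    max_artifact_g: int = DEFAULT_MAX_ARTIFACT_G,
    spikein_match_len: int = DEFAULT_SPIKEIN_MATCH_LEN,
    sample_id: str | None = None,
) -> FivePrimeCall:
    """Classify a single read's 5' origin against the construct template."""
    ctx = _TemplateCtx(template, max_scan, max_artifact_g, spikein_match_len)
    return _call_from_tuple(ctx, read_id, read_seq, _classify(ctx, read_seq), sample_id)


def _call_from_tuple(ctx, read_id, read_seq, tup, sample_id=None) -> FivePrimeCall:
    category, start, g, sevenmer = tup
    base5 = read_seq[g : g + BASE5_LEN] if g is not None else ""
    return FivePrimeCall(
        read_id=read_id,
        category=category,
        align_offset=start,
        n_stripped_G=g if g is not None else 0,
        base5=base5,
        sevenmer=sevenmer,
        sample_id=sample_id,
    )


def classify_reads(
    reads: Iterable[tuple[str, str]],
    template: ConstructTemplate,
    max_scan: int = DEFAULT_MAX_SCAN,
    max_artifact_g: int = DEFAULT_MAX_ARTIFACT_G,
    spikein_match_len: int = DEFAULT_SPIKEIN_MATCH_LEN,
    sample_id: str | None = None,
) -> Iterator[FivePrimeCall]:
    """Classify an iterable of ``(read_id, sequence)`` pairs."""
    ctx = _TemplateCtx(template, max_scan, max_artifact_g, spikein_match_len)
    for read_id, seq in reads:
        yield _call_from_tuple(ctx, read_id, seq, _classify(ctx, seq), sample_id)


# ---------------------------------------------------------------------
# aggregation


def collapse_calls(
    calls: Iterable[FivePrimeCall],
    sample_id: str | None = None,
    condition: dict | None = None,
    replicate: int | None = None,
) -> KmerCountTable:
    """Sum cassette-start calls per base 7-mer (read groups differing only in
    their number of stripped non-templated Gs collapse together) and tally
    every excluded category.  Mixing calls from different samples is an error.
    """
    counts: dict[str, int] = {}
    excluded = {c: 0 for c in CATEGORIES if c not in ("cassette_start", "spikein")}
    spikein = 0
    sample_seen: set = set()
    for call in calls:
        sample_seen.add(call.sample_id)
        if len(sample_seen) > 1:
            raise ValueError(f"calls from multiple samples: {sorted(map(str, sample_seen))}")
        if call.category == "cassette_start":
            counts[call.sevenmer] = counts.get(call.sevenmer, 0) + 1
        elif call.category == "spikein":
            spikein += 1
        else:
            excluded[call.category] += 1
    if sample_id is None and sample_seen:
        (only,) = sample_seen
        sample_id = only or "sample"
    return KmerCountTable(
        sample_id=sample_id or "sample",
        counts=pd.Series(counts, dtype="int64"),
        condition=condition or {},
        replicate=replicate,
        excluded={k: v for k, v in excluded.items() if v},
        spikein_count=spikein,
    )


def count_and_remove_spikein(
    reads: Sequence[tuple[str, str]],
    spikein_seq: str,
    match_len: int = DEFAULT_SPIKEIN_MATCH_LEN,
    max_artifact_g: int = DEFAULT_MAX_ARTIFACT_G,
) -> tuple[int, list[tuple[str, str]]]:
    """Count reads whose 5' end matches the spike-in's first ``match_len``
    nucleotides (allowing leading artifact Gs) and return the rest."""
    prefix = spikein_seq[:match_len]
    prefixes = tuple("G" * g + prefix for g in range(max_artifact_g + 1))
    count = 0
    remaining: list[tuple[str, str]] = []
    for rid, seq in reads:
        if seq.startswith(prefixes):
            count += 1
        else:
            remaining.append((rid, seq))
    return count, remaining


def tss_position_distribution(
    calls: Iterable[FivePrimeCall], template: ConstructTemplate
) -> dict[int, float]:
    """Fractions of inferred start positions (relative to the expected +1
    position) over all reads with a definitive origin.  Ambiguous, seedless
    and spike-in reads carry no position and are excluded."""
    tss = template.expected_tss_index
    tally: dict[int, int] = {}
    for call in calls:
        if call.category in ("cassette_start", "upstream_start", "downstream_start"):
            off = call.align_offset - tss
            tally[off] = tally.get(off, 0) + 1
    total = sum(tally.values())
    if total == 0:
        raise ValueError("no reads with a definitive start position")
    return {off: n / total for off, n in sorted(tally.items())}


# ---------------------------------------------------------------------
# FASTQ pipeline


def quantify_fastq(
    fastq_path: str | Path,
    template: ConstructTemplate,
    sample_id: str | None = None,
    condition: dict | None = None,
    replicate: int | None = None,
    max_scan: int = DEFAULT_MAX_SCAN,
    max_artifact_g: int = DEFAULT_MAX_ARTIFACT_G,
    spikein_match_len: int = DEFAULT_SPIKEIN_MATCH_LEN,
) -> tuple[KmerCountTable, dict]:
    """Stream a FASTQ file into per-7-mer counts.

    Returns the :class:`KmerCountTable` and a summary dict with category
    tallies, the spike-in count and the TSS position distribution over reads
    with a definitive origin.
    """
    ctx = _TemplateCtx(template, max_scan, max_artifact_g, spikein_match_len)
    tss = ctx.tss
    counts: dict[str, int] = {}
    excluded = {c: 0 for c in CATEGORIES if c not in ("cassette_start", "spikein")}
    offsets: dict[int, int] = {}
    spikein = 0
    n_reads = 0
    with pysam.FastxFile(str(fastq_path)) as fh:
        for entry in fh:
            n_reads += 1
            category, start, g, sevenmer = _classify(ctx, entry.sequence)
            if category == "cassette_start":
                counts[sevenmer] = counts.get(sevenmer, 0) + 1
            elif category == "spikein":
                spikein += 1
            else:
                excluded[category] += 1
            if start is not None:
                off = start - tss
                offsets[off] = offsets.get(off, 0) + 1
    table = KmerCountTable(
        sample_id=sample_id or Path(fastq_path).stem,
        counts=pd.Series(counts, dtype="int64"),
        condition=condition or {},
        replicate=replicate,
        excluded={k: v for k, v in excluded.items() if v},
        spikein_count=spikein,
    )
    n_pos = sum(offsets.values())
    summary = {
        "n_reads": n_reads,
        "assigned": table.total_assigned,
        "excluded": dict(table.excluded),
        "spikein_count": spikein,
        "tss_position_distribution": (
            {k: v / n_pos for k, v in sorted(offsets.items())} if n_pos else {}
        ),
    }
    return table, summary
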