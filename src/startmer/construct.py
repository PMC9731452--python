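"""Reporter construct coordinate model.

All read-processing operations share one coordinate system: 0-based positions
on the mRNA-sense construct sequence, running promoter -> randomized cassette
-> constant downstream 5' UTR.  The first cassette base is the transcript's
"+1" nucleotide (index ``expected_tss_index``); human-readable output adds 1
to recover the +1/+2/+3 convention.  The cassette itself is per-molecule
unknown and is represented by ``N`` placeholders in template FASTA files.

The internal alphabet is DNA; ``U`` is accepted on input and stored as ``T``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

NUCLEOTIDES = "ACGT"

#: Constant seed anchoring reads to the construct: the first 10 nt of the
#: constant region downstream of the randomized cassette.
DEFAULT_SEED = "AGCCGCCGCC"

#: Promoter region immediately upstream of the randomized cassette
#: (mRNA-sense; the final base is the -1 position).
DEFAULT_PROMOTER = "CAGAGCTGGTTTAGTGAACCGTC"

#: Constant 5' UTR beginning immediately after the cassette.
DEFAULT_DOWNSTREAM = (
    "GCCGCAGCCGCCGCC"
    "ATCGTCGACGCGCGCTTCCCTGTTCACCTCTGACTCTGAGAATCCGTCGCC"
)

#: Capped spike-in mRNA sequence (5' -> 3').  Its 5' end mimics a library
#: transcript with a TOP-like CTCTTCC start but carries a private CATG insert
#: before the constant region, so spike-in reads are distinguishable from a
#: genuine CTCTTCC library read.
SPIKEIN_SEQ = (
    "CTCTTCCCATGGCCGCAGCCGCCGCCATCGTCGACGCGCGCTTCCCTGTTCACCTCTGACTCT"
    "GAGAATCCGTCGCCATCCGCCACCGGCGCGCCGCTAGCCACCATGACTTCGAAAGTTTATG"
)


class ConstructError(ValueError):
    """Invalid construct template or configuration."""


def clean_seq(seq: str, allow_n: bool = False) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    s = seq.strip().upper().replace("U", "T")
    allowed = set(NUCLEOTIDES) | ({"N"} if allow_n else set())
    bad = set(s) - allowed
    if bad:
        raise ConstructError(f"non-ACGT{'N' if allow_n else ''} characters: {sorted(bad)}")
    return s


def as_sevenmer(seq: str) -> str:
    """Validate a 7-mer (length 7, unambiguous DNA; U accepted as T)."""
    s = clean_seq(seq)
    if len(s) != 7:
        raise ConstructError(f"7-mer must have length 7, got {len(s)}: {seq!r}")
    return s


def all_kmers(k: int) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)]


@dataclass(frozen=True)
class ConstructTemplate:
    """Coordinate model of the reporter construct.

    Parameters
    ----------
    promoter_seq
        Template-strand (mRNA-sense) sequence ending immediately before the
        randomized cassette.
    cassette_len
        Length of the randomized cassette (7 for the standard library).
    downstream_seq
        Constant sequence beginning immediately after the cassette.
    seed
        Substring of ``downstream_seq`` used to anchor reads; must occur
        exactly once there.
    spikein_seq
        Full spike-in mRNA sequence, or ``None`` when no spike-in was used.
    """

    promoter_seq: str = DEFAULT_PROMOTER
    cassette_len: int = 7
    downstream_seq: str = DEFAULT_DOWNSTREAM
    seed: str = DEFAULT_SEED
    spikein_seq: str | None = SPIKEIN_SEQ

    def __post_init__(self) -> None:
        object.__setattr__(self, "promoter_seq", clean_seq(self.promoter_seq))
        object.__setattr__(self, "downstream_seq", clean_seq(self.downstream_seq))
        object.__setattr__(self, "seed", clean_seq(self.seed))
        if self.spikein_seq is not None:
            object.__setattr__(self, "spikein_seq", clean_seq(self.spikein_seq))
        if self.cassette_len < 1:
            raise ConstructError("cassette_len must be >= 1")
        if self.downstream_seq.count(self.seed) != 1:
            raise ConstructError(
                f"seed {self.seed!r} must occur exactly once in the downstream "
                f"region (found {self.downstream_seq.count(self.seed)})"
            )

    # -- coordinates ---------------------------------------------------

    @property
    def expected_tss_index(self) -> int:
        """Construct coordinate of the cassette's first base (the +1 nt)."""
        return len(self.promoter_seq)

    @property
    def length(self) -> int:
        return len(self.promoter_seq) + self.cassette_len + len(self.downstream_seq)

    @property
    def seed_index(self) -> int:
        """Construct coordinate of the seed's first base."""
        return (
            self.expected_tss_index
            + self.cassette_len
            + self.downstream_seq.index(self.seed)
        )

    def base_at(self, coord: int) -> str | None:
        """Template base at a construct coordinate; ``None`` inside the
        cassette (per-molecule unknown).  Raises ``IndexError`` off-template."""
        if coord < 0 or coord >= self.length:
            raise IndexError(f"coordinate {coord} outside construct [0, {self.length})")
        tss = self.expected_tss_index
        if coord < tss:
            return self.promoter_seq[coord]
        if coord < tss + self.cassette_len:
            return None
        return self.downstream_seq[coord - tss - self.cassette_len]

    def in_cassette(self, coord: int) -> bool:
        tss = self.expected_tss_index
        return tss <= coord < tss + self.cassette_len

    def transcript(self, cassette: str, start_offset: int = 0) -> str:
        """mRNA-sense sequence of a molecule carrying ``cassette``, from
        ``start_offset`` (relative to the +1 position) to the construct end."""
        cassette = clean_seq(cassette)
        if len(cassette) != self.cassette_len:
            raise ConstructError(
                f"cassette length {len(cassette)} != {self.cassette_len}"
            )
        full = self.promoter_seq + cassette + self.downstream_seq
        start = self.expected_tss_index + start_offset
        if start < 0 or start >= self.length:
            raise ConstructError(f"start offset {start_offset} outside construct")
        return full[start:]

    def fasta_seq(self) -> str:
        """Construct sequence with the cassette as an N-run placeholder."""
        return self.promoter_seq + "N" * self.cassette_len + self.downstream_seq


# -- FASTA + config round trip -----------------------------------------


def _read_single_fasta(path: str | Path) -> str:
    seqs: list[str] = []
    n_records = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                n_records += 1
            else:
                seqs.append(line)
    if n_records != 1:
        raise ConstructError(f"expected exactly one FASTA record, found {n_records}")
    return "".join(seqs)


def load_template(fasta_path: str | Path, config: dict | str | Path) -> ConstructTemplate:
    """Build a :class:`ConstructTemplate` from a template FASTA and a config.

    ``config`` is a mapping (or path to a YAML file) with keys
    ``cassette_start``, ``cassette_len`` (default 7), ``seed`` and optionally
    ``spikein_seq``.  The cassette region of the FASTA may be any placeholder
    (typically an N-run); its content is discarded as per-molecule unknown.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seq = clean_seq(_read_single_fasta(fasta_path), allow_n=True)
    start = int(config["cassette_start"])
    clen = int(config.get("cassette_len", 7))
    if start < 0 or start + clen > len(seq):
        raise ConstructError("cassette region outside the FASTA sequence")
    promoter = seq[:start]
    downstream = seq[start + clen :]
    if "N" in promoter or "N" in downstream:
        raise ConstructError("N placeholders allowed only inside the cassette region")
    return ConstructTemplate(
        promoter_seq=promoter,
        cassette_len=clen,
        downstream_seq=downstream,
        seed=clean_seq(config.get("seed", DEFAULT_SEED)),
        spikein_seq=(
            clean_seq(config["spikein_seq"]) if config.get("spikein_seq") else None
        ),
    )


def save_template(
    template: ConstructTemplate, fasta_path: str | Path, config_path: str | Path
) -> None:
    """Write the template FASTA (cassette as N-run) and YAML config so that
    :func:`load_template` round-trips to an identical template."""
    with open(fasta_path, "w") as fh:
        fh.write(">construct_template\n")
        seq = template.fasta_seq()
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "cassette_start": template.expected_tss_index,
                "cassette_len": template.cassette_len,
                "seed": template.seed,
                "spikein_seq": template.spikein_seq,
            },
            fh,
        )
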