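"""Ground-truth simulators for every input the pipeline consumes.

The generators emulate the study design end to end: a plasmid 7-mer library
with a mild T/G synthesis bias; 5'-end reporter reads with preferential
initiation at the expected +1 position, minority upstream/downstream starts,
stochastic non-templated 5' G addition and spike-in reads; polysome /
sub-polysome fraction count tables under control and mTOR-inhibited (Torin)
conditions; transcription-shutoff (ActD) decay count tables; and CAGE-like
5' tags on a toy genome.  Every generator is deterministic given the
configured seed, and emits truth tables that partition its output exactly,
enabling parameter-recovery tests.

Default truth models (all documented in the package methods note):

* expression -- bimodal spanning >= 200-fold: +1 A high, +1 T low, +1 C
  spanning the range with a +2 T bonus; +1 G intermediate (transcribed but
  excluded downstream).
* translation -- control polysome/sub-polysome (P/SP) ratios stratified by
  +1 nucleotide; under Torin, TOP-like starts are repressed with strength
  [+1 C] * min(Y-run, 5)/5 * (0.3 + 0.7*[+3 is C/T]), so repression grows
  with the leading pyrimidine run, saturates at 5 nt, and depends more on
  the +3 than the +2 position.
* decay -- basal half-lives confined to a narrow (~2-fold) spread; under
  Torin, TOP-like starts are stabilized and +1 A starts destabilized.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cage import CageTagSet, TranscriptAnnotation
from .construct import ConstructTemplate, all_kmers
from .motifs import leading_pyrimidine_run
from .quantify import KmerCountTable

ALL_SEVENMERS = all_kmers(7)
_KMER_INDEX = pd.Index(ALL_SEVENMERS)

DEFAULT_TSS_POSITION_PROBS = {
    -3: 0.04, -2: 0.07, -1: 0.12, 0: 0.48, 1: 0.14, 2: 0.09, 3: 0.06,
}
DEFAULT_G_ARTIFACT_PROBS = {0: 0.30, 1: 0.60, 2: 0.10}
DEFAULT_PLASMID_BIAS = {"A": 0.23, "C": 0.23, "G": 0.27, "T": 0.27}

#: Torin translational-repression depth for a maximal TOP motif, in log2
#: units of the P/SP ratio.
TOP_REPRESSION_L2 = 4.0


def top_strength(kmer: str) -> float:
    """Truth TOP-repression strength in [0, 1] for one 7-mer."""
    if kmer[0] != "C":
        return 0.0
    run = leading_pyrimidine_run(kmer)
    return (min(run, 5) / 5.0) * (0.3 + 0.7 * (kmer[2] in "CT"))


def _check_probs(probs: dict, name: str) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} probabilities must be non-negative")


def default_models(model_seed: int) -> pd.DataFrame:
    """Per-7-mer truth table: transcription rate, P/SP ratios and half-lives.

    Columns: ``rate`` (relative transcription rate), ``psp_control`` /
    ``psp_torin`` (polysome over sub-polysome ratios), ``hl_control`` /
    ``hl_torin`` (half-lives, hours).  Deterministic given ``model_seed``.
    """
    rng = np.random.default_rng(model_seed)
    n = len(ALL_SEVENMERS)
    first = np.array([s[0] for s in ALL_SEVENMERS])
    second = np.array([s[1] for s in ALL_SEVENMERS])
    strength = np.array([top_strength(s) for s in ALL_SEVENMERS])

    # transcription: bimodal, keyed to +1 (and +2 for +1 C starts)
    log10 = np.where(first == "A", 1.3, np.where(first == "T", -1.0, 0.0))
    c_mask = first == "C"
    log10 = log10 + np.where(c_mask, rng.uniform(-1.0, 0.8, n), 0.0)
    log10 = log10 + np.where(c_mask & (second == "T"), 0.4, 0.0)
    log10 = log10 + rng.normal(0.0, 0.25, n)
    rate = 10.0 ** log10

    # translation: control P/SP stratified by +1, Torin adds TOP repression
    l2_psp_control = (
        np.where(first == "A", 0.5, np.where(first == "T", -0.3, 0.0))
        + rng.normal(0.0, 0.45, n)
    )
    l2_psp_torin = l2_psp_control - TOP_REPRESSION_L2 * strength + rng.normal(0.0, 0.10, n)

    # decay: narrow basal spread; Torin stabilizes TOPs, destabilizes +1 A
    hl_control = 2.0 ** (2.0 + rng.normal(0.0, 0.35, n))
    torin_factor = (1.0 + 2.0 * strength) * np.where(first == "A", 0.7, 1.0)
    hl_torin = hl_control * torin_factor

    return pd.DataFrame(
        {
            "rate": rate,
            "psp_control": 2.0 ** l2_psp_control,
            "psp_torin": 2.0 ** l2_psp_torin,
            "hl_control": hl_control,
            "hl_torin": hl_torin,
        },
        index=_KMER_INDEX,
    )


@dataclass
class SimulationConfig:
    """All ground-truth parameters of the synthetic study.

    ``expression_model`` maps each 7-mer to a relative transcription rate;
    ``translation_model`` holds P/SP ratio columns ``psp_control`` /
    ``psp_torin``; ``decay_model`` holds half-life columns ``hl_control`` /
    ``hl_torin`` in hours.  ``depth`` is the FASTQ read depth per reporter
    sample; ``count_depth`` the per-sample depth of fraction/decay count
    tables.
    """

    rng_seed: int = 0
    depth: int = 5_000_000
    count_depth: int = 30_000_000
    plasmid_depth: int = 20_000_000
    tss_position_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_TSS_POSITION_PROBS)
    )
    g_artifact_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_G_ARTIFACT_PROBS)
    )
    plasmid_bias: dict = field(default_factory=lambda: dict(DEFAULT_PLASMID_BIAS))
    spikein_fraction: float = 0.02
    models: pd.DataFrame | None = None  # built from the seed when omitted

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.count_depth <= 0 or self.plasmid_depth <= 0:
            raise ValueError("depth must be > 0")
        _check_probs(self.tss_position_probs, "tss_position")
        _check_probs(self.g_artifact_probs, "g_artifact")
        if abs(sum(self.plasmid_bias.values()) - 1.0) > 1e-9:
            raise ValueError("plasmid_bias weights must sum to 1")
        if not 0 <= self.spikein_fraction < 1:
            raise ValueError("spikein_fraction must be in [0, 1)")
        if self.models is None:
            self.models = default_models(self._seed_for("models"))
        m = self.models
        if (m["rate"] <= 0).any():
            raise ValueError("transcription rates must be strictly positive")
        if (m[["psp_control", "psp_torin"]] <= 0).any().any():
            raise ValueError("P/SP ratios must be strictly positive")
        if (m[["hl_control", "hl_torin"]] <= 0).any().any():
            raise ValueError("half-lives must be strictly positive")

    # deterministic per-purpose child seeds (process-independent hash)
    def _seed_for(self, purpose: str) -> int:
        tag = zlib.crc32(purpose.encode())
        return int(
            np.random.SeedSequence([self.rng_seed, tag]).generate_state(1)[0] % (2**31)
        )

    def rng(self, purpose: str, replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, self._seed_for(purpose), replicate])

    # -- truth accessors ----------------------------------------------

    @property
    def expression_model(self) -> pd.Series:
        """Per-copy relative transcription rate (the quantity the pipeline's
        plasmid-normalized expression estimates)."""
        return self.models["rate"]

    @property
    def plasmid_probs(self) -> pd.Series:
        """Plasmid library composition: per-nucleotide synthesis bias."""
        w = np.array([self.plasmid_bias[b] for b in "ACGT"])
        base_idx = {b: i for i, b in enumerate("ACGT")}
        probs = np.ones(len(ALL_SEVENMERS))
        for pos in range(7):
            probs *= w[[base_idx[s[pos]] for s in ALL_SEVENMERS]]
        return pd.Series(probs / probs.sum(), index=_KMER_INDEX)

    @property
    def expression_probs(self) -> pd.Series:
        """Steady-state mRNA composition: plasmid copy number (composition
        bias) times per-copy transcription rate."""
        p = self.plasmid_probs * self.models["rate"]
        return p / p.sum()

    def true_l2_psp(self, condition: str) -> pd.Series:
        return np.log2(self.models[f"psp_{_cond(condition)}"])

    def true_l2_decay(self, condition: str, actd_hours: float = 2.0) -> pd.Series:
        return -actd_hours / self.models[f"hl_{_cond(condition)}"]


def _cond(condition: str) -> str:
    c = condition.lower()
    if c not in ("control", "torin"):
        raise KeyError(f"unknown condition {condition!r} (use 'control' or 'torin')")
    return c


# ---------------------------------------------------------------------
# plasmid library


def simulate_plasmid_library(
    config: SimulationConfig, replicate: int = 0
) -> KmerCountTable:
    """Multinomial plasmid counts over all 16,384 7-mers with a mild
    per-nucleotide composition bias (synthesis artifact)."""
    rng = config.rng("plasmid", replicate)
    counts = rng.multinomial(config.plasmid_depth, config.plasmid_probs.values)
    return KmerCountTable(
        sample_id=f"plasmid_rep{replicate}",
        counts=pd.Series(counts, index=_KMER_INDEX),
        condition={"assay": "plasmid"},
        replicate=replicate,
    )


# ---------------------------------------------------------------------
# reporter FASTQ


@dataclass
class TruthTables:
    """Per-read ground truth for one simulated reporter FASTQ.

    Arrays are parallel to the emitted reads (in order): ``kmer_idx`` indexes
    :data:`ALL_SEVENMERS` (-1 for spike-ins), ``offset`` is the true start
    relative to the +1 position, ``n_artifact_g`` the number of prepended
    non-templated Gs, ``is_spikein`` marks spike-in reads.
    """

    kmer_idx: np.ndarray
    offset: np.ndarray
    n_artifact_g: np.ndarray
    is_spikein: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.kmer_idx)

    def true_sevenmer_counts(self) -> pd.Series:
        """True per-7-mer tallies of definitive cassette-origin reads: +1
        starts (offset 0) of library molecules whose +1 base is not G."""
        sel = (~self.is_spikein) & (self.offset == 0)
        idx = self.kmer_idx[sel]
        first_is_g = np.array([ALL_SEVENMERS[i][0] == "G" for i in range(len(ALL_SEVENMERS))])
        idx = idx[~first_is_g[idx]]
        counts = np.bincount(idx, minlength=len(ALL_SEVENMERS))
        return pd.Series(counts, index=_KMER_INDEX)

    def true_molecule_counts(self) -> pd.Series:
        """True per-7-mer molecule tallies regardless of start position."""
        idx = self.kmer_idx[~self.is_spikein]
        return pd.Series(np.bincount(idx, minlength=len(ALL_SEVENMERS)), index=_KMER_INDEX)

    def category_sizes(self) -> dict:
        return {
            "spikein": int(self.is_spikein.sum()),
            "library": int((~self.is_spikein).sum()),
        }

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "kmer_idx": self.kmer_idx,
                "offset": self.offset,
                "n_artifact_g": self.n_artifact_g,
                "is_spikein": self.is_spikein,
            }
        ).to_csv(path, sep="\t", index=False)


def simulate_reporter_reads(
    template: ConstructTemplate,
    config: SimulationConfig,
    fastq_path: str | Path,
    replicate: int = 0,
    read_into_downstream: int = 30,
) -> TruthTables:
    """Write a reporter FASTQ and return per-read truth.

    Each library read is (artifact Gs) + the mRNA 5' sequence from its
    sampled start offset through ``read_into_downstream`` nucleotides of the
    constant downstream region.  Spike-in reads (the exact spike-in 5'
    sequence, same artifact model) are interleaved at ``spikein_fraction``.
    """
    offsets = sorted(config.tss_position_probs)
    off_probs = np.array([config.tss_position_probs[o] for o in offsets])
    tss = template.expected_tss_index
    if min(offsets) + tss < 0:
        raise ValueError("start offset upstream of the construct 5' end")
    g_vals = sorted(config.g_artifact_probs)
    g_probs = np.array([config.g_artifact_probs[g] for g in g_vals])
    read_end = tss + template.cassette_len + read_into_downstream
    if read_end > template.length:
        raise ValueError("read extends past the construct (shorten read_into_downstream)")
    if template.seed_index + len(template.seed) > read_end:
        raise ValueError("reads too short to contain the anchoring seed")

    rng = config.rng("reporter", replicate)
    n = config.depth
    is_spike = rng.random(n) < config.spikein_fraction
    kmer_idx = rng.choice(len(ALL_SEVENMERS), size=n, p=config.expression_probs.values)
    kmer_idx[is_spike] = -1
    off_idx = rng.choice(len(offsets), size=n, p=off_probs)
    g_idx = rng.choice(len(g_vals), size=n, p=g_probs)

    full_prefix = template.promoter_seq  # cassette inserted per read
    downstream = template.downstream_seq[:read_into_downstream]
    g_strs = {g: "G" * g for g in g_vals}
    prom_tails = {o: full_prefix[tss + o :] for o in offsets if o <= 0}
    spike_seq = template.spikein_seq
    if is_spike.any() and spike_seq is None:
        raise ValueError("spikein_fraction > 0 but the template has no spike-in")
    spike_len = read_end - tss + 3  # comparable read length
    offs = np.array(offsets)[off_idx]
    gs = np.array(g_vals)[g_idx]

    with open(fastq_path, "w") as fh:
        chunk: list[str] = []
        for i in range(n):
            g = gs[i]
            if is_spike[i]:
                seq = g_strs[g] + spike_seq[:spike_len]
                offs[i] = 0
            else:
                kmer = ALL_SEVENMERS[kmer_idx[i]]
                o = offs[i]
                if o <= 0:
                    seq = g_strs[g] + prom_tails[o] + kmer + downstream
                else:
                    seq = g_strs[g] + kmer[o:] + downstream
            chunk.append(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}")
            if len(chunk) == 100_000:
                fh.write("\n".join(chunk) + "\n")
                chunk = []
        if chunk:
            fh.write("\n".join(chunk) + "\n")

    return TruthTables(
        kmer_idx=kmer_idx,
        offset=offs,
        n_artifact_g=gs,
        is_spikein=is_spike,
    )


# ---------------------------------------------------------------------
# fraction and decay count tables


def simulate_fraction_counts(
    config: SimulationConfig, condition: str, replicate: int = 0
) -> tuple[KmerCountTable, KmerCountTable]:
    """Polysome / sub-polysome count tables for one condition.

    Per-7-mer totals follow library abundance (multinomial at
    ``count_depth``); each 7-mer's reads split binomially between fractions
    with p = r / (1 + r), r its P/SP ratio under the condition.  Spike-in
    counts are added to both fractions at the configured level (the protocol
    adds equal spike-in amounts to each fraction).
    """
    c = _cond(condition)
    rng = config.rng(f"fraction_{c}", replicate)
    totals = rng.multinomial(config.count_depth, config.expression_probs.values)
    r = config.models[f"psp_{c}"].values
    p_poly = r / (1.0 + r)
    poly = rng.binomial(totals, p_poly)
    sub = totals - poly
    spike = int(round(config.count_depth * config.spikein_fraction))
    spike_poly = int(rng.poisson(spike)) if spike else 0
    spike_sub = int(rng.poisson(spike)) if spike else 0

    def _table(counts: np.ndarray, fraction: str, spikein_count: int) -> KmerCountTable:
        s = pd.Series(counts, index=_KMER_INDEX)
        return KmerCountTable(
            sample_id=f"{fraction}_{c}_rep{replicate}",
            counts=s[s > 0],
            condition={"assay": "polysome_profiling", "condition": c, "fraction": fraction},
            replicate=replicate,
            spikein_count=spikein_count,
        )

    return _table(poly, "polysome", spike_poly), _table(sub, "subpolysome", spike_sub)


def simulate_decay_counts(
    config: SimulationConfig,
    condition: str,
    actd_hours: float,
    replicate: int = 0,
) -> KmerCountTable:
    """Counts after ``actd_hours`` of transcription shutoff.

    Expected count at time t is count(0) * 2^(-t / half-life), Poisson
    sampled; the spike-in expectation does not decay.
    """
    if actd_hours < 0:
        raise ValueError("actd_hours must be >= 0")
    c = _cond(condition)
    rng = config.rng(f"decay_{c}_t{actd_hours}", replicate)
    baseline = config.count_depth * config.expression_probs.values
    hl = config.models[f"hl_{c}"].values
    lam = baseline * 2.0 ** (-actd_hours / hl)
    counts = rng.poisson(lam)
    spike = int(round(config.count_depth * config.spikein_fraction))
    s = pd.Series(counts, index=_KMER_INDEX)
    return KmerCountTable(
        sample_id=f"decay_{c}_t{actd_hours:g}_rep{replicate}",
        counts=s[s > 0],
        condition={
            "assay": "actd_decay",
            "condition": c,
            "actd_hours": float(actd_hours),
        },
        replicate=replicate,
        spikein_count=int(rng.poisson(spike)) if spike else 0,
    )


# ---------------------------------------------------------------------
# CAGE-like tags on a toy genome


TOP_HYBRID_3MERS = ("CTC", "CCC", "CTT", "CCT")


@dataclass
class CageTruth:
    genome: dict[str, str]
    annotation: TranscriptAnnotation
    tags: CageTagSet
    genes: pd.DataFrame  # gene_id, strand, tss, start_3mer, expression, gene_class


def simulate_cage(
    toy_genome_len: int,
    n_genes: int,
    per_gene_tss_model: dict[int, float] | None,
    config: SimulationConfig,
    n_tags: int = 200_000,
    window: int = 1000,
    rp_fraction: float = 0.15,
) -> CageTruth:
    """Toy genome + annotation + 5' tags drawn from per-gene TSS models.

    Genes are laid out non-overlapping (spacing >= ``window``), alternating
    strands.  Each gene gets an expression weight (lognormal), a planted
    start 3-mer written into the genome at its annotated TSS in transcript
    orientation, and tags sampled at offsets from ``per_gene_tss_model``
    (transcript orientation; default 70% at the annotated TSS).  A subset of
    genes is tagged ``RP`` and planted with TOP/TCT hybrid starts.
    """
    if per_gene_tss_model is None:
        # sharp-promoter genes: the bulk of tags at the annotated TSS, a
        # small minority at neighboring positions (whose genomic 3-mers are
        # arbitrary, as in real data)
        per_gene_tss_model = {-1: 0.04, 0: 0.90, 1: 0.04, 2: 0.02}
    _check_probs(per_gene_tss_model, "per_gene_tss")
    spacing = toy_genome_len // (n_genes + 1)
    if spacing < window:
        raise ValueError("genome too short for non-overlapping promoter windows")
    rng = config.rng("cage")
    seq = rng.choice(list("ACGT"), size=toy_genome_len)

    from .cage import revcomp

    # endogenous TSS usage mirrors the library's start-sequence preferences:
    # a gene's expression follows the library transcription rate of its start
    # 3-mer, with gene-to-gene lognormal noise
    rate3 = (
        config.expression_model.groupby(config.expression_model.index.str[:3]).mean()
    )
    non_g_3mers = [k for k in all_kmers(3) if not k.startswith("G")]
    genes = []
    for i in range(n_genes):
        tss = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        is_rp = rng.random() < rp_fraction
        if is_rp:
            start3 = TOP_HYBRID_3MERS[rng.integers(len(TOP_HYBRID_3MERS))]
            boost = 10 ** rng.normal(0.7, 0.2)  # RP genes are highly expressed
        else:
            start3 = non_g_3mers[rng.integers(len(non_g_3mers))]
            boost = 1.0
        expression = float(rate3[start3] * boost * 10 ** rng.normal(0.0, 0.4))
        planted = start3 if strand == "+" else revcomp(start3)
        if strand == "+":
            seq[tss : tss + 3] = list(planted)
        else:
            seq[tss - 2 : tss + 1] = list(planted)
        genes.append(
            {
                "gene_id": f"gene{i:04d}",
                "chrom": "chr1",
                "strand": strand,
                "tss": tss,
                "start_3mer": start3,
                "expression": expression,
                "gene_class": "RP" if is_rp else "",
            }
        )
    genes_df = pd.DataFrame(genes)
    genome = {"chr1": "".join(seq)}

    gene_probs = genes_df["expression"].values / genes_df["expression"].sum()
    per_gene_n = rng.multinomial(n_tags, gene_probs)
    offsets = sorted(per_gene_tss_model)
    off_probs = np.array([per_gene_tss_model[o] for o in offsets])
    records: dict[tuple, int] = {}
    for (_, gene), n_g in zip(genes_df.iterrows(), per_gene_n):
        if n_g == 0:
            continue
        off_counts = rng.multinomial(n_g, off_probs)
        sign = 1 if gene["strand"] == "+" else -1
        for off, cnt in zip(offsets, off_counts):
            if cnt == 0:
                continue
            pos = gene["tss"] + sign * off
            key = ("chr1", int(pos), gene["strand"])
            records[key] = records.get(key, 0) + int(cnt)
    tags = CageTagSet(
        pd.DataFrame(
            [(c, p, s, n) for (c, p, s), n in records.items()],
            columns=["chrom", "pos", "strand", "count"],
        )
    )
    annotation = TranscriptAnnotation(
        genes_df[["gene_id", "chrom", "strand", "tss", "gene_class"]].copy()
    )
    return CageTruth(genome=genome, annotation=annotation, tags=tags, genes=genes_df)
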