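import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from startmer.construct import ConstructTemplate, SPIKEIN_SEQ
from startmer.quantify import (
    FivePrimeCall,
    KmerCountTable,
    classify_read,
    classify_reads,
    collapse_calls,
    count_and_remove_spikein,
    find_seed,
    quantify_fastq,
    tss_position_distribution,
)
from startmer.simulate import SimulationConfig, simulate_reporter_reads

from .origin_oracle import brute_force_classify

SEED = "AGCCGCCGCC"


class TestFindSeed:
    def test_direct_match_offset(self, template):
        assert find_seed("CCTTAA" + SEED + "AAA", template) == 6

    def test_absent_seed_is_none(self, template):
        assert find_seed("T" * 40, template) is None

    def test_first_of_two_occurrences(self, template):
        read = "AA" + SEED + "TT" + SEED
        # brute-force scan oracle: first window equal to the seed
        expected = min(
            i for i in range(len(read) - 9) if read[i : i + 10] == SEED
        )
        assert find_seed(read, template) == expected == 2

    def test_scan_window_limit(self, template):
        read = "T" * 30 + SEED
        assert find_seed(read, template, max_scan=10) is None
        assert find_seed(read, template, max_scan=30) == 30

    def test_mismatch_tolerant_scan(self, template):
        read = "CC" + "AGCCGCCGCA" + "TTTT"  # one mismatch vs the seed
        assert find_seed(read, template) is None
        assert find_seed(read, template, max_mismatches=1) == 2


class TestClassifyRead:
    def test_plain_cassette_start(self, template):
        call = classify_read("AACCTTG" + template.downstream_seq, template)
        assert call.category == "cassette_start"
        assert call.sevenmer == "AACCTTG"
        assert call.n_stripped_G == 0
        assert call.align_offset == template.expected_tss_index

    def test_plus1_g_is_ambiguous(self, template):
        """A 5' G over the cassette could be a genuine +1 G start or a +2
        start with an artifact G -- irreducibly ambiguous."""
        call = classify_read("GAACCTT" + template.downstream_seq, template)
        assert call.category == "ambiguous_plus1G"
        assert call.sevenmer is None

    def test_two_artifact_gs_stripped_against_promoter(self, template):
        # leading GG mismatches the promoter tail (…T, C) so both are
        # non-templated; the first retained base C sits at +1
        call = classify_read("GG" + "CTCTTAA" + template.downstream_seq, template)
        assert call.category == "cassette_start"
        assert call.n_stripped_G == 2
        assert call.sevenmer == "CTCTTAA"

    def test_upstream_start_recorded_without_sevenmer(self, template):
        read = template.promoter_seq[-2:] + "AACCTTG" + template.downstream_seq
        call = classify_read(read, template)
        assert call.category == "upstream_start"
        assert call.align_offset == template.expected_tss_index - 2
        assert call.sevenmer is None

    def test_downstream_start_within_cassette(self, template):
        # a +2 start: only six cassette bases precede the constant region,
        # so no 7-mer can be assigned
        read = "CCTTGA" + template.downstream_seq
        call = classify_read(read, template)
        assert call.category == "downstream_start"
        assert call.align_offset == template.expected_tss_index + 1
        assert call.sevenmer is None

    def test_no_seed(self, template):
        call = classify_read("ACGTACGTACGTACGT", template)
        assert call.category == "no_seed"

    def test_spikein_detected_with_artifact_g(self, template):
        assert classify_read(SPIKEIN_SEQ[:40], template).category == "spikein"
        assert classify_read("G" + SPIKEIN_SEQ[:40], template).category == "spikein"

    def test_spikein_lookalike_library_read_not_spikein(self, template):
        # a genuine library CTCTTCC read shares the spike-in's first 7 nt but
        # not its private insert
        call = classify_read("CTCTTCC" + template.downstream_seq, template)
        assert call.category == "cassette_start"
        assert call.sevenmer == "CTCTTCC"

    def test_stripping_monotonicity(self, template):
        """Prepending a template-mismatching G leaves the 7-mer unchanged
        and increments the stripped-G count."""
        rng = np.random.default_rng(5)
        bases = "ACGT"
        for _ in range(50):
            kmer = "A" + "".join(rng.choice(list(bases), 6))
            read = kmer + template.downstream_seq
            for extra in range(1, 3):
                # positions -1, -2 of the promoter are C and T: mismatching
                read = "G" + read
                call = classify_read(read, template)
                assert call.category == "cassette_start"
                assert call.sevenmer == kmer
                assert call.n_stripped_G == extra

    def test_sevenmer_iff_cassette_start_enforced(self):
        with pytest.raises(ValueError):
            FivePrimeCall(read_id="x", category="no_seed", sevenmer="AAAAAAA")

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        kmer=st.text(alphabet="ACGT", min_size=7, max_size=7),
        off=st.integers(min_value=-3, max_value=3),
        g=st.integers(min_value=0, max_value=2),
        corrupt=st.integers(min_value=-1, max_value=20),
    )
    def test_oracle_equivalence_property(self, kmer, off, g, corrupt):
        """Anchored classification equals exhaustive origin enumeration for
        arbitrary origins, including reads corrupted at one position."""
        t = ConstructTemplate(
            promoter_seq="TGAACCGTC", cassette_len=7,
            downstream_seq="AGCCGCCGCCTAGTTACGAT", seed="AGCCGCCGCC",
            spikein_seq=None,
        )
        read = "G" * g + t.transcript(kmer, off)
        if 0 <= corrupt < len(read):
            base = "ACGT"[(("ACGT".index(read[corrupt])) + 1) % 4]
            read = read[:corrupt] + base + read[corrupt + 1 :]
        got = classify_read(read, t)
        exp = brute_force_classify(read, t)
        assert (got.category, got.align_offset, got.sevenmer) == (
            exp[0], exp[1], exp[3],
        )

    def test_oracle_equivalence_random_sample(self, small_template):
        """Seed-anchored classification agrees with exhaustive origin
        enumeration on randomized reads (offsets, artifact Gs, 7-mers)."""
        rng = np.random.default_rng(17)
        t = small_template
        for _ in range(400):
            kmer = "".join(rng.choice(list("ACGT"), 7))
            off = int(rng.integers(-3, 4))
            g = int(rng.integers(0, 3))
            read = "G" * g + t.transcript(kmer, off)
            got = classify_read(read, t)
            exp = brute_force_classify(read, t)
            assert (got.category, got.align_offset, got.sevenmer) == (
                exp[0], exp[1], exp[3],
            ), read


class TestCollapseAndTallies:
    def test_g_variants_group_to_one_base_sequence(self, template):
        reads = [
            ("a", "AACCTTG" + template.downstream_seq),
            ("b", "G" + "AACCTTG" + template.downstream_seq),
            ("c", "GG" + "AACCTTG" + template.downstream_seq),
        ]
        calls = list(classify_reads(reads, template, sample_id="s1"))
        assert [c.n_stripped_G for c in calls] == [0, 1, 2]
        table = collapse_calls(calls)
        assert table.counts.to_dict() == {"AACCTTG": 3}
        assert table.total_assigned == 3

    def test_no_cassette_calls_preserves_totals(self, template):
        reads = [("a", "ACGT" * 10), ("b", "GAACCTT" + template.downstream_seq)]
        table = collapse_calls(classify_reads(reads, template, sample_id="s"))
        assert table.counts.empty
        assert table.excluded == {"ambiguous_plus1G": 1, "no_seed": 1}
        assert table.total_reads == 2

    def test_mixed_samples_rejected(self, template):
        read = "AACCTTG" + template.downstream_seq
        calls = [
            classify_read(read, template, sample_id="s1"),
            classify_read(read, template, sample_id="s2"),
        ]
        with pytest.raises(ValueError, match="multiple samples"):
            collapse_calls(calls)

    def test_count_table_tsv_round_trip(self, tmp_path):
        table = KmerCountTable(
            sample_id="x",
            counts={"AACCTTG": 3, "CTCTTAA": 1},
            condition={"assay": "demo"},
            replicate=1,
            excluded={"no_seed": 2},
            spikein_count=5,
        )
        table.to_tsv(tmp_path / "x.tsv")
        again = KmerCountTable.from_tsv(tmp_path / "x.tsv")
        assert again.counts.equals(table.counts)
        assert again.condition == table.condition
        assert again.spikein_count == 5
        assert again.total_reads == table.total_reads


class TestSpikein:
    def test_no_spikein_reads(self):
        reads = [("a", "ACGTACGT")]
        n, rest = count_and_remove_spikein(reads, SPIKEIN_SEQ)
        assert n == 0 and rest == reads

    def test_injected_spikeins_counted_exactly(self, template):
        spike = [("s%d" % i, SPIKEIN_SEQ[:40]) for i in range(500)]
        lib = [("l%d" % i, "AACCTTG" + template.downstream_seq) for i in range(100)]
        n, rest = count_and_remove_spikein(spike + lib, SPIKEIN_SEQ)
        assert n == 500
        assert len(rest) == 100

    def test_artifact_g_spikein_counted(self):
        n, rest = count_and_remove_spikein([("a", "G" + SPIKEIN_SEQ[:30])], SPIKEIN_SEQ)
        assert n == 1 and rest == []


class TestTssDistribution:
    def test_degenerate_position_model(self, template, tmp_path):
        cfg = SimulationConfig(
            rng_seed=2, depth=2000, tss_position_probs={0: 1.0},
            g_artifact_probs={0: 1.0}, spikein_fraction=0.0,
        )
        fq = tmp_path / "r.fastq"
        simulate_reporter_reads(template, cfg, fq)
        _, summary = quantify_fastq(fq, template)
        dist = summary["tss_position_distribution"]
        assert dist == {0: 1.0}

    def test_empty_distribution_raises(self, template):
        with pytest.raises(ValueError):
            tss_position_distribution([], template)

    def test_recovery_matches_conditional_multinomial(self, template, tmp_path):
        """With no artifact Gs and a uniform library, reads starting in the
        cassette are lost iff their first base is G (prob 1/4), so recovered
        fractions follow the retention-conditioned multinomial."""
        from .conftest import uniform_models

        probs = {0: 0.48, -1: 0.2, 1: 0.2, 2: 0.12}
        cfg = SimulationConfig(
            rng_seed=7, depth=120_000, tss_position_probs=probs,
            g_artifact_probs={0: 1.0}, spikein_fraction=0.0,
            plasmid_bias={b: 0.25 for b in "ACGT"},  # uniform cassette pool
            models=uniform_models(),
        )
        fq = tmp_path / "r.fastq"
        simulate_reporter_reads(template, cfg, fq)
        _, summary = quantify_fastq(fq, template)
        dist = summary["tss_position_distribution"]
        keep = {0: 0.75, -1: 1.0, 1: 0.75, 2: 0.75}  # non-G +1 retention
        z = sum(probs[o] * keep[o] for o in probs)
        n = 120_000 * z
        for off, p in probs.items():
            expected = p * keep[off] / z
            se = (expected * (1 - expected) / n) ** 0.5
            assert abs(dist[off] - expected) < 3 * se, (off, dist[off], expected)


class TestReadConservation:
    def test_category_partition_sums_to_input(self, template, sim_small, tmp_path):
        fq = tmp_path / "r.fastq"
        truth = simulate_reporter_reads(template, sim_small, fq)
        table, summary = quantify_fastq(fq, template)
        assert summary["n_reads"] == truth.n_reads == sim_small.depth
        assert (
            table.total_assigned + sum(table.excluded.values()) + table.spikein_count
            == summary["n_reads"]
        )

    def test_no_plus1_g_sevenmer_in_counts(self, template, sim_small, tmp_path):
        fq = tmp_path / "r2.fastq"
        simulate_reporter_reads(template, sim_small, fq)
        table, _ = quantify_fastq(fq, template)
        assert not any(s.startswith("G") for s in table.counts.index)
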