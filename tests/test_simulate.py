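import numpy as np
import pandas as pd
import pytest
from scipy import stats

from startmer.quantify import quantify_fastq
from startmer.regulation import log2_ratio
from startmer.simulate import (
    ALL_SEVENMERS,
    SimulationConfig,
    default_models,
    simulate_cage,
    simulate_decay_counts,
    simulate_fraction_counts,
    simulate_plasmid_library,
    simulate_reporter_reads,
    top_strength,
)

from .conftest import uniform_models


def custom_models(**overrides) -> pd.DataFrame:
    m = uniform_models()
    for col, mapping in overrides.items():
        for kmer, val in mapping.items():
            m.loc[kmer, col] = val
    return m


class TestConfigValidation:
    def test_probability_maps_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(tss_position_probs={0: 0.9})

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError, match="depth"):
            SimulationConfig(depth=0)

    def test_rates_strictly_positive(self):
        m = uniform_models()
        m.iloc[0, m.columns.get_loc("rate")] = 0.0
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(models=m)

    def test_half_lives_strictly_positive(self):
        m = uniform_models()
        m.iloc[5, m.columns.get_loc("hl_torin")] = -1.0
        with pytest.raises(ValueError, match="alf-li"):
            SimulationConfig(models=m)


class TestPlasmidLibrary:
    def test_uniform_weights_fit_uniform_multinomial(self):
        cfg = SimulationConfig(
            rng_seed=3, plasmid_depth=16_384_000,
            plasmid_bias={b: 0.25 for b in "ACGT"},
        )
        table = simulate_plasmid_library(cfg)
        counts = table.counts.reindex(ALL_SEVENMERS, fill_value=0)
        assert counts.sum() == 16_384_000
        _, p = stats.chisquare(counts.values)
        assert p > 0.001

    def test_biased_positional_frequencies_match_weights(self):
        bias = {"A": 0.23, "C": 0.23, "G": 0.27, "T": 0.27}
        cfg = SimulationConfig(rng_seed=4, plasmid_depth=8_000_000, plasmid_bias=bias)
        counts = simulate_plasmid_library(cfg).counts
        depth = counts.sum()
        # per-position composition is multinomial at the bias weights
        for pos in range(7):
            obs = counts.groupby(counts.index.str[pos]).sum().reindex(list("ACGT"))
            expected = depth * np.array([bias[b] for b in "ACGT"])
            _, p = stats.chisquare(obs.values, expected)
            assert p > 0.001
        # pooled over positions, each base frequency sits within 3 SE
        pooled = sum(
            counts.groupby(counts.index.str[pos]).sum() for pos in range(7)
        ) / (7 * depth)
        for b, w in bias.items():
            se = (w * (1 - w) / (7 * depth)) ** 0.5
            assert abs(pooled[b] - w) < 3 * se

    def test_nearly_complete_library_at_default_depth(self):
        cfg = SimulationConfig(rng_seed=5, plasmid_depth=5_000_000)
        table = simulate_plasmid_library(cfg)
        assert (table.counts > 0).sum() == 16_384

    def test_mrna_pool_carries_plasmid_bias(self):
        """Steady-state mRNA abundance is plasmid copy number times per-copy
        rate, so the synthesis bias propagates into the reporter pool (and is
        later removed by plasmid normalization)."""
        cfg = SimulationConfig(rng_seed=5, models=uniform_models())
        probs = cfg.expression_probs
        assert probs["TTTTGGG"] > probs["AAAACCC"]
        ratio = probs["TTTTTTT"] / probs["AAAAAAA"]
        assert ratio == pytest.approx((0.27 / 0.23) ** 7)


class TestReporterReads:
    def test_degenerate_artifact_model_adds_no_gs(self, template, tmp_path):
        cfg = SimulationConfig(
            rng_seed=6, depth=2_000, g_artifact_probs={0: 1.0}, spikein_fraction=0.0
        )
        truth = simulate_reporter_reads(template, cfg, tmp_path / "r.fastq")
        assert (truth.n_artifact_g == 0).all()

    def test_direct_construction_single_origin(self, template, tmp_path):
        """Concentrating all probability on one 7-mer, one offset and one
        artifact G yields reads that are literally G + cassette + UTR."""
        rate = pd.Series(1e-12, index=ALL_SEVENMERS)
        rate["AACCTTG"] = 1.0
        m = uniform_models()
        m["rate"] = rate / rate.sum() * len(rate)
        cfg = SimulationConfig(
            rng_seed=7, depth=500, tss_position_probs={0: 1.0},
            g_artifact_probs={1: 1.0}, spikein_fraction=0.0, models=m,
        )
        fq = tmp_path / "r.fastq"
        truth = simulate_reporter_reads(template, cfg, fq)
        assert (truth.n_artifact_g == 1).all()
        expected = "G" + "AACCTTG" + template.downstream_seq[:30]
        seqs = [l.strip() for i, l in enumerate(fq.read_text().splitlines()) if i % 4 == 1]
        assert set(seqs) == {expected}

    def test_relative_rates_recovered(self, template, tmp_path):
        rate = pd.Series(1e-9, index=ALL_SEVENMERS)
        rate["AACCTTG"] = 10.0
        rate["CTCTTAA"] = 1.0
        m = uniform_models()
        m["rate"] = rate
        cfg = SimulationConfig(
            rng_seed=8, depth=60_000, tss_position_probs={0: 1.0},
            g_artifact_probs={0: 1.0}, spikein_fraction=0.0,
            plasmid_bias={b: 0.25 for b in "ACGT"}, models=m,
        )
        fq = tmp_path / "r.fastq"
        simulate_reporter_reads(template, cfg, fq)
        table, _ = quantify_fastq(fq, template)
        x, y = table.counts["AACCTTG"], table.counts["CTCTTAA"]
        ratio = x / y
        se = ratio * (1 / x + 1 / y) ** 0.5  # Poisson sampling oracle
        assert abs(ratio - 10) < 3 * se

    def test_truth_partitions_fastq(self, template, sim_small, tmp_path):
        fq = tmp_path / "r.fastq"
        truth = simulate_reporter_reads(template, sim_small, fq)
        n_lines = sum(1 for _ in open(fq))
        assert n_lines == 4 * truth.n_reads
        sizes = truth.category_sizes()
        assert sizes["spikein"] + sizes["library"] == truth.n_reads

    def test_deterministic_given_seed(self, template, tmp_path):
        cfg = SimulationConfig(rng_seed=9, depth=5_000)
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_reporter_reads(template, cfg, a)
        simulate_reporter_reads(template, cfg, b)
        assert a.read_bytes() == b.read_bytes()
        pa = simulate_plasmid_library(cfg).counts
        pb = simulate_plasmid_library(cfg).counts
        assert pa.equals(pb)


class TestFractionCounts:
    def test_even_ratio_splits_half_and_half(self):
        cfg = SimulationConfig(rng_seed=10, count_depth=2_000_000, models=uniform_models())
        poly, sub = simulate_fraction_counts(cfg, "control")
        frac = poly.total_assigned / (poly.total_assigned + sub.total_assigned)
        se = 0.5 / (poly.total_assigned + sub.total_assigned) ** 0.5
        assert abs(frac - 0.5) < 4 * se

    def test_top_like_l2fc_difference_recovered(self):
        m = custom_models(
            psp_control={"CTCTTCC": 4.0}, psp_torin={"CTCTTCC": 0.25}
        )
        cfg = SimulationConfig(rng_seed=11, count_depth=8_000_000, models=m)
        pc, sc = simulate_fraction_counts(cfg, "control")
        pt, st = simulate_fraction_counts(cfg, "torin")
        l2c = log2_ratio(pc, sc, pseudocount=1e-6)["CTCTTCC"]
        l2t = log2_ratio(pt, st, pseudocount=1e-6)["CTCTTCC"]
        # closed-form expectation log2(0.25) - log2(4) = -4, with the
        # binomial-sampling standard error derived from the counts
        se = sum(
            1 / t.counts["CTCTTCC"] for t in (pc, sc, pt, st)
        ) ** 0.5 / np.log(2)
        assert abs((l2t - l2c) - (-4.0)) < 3 * se

    def test_unknown_condition_rejected(self):
        cfg = SimulationConfig(rng_seed=1, count_depth=1000, models=uniform_models())
        with pytest.raises(KeyError, match="condition"):
            simulate_fraction_counts(cfg, "heatshock")

    def test_unsampled_sevenmers_absent_from_both_fractions(self):
        rate = pd.Series(1e-12, index=ALL_SEVENMERS)
        rate["AAAAAAA"] = 1.0
        m = uniform_models()
        m["rate"] = rate
        cfg = SimulationConfig(rng_seed=12, count_depth=10_000, models=m)
        poly, sub = simulate_fraction_counts(cfg, "control")
        assert set(poly.counts.index) == {"AAAAAAA"}
        assert set(sub.counts.index) == {"AAAAAAA"}


class TestDecayCounts:
    def test_time_zero_equals_baseline_expectation(self):
        cfg = SimulationConfig(rng_seed=13, count_depth=4_000_000, models=uniform_models())
        t0 = simulate_decay_counts(cfg, "control", 0.0)
        assert abs(t0.total_assigned - 4_000_000) < 4 * 4_000_000**0.5

    def test_half_life_two_hours_gives_minus_one_l2fc(self):
        cfg = SimulationConfig(rng_seed=14, count_depth=4_000_000, models=uniform_models())
        minus = simulate_decay_counts(cfg, "control", 0.0)
        plus = simulate_decay_counts(cfg, "control", 2.0)
        l2 = log2_ratio(plus, minus, spikein_scaled=True, pseudocount=1e-6)
        assert abs(l2.mean() - (-1.0)) < 0.02
        # spike-in expectation does not decay
        assert abs(plus.spikein_count / minus.spikein_count - 1) < 0.05

    def test_mixed_half_life_ordering_recovered(self):
        m = custom_models(
            hl_control={"AAAAAAA": 1.0, "CCCCCCC": 2.0, "TTTTTTT": 4.0}
        )
        cfg = SimulationConfig(rng_seed=15, count_depth=8_000_000, models=m)
        minus = simulate_decay_counts(cfg, "control", 0.0)
        plus = simulate_decay_counts(cfg, "control", 2.0)
        l2 = log2_ratio(plus, minus, pseudocount=1e-6)
        assert l2["AAAAAAA"] < l2["CCCCCCC"] < l2["TTTTTTT"]

    def test_negative_time_rejected(self):
        cfg = SimulationConfig(rng_seed=1, count_depth=1000, models=uniform_models())
        with pytest.raises(ValueError, match="actd_hours"):
            simulate_decay_counts(cfg, "control", -1.0)


class TestCage:
    def test_single_plus_strand_gene_all_tags_at_tss(self):
        cfg = SimulationConfig(rng_seed=16, depth=1000)
        truth = simulate_cage(5000, 1, {0: 1.0}, cfg, n_tags=500, window=1000)
        df = truth.tags.df
        assert len(df) == 1
        assert df.iloc[0]["count"] == 500
        assert df.iloc[0]["pos"] == truth.genes.iloc[0]["tss"]

    def test_minus_strand_positions_decrease_with_offset(self):
        cfg = SimulationConfig(rng_seed=17, depth=1000)
        truth = simulate_cage(8000, 2, {0: 0.5, 2: 0.5}, cfg, n_tags=4000, window=1000)
        minus = truth.genes[truth.genes["strand"] == "-"].iloc[0]
        tags = truth.tags.df
        pos = set(tags[tags["strand"] == "-"]["pos"])
        # offset +2 in transcript orientation lies 2 nt genomic-left of TSS
        assert pos == {minus["tss"], minus["tss"] - 2}

    def test_tag_totals_track_gene_expression(self):
        cfg = SimulationConfig(rng_seed=18, depth=1000)
        truth = simulate_cage(60_000, 40, {0: 1.0}, cfg, n_tags=300_000, window=1000)
        genes = truth.genes.set_index("tss")
        tags = truth.tags.df.set_index("pos")["count"]
        top2 = genes["expression"].nlargest(2)
        n1, n2 = tags[top2.index[0]], tags[top2.index[1]]
        true_ratio = top2.iloc[0] / top2.iloc[1]
        obs_ratio = n1 / n2
        se = obs_ratio * (1 / n1 + 1 / n2) ** 0.5  # binomial oracle
        assert abs(obs_ratio - true_ratio) < 3 * se

    def test_gene_spacing_narrower_than_window_rejected(self):
        cfg = SimulationConfig(rng_seed=19, depth=1000)
        with pytest.raises(ValueError, match="windows"):
            simulate_cage(5000, 20, {0: 1.0}, cfg, n_tags=100, window=1000)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(rng_seed=20, depth=1000)
        a = simulate_cage(20_000, 10, None, cfg, n_tags=5000)
        b = simulate_cage(20_000, 10, None, cfg, n_tags=5000)
        assert a.genome == b.genome
        assert a.tags.df.equals(b.tags.df)


class TestDefaultTruthModels:
    def test_top_strength_shape(self):
        # grows with the run, saturates at 5 nt; a +3 purine collapses the gate
        assert top_strength("CTCAAAA") == pytest.approx(0.6)
        assert top_strength("CTCTAAA") == pytest.approx(0.8)
        assert top_strength("CTCTTAA") == pytest.approx(1.0)
        assert top_strength("CTCTTTT") == pytest.approx(1.0)
        assert top_strength("CGCTTTT") == pytest.approx(0.2 * 1.0)
        assert top_strength("CTGTTTT") == pytest.approx(0.4 * 0.3)
        assert top_strength("ATCTTTT") == 0.0

    def test_expression_model_is_bimodal_and_wide(self):
        m = default_models(123)
        act = m.loc[[s for s in m.index if s[0] in "ACT"], "rate"]
        assert act.max() / act.min() > 200
        plus1_means = np.log10(act).groupby(act.index.str[0]).mean()
        assert plus1_means["A"] > plus1_means["C"] > plus1_means["T"]

    def test_torin_represses_top_motifs(self):
        m = default_models(123)
        l2c = np.log2(m["psp_control"])
        l2t = np.log2(m["psp_torin"])
        delta = l2t - l2c
        tops = [s for s in m.index if s.startswith("CTCTT")]
        nontops = [s for s in m.index if s[0] == "A"]
        assert delta[tops].mean() < -3
        assert abs(delta[nontops].mean()) < 0.2
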