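"""In-read index recovery, bleed counting and hop-rate estimation."""
import math

import pytest

from charauth.bleed_detect import (
    IndexAssayConfig,
    IndexRegistry,
    UNREADABLE,
    UNRECOGNIZED,
    bleed_fraction,
    build_bleed_report,
    count_indexes,
    estimate_hop_rate,
    recover_index,
)
from charauth.preprocess import ReadRecord
from charauth.seqs import P7_ADAPTER
from charauth.synthetic_data import (
    PoolConfig,
    default_samples,
    render_read,
    simulate_pool,
)

SAMPLES = {"s1": "AACCGGT", "s2": "TTGGCCA", "s3": "CGCGAGA"}


@pytest.fixture
def registry():
    return IndexRegistry(SAMPLES)


@pytest.fixture
def cfg():
    return IndexAssayConfig()


def read_for(sample, insert_len=60, read_len=100, rid="r", lib="s1"):
    bases, quals = render_read("A" * insert_len, SAMPLES[sample], P7_ADAPTER,
                               read_len)
    return ReadRecord(rid, bases, quals, lib)


class TestRecoverIndex:
    def test_no_prefix_is_unreadable(self, cfg, registry):
        assert recover_index("ACGT" * 25, cfg, registry) == UNREADABLE

    def test_recovery_tolerates_mutated_spacer(self, cfg, registry):
        insert = "T" * 60
        bases, _ = render_read(insert, SAMPLES["s2"], P7_ADAPTER, 100)
        # scramble the 22-base spacer completely; the rule must not care
        lo, hi = 60 + 12, 60 + 34
        scrambled = bases[:lo] + "A" * 22 + bases[hi:]
        assert recover_index(scrambled, cfg, registry) == "s2"

    def test_index_truncated_by_one_base_is_unreadable(self, cfg, registry):
        bases, _ = render_read("T" * 61, SAMPLES["s1"], P7_ADAPTER, 100)
        assert recover_index(bases, cfg, registry) == UNREADABLE

    def test_unknown_index_is_unrecognized(self, cfg):
        registry = IndexRegistry({"s1": "AACCGGT"})
        bases, _ = render_read("T" * 50, "GGTTAAC", P7_ADAPTER, 100)
        assert recover_index(bases, cfg, registry) == UNRECOGNIZED

    def test_n_in_index_window_is_unrecognized(self, cfg, registry):
        bases, _ = render_read("T" * 50, SAMPLES["s1"], P7_ADAPTER, 100)
        mutated = bases[: 50 + 34] + "N" + bases[50 + 35 :]
        assert recover_index(mutated, cfg, registry) == UNRECOGNIZED

    def test_exhaustive_over_insert_length_boundary(self, cfg, registry):
        """Readable exactly when insert <= read_len - 40 (margin = 12+22+6)."""
        read_len = 100
        for insert_len in range(40, 81):
            bases, _ = render_read("T" * insert_len, SAMPLES["s3"], P7_ADAPTER,
                                   read_len)
            outcome = recover_index(bases, cfg, registry)
            if insert_len <= read_len - 40:
                assert outcome == "s3", insert_len
            else:
                assert outcome == UNREADABLE, insert_len

    def test_empty_read_rejected(self, cfg, registry):
        with pytest.raises(ValueError):
            recover_index("", cfg, registry)


class TestIndexAssayConfig:
    def test_margin_arithmetic(self, cfg):
        assert cfg.margin == 12 + 22 + 6 == 40

    def test_registry_rejects_close_indexes(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            IndexRegistry({"a": "AAAAAAA", "b": "AAAAATT"})

    def test_registry_rejects_truncation_collision(self):
        # distance >= 3 on the full 7 bases, yet ambiguous after truncation
        with pytest.raises(ValueError, match="collision"):
            IndexRegistry({"a": "AAAATTT", "b": "AAAACCC"}, index_len=4)


class TestCountIndexes:
    def test_crafted_counts_and_conservation(self, cfg, registry):
        reads = []
        for i in range(7):
            reads.append(read_for("s1", rid=f"c{i}"))
        for i in range(2):
            reads.append(read_for("s2", rid=f"f{i}"))
        bases, quals = render_read("T" * 50, "GGTTAAC", P7_ADAPTER, 100)
        reads.append(ReadRecord("u0", bases, quals, "s1"))
        counts = count_indexes(
            {"s1": reads}, lambda rid: "mapped", cfg, registry
        )
        row = counts.get("s1", "mapped")
        assert (row.readable_total, row.correct, row.unrecognized) == (10, 7, 1)
        assert row.foreign == {"s2": 2}
        row.check_conservation()

    def test_all_unreadable_gives_zero_totals(self, cfg, registry):
        reads = [ReadRecord("r", "ACGT" * 25, (37,) * 100, "s1")]
        counts = count_indexes({"s1": reads}, lambda rid: "mapped", cfg, registry)
        assert counts.get("s1", "mapped").readable_total == 0
        assert counts.get("s1", "background").readable_total == 0

    def test_empty_partition_row_present(self, cfg, registry):
        counts = count_indexes(
            {"s1": [read_for("s1")]}, lambda rid: "background", cfg, registry
        )
        assert counts.get("s1", "mapped").readable_total == 0
        assert counts.get("s1", "background").readable_total == 1

    def test_unknown_partition_label_rejected(self, cfg, registry):
        with pytest.raises(ValueError, match="partition"):
            count_indexes({"s1": [read_for("s1")]}, lambda rid: "odd", cfg,
                          registry)


class TestBleedFraction:
    def test_arithmetic(self, cfg, registry):
        reads = [read_for("s1", rid=f"a{i}") for i in range(990)]
        reads += [read_for("s2", rid=f"b{i}") for i in range(10)]
        counts = count_indexes({"s1": reads}, lambda rid: "mapped", cfg,
                               registry)
        assert bleed_fraction(counts, "s1", "mapped", {"s2", "s3"}) == (
            pytest.approx(0.01)
        )
        assert bleed_fraction(counts, "s1", "mapped", set()) == 0.0

    def test_zero_readable_rejected(self, cfg, registry):
        counts = count_indexes({"s1": []}, lambda rid: "mapped", cfg, registry)
        with pytest.raises(ValueError, match="undefined"):
            bleed_fraction(counts, "s1", "mapped", {"s2"})


class TestHopRateEstimation:
    def test_zero_foreign_gives_zero(self, cfg, registry):
        reads = [read_for("s1", rid=f"r{i}") for i in range(50)]
        counts = count_indexes({"s1": reads}, lambda rid: "background", cfg,
                               registry)
        est = estimate_hop_rate(counts)
        assert est.rate == 0.0 and est.ci_low == 0.0

    def test_recovers_configured_rate(self, hopping_pool, cfg):
        config, reads, _ = hopping_pool
        registry = IndexRegistry.from_samples(config.samples)
        counts = count_indexes(reads, lambda rid: "background", cfg, registry)
        est = estimate_hop_rate(counts)
        assert est.ci_low <= 0.003 <= est.ci_high
        sd = math.sqrt(0.003 * 0.997 / est.readable)
        assert abs(est.rate - 0.003) <= 3 * sd

    def test_estimator_consistency(self, small_genomes, cfg):
        """Absolute error shrinks as the pool grows (hop rate 0.05)."""
        errors = []
        for n in (400, 8000):
            samples = default_samples(4, source_genome="genome_1")
            pool = PoolConfig(samples=tuple(samples), hop_rate=0.05,
                              insert_mean=40.0, insert_sd=8.0,
                              n_reads_per_sample=n, seed=23)
            reads, _ = simulate_pool(pool, small_genomes)
            registry = IndexRegistry.from_samples(samples)
            counts = count_indexes(reads, lambda rid: "background", cfg,
                                   registry)
            est = estimate_hop_rate(counts)
            errors.append(abs(est.rate - 0.05))
            sd = math.sqrt(0.05 * 0.95 / est.readable)
            assert abs(est.rate - 0.05) <= 3 * sd
        assert errors[1] < errors[0]


class TestBleedReport:
    def test_report_from_simulated_pool(self, hopping_pool, cfg):
        config, reads, truth = hopping_pool
        registry = IndexRegistry.from_samples(config.samples)
        hopped = set(truth.loc[truth.true_sample != truth.assigned_sample,
                               "read_id"])
        # treat hopped reads as the "mapped" partition: every library's mapped
        # foreign fraction should dwarf its background fraction
        counts = count_indexes(
            reads, lambda rid: "mapped" if rid in hopped else "background",
            cfg, registry,
        )
        report = build_bleed_report(counts, registry=registry)
        assert report.n_pairs == 4
        assert report.w_statistic == 0.0
        per = report.per_library
        assert (per.mapped_foreign_fraction > per.background_foreign_fraction).all()
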