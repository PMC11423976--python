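from decimal import Decimal

import pytest

from synaptome import (
    BrainCensus,
    EncodingProfile,
    IdScheme,
    ModelLevel,
    ModelSpec,
    ModelVariant,
    capacity_fit,
    coord_byte_width,
    extended_geometric_bytes,
    format_size,
    id_byte_width,
    per_synapse_bytes,
    reduction_ratios,
    reproduce_tables,
    scale_estimate,
    synapse_count,
    total_storage,
)
from synaptome.errors import ValidationError

CORTEX = BrainCensus("cerebral cortex", 12.4e9, 1_000)


class TestByteWidths:
    @pytest.mark.parametrize(
        "n,want",
        [
            (1.38e11, 5),   # whole-brain neuron ids: 2^37.01
            (30e9, 5),
            (30_000, 2),    # per-neuron terminal ids
            (1_000, 2),
            (7_000, 2),     # nematode synapse ids
            (32e6, 4),      # fly synapse ids: 2^24.93
            (256, 1),
            (257, 2),
            (1, 1),
        ],
    )
    def test_id_width(self, n, want):
        assert id_byte_width(n) == want

    def test_id_width_rejects_empty_population(self):
        with pytest.raises(ValidationError):
            id_byte_width(0)

    @pytest.mark.parametrize(
        "extent,res,want",
        [
            (1e9, 10, 4),   # metre-scale volume, chemical-synapse sampling
            (1e9, 1, 4),    # electrical-synapse sampling
            (255, 1, 1),
            (1e6, 1, 3),
        ],
    )
    def test_coord_width(self, extent, res, want):
        assert coord_byte_width(extent, res) == want


class TestPerSynapseBytes:
    @pytest.mark.parametrize(
        "level,variant,want",
        [
            ("topologic", "full", 14),
            ("point", "full", 38),
            ("geometric", "full", 46),
            ("topologic", "simplified", 9),
            ("point", "simplified", 21),
            ("geometric", "simplified", 25),
        ],
    )
    def test_human_widths(self, human_profile, level, variant, want):
        assert per_synapse_bytes(ModelSpec(level, variant), human_profile) == want

    @pytest.mark.parametrize(
        "sid,level,variant,want",
        [
            (2, "topologic", "full", 4),
            (2, "point", "full", 28),
            (2, "geometric", "full", 36),
            (2, "point", "simplified", 14),
            (4, "topologic", "full", 8),
            (4, "geometric", "simplified", 20),
        ],
    )
    def test_synapse_id_widths(self, sid, level, variant, want):
        profile = EncodingProfile(scheme="synapse-id", synapse_id_bytes=sid)
        spec = ModelSpec(level, variant, "synapse-id")
        assert per_synapse_bytes(spec, profile) == want

    def test_reduction_ratios(self, human_profile):
        ratios = reduction_ratios(human_profile)
        assert round(ratios[ModelLevel.TOPOLOGIC], 2) == 1.56  # 14/9
        assert round(ratios[ModelLevel.POINT], 2) == 1.81      # 38/21
        assert round(ratios[ModelLevel.GEOMETRIC], 2) == 1.84  # 46/25

    def test_simplified_never_larger(self, human_profile):
        for level in ModelLevel:
            full = per_synapse_bytes(ModelSpec(level, "full"), human_profile)
            simp = per_synapse_bytes(
                ModelSpec(level, "simplified"), human_profile
            )
            assert simp <= full


class TestTotals:
    def test_synapse_count_is_half_product(self):
        assert synapse_count(BrainCensus("wb", 1e11, 1e4)) == 5 * 10**14
        assert synapse_count(BrainCensus("tiny", 2, 1)) == 1
        assert synapse_count(BrainCensus("wb", 86e9, 1_000)) == 43 * 10**12

    def test_whole_brain_topologic_is_seven_petabytes(self, human_profile):
        est = total_storage(
            BrainCensus("wb", 1e11, 1e4), ModelSpec("topologic"), human_profile
        )
        assert est.total_bytes == 7 * 10**15
        assert est.formatted == "7.00 PB"

    def test_max_census_geometric(self, human_profile):
        est = total_storage(
            BrainCensus("wb", 138e9, 30_000), ModelSpec("geometric"),
            human_profile,
        )
        assert est.value_in("PB") == Decimal("95.22")

    def test_nematode_geometric_full(self):
        profile = EncodingProfile(scheme="synapse-id", synapse_id_bytes=2)
        est = total_storage(
            7_000, ModelSpec("geometric", "full", "synapse-id"), profile
        )
        assert est.total_bytes == 252_000
        assert est.formatted == "252.00 KB"

    def test_zero_synapses(self, human_profile):
        est = total_storage(0, ModelSpec("geometric"), human_profile)
        assert est.total_bytes == 0

    def test_census_rejected_for_synapse_id_scheme(self):
        profile = EncodingProfile(scheme="synapse-id", synapse_id_bytes=2)
        with pytest.raises(ValidationError):
            total_storage(
                BrainCensus("x", 10, 10),
                ModelSpec("topologic", "full", "synapse-id"),
                profile,
            )

    def test_monotone_in_census_and_level(self, human_profile):
        base = None
        for level in ModelLevel:  # topologic < point < geometric
            est = total_storage(
                BrainCensus("wb", 86e9, 1_000), ModelSpec(level), human_profile
            )
            if base is not None:
                assert est.total_bytes > base
            base = est.total_bytes
        small = total_storage(
            BrainCensus("wb", 30e9, 1_000), ModelSpec("point"), human_profile
        )
        big = total_storage(
            BrainCensus("wb", 30e9, 10_000), ModelSpec("point"), human_profile
        )
        assert big.total_bytes > small.total_bytes


class TestExtendedAndScaled:
    def test_extended_geometric(self, human_profile):
        assert extended_geometric_bytes(human_profile) == 102
        assert extended_geometric_bytes(human_profile, extra_numbers=0) == 46
        total = extended_geometric_bytes(human_profile) * 150 * 10**6
        assert format_size(total) == "15.30 GB"

    def test_diseased_cortex_scaling(self, human_profile):
        est = total_storage(
            CORTEX, ModelSpec("topologic", "simplified"), human_profile
        )
        assert est.value_in("TB") == Decimal("55.80")
        scaled = scale_estimate(est, 0.75)
        assert scaled.value_in("TB") == Decimal("41.85")
        assert scaled.per_synapse_bytes == est.per_synapse_bytes

        worst = total_storage(
            BrainCensus("cerebral cortex", 12.4e9, 30_000),
            ModelSpec("geometric"), human_profile,
        )
        assert scale_estimate(worst, 0.75).value_in("TB") == Decimal("6417.00")

    def test_identity_factor(self, human_profile):
        est = total_storage(CORTEX, ModelSpec("point"), human_profile)
        assert scale_estimate(est, 1.0) == est

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.01])
    def test_factor_domain(self, human_profile, factor):
        est = total_storage(CORTEX, ModelSpec("point"), human_profile)
        with pytest.raises(ValidationError):
            scale_estimate(est, factor)


class TestCapacityFit:
    def test_petabyte_memory_bound(self, human_profile):
        # 1.5 PB of supercomputer memory, whole brain, full topologic:
        # about two thousand synapses per neuron fit.
        assert capacity_fit(
            1.5e15, 1e11, ModelSpec("topologic"), human_profile
        ) == 2142

    def test_exascale_geometric(self, human_profile):
        assert capacity_fit(
            37e15, 86e9, ModelSpec("geometric"), human_profile
        ) == 18_705

    def test_capacity_below_one_synapse(self, human_profile):
        assert capacity_fit(10, 1e11, ModelSpec("topologic"),
                            human_profile) == 0


class TestFormatSize:
    @pytest.mark.parametrize(
        "n,want",
        [
            (7 * 10**15, "7.00 PB"),
            (28_000, "28.00 KB"),
            (0, "0 B"),
            (999, "999 B"),
            (1_024_000_000, "1.02 GB"),
            (102 * 150 * 10**6, "15.30 GB"),
        ],
    )
    def test_decimal_units(self, n, want):
        assert format_size(n) == want


@pytest.fixture(scope="module")
def tables():
    return reproduce_tables()


class TestTableReproduction:
    def test_whole_brain_table_has_72_values(self, tables):
        wb = tables.tidy[tables.tidy.census.str.contains("billion")]
        assert len(wb) == 72

    def test_spot_cells(self, tables):
        tidy = tables.tidy
        cell = tidy[
            (tidy.n_neurons == 30e9) & (tidy.syn_per_neuron == 1_000)
            & (tidy.level == "topologic") & (tidy.variant == "full")
        ]
        assert cell.value.item() == 0.21
        cell = tidy[
            (tidy.census == "cerebral cortex") & (tidy.syn_per_neuron == 10_000)
            & (tidy.level == "point") & (tidy.variant == "full")
        ]
        assert cell.value.item() == 2356.00

    def test_flagged_errata(self, tables):
        t3 = [e for e in tables.errata if e.table == "table3"]
        assert len(t3) == 2
        by_level = {e.level.value: e for e in t3}
        assert by_level["point"].computed == Decimal("130.20")
        assert by_level["point"].printed == Decimal("130.02")
        assert by_level["geometric"].computed == Decimal("25.88")
        assert by_level["geometric"].printed == Decimal("35.86")

    def test_deterministic_emission(self, tables, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        tables.to_csv_dir(a)
        reproduce_tables().to_csv_dir(b)
        for name in ("table_whole_brain.csv", "table_regions.csv",
                     "table_species.csv", "storage_tidy.csv", "errata.csv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
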