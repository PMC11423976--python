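import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from synaptome import (
    EncodingProfile,
    GeneratorConfig,
    IdScheme,
    ModelLevel,
    ModelSpec,
    ModelVariant,
    decode,
    encode,
    payload_size,
    per_synapse_bytes,
    quantize,
    dequantize,
    simplify,
)
from synaptome.codec import HEADER_LEN, MAGIC
from synaptome.errors import CorruptionError, FormatError, RangeError
from conftest import generate_quiet


def synapse_id_profile(base: EncodingProfile, n: int) -> EncodingProfile:
    from synaptome import id_byte_width

    return dataclasses.replace(
        base, scheme=IdScheme.SYNAPSE_ID,
        synapse_id_bytes=id_byte_width(max(1, n)),
    )


class TestQuantize:
    @pytest.mark.parametrize(
        "x,res,want",
        [
            (0, 10, 0),
            (25, 10, 3),        # half-up at the midpoint
            (24.9, 10, 2),
            (123_456_789, 1, 123_456_789),
        ],
    )
    def test_examples(self, x, res, want):
        assert quantize(x, res) == want

    def test_out_of_extent(self):
        with pytest.raises(RangeError):
            quantize(11.0, 1.0, extent_nm=10.0)
        with pytest.raises(RangeError):
            quantize(-1.0, 1.0)

    @given(x=st.floats(0, 1e9), res=st.sampled_from([1.0, 10.0]))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_error_bounded(self, x, res):
        assert abs(dequantize(quantize(x, res), res) - x) <= res / 2 + 1e-6


class TestPayloadIdentity:
    @pytest.mark.parametrize("level", list(ModelLevel))
    @pytest.mark.parametrize("variant", list(ModelVariant))
    @pytest.mark.parametrize("scheme", list(IdScheme))
    def test_payload_equals_sizing_arithmetic(
        self, small_synaptome, level, variant, scheme
    ):
        profile = small_synaptome.profile
        if scheme is IdScheme.SYNAPSE_ID:
            profile = synapse_id_profile(profile, len(small_synaptome))
        model = ModelSpec(level, variant, scheme)
        data = encode(small_synaptome, model, profile)
        assert payload_size(data) == (
            per_synapse_bytes(model, profile) * len(small_synaptome)
        )

    def test_known_payload_sizes(self, small_synaptome):
        profile = small_synaptome.profile
        full_geo = encode(small_synaptome, ModelSpec("geometric"), profile)
        assert payload_size(full_geo) == 20 * 46 == 920
        full_top = encode(small_synaptome, ModelSpec("topologic"), profile)
        assert payload_size(full_top) == 20 * 14
        simp_top = encode(
            small_synaptome, ModelSpec("topologic", "simplified"), profile
        )
        assert payload_size(simp_top) == 20 * 9

    def test_empty_synaptome(self, human_profile):
        from synaptome import Synaptome

        data = encode(Synaptome(synapses=[]), ModelSpec("geometric"),
                      human_profile)
        assert len(data) == HEADER_LEN
        assert payload_size(data) == 0
        assert decode(data).n_synapses == 0


class TestRoundTrip:
    def test_full_geometric_recovers_quantized_records(self, medium_synaptome):
        profile = medium_synaptome.profile
        res = profile.resolution_nm
        dec = decode(encode(medium_synaptome, ModelSpec("geometric"), profile))
        assert dec.n_synapses == len(medium_synaptome) == 50
        for row, s in zip(dec.records.itertuples(index=False),
                          medium_synaptome):
            assert (row.pre_neuron, row.pre_terminal) == s.pre.key
            assert (row.post_neuron, row.post_terminal) == s.post.key
            for got, want in zip(
                (row.pre_x, row.pre_y, row.pre_z), s.pre.center
            ):
                assert abs(got - want) <= res / 2 + 1e-9
            assert abs(row.pre_r - s.pre.radius) <= res / 2 + 1e-9
            assert abs(row.post_r - s.post.radius) <= res / 2 + 1e-9

    def test_second_decode_identical(self, medium_synaptome):
        data = encode(medium_synaptome, ModelSpec("point"),
                      medium_synaptome.profile)
        assert decode(data).records.equals(decode(data).records)

    def test_simplified_point_yields_mean_centers(self, small_synaptome):
        profile = small_synaptome.profile
        dec = decode(
            encode(small_synaptome, ModelSpec("point", "simplified"), profile)
        )
        means = {
            simplify(s).id_tuple: simplify(s).mean_center
            for s in small_synaptome
        }
        for row in dec.records.itertuples(index=False):
            key = (row.pre_neuron, row.pre_terminal,
                   row.post_neuron, row.post_terminal)
            want = means[key]
            for got, expect in zip((row.x, row.y, row.z), want):
                assert abs(got - expect) <= profile.resolution_nm / 2 + 1e-9

    def test_topologic_decode_is_ids_only(self, small_synaptome):
        dec = decode(
            encode(small_synaptome, ModelSpec("topologic"),
                   small_synaptome.profile)
        )
        assert list(dec.records.columns) == [
            "pre_neuron", "pre_terminal", "post_neuron", "post_terminal"
        ]

    @pytest.mark.parametrize("resolution", [1.0, 10.0])
    @given(seed=st.integers(0, 2**16), n_neurons=st.integers(2, 8),
           syn=st.integers(1, 10))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip_property(self, resolution, seed, n_neurons, syn):
        """Ids exact, geometry within resolution/2, at 1 and 10 nm."""
        syn_type = "electrical" if resolution == 1.0 else "chemical"
        synaptome = generate_quiet(
            GeneratorConfig(n_neurons=n_neurons, syn_per_neuron=syn,
                            seed=seed, synapse_type=syn_type)
        )
        profile = synaptome.profile
        assert profile.resolution_nm == resolution
        dec = decode(encode(synaptome, ModelSpec("geometric"), profile))
        back = dec.to_synaptome()
        for a, b in zip(synaptome, back):
            assert a.id_tuple == b.id_tuple
            for axis in range(3):
                assert abs(a.pre.center[axis] - b.pre.center[axis]) <= (
                    resolution / 2 + 1e-9
                )
                assert abs(a.post.center[axis] - b.post.center[axis]) <= (
                    resolution / 2 + 1e-9
                )
            assert abs(a.pre.radius - b.pre.radius) <= resolution / 2 + 1e-9


class TestDeterminismAndErrors:
    def test_encoding_deterministic(self, small_synaptome):
        profile = small_synaptome.profile
        for spec in (ModelSpec("geometric"), ModelSpec("point", "simplified")):
            assert encode(small_synaptome, spec, profile) == encode(
                small_synaptome, spec, profile
            )

    def test_bad_magic(self):
        with pytest.raises(FormatError):
            decode(b"NOTASYNAPTOMEFILE" + b"\x00" * 64)

    def test_truncated_payload_names_record(self, small_synaptome):
        data = encode(small_synaptome, ModelSpec("geometric"),
                      small_synaptome.profile)
        # Cut mid-way through record 3 of 20.
        cut = HEADER_LEN + 3 * 46 + 10
        with pytest.raises(CorruptionError) as err:
            decode(data[:cut])
        assert err.value.record_index == 3
        assert err.value.byte_offset <= cut

    def test_payload_size_detects_truncation(self, small_synaptome):
        data = encode(small_synaptome, ModelSpec("topologic"),
                      small_synaptome.profile)
        with pytest.raises(CorruptionError):
            payload_size(data[:-5])

    def test_id_overflow_is_encoding_error(self, human_profile):
        import dataclasses

        from synaptome import Synaptome
        from synaptome.errors import EncodingError
        from test_core import axonal, dendritic
        from synaptome.core import Synapse

        tight = dataclasses.replace(human_profile, terminal_id_bytes=1)
        s = Synapse(pre=axonal(1, 300), post=dendritic(2, 1))
        with pytest.raises(EncodingError):
            encode(Synaptome(synapses=[s]), ModelSpec("topologic"), tight)

    def test_header_magic_is_16_bytes(self):
        assert len(MAGIC) == 16
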