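"""Bit-exact binary serialization of synaptomes (the ``.synap`` format).

Records are fixed-width little-endian unsigned integers.  Coordinates and
radii are quantized to the profile's spatial resolution (10 nm suffices to
resolve chemical synaptic clefts, 1 nm electrical ones) with half-up
rounding, so a round trip recovers identifiers exactly and geometry to
within half a resolution step per axis.

Layouts (field widths from the :class:`EncodingProfile`; bracketed fields
present per model level):

* full, neuron-terminal — per synapse:
  ``pre_neuron, pre_terminal, [pre x,y,z], [pre r],
  post_neuron, post_terminal, [post x,y,z], [post r]``
* simplified, neuron-terminal — records grouped into blocks per
  presynaptic neuron; block header = ``pre_neuron_id`` + 4-byte record
  count; each record:
  ``pre_terminal, post_neuron, post_terminal, [mean x,y,z], [mean r]``
* full, synapse-id — per synapse (one identifier per stored terminal):
  ``syn_id, [pre x,y,z], [pre r], syn_id, [post x,y,z], [post r]``
* simplified, synapse-id:
  ``syn_id, [mean x,y,z], [mean r]``

The file header (magic, version, widths, resolution, extent, counts) and
the simplified-variant block headers are additive overhead, excluded from
payload accounting: the record payload is exactly
``per_synapse_bytes(model, profile) * n_synapses``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core import (
    IdScheme,
    ModelLevel,
    ModelSpec,
    ModelVariant,
    SimplifiedSynapse,
    Synapse,
    Synaptome,
    TerminalKind,
    TerminalQuadruple,
    simplify,
)
from .errors import (
    CorruptionError,
    EncodingError,
    FormatError,
    RangeError,
    ValidationError,
)
from .sizing import coord_byte_width, per_synapse_bytes

__all__ = [
    "EncodingProfile",
    "DecodedSynaptome",
    "quantize",
    "dequantize",
    "encode",
    "decode",
    "payload_size",
    "save",
    "load",
    "MAGIC",
    "HEADER_LEN",
]

MAGIC = b"SYNAPTOMEBINv001"  # 16-byte magic + version prefix
# After the magic: scheme, level, variant, five widths (u8 each),
# extra_attr_count (u16), resolution and extent (f64), synapse and block
# counts (u64), all little-endian.
_HEADER_STRUCT = struct.Struct("<8BHddQQ")
HEADER_LEN = len(MAGIC) + _HEADER_STRUCT.size

_SCHEME_CODES = {IdScheme.NEURON_TERMINAL: 0, IdScheme.SYNAPSE_ID: 1}
_LEVEL_CODES = {ModelLevel.TOPOLOGIC: 0, ModelLevel.POINT: 1, ModelLevel.GEOMETRIC: 2}
_VARIANT_CODES = {ModelVariant.FULL: 0, ModelVariant.SIMPLIFIED: 1}
_SCHEMES = {v: k for k, v in _SCHEME_CODES.items()}
_LEVELS = {v: k for k, v in _LEVEL_CODES.items()}
_VARIANTS = {v: k for k, v in _VARIANT_CODES.items()}


@dataclass(frozen=True)
class EncodingProfile:
    """Byte widths, id scheme and spatial quantization for one encoding.

    Defaults are the human-scale profile: 5-byte neuron ids (enough for
    up to 2^40 neurons), 2-byte per-neuron terminal ids, 4-byte
    coordinates covering a 1e9 nm extent at 10 nm or 1 nm resolution,
    4-byte radii.  ``synapse_id_bytes`` is required by the synapse-id
    scheme and sized to the synapse count.  ``extra_attr_count`` records
    how many 4-byte annotation attributes an extended record would carry;
    it is metadata for sizing, not serialized per record.
    """

    scheme: IdScheme = IdScheme.NEURON_TERMINAL
    neuron_id_bytes: int = 5
    terminal_id_bytes: int = 2
    synapse_id_bytes: int | None = None
    coord_bytes: int = 4
    radius_bytes: int = 4
    resolution_nm: float = 10.0
    extent_nm: float = 1e9
    extra_attr_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", IdScheme(self.scheme))
        for name in ("neuron_id_bytes", "terminal_id_bytes", "coord_bytes",
                     "radius_bytes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.synapse_id_bytes is not None and self.synapse_id_bytes < 1:
            raise ValidationError("synapse_id_bytes must be >= 1")
        if self.resolution_nm <= 0 or self.extent_nm <= 0:
            raise ValidationError("resolution and extent must be positive")
        needed = coord_byte_width(self.extent_nm, self.resolution_nm)
        if self.coord_bytes < needed:
            raise ValidationError(
                f"coord_bytes={self.coord_bytes} cannot index an extent of "
                f"{self.extent_nm} nm at {self.resolution_nm} nm resolution "
                f"(needs {needed})"
            )


def quantize(coordinate_nm: float, resolution_nm: float,
             extent_nm: float | None = None) -> int:
    """Map a nm coordinate to its voxel index with half-up rounding."""
    if extent_nm is not None and not 0 <= coordinate_nm <= extent_nm:
        raise RangeError(
            f"coordinate {coordinate_nm} nm outside [0, {extent_nm}] nm"
        )
    if coordinate_nm < 0:
        raise RangeError(f"coordinate {coordinate_nm} nm is negative")
    return int(coordinate_nm / resolution_nm + 0.5)


def dequantize(index: int, resolution_nm: float) -> float:
    return index * resolution_nm


def _pack(value: int, width: int, what: str, out: bytearray) -> None:
    if value < 0 or value >= 256**width:
        raise EncodingError(
            f"{what}={value} does not fit in {width} byte(s)"
        )
    out += value.to_bytes(width, "little")


@dataclass
class _Reader:
    data: bytes
    pos: int
    record: int | None = None

    def take(self, width: int, what: str) -> int:
        if self.pos + width > len(self.data):
            raise CorruptionError(
                f"stream truncated while reading {what}",
                byte_offset=self.pos,
                record_index=self.record,
            )
        value = int.from_bytes(self.data[self.pos:self.pos + width], "little")
        self.pos += width
        return value


def _quantized_terminal(t: TerminalQuadruple, profile: EncodingProfile
                        ) -> tuple[tuple[int, int, int], int]:
    coords = tuple(
        quantize(c, profile.resolution_nm, profile.extent_nm) for c in t.center
    )
    r = quantize(t.radius, profile.resolution_nm)
    return coords, r  # type: ignore[return-value]


def encode(synaptome: Synaptome, model: ModelSpec,
           profile: EncodingProfile | None = None) -> bytes:
    """Serialize a synaptome under the given model level/variant/scheme.

    The in-memory synaptome always carries full geometry; lower levels
    simply omit fields and the simplified variant stores merged mean
    locations/radii.  Encoding is deterministic: identical synaptome and
    profile give identical bytes.
    """
    profile = profile or synaptome.profile or EncodingProfile()
    if model.scheme is not profile.scheme:
        raise ValidationError(
            f"model scheme {model.scheme.value} != profile scheme "
            f"{profile.scheme.value}"
        )
    level, variant, scheme = model.level, model.variant, model.scheme
    has_loc = level in (ModelLevel.POINT, ModelLevel.GEOMETRIC)
    has_rad = level is ModelLevel.GEOMETRIC
    n = len(synaptome)

    payload = bytearray()
    n_blocks = 0

    if scheme is IdScheme.NEURON_TERMINAL and variant is ModelVariant.FULL:
        for s in synaptome:
            for t in (s.pre, s.post):
                _pack(t.neuron_id, profile.neuron_id_bytes, "neuron_id", payload)
                _pack(t.terminal_id, profile.terminal_id_bytes, "terminal_id",
                      payload)
                if has_loc:
                    coords, r = _quantized_terminal(t, profile)
                    for c in coords:
                        _pack(c, profile.coord_bytes, "coordinate", payload)
                    if has_rad:
                        _pack(r, profile.radius_bytes, "radius", payload)

    elif scheme is IdScheme.NEURON_TERMINAL:  # simplified: per-neuron blocks
        blocks: dict[int, list[SimplifiedSynapse]] = {}
        for s in synaptome:
            blocks.setdefault(s.pre.neuron_id, []).append(simplify(s))
        n_blocks = len(blocks)
        for pre_neuron in sorted(blocks):
            recs = sorted(blocks[pre_neuron], key=lambda r: r.pre_terminal_id)
            _pack(pre_neuron, profile.neuron_id_bytes, "block neuron_id", payload)
            _pack(len(recs), 4, "block record count", payload)
            for rec in recs:
                _pack(rec.pre_terminal_id, profile.terminal_id_bytes,
                      "pre_terminal_id", payload)
                _pack(rec.post_neuron_id, profile.neuron_id_bytes,
                      "post_neuron_id", payload)
                _pack(rec.post_terminal_id, profile.terminal_id_bytes,
                      "post_terminal_id", payload)
                if has_loc:
                    for c in rec.mean_center:
                        _pack(quantize(c, profile.resolution_nm,
                                       profile.extent_nm),
                              profile.coord_bytes, "coordinate", payload)
                    if has_rad:
                        _pack(quantize(rec.mean_radius, profile.resolution_nm),
                              profile.radius_bytes, "radius", payload)

    else:  # synapse-id scheme: identifier = record index
        if profile.synapse_id_bytes is None:
            raise ValidationError(
                "synapse-id scheme requires profile.synapse_id_bytes"
            )
        sw = profile.synapse_id_bytes
        for idx, s in enumerate(synaptome):
            if variant is ModelVariant.FULL:
                for t in (s.pre, s.post):
                    _pack(idx, sw, "synapse_id", payload)
                    if has_loc:
                        coords, r = _quantized_terminal(t, profile)
                        for c in coords:
                            _pack(c, profile.coord_bytes, "coordinate", payload)
                        if has_rad:
                            _pack(r, profile.radius_bytes, "radius", payload)
            else:
                rec = simplify(s)
                _pack(idx, sw, "synapse_id", payload)
                if has_loc:
                    for c in rec.mean_center:
                        _pack(quantize(c, profile.resolution_nm,
                                       profile.extent_nm),
                              profile.coord_bytes, "coordinate", payload)
                    if has_rad:
                        _pack(quantize(rec.mean_radius, profile.resolution_nm),
                              profile.radius_bytes, "radius", payload)

    header = MAGIC + _HEADER_STRUCT.pack(
        _SCHEME_CODES[scheme],
        _LEVEL_CODES[level],
        _VARIANT_CODES[variant],
        profile.neuron_id_bytes,
        profile.terminal_id_bytes,
        profile.synapse_id_bytes or 0,
        profile.coord_bytes,
        profile.radius_bytes,
        profile.extra_attr_count,
        profile.resolution_nm,
        profile.extent_nm,
        n,
        n_blocks,
    )
    return bytes(header + payload)


def _parse_header(data: bytes) -> tuple[ModelSpec, EncodingProfile, int, int]:
    if len(data) < HEADER_LEN:
        raise FormatError(
            f"stream of {len(data)} bytes is shorter than the "
            f"{HEADER_LEN}-byte header"
        )
    if data[:len(MAGIC)] != MAGIC:
        raise FormatError("bad magic/version: not a synaptome binary stream")
    (scheme_c, level_c, variant_c, nb, tb, sb, cb, rb, extra,
     resolution, extent, n, n_blocks) = _HEADER_STRUCT.unpack(
        data[len(MAGIC):HEADER_LEN]
    )
    try:
        model = ModelSpec(_LEVELS[level_c], _VARIANTS[variant_c],
                          _SCHEMES[scheme_c])
    except KeyError as exc:
        raise FormatError(f"unknown model code in header: {exc}") from exc
    profile = EncodingProfile(
        scheme=model.scheme,
        neuron_id_bytes=nb,
        terminal_id_bytes=tb,
        synapse_id_bytes=sb or None,
        coord_bytes=cb,
        radius_bytes=rb,
        resolution_nm=resolution,
        extent_nm=extent,
        extra_attr_count=extra,
    )
    return model, profile, n, n_blocks


@dataclass
class DecodedSynaptome:
    """Decoded record set at the richness the stream encodes.

    ``records`` is a DataFrame whose columns depend on level, variant and
    scheme; coordinates and radii are dequantized back to nm.  A full
    geometric neuron-terminal decode can be lifted back into a
    :class:`~synaptome.core.Synaptome` via :meth:`to_synaptome`.
    """

    model: ModelSpec
    profile: EncodingProfile
    records: pd.DataFrame
    n_synapses: int

    @property
    def has_locations(self) -> bool:
        return self.model.level in (ModelLevel.POINT, ModelLevel.GEOMETRIC)

    @property
    def has_radii(self) -> bool:
        return self.model.level is ModelLevel.GEOMETRIC

    def to_synaptome(self) -> Synaptome:
        if (self.model.scheme is not IdScheme.NEURON_TERMINAL
                or self.model.variant is not ModelVariant.FULL
                or self.model.level is not ModelLevel.GEOMETRIC):
            raise ValidationError(
                "only full geometric neuron-terminal decodes carry enough "
                "information to rebuild a Synaptome"
            )
        synapses = []
        for row in self.records.itertuples(index=False):
            pre = TerminalQuadruple(
                int(row.pre_neuron), int(row.pre_terminal),
                (row.pre_x, row.pre_y, row.pre_z), row.pre_r,
                TerminalKind.AXONAL,
            )
            post = TerminalQuadruple(
                int(row.post_neuron), int(row.post_terminal),
                (row.post_x, row.post_y, row.post_z), row.post_r,
                TerminalKind.DENDRITIC,
            )
            synapses.append(Synapse(pre=pre, post=post))
        return Synaptome(synapses=synapses, profile=self.profile)


def decode(data: bytes) -> DecodedSynaptome:
    """Parse a synaptome byte stream back into records.

    Identifiers round-trip exactly; coordinates and radii come back
    dequantized, within resolution/2 of the encoded values.  Truncated
    payloads raise :class:`CorruptionError` naming the failing record.
    """
    model, profile, n, n_blocks = _parse_header(data)
    level, variant, scheme = model.level, model.variant, model.scheme
    has_loc = level in (ModelLevel.POINT, ModelLevel.GEOMETRIC)
    has_rad = level is ModelLevel.GEOMETRIC
    res = profile.resolution_nm
    reader = _Reader(data, HEADER_LEN)
    rows: list[tuple] = []

    def read_geom(what: str) -> list[float]:
        vals = [
            dequantize(reader.take(profile.coord_bytes, f"{what} coordinate"),
                       res)
            for _ in range(3)
        ]
        if has_rad:
            vals.append(
                dequantize(reader.take(profile.radius_bytes, f"{what} radius"),
                           res)
            )
        return vals

    if scheme is IdScheme.NEURON_TERMINAL and variant is ModelVariant.FULL:
        columns = ["pre_neuron", "pre_terminal", "post_neuron", "post_terminal"]
        if has_loc:
            columns += ["pre_x", "pre_y", "pre_z", "post_x", "post_y", "post_z"]
        if has_rad:
            columns += ["pre_r", "post_r"]
        for i in range(n):
            reader.record = i
            pre_n = reader.take(profile.neuron_id_bytes, "pre neuron_id")
            pre_t = reader.take(profile.terminal_id_bytes, "pre terminal_id")
            pre_geom = read_geom("pre") if has_loc else []
            post_n = reader.take(profile.neuron_id_bytes, "post neuron_id")
            post_t = reader.take(profile.terminal_id_bytes, "post terminal_id")
            post_geom = read_geom("post") if has_loc else []
            row = [pre_n, pre_t, post_n, post_t]
            if has_loc:
                row += pre_geom[:3] + post_geom[:3]
            if has_rad:
                row += [pre_geom[3], post_geom[3]]
            rows.append(tuple(row))

    elif scheme is IdScheme.NEURON_TERMINAL:  # simplified blocks
        columns = ["pre_neuron", "pre_terminal", "post_neuron", "post_terminal"]
        if has_loc:
            columns += ["x", "y", "z"]
        if has_rad:
            columns += ["r"]
        read = 0
        for b in range(n_blocks):
            reader.record = read
            pre_n = reader.take(profile.neuron_id_bytes, "block neuron_id")
            count = reader.take(4, "block record count")
            for _ in range(count):
                reader.record = read
                pre_t = reader.take(profile.terminal_id_bytes, "pre_terminal_id")
                post_n = reader.take(profile.neuron_id_bytes, "post_neuron_id")
                post_t = reader.take(profile.terminal_id_bytes,
                                     "post_terminal_id")
                row = [pre_n, pre_t, post_n, post_t]
                if has_loc:
                    row += read_geom("mean")
                rows.append(tuple(row))
                read += 1
        if read != n:
            raise CorruptionError(
                f"block records ({read}) disagree with header synapse "
                f"count ({n})",
                byte_offset=reader.pos,
                record_index=read,
            )

    else:  # synapse-id scheme
        if variant is ModelVariant.FULL:
            columns = ["synapse_id"]
            if has_loc:
                columns += ["pre_x", "pre_y", "pre_z",
                            "post_x", "post_y", "post_z"]
            if has_rad:
                columns += ["pre_r", "post_r"]
            for i in range(n):
                reader.record = i
                sid = reader.take(profile.synapse_id_bytes, "synapse_id")
                pre_geom = read_geom("pre") if has_loc else []
                sid2 = reader.take(profile.synapse_id_bytes, "synapse_id")
                post_geom = read_geom("post") if has_loc else []
                if sid != sid2:
                    raise CorruptionError(
                        f"pre/post synapse ids disagree ({sid} != {sid2})",
                        byte_offset=reader.pos,
                        record_index=i,
                    )
                row = [sid]
                if has_loc:
                    row += pre_geom[:3] + post_geom[:3]
                if has_rad:
                    row += [pre_geom[3], post_geom[3]]
                rows.append(tuple(row))
        else:
            columns = ["synapse_id"]
            if has_loc:
                columns += ["x", "y", "z"]
            if has_rad:
                columns += ["r"]
            for i in range(n):
                reader.record = i
                sid = reader.take(profile.synapse_id_bytes, "synapse_id")
                row = [sid]
                if has_loc:
                    row += read_geom("mean")
                rows.append(tuple(row))

    if reader.pos != len(data):
        raise CorruptionError(
            f"{len(data) - reader.pos} trailing bytes after the last record",
            byte_offset=reader.pos,
            record_index=n,
        )
    records = pd.DataFrame(rows, columns=columns)
    return DecodedSynaptome(model=model, profile=profile, records=records,
                            n_synapses=n)


def payload_size(data: bytes) -> int:
    """Record payload length: stream length minus the header and the
    simplified-variant block headers.

    This is the quantity the sizing arithmetic predicts: it equals
    ``per_synapse_bytes(model, profile) * n_synapses`` exactly for every
    well-formed stream.
    """
    model, profile, n, n_blocks = _parse_header(data)
    overhead = HEADER_LEN + n_blocks * (profile.neuron_id_bytes + 4)
    measured = len(data) - overhead
    expected = per_synapse_bytes(model, profile) * n
    if measured != expected:
        raise CorruptionError(
            f"payload is {measured} B but the header promises {n} records "
            f"of {per_synapse_bytes(model, profile)} B",
            byte_offset=len(data),
            record_index=max(0, measured) // max(1, per_synapse_bytes(model,
                                                                      profile)),
        )
    return measured


def save(path, synaptome: Synaptome, model: ModelSpec,
         profile: EncodingProfile | None = None) -> int:
    """Encode to a ``.synap`` file; returns the byte count written."""
    data = encode(synaptome, model, profile)
    with open(path, "wb") as fh:
        fh.write(data)
    return len(data)


def load(path) -> DecodedSynaptome:
    with open(path, "rb") as fh:
        return decode(fh.read())
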