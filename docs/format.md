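# The `.synap` binary format

All integers are little-endian and unsigned. One file holds one synaptome
encoded at one model level/variant/scheme.

## Header (58 bytes)

| offset | size | field |
|--------|------|-------|
| 0      | 16   | magic + version: ASCII `SYNAPTOMEBINv001` |
| 16     | 1    | scheme: 0 = neuron-terminal, 1 = synapse-id |
| 17     | 1    | level: 0 = topologic, 1 = point, 2 = geometric |
| 18     | 1    | variant: 0 = full, 1 = simplified |
| 19     | 1    | neuron_id_bytes |
| 20     | 1    | terminal_id_bytes |
| 21     | 1    | synapse_id_bytes (0 when unused) |
| 22     | 1    | coord_bytes |
| 23     | 1    | radius_bytes |
| 24     | 2    | extra_attr_count (metadata only; not serialized per record) |
| 26     | 8    | resolution_nm (IEEE 754 double) |
| 34     | 8    | extent_nm (IEEE 754 double) |
| 42     | 8    | n_synapses |
| 50     | 8    | n_blocks (simplified neuron-terminal variant; else 0) |

## Records

Coordinates and radii are stored as voxel indices:
`index = round_half_up(value_nm / resolution_nm)`; decoding returns
`index × resolution_nm`. Bracketed fields are present at the point level
(coordinates) and geometric level (coordinates + radius).

**Full, neuron-terminal** — `n_synapses` records, each:

```
pre_neuron  pre_terminal  [pre_x pre_y pre_z]  [pre_r]
post_neuron post_terminal [post_x post_y post_z] [post_r]
```

**Simplified, neuron-terminal** — `n_blocks` blocks ordered by
presynaptic neuron id. Block header: `pre_neuron_id` (neuron_id_bytes) +
record count (4 bytes). Records ordered by presynaptic terminal id:

```
pre_terminal  post_neuron  post_terminal  [mean_x mean_y mean_z]  [mean_r]
```

**Full, synapse-id** — `n_synapses` records; the synapse id is the record
index, written once per stored terminal:

```
syn_id [pre_x pre_y pre_z] [pre_r] syn_id [post_x post_y post_z] [post_r]
```

**Simplified, synapse-id** — `n_synapses` records:

```
syn_id [mean_x mean_y mean_z] [mean_r]
```

## Payload accounting

The header and the simplified-variant block headers are additive overhead.
The record payload — file length minus header minus
`n_blocks × (neuron_id_bytes + 4)` — equals
`per_synapse_bytes(model, profile) × n_synapses` exactly; `payload_size`
verifies this identity and raises a corruption error (with byte offset and
record index) when it fails, as does `decode` on any truncated stream.
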