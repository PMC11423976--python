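# Methods

## The synapse model

A synapse is represented as a pair of terminal quadruples

```
[ N_i, A_im, (x,y,z)_im, r_im ;  N_j, D_jn, (x,y,z)_jn, r_jn ]
```

where `N_i`/`N_j` are the presynaptic and postsynaptic neuron identifiers,
`A_im`/`D_jn` the axonal and dendritic terminal identifiers (unique within
their neuron, one counter across both kinds), `(x,y,z)` the terminal-centre
coordinates in nm in a single global Cartesian frame with the origin at the
volume corner, and `r` the terminal radius in nm (the terminal fundus
approximated as circular). The synaptome is the set of all such synapses;
the connectome follows from it as the directed multigraph over neuron ids
with one edge per synapse.

Three record richness levels exist — **topologic** (identifiers only),
**point** (identifiers + locations), **geometric** (identifiers +
locations + radii) — each in a **full** variant storing both terminals and
a **simplified** variant that (a) amortizes the presynaptic neuron id over
a per-neuron block, (b) replaces the two centres by their component-wise
arithmetic mean, and (c) replaces the two radii by their mean. Means are
computed in continuous nm before quantization; quantization is strictly a
codec concern.

Autapses (same neuron, distinct terminals) are permitted with a warning:
nothing in the model forbids them, and forbidding them silently would bias
generated circuits. Self-referencing synapses (identical terminal on both
sides) are invalid. A terminal participates in exactly one synapse, so for
any valid synaptome the number of distinct presynaptic terminals, distinct
postsynaptic terminals, and synapses coincide.

## Storage arithmetic

Total storage = per-synapse bytes × synapse count. The synapse count for a
census of `N` neurons with `S` synaptic terminals per neuron is `0.5·N·S`
(every output terminal pairs with exactly one input terminal; half the
product avoids double counting), rounded half-up to an integer — at census
scales the product is always an even integer, so rounding never moves a
published value.

Identifier widths are minimal byte widths: the smallest `b` with
`2^(8b) ≥ n_distinct`. The whole-brain censuses (30–138 billion neurons,
`2^34.8`–`2^37.0`) all need 5 B; 1,000–30,000 terminals per neuron need
2 B. One coordinate needs `id_byte_width(ceil(extent/resolution))` bytes:
a 1e9 nm (≈1 m) bounding box needs 4 B at both 10 nm and 1 nm resolution.
Radii take one 4-byte number. Hence per synapse:

| level     | full            | simplified      |
|-----------|-----------------|-----------------|
| topologic | 2·5+2·2 = 14 B  | 1·5+2·2 = 9 B   |
| point     | 14+2·3·4 = 38 B | 9+1·3·4 = 21 B  |
| geometric | 38+2·4 = 46 B   | 21+1·4 = 25 B   |

giving simplification ratios 14/9 ≈ 1.56, 38/21 ≈ 1.81, 46/25 ≈ 1.84.

Small brains use the **synapse-id scheme**: a single identifier sized to
the synapse count replaces the neuron+terminal pair, one identifier per
stored terminal record (so the full topologic record is two synapse ids).
7,000 synapses need 2 B ids; 32 million need 4 B. Small-brain totals use
the raw synapse count without the 0.5 factor, since the count is given
directly rather than derived from a census.

The **extended geometric** record adds `k` 4-byte annotation numbers
(default 14: a 12-number bounding box plus type and layer), i.e.
46 + 14·4 = 102 B. The **density-scaling** operation models synapse loss
(e.g. a 25% spine-density decrease → factor 0.75) by scaling the synapse
count, not the per-synapse cost. The **capacity fit** inverts the estimate:
`floor(capacity / (0.5 · per_synapse_bytes · n_neurons))` synapses per
neuron fit a given memory size.

### Rounding and table reproduction

Byte totals are exact Python integers end to end. Table cells are obtained
by dividing the exact total by the decimal unit (KB = 10^3 … EB = 10^18)
in `decimal.Decimal` and quantizing to two decimals with half-up rounding;
several published cells (e.g. 7.245e15 B → 7.25 PB) sit exactly on the
midpoint, where binary floating point would round unreliably.

`reproduce_tables()` recomputes every cell of the three published storage
tables from the census presets. Three printed cells do not satisfy the
arithmetic that all other cells follow and are flagged as errata rather
than matched: cortex simplified point at 1,000 syn/neuron (printed
130.02 TB, computed 130.20 TB), cerebellum simplified geometric at 30,000
(printed 35.86 PB, computed 25.88 PB), and the cross-species table's
nematode simplified point (printed 96 KB where 14 B × 7,000 = 98 KB, the
value the accompanying text itself derives).

## Binary format

See `docs/format.md` for the byte map. Design choices the record widths do
not determine: little-endian unsigned integers; a fixed 16-byte
magic+version prefix followed by a 42-byte parameter block; simplified
records grouped into per-presynaptic-neuron blocks (block header = neuron
id + 4-byte count) ordered by neuron id, records within a block by
presynaptic terminal id, so encoding is deterministic and byte-exact
comparisons are meaningful. Header and block headers are additive overhead
excluded from payload accounting — the payload is exactly
`per_synapse_bytes × n_synapses`, which is the identity the tests enforce
for every layout. Radii are quantized at the same resolution as
coordinates (the record layout allots them one number without a unit
rule). Round trips recover identifiers exactly and geometry to within
resolution/2 per axis.

## Synthetic generator

The generator emulates exactly the structure the model assumes, nothing
more:

* **Connectivity.** Presynaptic neuron assignments are round-robin over
  `n_synapses = 0.5·n_neurons·syn_per_neuron` slots; postsynaptic
  assignments are a seeded permutation of the same list. Every neuron
  therefore contributes an exact equal share of inputs and outputs
  (when `n_neurons` divides the slot count), making the 0.5·N·S identity
  exact rather than asymptotic. Autapses can arise from the permutation
  and are warned about.
* **Geometry.** Terminal radii ~ Uniform(100, 500) nm — bouton-scale
  values; no radius distribution is prescribed by the model, so a flat
  one is the least-informative choice. The presynaptic terminal is placed
  at its neuron's soma position plus an isotropic Gaussian offset
  (`soma_spread_nm`, default 1e4 nm); the postsynaptic terminal sits at
  centre distance `r_pre + r_post + cleft` along a uniformly random
  direction, with the cleft drawn uniformly from the type interval:
  chemical 20–40 nm, electrical 2–4 nm. The cleft is the only geometric
  constraint the model states, and it holds for every generated synapse
  by construction, not just in distribution.
* **Placement modes.** Default `"soma"` placement clusters terminals
  around uniformly scattered somata, giving the patchy spatial structure
  real tissue has at coarse scale. `"uniform"` placement scatters
  presynaptic terminals homogeneously instead; it exists so that spatial
  statistics (density-grid uniformity via chi-square) can be tested
  against a known-flat reference, which soma clustering deliberately
  violates.
* **Scale and resolution.** Default extent is 1e6 nm (a 1 mm cube) — a
  desk-scale volume in which thousands of synapses can be generated and
  encoded in memory. The profile resolution follows the synapse type:
  10 nm for chemical, 1 nm for electrical, matching the sampling rates
  needed to resolve the respective clefts. A margin of 4 soma-spread
  standard deviations plus the widest pre/post span keeps all terminals
  inside the volume; a too-small extent is a configuration error.
* **Determinism.** One `numpy` Generator seeded from the config drives
  every draw in a fixed order; identical configs give byte-identical
  encodings.

What the generator does **not** emulate: cortical layers, tracts,
distance-dependent connectivity, degree heterogeneity, realistic radius or
cleft distributions, polyadic contacts. Tests passing on generated data
therefore validate the storage arithmetic, the codec, and the graph
derivation — not any biological claim about real synaptomes.

## Connectome analyses

The graph is a `networkx.MultiDiGraph` with one edge per synapse, so edge
count always equals synapse count. The model names three topological
quantities without defining them; this package operationalizes them as:
**microcircuit** = simple directed path of synapses, **loop** = simple
directed cycle (self-loops from autapses count, length 1), **feedback** =
reciprocally connected unordered neuron pair. Counts are at the neuron
level — parallel synapses collapse to one edge, with their multiplicity
available separately (`path_multiplicity`). Enumeration is exhaustive and
exact, gated at 20 nodes by default with an explicit override, since simple
cycle/path counts grow exponentially.

Point-level records enable the synaptic **density grid** (midpoint
histogram over cubic bins; total count conserved exactly); geometric-level
records the **terminal-size distribution** (both radii per full synapse,
one mean radius per simplified record, so the simplified histogram carries
half the mass).

## Problem sizes used in tests

Tests and the acceptance script run at desk scale: synaptomes of 20–10,000
synapses, codec checks over 1–1,000 synapses across 20 seeds and all
twelve layout combinations, graph-oracle comparisons on 100 random graphs
of ≤ 10 nodes. The petabyte-scale figures are reproduced as estimator
arithmetic (exact integers), never as materialized files — materialization
is exercised only at desk scale, where the payload identity ties the
format to the arithmetic byte for byte.

## Known limitations

* The in-memory model always carries full geometry; a topologic-only
  synaptome exists only as a decoded record set, not as `Synaptome`.
* Whether multiple synapses may join the same ordered terminal pair is
  left open by the model; this package forbids terminal reuse entirely
  (one synapse per terminal), the strictest reading.
* No compression, no memory-mapped partial reads; streams are parsed
  whole.
* `capacity_fit` is pure arithmetic; it ignores replication, file-system
  overhead and working memory of any computation over the data.
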