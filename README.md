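# synaptome

Morphology modeling and storage estimation for nanoscale synaptomes — the
complete set of a brain's synapses, each represented as a pair of
(neuron, terminal) quadruples

```
[ N_i, A_im, (x,y,z)_im, r_im ;  N_j, D_jn, (x,y,z)_jn, r_jn ]
```

pre- and postsynaptic neuron id, terminal id, terminal-centre coordinates
(nm) and terminal radius (nm). The package is for neuroinformaticians and
big-data planners who need to answer, concretely: *how many bytes does a
whole-brain synaptome take, under which representation, and what analyses
does each representation support?*

It provides:

* **Three model levels × two variants.** `topologic` (ids only), `point`
  (+ locations), `geometric` (+ radii), each `full` (both terminals) or
  `simplified` (amortized presynaptic neuron id, mean location/radius) —
  14/38/46 B vs 9/21/25 B per synapse at human scale, and a `synapse-id`
  scheme for small brains (nematode: 2-byte ids; fly: 4-byte ids).
* **A storage estimator** (`synaptome.sizing`): total storage =
  per-synapse bytes × `0.5·N·S` synapses, with census presets spanning the
  literature (30/86/100/138 billion neurons; 1,000/10,000/30,000 synapses
  per neuron; cortex 12.4e9, cerebellum 69e9, brainstem/striatum/
  diencephalon 0.7e9), extended-record and disease-scaling variants, a
  supercomputer capacity fit, and full recomputation of the published
  storage tables with errata flagging.
* **A byte-exact binary codec** (`.synap`, `synaptome.codec`): fixed-width
  little-endian records, nm coordinates quantized at 10 nm (chemical) or
  1 nm (electrical) resolution, payload size provably equal to the
  estimator's arithmetic. See `docs/format.md`.
* **A synthetic generator** (`synaptome.generator`): balanced random
  circuits whose pre/post terminal pairs sit exactly
  `r_pre + r_post + cleft` apart, cleft ~ U(20, 40) nm chemical or
  U(2, 4) nm electrical, reproducible from a seed.
* **Connectome derivation** (`synaptome.connectome`): directed multigraph
  with one edge per synapse; exhaustive microcircuit (simple path), loop
  (simple cycle) and feedback (reciprocal pair) counts; synaptic density
  grids (point level) and terminal-size distributions (geometric level).

## Worked example

Storage for the 86-billion-neuron brain at 10,000 synapses per neuron
under the richest (full geometric) model:

```
$ synaptome estimate --neurons 86e9 --syn 10000 --level geometric --variant full
model: full geometric (neuron-terminal)
per-synapse bytes: 46
synapses: 430,000,000,000,000
total: 19,780,000,000,000,000 B = 19.78 PB
```

46 B per synapse (two 5-byte neuron ids, two 2-byte terminal ids, six
4-byte coordinates, two 4-byte radii) × 0.5 · 86e9 · 10^4 = 4.3e14
synapses ≈ 19.78 PB — about 20 petabytes for one brain's synapse geometry,
before any raw imagery.

A desk-scale synthetic synaptome, encoded and verified:

```
$ synaptome generate --neurons 10 --syn 4 --seed 42 --out desk.synap
wrote 20 synapses over 10 neurons to desk.synap
$ synaptome verify desk.synap
ok: 20 records, payload 920 B = 46 B/synapse x 20
$ synaptome analyze desk.synap --loops 4 --radii 8
graph: 10 neurons, 20 synapses, feedbacks 3
loops (<= 4): 7
radii: 40 terminals in [120.0, 480.0] nm over 8 bins
```

Ten neurons with four terminals each give exactly 0.5 · 10 · 4 = 20
synapses; the 920-byte payload is the estimator's 46 B × 20 measured on
disk, record for record. The derived connectome has 3 reciprocally
connected neuron pairs and 7 simple cycles of length ≤ 4; the 40 terminal
radii (two per synapse) span the generator's 100–500 nm range.

The same library calls are available in Python:

```python
from synaptome import BrainCensus, EncodingProfile, ModelSpec, total_storage

est = total_storage(BrainCensus("whole brain", 86e9, 10_000),
                    ModelSpec("geometric"), EncodingProfile())
print(est.per_synapse_bytes, est.formatted)   # 46 19.78 PB
```

`synaptome tables` recomputes the full whole-brain (72 values), regional
and cross-species storage tables as CSV, flagging the cells whose
published print disagrees with the defining arithmetic.

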