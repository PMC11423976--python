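"""Domain model for nanoscale synaptome morphology.

A synapse is a pair of terminal quadruples: the presynaptic axonal terminal
and the postsynaptic dendritic terminal, each described by its neuron
identifier, a terminal identifier unique within that neuron, the centre
coordinates of the terminal (nm, single global Cartesian frame with the
origin at the volume corner) and the terminal radius (nm).  The synaptome
is the set of all synapses; everything else in the package (storage sizing,
binary encoding, connectome derivation) is built on these types.

Three richness levels exist for the serialized representation —
``topologic`` (identifiers only), ``point`` (identifiers + locations) and
``geometric`` (identifiers + locations + radii) — each in a ``full`` variant
storing both terminals and a ``simplified`` variant that amortizes the
presynaptic neuron identifier and merges the two locations/radii into their
arithmetic means.  The in-memory model always carries full geometry; the
level/variant is a property of an encoding, captured by :class:`ModelSpec`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence, TYPE_CHECKING

import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .codec import EncodingProfile

__all__ = [
    "TerminalKind",
    "ModelLevel",
    "ModelVariant",
    "IdScheme",
    "TerminalQuadruple",
    "Synapse",
    "SimplifiedSynapse",
    "ModelSpec",
    "BrainCensus",
    "Synaptome",
    "ValidationReport",
    "make_synapse",
    "simplify",
    "validate_synaptome",
    "synaptome_to_csv",
    "synaptome_from_csv",
    "synaptome_to_json",
    "synaptome_from_json",
]


class TerminalKind(str, Enum):
    AXONAL = "axonal"
    DENDRITIC = "dendritic"


class ModelLevel(str, Enum):
    """Record richness: identifiers only, + locations, + radii."""

    TOPOLOGIC = "topologic"
    POINT = "point"
    GEOMETRIC = "geometric"


class ModelVariant(str, Enum):
    FULL = "full"
    SIMPLIFIED = "simplified"


class IdScheme(str, Enum):
    """How records are identified.

    ``neuron-terminal`` pairs a neuron id with a per-neuron terminal id
    (the large-brain layout).  ``synapse-id`` replaces both with a single
    identifier sized to the total synapse count — the small-brain layout
    used for nematode- and fly-scale synaptomes.
    """

    NEURON_TERMINAL = "neuron-terminal"
    SYNAPSE_ID = "synapse-id"


Vec3 = tuple[float, float, float]


@dataclass(frozen=True)
class TerminalQuadruple:
    """One synaptic terminal: (neuron id, terminal id, centre, radius).

    Parameters
    ----------
    neuron_id : int
        Non-negative neuron identifier.
    terminal_id : int
        Non-negative terminal identifier, unique within its neuron
        (a single counter across axonal and dendritic terminals).
    center : (float, float, float)
        Centre coordinates in nm; non-negative.
    radius : float
        Terminal radius in nm; strictly positive.
    kind : TerminalKind
        ``axonal`` (presynaptic) or ``dendritic`` (postsynaptic).
    """

    neuron_id: int
    terminal_id: int
    center: Vec3
    radius: float
    kind: TerminalKind

    def __post_init__(self) -> None:
        if self.neuron_id < 0:
            raise ValidationError(f"neuron_id must be >= 0, got {self.neuron_id}")
        if self.terminal_id < 0:
            raise ValidationError(f"terminal_id must be >= 0, got {self.terminal_id}")
        if len(self.center) != 3:
            raise ValidationError("center must have exactly 3 coordinates")
        if any(c < 0 for c in self.center):
            raise ValidationError(f"coordinates must be non-negative, got {self.center}")
        if not self.radius > 0:
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        object.__setattr__(self, "kind", TerminalKind(self.kind))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def key(self) -> tuple[int, int]:
        """The (neuron_id, terminal_id) pair identifying this terminal."""
        return (self.neuron_id, self.terminal_id)


@dataclass(frozen=True)
class Synapse:
    """Pre (axonal) + post (dendritic) terminal pair.

    ``cleft_nm`` is derived metadata: the centre distance minus both radii,
    i.e. the synaptic gap implied by the geometry.  Chemical synapses have
    clefts of roughly 20–40 nm, electrical synapses 2–4 nm.
    """

    pre: TerminalQuadruple
    post: TerminalQuadruple

    def __post_init__(self) -> None:
        if self.pre.kind is not TerminalKind.AXONAL:
            raise ValidationError("pre terminal must be axonal")
        if self.post.kind is not TerminalKind.DENDRITIC:
            raise ValidationError("post terminal must be dendritic")
        if self.pre.key == self.post.key:
            raise ValidationError(
                f"pre and post refer to the same terminal {self.pre.key}"
            )

    @property
    def cleft_nm(self) -> float:
        """Synaptic gap: centre distance minus the two radii, in nm."""
        d = math.dist(self.pre.center, self.post.center)
        return d - self.pre.radius - self.post.radius

    @property
    def id_tuple(self) -> tuple[int, int, int, int]:
        return (*self.pre.key, *self.post.key)

    @property
    def midpoint(self) -> Vec3:
        return tuple((a + b) / 2 for a, b in zip(self.pre.center, self.post.center))


@dataclass(frozen=True)
class SimplifiedSynapse:
    """Simplified record: all four identifiers plus merged geometry.

    ``mean_center``/``mean_radius`` are the arithmetic means of the source
    pre/post centres and radii, computed in continuous nm (quantization is
    a codec concern).
    """

    pre_neuron_id: int
    pre_terminal_id: int
    post_neuron_id: int
    post_terminal_id: int
    mean_center: Vec3
    mean_radius: float

    @property
    def id_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.pre_neuron_id,
            self.pre_terminal_id,
            self.post_neuron_id,
            self.post_terminal_id,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which serialized representation is in effect."""

    level: ModelLevel
    variant: ModelVariant = ModelVariant.FULL
    scheme: IdScheme = IdScheme.NEURON_TERMINAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", ModelLevel(self.level))
        object.__setattr__(self, "variant", ModelVariant(self.variant))
        object.__setattr__(self, "scheme", IdScheme(self.scheme))

    def __str__(self) -> str:
        return f"{self.variant.value} {self.level.value} ({self.scheme.value})"


def all_model_specs(scheme: IdScheme = IdScheme.NEURON_TERMINAL) -> list[ModelSpec]:
    """The six level/variant combinations under one id scheme."""
    return [
        ModelSpec(level, variant, scheme)
        for level in ModelLevel
        for variant in ModelVariant
    ]


@dataclass(frozen=True)
class BrainCensus:
    """A (region, neuron count, synapses-per-neuron) triple.

    ``syn_per_neuron`` counts terminals per neuron (inputs plus outputs);
    since every presynaptic terminal pairs with exactly one postsynaptic
    terminal, the synapse count is half of ``n_neurons * syn_per_neuron``.
    """

    region: str
    n_neurons: float
    syn_per_neuron: float

    def __post_init__(self) -> None:
        if not self.n_neurons > 0:
            raise ValidationError(f"n_neurons must be > 0, got {self.n_neurons}")
        if not self.syn_per_neuron > 0:
            raise ValidationError(
                f"syn_per_neuron must be > 0, got {self.syn_per_neuron}"
            )


@dataclass
class Synaptome:
    """An ordered collection of synapses plus its governing encoding profile.

    Invariants (checked by :func:`validate_synaptome`): no duplicate
    (pre neuron, pre terminal, post neuron, post terminal) tuples, and each
    terminal participates in exactly one synapse.
    """

    synapses: list[Synapse]
    profile: "EncodingProfile | None" = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.synapses)

    def __iter__(self) -> Iterator[Synapse]:
        return iter(self.synapses)

    def neuron_ids(self) -> set[int]:
        out: set[int] = set()
        for s in self.synapses:
            out.add(s.pre.neuron_id)
            out.add(s.post.neuron_id)
        return out

    def simplified(self) -> list[SimplifiedSynapse]:
        return [simplify(s) for s in self.synapses]


def make_synapse(pre: TerminalQuadruple, post: TerminalQuadruple) -> Synapse:
    """Pair an axonal and a dendritic terminal into a validated synapse.

    Autapses (pre and post on the same neuron, distinct terminals) are
    permitted but warned about, since they are unusual in cortical data.
    """
    s = Synapse(pre=pre, post=post)
    if pre.neuron_id == post.neuron_id:
        warnings.warn(
            f"autapse: neuron {pre.neuron_id} synapses onto itself",
            stacklevel=2,
        )
    return s


def simplify(s: Synapse) -> SimplifiedSynapse:
    """Merge a full synapse into its simplified record.

    The two centres are replaced by their component-wise arithmetic mean
    and the two radii by their mean; all four identifiers are retained.
    """
    mean_center = tuple(
        (a + b) / 2 for a, b in zip(s.pre.center, s.post.center)
    )
    return SimplifiedSynapse(
        pre_neuron_id=s.pre.neuron_id,
        pre_terminal_id=s.pre.terminal_id,
        post_neuron_id=s.post.neuron_id,
        post_terminal_id=s.post.terminal_id,
        mean_center=mean_center,  # type: ignore[arg-type]
        mean_radius=(s.pre.radius + s.post.radius) / 2,
    )


@dataclass
class ValidationReport:
    """Findings from a synaptome invariant scan; empty iff all hold."""

    duplicate_tuples: list[tuple[int, int, int, int]] = field(default_factory=list)
    terminal_reuse: list[tuple[int, int]] = field(default_factory=list)
    id_range_violations: list[str] = field(default_factory=list)
    coordinate_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.duplicate_tuples
            or self.terminal_reuse
            or self.id_range_violations
            or self.coordinate_violations
        )

    def findings(self) -> list[str]:
        out = [f"duplicate synapse tuple {t}" for t in self.duplicate_tuples]
        out += [f"terminal reuse {t}" for t in self.terminal_reuse]
        out += self.id_range_violations
        out += self.coordinate_violations
        return out


def validate_synaptome(
    synaptome: Synaptome, profile: "EncodingProfile | None" = None
) -> ValidationReport:
    """Scan a synaptome for invariant violations.

    Checks duplicate identifier tuples, terminal reuse across synapses,
    and — when an encoding profile is available — identifier ranges versus
    the profile's byte widths and coordinates versus the volume extent.
    """
    report = ValidationReport()
    profile = profile or synaptome.profile

    seen_tuples: set[tuple[int, int, int, int]] = set()
    seen_terminals: set[tuple[int, int]] = set()
    for s in synaptome:
        t = s.id_tuple
        if t in seen_tuples:
            report.duplicate_tuples.append(t)
        seen_tuples.add(t)
        for term in (s.pre, s.post):
            if term.key in seen_terminals:
                report.terminal_reuse.append(term.key)
            seen_terminals.add(term.key)

    if profile is not None:
        n_max = 256 ** profile.neuron_id_bytes
        t_max = 256 ** profile.terminal_id_bytes
        for idx, s in enumerate(synaptome):
            for term in (s.pre, s.post):
                if term.neuron_id >= n_max:
                    report.id_range_violations.append(
                        f"synapse {idx}: neuron_id {term.neuron_id} "
                        f">= 256^{profile.neuron_id_bytes}"
                    )
                if term.terminal_id >= t_max:
                    report.id_range_violations.append(
                        f"synapse {idx}: terminal_id {term.terminal_id} "
                        f">= 256^{profile.terminal_id_bytes}"
                    )
                if any(
                    not (0 <= c <= profile.extent_nm) for c in term.center
                ):
                    report.coordinate_violations.append(
                        f"synapse {idx}: center {term.center} outside "
                        f"[0, {profile.extent_nm}] nm"
                    )
    return report


# ---------------------------------------------------------------------------
# CSV / JSON interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "pre_neuron", "pre_terminal", "pre_x", "pre_y", "pre_z", "pre_r",
    "post_neuron", "post_terminal", "post_x", "post_y", "post_z", "post_r",
]


def synaptome_to_frame(synaptome: Synaptome) -> pd.DataFrame:
    """One row per synapse, columns as in the CSV interchange format."""
    rows = []
    for s in synaptome:
        rows.append(
            (
                s.pre.neuron_id, s.pre.terminal_id, *s.pre.center, s.pre.radius,
                s.post.neuron_id, s.post.terminal_id, *s.post.center, s.post.radius,
            )
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def synaptome_from_frame(
    df: pd.DataFrame, profile: "EncodingProfile | None" = None
) -> Synaptome:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"interchange table missing columns: {missing}")
    synapses = []
    for row in df.itertuples(index=False):
        pre = TerminalQuadruple(
            int(row.pre_neuron), int(row.pre_terminal),
            (row.pre_x, row.pre_y, row.pre_z), float(row.pre_r),
            TerminalKind.AXONAL,
        )
        post = TerminalQuadruple(
            int(row.post_neuron), int(row.post_terminal),
            (row.post_x, row.post_y, row.post_z), float(row.post_r),
            TerminalKind.DENDRITIC,
        )
        synapses.append(Synapse(pre=pre, post=post))
    return Synaptome(synapses=synapses, profile=profile)


def synaptome_to_csv(synaptome: Synaptome, path) -> None:
    synaptome_to_frame(synaptome).to_csv(path, index=False)


def synaptome_from_csv(path, profile: "EncodingProfile | None" = None) -> Synaptome:
    return synaptome_from_frame(pd.read_csv(path), profile=profile)


def synaptome_to_json(synaptome: Synaptome, path=None) -> str | None:
    records = synaptome_to_frame(synaptome).to_dict(orient="records")
    text = json.dumps({"synapses": records}, indent=1)
    if path is None:
        return text
    with open(path, "w") as fh:
        fh.write(text)
    return None


def synaptome_from_json(source, profile: "EncodingProfile | None" = None) -> Synaptome:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    df = pd.DataFrame(payload["synapses"], columns=_CSV_COLUMNS)
    return synaptome_from_frame(df, profile=profile)
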