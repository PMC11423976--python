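"""Synthetic synaptome generation.

Emulates the geometric structure the synapse model assumes: paired
axonal/dendritic terminals whose centre distance equals the sum of the two
radii plus a type-dependent synaptic cleft (chemical 20-40 nm, electrical
2-4 nm).  Connectivity is random and balanced — every neuron contributes
``syn_per_neuron`` terminals, half presynaptic and half postsynaptic, so
the synapse count is exactly ``0.5 * n_neurons * syn_per_neuron``.

This is desk-scale test scaffolding for codecs, estimators and graph
analyses, not a biophysically realistic circuit: there are no layers,
tracts or distance-dependent wiring rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .codec import EncodingProfile
from .core import (
    Synapse,
    Synaptome,
    TerminalKind,
    TerminalQuadruple,
)
from .errors import ConfigurationError, ValidationError

__all__ = [
    "GeneratorConfig",
    "CensusSummary",
    "CLEFT_RANGES_NM",
    "generate",
    "census_of",
]

# Default synaptic-gap intervals by synapse type, in nm.
CLEFT_RANGES_NM: dict[str, tuple[float, float]] = {
    "chemical": (20.0, 40.0),
    "electrical": (2.0, 4.0),
}
# Spatial resolution sufficient to resolve each cleft type, in nm.
_RESOLUTION_NM = {"chemical": 10.0, "electrical": 1.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic synaptome.

    ``syn_per_neuron`` counts terminals per neuron, inputs and outputs
    combined, matching the census convention of the storage estimator.
    ``extent_nm`` defaults to 1e6 nm (a 1 mm cube), a desk-scale volume;
    ``soma_spread_nm`` is the standard deviation of terminal offsets
    around the soma.  Terminal radii are drawn uniformly from
    ``radius_range_nm`` (bouton-scale 100-500 nm by default).

    ``placement`` controls spatial structure: ``"soma"`` (default)
    clusters terminals around per-neuron soma positions; ``"uniform"``
    scatters presynaptic terminals uniformly through the volume, giving
    spatially homogeneous synapse densities for statistical checks.
    """

    n_neurons: int
    syn_per_neuron: int
    synapse_type: str = "chemical"
    cleft_range_nm: tuple[float, float] | None = None
    radius_range_nm: tuple[float, float] = (100.0, 500.0)
    extent_nm: float = 1e6
    soma_spread_nm: float = 1e4
    seed: int = 0
    allow_autapses: bool = True
    placement: str = "soma"

    def __post_init__(self) -> None:
        if self.placement not in ("soma", "uniform"):
            raise ConfigurationError(
                f"placement must be 'soma' or 'uniform', got {self.placement!r}"
            )
        if self.synapse_type not in CLEFT_RANGES_NM:
            raise ConfigurationError(
                f"synapse_type must be one of {sorted(CLEFT_RANGES_NM)}, "
                f"got {self.synapse_type!r}"
            )
        if self.cleft_range_nm is None:
            object.__setattr__(
                self, "cleft_range_nm", CLEFT_RANGES_NM[self.synapse_type]
            )
        lo, hi = self.cleft_range_nm
        rlo, rhi = self.radius_range_nm
        if not (0 < lo <= hi and 0 < rlo <= rhi):
            raise ConfigurationError(
                "cleft and radius ranges must be positive and ordered"
            )
        if self.n_neurons < 1 or (self.n_neurons < 2 and not self.allow_autapses):
            raise ConfigurationError(
                "need at least 2 neurons unless autapses are allowed"
            )
        if self.syn_per_neuron < 1:
            raise ConfigurationError("syn_per_neuron must be >= 1")
        if self.extent_nm <= 0 or self.soma_spread_nm <= 0:
            raise ConfigurationError("extent and soma spread must be positive")

    @property
    def resolution_nm(self) -> float:
        return _RESOLUTION_NM[self.synapse_type]

    @property
    def n_synapses(self) -> int:
        return int(math.floor(0.5 * self.n_neurons * self.syn_per_neuron + 0.5))


def _placement_margin(cfg: GeneratorConfig) -> float:
    # Room for the widest possible pre-post separation — and, in soma
    # mode, the Gaussian offset (4 sigma) — so terminals stay inside
    # the volume.
    pair_span = 2.0 * cfg.radius_range_nm[1] + cfg.cleft_range_nm[1]
    if cfg.placement == "uniform":
        return pair_span
    return 4.0 * cfg.soma_spread_nm + pair_span


def generate(cfg: GeneratorConfig) -> Synaptome:
    """Generate a synaptome from a config, reproducibly from its seed.

    Presynaptic neuron assignments are round-robin (every neuron gets an
    exact share of pre terminals); postsynaptic assignments are a seeded
    permutation of the same round-robin list, so inputs and outputs
    balance exactly.  Each synapse places the axonal terminal near its
    neuron's soma and the dendritic terminal at centre distance
    ``r_pre + r_post + cleft`` along a uniform random direction, with the
    cleft drawn uniformly from the type's interval.
    """
    margin = _placement_margin(cfg)
    if cfg.extent_nm <= 2 * margin:
        raise ConfigurationError(
            f"extent {cfg.extent_nm} nm too small to place terminals: needs "
            f"> {2 * margin:.0f} nm for the configured spread/radii/cleft"
        )
    rng = np.random.default_rng(cfg.seed)
    n_syn = cfg.n_synapses
    n = cfg.n_neurons

    pre_neurons = np.arange(n_syn) % n
    post_neurons = rng.permutation(pre_neurons)

    somata = rng.uniform(margin, cfg.extent_nm - margin, size=(n, 3))
    next_terminal = np.zeros(n, dtype=np.int64)

    def take_terminal_id(neuron: int) -> int:
        tid = int(next_terminal[neuron])
        next_terminal[neuron] += 1
        return tid

    rlo, rhi = cfg.radius_range_nm
    clo, chi = cfg.cleft_range_nm
    synapses: list[Synapse] = []
    n_autapses = 0
    for k in range(n_syn):
        i = int(pre_neurons[k])
        j = int(post_neurons[k])
        r_pre = float(rng.uniform(rlo, rhi))
        r_post = float(rng.uniform(rlo, rhi))
        cleft = float(rng.uniform(clo, chi))
        dist = r_pre + r_post + cleft
        for _ in range(100):
            if cfg.placement == "uniform":
                pre_center = rng.uniform(margin, cfg.extent_nm - margin, size=3)
            else:
                pre_center = somata[i] + rng.normal(
                    0.0, cfg.soma_spread_nm, size=3
                )
            direction = rng.normal(0.0, 1.0, size=3)
            direction /= np.linalg.norm(direction)
            post_center = pre_center + dist * direction
            if (
                np.all((pre_center >= 0) & (pre_center <= cfg.extent_nm))
                and np.all((post_center >= 0) & (post_center <= cfg.extent_nm))
            ):
                break
        else:  # pragma: no cover - margin makes this effectively unreachable
            raise ConfigurationError(
                "could not place a terminal inside the extent"
            )
        if i == j:
            n_autapses += 1
        pre = TerminalQuadruple(
            neuron_id=i,
            terminal_id=take_terminal_id(i),
            center=tuple(pre_center),
            radius=r_pre,
            kind=TerminalKind.AXONAL,
        )
        post = TerminalQuadruple(
            neuron_id=j,
            terminal_id=take_terminal_id(j),
            center=tuple(post_center),
            radius=r_post,
            kind=TerminalKind.DENDRITIC,
        )
        synapses.append(Synapse(pre=pre, post=post))

    if n_autapses and not cfg.allow_autapses:
        raise ConfigurationError(
            f"{n_autapses} autapses drawn but allow_autapses=False"
        )
    if n_autapses:
        warnings.warn(
            f"generated synaptome contains {n_autapses} autapse(s)",
            stacklevel=2,
        )

    profile = EncodingProfile(
        resolution_nm=cfg.resolution_nm,
        extent_nm=cfg.extent_nm,
    )
    return Synaptome(
        synapses=synapses,
        profile=profile,
        provenance={"seed": cfg.seed, "config": asdict(cfg)},
    )


@dataclass(frozen=True)
class CensusSummary:
    """Observed counts of a synaptome."""

    n_neurons: int
    n_synapses: int
    n_pre_terminals: int
    n_post_terminals: int
    mean_terminals_per_neuron: float

    @property
    def balanced(self) -> bool:
        return self.n_pre_terminals == self.n_post_terminals == self.n_synapses


def census_of(synaptome: Synaptome) -> CensusSummary:
    """Count neurons, synapses and terminals actually present."""
    neurons = synaptome.neuron_ids()
    n_syn = len(synaptome)
    pre = {s.pre.key for s in synaptome}
    post = {s.post.key for s in synaptome}
    mean_terms = (len(pre) + len(post)) / len(neurons) if neurons else 0.0
    return CensusSummary(
        n_neurons=len(neurons),
        n_synapses=n_syn,
        n_pre_terminals=len(pre),
        n_post_terminals=len(post),
        mean_terminals_per_neuron=mean_terms,
    )
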