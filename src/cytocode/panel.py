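"""Panel, population, effect and lattice specifications.

A *panel* is the ordered list of measured channels.  Analyte channels carry
either signaling state (phospho-epitopes), cell identity (lineage markers) or
viability (cleaved caspase-3); every panel additionally carries exactly one
DNA-intercalator channel and one event-length channel used for debris and
doublet gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

ROLES = ("signaling", "identity", "viability", "dna", "length")

#: analyte channels of the default 21-plex epithelial signaling panel
DEFAULT_SIGNALING = (
    "p-ERK", "p-P38", "p-CREB", "p-CJUN", "p-STAT3", "p-S6", "p-P90RSK",
    "p-RB", "p-AKT", "p-NFKB", "p-JNK", "p-MEK", "p-GSK3B",
)
DEFAULT_IDENTITY = ("CLCA1", "CHGA", "DCLK1", "CK18", "CK20", "CD45", "Villin")
DEFAULT_VIABILITY = ("CC3",)

DNA_CHANNEL = "DNA"
LENGTH_CHANNEL = "Event_length"


@dataclass(frozen=True)
class Channel:
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class PanelSpec:
    """Ordered channel list with role metadata.

    Invariants: exactly one ``dna`` and one ``length`` channel, at least one
    ``signaling`` channel, unique names.
    """

    channels: list[Channel]

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        roles = [c.role for c in self.channels]
        if roles.count("dna") != 1 or roles.count("length") != 1:
            raise ValueError("panel requires exactly one dna and one length channel")
        if roles.count("signaling") < 1:
            raise ValueError("panel requires at least one signaling channel")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def analyte_names(self) -> list[str]:
        return [c.name for c in self.channels
                if c.role in ("signaling", "identity", "viability")]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in panel") from None

    def role_of(self, name: str) -> str:
        return self.channels[self.index(name)].role


def default_panel() -> PanelSpec:
    """21 analyte channels (13 signaling, 7 identity, CC3) plus DNA and length."""
    chans = [Channel(n, "signaling") for n in DEFAULT_SIGNALING]
    chans += [Channel(n, "identity") for n in DEFAULT_IDENTITY]
    chans += [Channel(n, "viability") for n in DEFAULT_VIABILITY]
    chans.append(Channel(DNA_CHANNEL, "dna"))
    chans.append(Channel(LENGTH_CHANNEL, "length"))
    return PanelSpec(chans)


@dataclass
class PopulationSpec:
    """One mixture component: log-normal marker expression per analyte channel.

    ``log_mean``/``log_sd`` map analyte channel name -> location/spread on the
    natural-log scale.  Channels absent from the maps fall back to the
    population's ``base_log_mean``/``base_log_sd``.
    """

    name: str
    fraction: float
    log_mean: Mapping[str, float] = field(default_factory=dict)
    log_sd: Mapping[str, float] = field(default_factory=dict)
    base_log_mean: float = np.log(10.0)
    base_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction of {self.name!r} must be in [0,1]")
        if self.base_log_sd <= 0 or any(s <= 0 for s in self.log_sd.values()):
            raise ValueError(f"log_sd of {self.name!r} must be strictly positive")

    def mu_sigma(self, analytes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        mu = np.array([self.log_mean.get(a, self.base_log_mean) for a in analytes])
        sd = np.array([self.log_sd.get(a, self.base_log_sd) for a in analytes])
        return mu, sd


@dataclass
class EffectSpec:
    """A planted perturbation: log-scale shifts on selected channels of one
    target population (a population name, or ``"dying"`` for the planted
    apoptotic subset)."""

    target_population: str
    affected_channels: list[tuple[str, int, float]]  # (channel, direction ±1, shift ≥ 0)

    def __post_init__(self) -> None:
        for ch, direction, shift in self.affected_channels:
            if direction not in (+1, -1):
                raise ValueError(f"direction for {ch!r} must be +1 or -1")
            if shift < 0:
                raise ValueError(f"shift for {ch!r} must be >= 0")

    def validate_against(self, panel: PanelSpec) -> None:
        for ch, _, _ in self.affected_channels:
            if ch not in panel.names:
                raise ValueError(f"EffectSpec references unknown channel {ch!r}")


@dataclass
class LatticeSpec:
    """Hexagonal sheet of cells; interior cells have six neighbors."""

    rows: int
    cols: int
    death_prob: float
    neighbor_rule: str = "hex6"

    def __post_init__(self) -> None:
        if self.rows < 3 or self.cols < 3:
            raise ValueError("lattice must be at least 3x3")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob must be in [0,1]")
        if self.neighbor_rule != "hex6":
            raise ValueError("only the hex6 neighbor rule is supported")


def check_fractions(populations: Sequence[PopulationSpec], tol: float = 1e-9) -> None:
    total = sum(p.fraction for p in populations)
    if abs(total - 1.0) > tol:
        raise ValueError(f"population fractions sum to {total}, expected 1")
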