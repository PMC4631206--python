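"""Event-level cytometry data: container, IO, transform, gating, typing.

The central container is :class:`EventMatrix` — an events × channels array of
nonnegative ion-count intensities with per-channel role metadata, optionally
carrying a hidden ground-truth sidecar when the events were simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Channel, PanelSpec
from . import fcs as _fcs

_ROLE_GUESS = {
    "dna": "dna", "iridium": "dna", "hoechst": "dna",
    "event_length": "length", "length": "length",
}


@dataclass
class EventMatrix:
    """Events × channels intensity matrix with channel roles.

    ``transform_state`` is ``"none"`` for raw intensities or
    ``("arcsinh", cofactor)`` once variance-stabilized; the transform is
    guarded against double application.  ``truth`` is an optional per-event
    ground-truth table (simulated data only) that never enters FCS output.
    """

    values: np.ndarray
    channels: list[Channel]
    transform_state: object = "none"
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (events x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel metadata length must equal column count")
        if self.transform_state == "none" and np.any(self.values < 0):
            raise ValueError("negative raw intensities are not allowed")
        if self.truth is not None and len(self.truth) != self.n_events:
            raise ValueError("truth sidecar row count must equal event count")

    # -- basic accessors -------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index(name)]

    def role_columns(self, *roles: str) -> list[str]:
        return [c.name for c in self.channels if c.role in roles]

    @property
    def analyte_names(self) -> list[str]:
        return self.role_columns("signaling", "identity", "viability")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)

    def subset(self, mask: np.ndarray) -> "EventMatrix":
        truth = self.truth.loc[mask].reset_index(drop=True) if self.truth is not None else None
        return EventMatrix(self.values[mask], list(self.channels),
                           self.transform_state, truth)

    # -- IO --------------------------------------------------------------
    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        """Comma-separated, UTF-8, '.' decimal, header = channel names.

        Hidden ground-truth columns go only to the optional sidecar."""
        self.to_dataframe().to_csv(path, index=False)
        if truth_path is not None and self.truth is not None:
            self.truth.to_csv(truth_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, panel: PanelSpec | None = None,
                 roles: Mapping[str, str] | None = None) -> "EventMatrix":
        df = pd.read_csv(path)
        if df.shape[1] == 0:
            raise ValueError(f"{path}: no channels found")
        values = df.to_numpy(dtype=float)
        if np.any(values < 0):
            bad = df.columns[np.where(values < 0)[1][0]]
            raise ValueError(f"{path}: negative intensity in channel {bad!r}")
        channels = _assign_roles(list(df.columns), panel, roles)
        return cls(values, channels)

    def to_fcs(self, path: str | Path) -> None:
        _fcs.write_fcs(path, self.values, self.channel_names)

    @classmethod
    def from_fcs(cls, path: str | Path, panel: PanelSpec | None = None,
                 roles: Mapping[str, str] | None = None) -> "EventMatrix":
        values, names = _fcs.read_fcs(path)
        channels = _assign_roles(names, panel, roles)
        return cls(np.asarray(values, dtype=float), channels)


def _assign_roles(names: Sequence[str], panel: PanelSpec | None,
                  roles: Mapping[str, str] | None) -> list[Channel]:
    out: list[Channel] = []
    for n in names:
        if roles is not None and n in roles:
            out.append(Channel(n, roles[n]))
        elif panel is not None and n in panel.names:
            out.append(Channel(n, panel.role_of(n)))
        else:
            guess = _ROLE_GUESS.get(n.lower())
            if guess is None:
                # analyte by default; explicit config needed only for dna/length
                guess = "signaling"
            out.append(Channel(n, guess))
    return out


def read_events(path: str | Path, format: str | None = None,
                panel: PanelSpec | None = None,
                roles: Mapping[str, str] | None = None) -> EventMatrix:
    """Read an :class:`EventMatrix` from FCS 3.0/3.1 or CSV."""
    if format is None:
        format = "fcs" if str(path).lower().endswith(".fcs") else "csv"
    if format == "fcs":
        return EventMatrix.from_fcs(path, panel, roles)
    if format == "csv":
        return EventMatrix.from_csv(path, panel, roles)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def arcsinh_transform(events: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """asinh(x / cofactor) on analyte channels; DNA/length left untouched.

    The cofactor (default 5, the mass-cytometry convention) sets the scale
    below which the transform is ~linear and above which it is ~logarithmic.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.transform_state != "none":
        raise ValueError("events already transformed; arcsinh is applied at most once")
    out = events.values.copy()
    for name in events.analyte_names:
        j = events.index(name)
        out[:, j] = np.arcsinh(out[:, j] / cofactor)
    return EventMatrix(out, list(events.channels), ("arcsinh", cofactor),
                       None if events.truth is None else events.truth.copy())


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

@dataclass
class GateResult:
    mask: np.ndarray
    gate_name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _scaled_mad(x: np.ndarray) -> float:
    # 1.4826 * MAD ~ sd under normality
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def gate_dna_singlets(events: EventMatrix, dna_2n: float | None = None,
                      dna_4n: float | None = None) -> GateResult:
    """Debris/doublet gate on DNA content and event length.

    The DNA window is ``[2n - 2*MAD, 4n + 2*MAD]`` (MAD scaled to the
    sd-equivalent, estimated around each location); events inside it and
    below the length doublet cutoff (median + 3*MAD) are kept.

    By default the 2n location is the mode of the DNA channel and 4n is
    pinned at twice it (the DNA-content doubling of G2/M cells).  For samples
    that may be dominated by debris — where no intact-cell mode exists to
    find — pass ``dna_2n``/``dna_4n`` from a control sample's gate params.
    """
    dna_cols = events.role_columns("dna")
    len_cols = events.role_columns("length")
    if not dna_cols or not len_cols:
        raise ValueError("gate_dna_singlets requires dna and length channels")
    dna = events.column(dna_cols[0])
    length = events.column(len_cols[0])
    if np.ptp(dna) == 0:
        raise ValueError("DNA channel is degenerate (zero variance); cannot gate")

    if dna_2n is None:
        hist, edges = np.histogram(dna, bins=128)
        j = int(np.argmax(hist))
        width = edges[1] - edges[0]
        # refine the modal-bin estimate to the median of the nearby events,
        # removing the binning bias
        near_mode = dna[(dna >= edges[j] - width) & (dna <= edges[j + 1] + width)]
        dna_2n = float(np.median(near_mode))
    if dna_4n is None:
        dna_4n = 2.0 * dna_2n

    near_2n = dna[(dna >= 0.7 * dna_2n) & (dna <= 0.5 * (dna_2n + dna_4n))]
    near_4n = dna[(dna > 0.5 * (dna_2n + dna_4n)) & (dna <= 1.35 * dna_4n)]
    mad_2n = _scaled_mad(near_2n) if near_2n.size else 0.0
    mad_4n = _scaled_mad(near_4n) if near_4n.size else mad_2n
    lo = dna_2n - 2.0 * mad_2n
    hi = dna_4n + 2.0 * mad_4n
    centers = (dna_2n, dna_4n)

    len_cut = float(np.median(length) + 3.0 * _scaled_mad(length))
    if np.ptp(length) == 0:
        len_cut = float(length[0]) + 1.0  # identical valid lengths: keep all
    mask = (dna >= lo) & (dna <= hi) & (length <= len_cut)
    return GateResult(mask, "dna_singlets",
                      {"dna_low": float(lo), "dna_high": float(hi),
                       "dna_2n": float(centers[0]), "dna_4n": float(centers[1]),
                       "length_cutoff": len_cut})


def threshold_from_control(control: EventMatrix, channel: str,
                           quantile: float = 0.99) -> float:
    """Positivity cutoff anchored on a vehicle-control sample.

    Returns the control distribution's quantile, computed by linear
    interpolation between order statistics (numpy's default convention,
    frozen here): on values {1..100}, quantile 0.99 gives 99.01.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    x = control.column(channel)
    if x.size == 0:
        raise ValueError("empty control sample")
    return float(np.quantile(x, quantile, method="linear"))


# ---------------------------------------------------------------------------
# cell typing
# ---------------------------------------------------------------------------

#: precedence when multiple identity markers exceed threshold
TYPE_PRECEDENCE = (
    ("CD45", "leukocyte"),
    ("CHGA", "enteroendocrine"),
    ("DCLK1", "tuft"),
    ("CLCA1", "goblet"),
    ("CK18", "secretory-CK18"),
)


@dataclass
class CellTypeCall:
    labels: np.ndarray            # per-event type label
    dying: np.ndarray             # per-event CC3-positive flag
    fractions: pd.Series          # per-type fraction of events
    cooccurrence: pd.DataFrame    # type x {CC3+, CC3-} counts


def classify_cell_types(events: EventMatrix, thresholds: Mapping[str, float],
                        cc3_channel: str = "CC3") -> CellTypeCall:
    """Rule-based cell typing by identity-marker positivity.

    Precedence CD45 > CHGA > DCLK1 > CLCA1 > CK18; events below all identity
    thresholds default to enterocyte.  The dying flag (CC3 above threshold)
    is orthogonal to the type label.
    """
    required = [m for m, _ in TYPE_PRECEDENCE] + [cc3_channel]
    missing = [m for m in required if m not in thresholds]
    if missing:
        raise ValueError(f"missing thresholds for markers: {missing}")
    for m in required:
        events.index(m)  # raises KeyError if channel absent

    n = events.n_events
    labels = np.array(["enterocyte"] * n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for marker, label in TYPE_PRECEDENCE:
        pos = events.column(marker) > thresholds[marker]
        take = pos & unassigned
        labels[take] = label
        unassigned &= ~pos
    dying = events.column(cc3_channel) > thresholds[cc3_channel]

    fractions = pd.Series(labels).value_counts(normalize=True)
    co = pd.crosstab(pd.Series(labels, name="type"),
                     pd.Series(np.where(dying, "CC3+", "CC3-"), name="cc3"))
    return CellTypeCall(labels, dying, fractions, co)


def dying_marker_ratio(frac_dying: float, frac_marker_pos: float) -> tuple[float, str]:
    """Ratio of dying cells to marker-positive cells, as ``1:x``.

    Returns ``(x, "1:x")`` with x = frac_marker_pos / frac_dying printed to
    two decimals, the convention used for dying : p-ERK+ cell ratios.
    """
    if frac_dying <= 0:
        raise ValueError("ratio undefined: fraction of dying cells is zero")
    x = frac_marker_pos / frac_dying
    return x, f"1:{x:.2f}"
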