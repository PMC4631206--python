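"""Synthetic mass-cytometry cohorts with a planted apoptotic signaling code.

The generator emulates the statistical structure of an intestinal-epithelium
CyTOF acquisition after an acute TNF-α challenge:

* a mixture of epithelial cell types (enterocytes dominating, goblet ~10%,
  enteroendocrine ~1%, tuft ~1%, a small leukocyte admixture), each with
  log-normal marker expression and elevated lineage markers;
* a planted CC3+ "dying" subset of enterocytes whose signaling is shifted on
  four of ~20 analytes (the signaling code: p-P38 up, p-CREB up, p-ERK down,
  CK20 down by default — directions are configurable modeling choices);
* a DNA-intercalator channel that is bimodal (2n/4n) for intact cells, with
  sub-2n debris, and an event-length channel with doublets formed by summing
  two singlet events;
* an optional hexagonal-lattice spatial mode in which the living neighbors of
  each dying cell activate p-ERK (the "flower petal" geometry).

All randomness flows from one top-level seed through deterministic
sub-streams, so identical (spec, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventMatrix
from .panel import (Channel, EffectSpec, LatticeSpec, PanelSpec,
                    PopulationSpec, check_fractions, default_panel)

# DNA/length location constants (arbitrary intensity units)
DNA_2N, DNA_4N, DNA_DEBRIS = 100.0, 200.0, 20.0
DNA_LOG_SD = 0.08
FOURN_FRACTION = 0.20
LENGTH_MEAN, LENGTH_LOG_SD = 30.0, 0.10

#: default planted code in dying enterocytes (channel, direction, shift in log units)
DEFAULT_CODE = (("p-P38", +1, 1.0), ("p-CREB", +1, 1.0),
                ("p-ERK", -1, 1.0), ("CK20", -1, 1.0))
CC3_DYING_SHIFT = 2.5  # log-scale elevation of cleaved caspase-3 in dying cells

IDENTITY_HIGH = 2.5  # log-scale elevation of a population's own lineage marker


def default_populations() -> list[PopulationSpec]:
    """Villus epithelium mixture: enterocyte-dominated with minor types."""
    def pop(name, frac, high):
        return PopulationSpec(name, frac,
                              log_mean={m: np.log(10.0) + IDENTITY_HIGH for m in high})
    return [
        pop("enterocyte", 0.87, ["Villin", "CK20", "CK18"]),
        pop("goblet", 0.10, ["CLCA1", "CK18", "Villin"]),
        pop("enteroendocrine", 0.01, ["CHGA", "CK18"]),
        pop("tuft", 0.01, ["DCLK1", "Villin"]),
        pop("leukocyte", 0.01, ["CD45"]),
    ]


def default_death_effects(shift: float = 1.0) -> list[EffectSpec]:
    """The planted 4-marker code applied to the dying enterocyte subset."""
    return [EffectSpec("dying", [(ch, d, shift * abs(s))
                                 for ch, d, s in DEFAULT_CODE])]


def tnf_duodenum_preset() -> dict:
    """Generator settings for the acute-TNF duodenum condition, where roughly
    one third of villus epithelial cells undergo apoptosis."""
    return {"panel": default_panel(), "populations": default_populations(),
            "effects": default_death_effects(), "dying_fraction": 1.0 / 3.0,
            "doublet_fraction": 0.05}


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(panel: PanelSpec | None = None,
                    populations: Sequence[PopulationSpec] | None = None,
                    effects: Sequence[EffectSpec] | None = None,
                    n_events: int = 10_000,
                    doublet_fraction: float = 0.05,
                    debris_fraction: float = 0.0,
                    dying_fraction: float = 0.10,
                    dying_population: str = "enterocyte",
                    seed: int = 0) -> EventMatrix:
    """Draw a synthetic cohort.

    ``n_events`` is the total event count; ``debris_fraction`` of events are
    sub-2n debris, ``doublet_fraction`` are two-cell aggregates (sums of two
    singlets), and ``dying_fraction`` of the ``dying_population`` cells are
    planted CC3+ apoptotic cells carrying the effect shifts.  Hidden
    ground-truth columns (population, dying/debris/doublet flags) live in the
    ``truth`` sidecar only.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 <= doublet_fraction < 1 or not 0 <= debris_fraction < 1:
        raise ValueError("doublet/debris fractions must be in [0, 1)")
    panel = panel or default_panel()
    populations = list(populations) if populations is not None else default_populations()
    effects = list(effects) if effects is not None else default_death_effects()
    check_fractions(populations)
    for eff in effects:
        eff.validate_against(panel)
        names = {p.name for p in populations} | {"dying"}
        if eff.target_population not in names:
            raise ValueError(
                f"EffectSpec targets unknown population {eff.target_population!r}")

    rng_pop, rng_val, rng_dna, rng_len, rng_mix = _streams(seed, 5)
    analytes = panel.analyte_names
    n_an = len(analytes)

    n_debris = int(round(debris_fraction * n_events))
    n_doublet = int(round(doublet_fraction * n_events))
    n_singlet = n_events - n_debris - n_doublet
    if n_singlet < 1:
        raise ValueError("debris + doublet fractions leave no singlet events")
    # doublets are sums of two singlet draws, so draw extras
    n_cells = n_singlet + 2 * n_doublet

    fracs = np.array([p.fraction for p in populations])
    pop_idx = rng_pop.choice(len(populations), size=n_cells, p=fracs)

    log_x = np.empty((n_cells, n_an))
    for i, p in enumerate(populations):
        sel = pop_idx == i
        mu, sd = p.mu_sigma(analytes)
        log_x[sel] = rng_val.normal(mu, sd, size=(int(sel.sum()), n_an))

    dying = np.zeros(n_cells, dtype=bool)
    target = np.array([populations[i].name == dying_population for i in pop_idx])
    dying[target] = rng_mix.random(int(target.sum())) < dying_fraction
    cc3_j = analytes.index("CC3") if "CC3" in analytes else None
    if cc3_j is not None:
        log_x[dying, cc3_j] += CC3_DYING_SHIFT

    pop_names = np.array([populations[i].name for i in pop_idx], dtype=object)
    for eff in effects:
        sel = dying if eff.target_population == "dying" else (pop_names == eff.target_population)
        for ch, direction, shift in eff.affected_channels:
            if ch in analytes:
                log_x[sel, analytes.index(ch)] += direction * shift

    x = np.exp(log_x)

    # dna: 2n/4n bimodal for intact cells
    is_4n = rng_dna.random(n_cells) < FOURN_FRACTION
    dna = np.where(is_4n, DNA_4N, DNA_2N) * np.exp(
        rng_dna.normal(0.0, DNA_LOG_SD, n_cells))
    length = LENGTH_MEAN * np.exp(rng_len.normal(0.0, LENGTH_LOG_SD, n_cells))

    # assemble singlets / doublets / debris
    sx = x[:n_singlet]
    sdna, slen = dna[:n_singlet], length[:n_singlet]
    a = slice(n_singlet, n_singlet + n_doublet)
    b = slice(n_singlet + n_doublet, n_cells)
    dx = x[a] + x[b]
    ddna, dlen = dna[a] + dna[b], length[a] + length[b]
    deb_x = np.exp(rng_mix.normal(np.log(3.0), 0.5, size=(n_debris, n_an)))
    deb_dna = DNA_DEBRIS * np.exp(rng_mix.normal(0.0, 0.4, n_debris))
    deb_len = 0.5 * LENGTH_MEAN * np.exp(rng_mix.normal(0.0, 0.3, n_debris))

    full_x = np.vstack([sx, dx, deb_x])
    full_dna = np.concatenate([sdna, ddna, deb_dna])
    full_len = np.concatenate([slen, dlen, deb_len])

    values = np.empty((n_events, panel.n_channels))
    for j, ch in enumerate(panel.channels):
        if ch.role == "dna":
            values[:, j] = full_dna
        elif ch.role == "length":
            values[:, j] = full_len
        else:
            values[:, j] = full_x[:, analytes.index(ch.name)]

    truth = pd.DataFrame({
        "population": np.concatenate([
            pop_names[:n_singlet],
            np.array(["doublet"] * n_doublet + ["debris"] * n_debris, dtype=object)]),
        "dying": np.concatenate([dying[:n_singlet],
                                 np.zeros(n_doublet + n_debris, dtype=bool)]),
        "is_doublet": np.concatenate([np.zeros(n_singlet, dtype=bool),
                                      np.ones(n_doublet, dtype=bool),
                                      np.zeros(n_debris, dtype=bool)]),
        "is_debris": np.concatenate([np.zeros(n_singlet + n_doublet, dtype=bool),
                                     np.ones(n_debris, dtype=bool)]),
    })

    # fixed shuffle so cohort order carries no block structure
    perm = rng_mix.permutation(n_events)
    return EventMatrix(values[perm], list(panel.channels), "none",
                       truth.iloc[perm].reset_index(drop=True))


# ---------------------------------------------------------------------------
# hexagonal lattice mode
# ---------------------------------------------------------------------------

_HEX_EVEN = ((+1, 0), (-1, 0), (0, +1), (0, -1), (-1, -1), (+1, -1))
_HEX_ODD = ((+1, 0), (-1, 0), (0, +1), (0, -1), (-1, +1), (+1, +1))


def hex_neighbors(r: int, c: int, rows: int, cols: int) -> list[tuple[int, int]]:
    """Six neighbors of (r, c) on an odd-r offset hexagonal grid, clipped to
    the lattice bounds."""
    offs = _HEX_ODD if r % 2 else _HEX_EVEN
    out = []
    for dr, dc in offs:
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            out.append((rr, cc))
    return out


def lattice_expected_ratio(p: float) -> float:
    """Expected activated : dying ratio on an infinite hex lattice with
    independent per-cell death probability p:  (1-p) * (1 - (1-p)^6) / p."""
    if p <= 0:
        raise ValueError("ratio undefined at p = 0")
    return (1.0 - p) * (1.0 - (1.0 - p) ** 6) / p


def observed_lattice_ratio(em: EventMatrix, interior_only: bool = True) -> float:
    """Activated : dying ratio of a lattice cohort.

    By default only interior cells are counted (every interior cell has the
    full six neighbors), which is the regime where the closed form
    :func:`lattice_expected_ratio` is exact; boundary cells see fewer
    neighbors and would bias the ratio low.
    """
    t = em.truth
    if t is None or "died" not in t:
        raise ValueError("not a lattice cohort (no died/activated truth)")
    if interior_only:
        rows, cols = int(t["row"].max()) + 1, int(t["col"].max()) + 1
        keep = ((t["row"] > 0) & (t["row"] < rows - 1)
                & (t["col"] > 0) & (t["col"] < cols - 1))
        t = t.loc[keep]
    died = int(t["died"].sum())
    if died == 0:
        raise ValueError("ratio undefined: no dying cells")
    return float(t["activated"].sum()) / died


def generate_lattice_cohort(panel: PanelSpec | None = None,
                            lattice: LatticeSpec | None = None,
                            base: PopulationSpec | None = None,
                            erk_shift: float = 1.5,
                            erk_channel: str = "p-ERK",
                            death_mask: np.ndarray | None = None,
                            seed: int = 0) -> EventMatrix:
    """Cells on a hex lattice; living neighbors of dying cells activate p-ERK.

    Each cell dies independently with ``lattice.death_prob`` (or per the
    explicit ``death_mask``); every surviving cell adjacent to at least one
    dying cell receives ``erk_shift`` on the p-ERK channel.  The sheet is
    flattened row-major into an :class:`EventMatrix` whose truth sidecar holds
    ``died``, ``activated`` and lattice coordinates.
    """
    if erk_shift < 0:
        raise ValueError("erk_shift must be >= 0")
    panel = panel or default_panel()
    lattice = lattice or LatticeSpec(30, 30, 0.05)
    base = base or PopulationSpec("enterocyte", 1.0)
    if erk_channel not in panel.analyte_names:
        raise ValueError(f"erk channel {erk_channel!r} not in panel")

    rows, cols = lattice.rows, lattice.cols
    rng_death, rng_val, rng_dna, rng_len = _streams(seed, 4)
    if death_mask is None:
        died = rng_death.random((rows, cols)) < lattice.death_prob
    else:
        died = np.asarray(death_mask, dtype=bool)
        if died.shape != (rows, cols):
            raise ValueError("death_mask shape must match the lattice")

    activated = np.zeros_like(died)
    for r in range(rows):
        for c in range(cols):
            if died[r, c]:
                continue
            if any(died[rr, cc] for rr, cc in hex_neighbors(r, c, rows, cols)):
                activated[r, c] = True

    n = rows * cols
    analytes = panel.analyte_names
    mu, sd = base.mu_sigma(analytes)
    log_x = rng_val.normal(mu, sd, size=(n, len(analytes)))
    flat_died = died.ravel()
    flat_act = activated.ravel()
    j_erk = analytes.index(erk_channel)
    log_x[flat_act, j_erk] += erk_shift
    if "CC3" in analytes:
        log_x[flat_died, analytes.index("CC3")] += CC3_DYING_SHIFT
    x = np.exp(log_x)

    is_4n = rng_dna.random(n) < FOURN_FRACTION
    dna = np.where(is_4n, DNA_4N, DNA_2N) * np.exp(rng_dna.normal(0, DNA_LOG_SD, n))
    length = LENGTH_MEAN * np.exp(rng_len.normal(0, LENGTH_LOG_SD, n))

    values = np.empty((n, panel.n_channels))
    for j, ch in enumerate(panel.channels):
        if ch.role == "dna":
            values[:, j] = dna
        elif ch.role == "length":
            values[:, j] = length
        else:
            values[:, j] = x[:, analytes.index(ch.name)]

    rr, cc = np.divmod(np.arange(n), cols)
    truth = pd.DataFrame({"died": flat_died, "activated": flat_act,
                          "row": rr, "col": cc})
    return EventMatrix(values, list(panel.channels), "none", truth)
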