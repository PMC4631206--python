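"""End-to-end analysis pipeline driven by a declarative config.

Stages, in order: simulate (or read) events -> arcsinh transform -> DNA/length
gate -> optional 2-D embedding + contour gating -> dying/living labels (CC3
threshold, optionally intersected with the contour population) -> PLSDA fit
-> cross-validation -> permutation null -> VIP -> feature selection ->
unscaled combined score -> dying : p-ERK+ ratio -> JSON report.

Every stage logs its parameters, seed and row counts; the report embeds a
hash of the config so a run is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .embedding import contour_gate, embed2d
from .events import (EventMatrix, arcsinh_transform, classify_cell_types,
                     dying_marker_ratio, gate_dna_singlets, read_events,
                     threshold_from_control)
from .panel import default_panel
from .plsda import (combined_score, cross_validate, fit_plsda,
                    permutation_test_beta, predict_scores, roc_auc,
                    select_features, vip_scores)


@dataclass
class RunConfig:
    """Flat declarative configuration for one end-to-end run."""

    seed: int = 0
    # exactly one of input_path / simulate
    input_path: str | None = None
    simulate: dict = field(default_factory=lambda: {
        "n_events": 5000, "dying_fraction": 0.10,
        "doublet_fraction": 0.05, "debris_fraction": 0.05})
    cofactor: float = 5.0
    embed: bool = False
    perplexity: float = 30.0
    exclusion: float = 0.10
    cc3_quantile: float = 0.99
    n_lv: int = 2
    B: int = 1000
    holdout: float = 0.10
    schemes: tuple = ("random", "venetian", "block")
    k_features: int = 4
    erk_channel: str = "p-ERK"
    exclude_from_model: tuple = ("CC3",)

    def validate(self) -> None:
        if (self.input_path is None) == (not self.simulate):
            raise ValueError("exactly one of input_path / simulate must be set")
        if not 0 < self.holdout < 1:
            raise ValueError("holdout must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if "simulate" in raw and raw.get("input_path"):
            cfg.simulate = {}
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log(report: dict, stage: str, t0: float, **info) -> None:
    report["stages"].append({"stage": stage, "elapsed_s": round(time.time() - t0, 3),
                             **info})


def run(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis chain; returns (and optionally writes) the
    report bundle."""
    config.validate()
    report: dict = {"config_hash": config.digest(), "seed": config.seed,
                    "stages": []}
    rng = np.random.SeedSequence(config.seed)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rng.spawn(6)]

    t0 = time.time()
    if config.input_path:
        em = read_events(config.input_path)
    else:
        em = synth.generate_cohort(seed=sub[0], **config.simulate)
    _log(report, "events", t0, n_events=em.n_events,
         n_channels=len(em.channels))

    t0 = time.time()
    em_t = arcsinh_transform(em, config.cofactor)
    _log(report, "transform", t0, cofactor=config.cofactor)

    t0 = time.time()
    gate = gate_dna_singlets(em_t)
    cells = em_t.subset(gate.mask)
    _log(report, "gate", t0, kept=int(gate.mask.sum()), params=gate.params)

    t0 = time.time()
    # marker thresholds anchored on a vehicle control: a simulated cohort
    # with no planted death, or the sample's own quantiles for file input
    markers = ["CD45", "CHGA", "DCLK1", "CLCA1", "CK18", "CC3"]
    if config.input_path is None:
        veh = synth.generate_cohort(seed=sub[2], **{**config.simulate,
                                                    "dying_fraction": 0.0})
        veh_t = arcsinh_transform(veh, config.cofactor)
        cuts = {m: threshold_from_control(veh_t, m, config.cc3_quantile)
                for m in markers + [config.erk_channel]}
    else:
        veh_t = None
        cuts = {m: float(np.quantile(cells.column(m), config.cc3_quantile))
                for m in markers + [config.erk_channel]}
    call = classify_cell_types(cells, cuts)
    # the discriminant contrasts dying vs living enterocytes, so restrict to
    # the enterocyte call before supervision
    ent_mask = call.labels == "enterocyte"
    cells = cells.subset(ent_mask)
    labels = call.dying[ent_mask].astype(int)
    _log(report, "classify+label", t0,
         fractions={k: round(v, 4) for k, v in call.fractions.items()},
         cc3_threshold=cuts["CC3"], n_enterocytes=int(ent_mask.sum()),
         n_dying=int(labels.sum()))

    if config.embed:
        t0 = time.time()
        emb = embed2d(cells, perplexity=config.perplexity, seed=sub[1])
        pops = contour_gate(emb, exclusion=config.exclusion)
        _log(report, "embed+contour", t0, n_populations=pops.n_populations,
             n_excluded=int(pops.excluded.sum()))
        report["n_populations"] = pops.n_populations
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise RuntimeError("label stage produced a single class; "
                           "check CC3 threshold/config")

    feat = [c for c in cells.analyte_names if c not in config.exclude_from_model]
    X = np.column_stack([cells.column(f) for f in feat])

    t0 = time.time()
    model = fit_plsda(X, labels, n_lv=config.n_lv)
    cal_auc, fpr, tpr = roc_auc(predict_scores(model, X), labels)
    _log(report, "fit", t0, calibration_auc=cal_auc)

    t0 = time.time()
    cv = {}
    for i, scheme in enumerate(config.schemes):
        res = cross_validate(X, labels, n_lv=config.n_lv, scheme=scheme,
                             holdout=config.holdout, seed=sub[3] + i)
        cv[scheme] = res["pooled_auc"]
    _log(report, "crossval", t0, **{f"cv_auc_{k}": v for k, v in cv.items()})

    t0 = time.time()
    perm = permutation_test_beta(X, labels, n_lv=config.n_lv, B=config.B,
                                 seed=sub[4])
    vip = vip_scores(model)
    sel = select_features(perm, vip, feat, k=config.k_features)
    _log(report, "permute+vip+select", t0, B=config.B,
         selected=sel.by_permutation, vip_gt1=sel.by_vip,
         agreement=sel.agreement)

    t0 = time.time()
    signs = [int(np.sign(perm.observed_beta[feat.index(f)]) or 1)
             for f in sel.by_permutation]
    cscore = combined_score(cells, sel.by_permutation, signs)
    comb_auc, _, _ = roc_auc(cscore, labels)
    single_aucs = {f: roc_auc(cells.column(f), labels)[0]
                   for f in sel.by_permutation}
    _log(report, "combined_score", t0, combined_auc=comb_auc)

    # dying : p-ERK+ ratio among enterocytes, control-anchored p-ERK cutoff
    frac_dying = labels.mean()
    erk_cut = cuts[config.erk_channel]
    frac_erk = float((cells.column(config.erk_channel) > erk_cut).mean())
    ratio_x, ratio_str = (dying_marker_ratio(frac_dying, frac_erk)
                          if frac_dying > 0 else (float("nan"), "undefined"))

    report.update({
        "calibration_auc": cal_auc,
        "cv_auc": cv,
        "beta": dict(zip(feat, perm.observed_beta.tolist())),
        "beta_null_sd": dict(zip(feat, perm.null_sd.tolist())),
        "p_values": dict(zip(feat, perm.p_two_sided.tolist())),
        "vip": dict(zip(feat, vip.tolist())),
        "selected_features": sel.by_permutation,
        "vip_selected": sel.by_vip,
        "selector_agreement": sel.agreement,
        "combined_auc": comb_auc,
        "single_marker_aucs": single_aucs,
        "dying_perk_ratio": ratio_str,
        "dying_perk_ratio_x": ratio_x,
    })

    if outdir is not None:
        outdir = Path(outdir)
        for d in ("events", "model", "report"):
            (outdir / d).mkdir(parents=True, exist_ok=True)
        cells.to_csv(outdir / "events" / "gated_events.csv")
        model_doc = {
            "format_version": 1, "n_lv": config.n_lv,
            "features": feat,
            "center": model.x_mean_.tolist(), "scale": model.x_std_.tolist(),
            "W": model.x_weights_.tolist(), "P": model.x_loadings_.tolist(),
            "q": model.y_loadings_.tolist(), "beta": model.coef_.tolist(),
            "intercept": model.intercept_,
        }
        (outdir / "model" / "plsda.json").write_text(json.dumps(model_doc, indent=1))
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            outdir / "report" / "roc_calibration.csv", index=False)
        pd.DataFrame(perm.null_beta, columns=feat).to_csv(
            outdir / "report" / "beta_null.csv", index=False)
        (outdir / "report" / "report.json").write_text(
            json.dumps(report, indent=1, default=str))
    return report
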