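"""Cross-platform quantitative comparison of signaling time courses.

Bulk-level summaries of the same analyte measured on different platforms
(single-cell cytometry medians, immunoblot integrated band intensities,
imaging mean pixel intensities) are put on a common scale by Z-scoring each
time-course experiment — mean centering and variance scaling within one
(platform, analyte, region, experiment) series — and then compared by
Pearson correlation, per analyte and pooled across all analytes.  Outliers
are deliberately not removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PLATFORMS = ("flow_median", "blot_integrated", "imaging_meanpixel", "cytof_median")
COURSE_KEYS = ["platform", "analyte", "region", "experiment"]
MATCH_KEYS = ["analyte", "region", "time"]


def _as_panel(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "experiment" not in out.columns:
        out["experiment"] = 0
    required = set(COURSE_KEYS + ["time", "value"])
    missing = required - set(out.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    return out


def average_replicates(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean over replicates at each (course, time) point."""
    panel = _as_panel(panel)
    return (panel.groupby(COURSE_KEYS + ["time"], as_index=False)["value"]
            .mean())


def zscore_timecourse(panel: pd.DataFrame, average_reps: bool = True) -> pd.DataFrame:
    """Z-score each time-course experiment: v' = (v - mean) / sd, sample sd
    (ddof=1), within every (platform, analyte, region, experiment) series.

    Replicates are averaged per time point first by default.  A series needs
    at least 3 time points and nonzero variance; a flat course raises an
    error naming it.
    """
    panel = average_replicates(panel) if average_reps else _as_panel(panel)
    out = panel.copy()

    def _z(g: pd.DataFrame) -> pd.DataFrame:
        v = g["value"].to_numpy(dtype=float)
        if len(v) < 3:
            raise ValueError(f"time course {g.name} has < 3 time points")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"time course {g.name} has zero variance")
        g = g.copy()
        g["value"] = (v - v.mean()) / sd
        return g

    out = (out.groupby(COURSE_KEYS, group_keys=False)[out.columns]
           .apply(_z).reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# platform aggregation conventions
# ---------------------------------------------------------------------------

def aggregate_platform(raw, platform: str, **kw) -> float:
    """Collapse raw measurements to one number by the platform's convention:
    cytometry -> median event intensity; immunoblot -> integrated band
    intensity after linear background subtraction; imaging -> mean pixel
    intensity within the compartment mask."""
    if platform in ("flow_median", "cytof_median", "cytometry"):
        events = np.asarray(raw, dtype=float)
        if events.size == 0:
            raise ValueError("empty event vector")
        return float(np.median(events))
    if platform in ("blot_integrated", "blot"):
        profile = np.asarray(raw, dtype=float)
        if profile.size == 0:
            raise ValueError("empty band profile")
        # background: straight line between the top and bottom of the
        # bounding box
        bg = np.linspace(profile[0], profile[-1], profile.size)
        return float(np.sum(profile - bg))
    if platform in ("imaging_meanpixel", "imaging"):
        image = np.asarray(raw, dtype=float)
        mask = np.asarray(kw.get("mask", np.ones_like(image, dtype=bool)), dtype=bool)
        if not mask.any():
            raise ValueError("empty imaging mask")
        return float(image[mask].mean())
    raise ValueError(f"unknown platform {platform!r}")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate_platforms(panel_a: pd.DataFrame, panel_b: pd.DataFrame,
                        per_analyte: bool = True,
                        zscored: bool = False) -> dict:
    """Pearson correlation between two platforms' Z-scored panels.

    Values are matched pairwise on (analyte, region, time); unmatched points
    drop out, nothing is imputed, and outliers are not removed.  Returns
    per-analyte r/p/n (needing >= 3 pairs each) and the combined analysis
    pooling all matched Z-scored pairs across analytes.  Symmetric in its
    arguments.
    """
    a = panel_a if zscored else zscore_timecourse(panel_a)
    b = panel_b if zscored else zscore_timecourse(panel_b)
    merged = a.merge(b, on=MATCH_KEYS, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("fewer than 3 matched (analyte, region, time) pairs")

    rows = []
    if per_analyte:
        for analyte, g in merged.groupby("analyte"):
            if len(g) < 3:
                continue
            r, p = stats.pearsonr(g["value_a"], g["value_b"])
            rows.append({"analyte": analyte, "r": r, "p": p, "n": len(g)})
    r_all, p_all = stats.pearsonr(merged["value_a"], merged["value_b"])
    return {
        "per_analyte": pd.DataFrame(rows),
        "combined": {"r": float(r_all), "p": float(p_all), "n": len(merged)},
        "pairs": merged,
    }


def simulate_two_platform_panel(n_pairs: int = 200, noise_sd: float = 0.577,
                                n_analytes: int = 11, seed: int = 0
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent-signal model for two platforms: each reports signal + its own
    independent Gaussian noise of sd ``noise_sd``, so the expected pooled
    Pearson r between platforms is attenuated to 1 / (1 + noise_sd**2).

    Returns two long-format panels sharing (analyte, region, time) keys.
    """
    rng = np.random.default_rng(seed)
    per = max(3, int(np.ceil(n_pairs / n_analytes)))
    rows_a, rows_b = [], []
    for ai in range(n_analytes):
        signal = rng.normal(0.0, 1.0, per)
        va = signal + rng.normal(0.0, noise_sd, per)
        vb = signal + rng.normal(0.0, noise_sd, per)
        for t in range(per):
            key = {"analyte": f"analyte{ai}", "region": "duodenum",
                   "time": float(t), "experiment": 0}
            rows_a.append({**key, "platform": "flow_median", "value": va[t]})
            rows_b.append({**key, "platform": "imaging_meanpixel", "value": vb[t]})
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b)
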