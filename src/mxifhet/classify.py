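"""Positivity calls, EPH/Ki67 class assignment, per-core summaries and surrogate subtyping.

The EPH grouping is the 8-way single-cell class obtained by thresholding the
normalized ER, PR and HER2 signals; crossing with Ki67 positivity yields 16
classes.  The group index is the fixed bijection

====== ========= ===== ======
group  ER        PR    HER2
====== ========= ===== ======
1      weak/neg  −     −
2      weak/neg  −     +
3      weak/neg  +     −
4      weak/neg  +     +
5      mod/str   −     −
6      mod/str   −     +
7      mod/str   +     −
8      mod/str   +     +
====== ========= ===== ======

and ``class = 2*(group - 1) + 1 + [Ki67+]`` (group-major, Ki67-minor ordering;
odd classes Ki67−, even classes Ki67+).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import norm_col, pos_col

#: markers with a positivity cut-point on the normalized 0-15 scale
THRESHOLDED_MARKERS = ("er", "pr", "her2", "ki67", "p53", "p16", "p21", "cd8", "cd20")

N_EPH_GROUPS = 8
N_CLASSES = 16
CLASS_LABELS = tuple(range(1, N_CLASSES + 1))


@dataclass(frozen=True)
class MarkerThresholds:
    """IHC-calibrated cut-points on the normalized 0-15 scale.

    A cell is positive when its normalized signal is strictly greater than the
    cut-point (the strict comparator generalizes the explicitly stated "> 0"
    rule for P53 to all markers).  ER's cut (0.4) separates weak/negative from
    moderate/strong staining; PR 1.6 and HER2 5.0 are the maxima observed in
    IHC-negative and 1+ cores respectively; Ki67 0.2 includes weakly positive
    cells; CD8/CD20 calls lymphocytes at 0.2.
    """

    er: float = 0.4
    pr: float = 1.6
    her2: float = 5.0
    ki67: float = 0.2
    p53: float = 0.0
    p16: float = 2.0
    p21: float = 1.0
    cd8: float = 0.2
    cd20: float = 0.2

    def __post_init__(self):
        for m in THRESHOLDED_MARKERS:
            v = getattr(self, m)
            if not 0.0 <= v <= 15.0:
                raise ValueError(f"threshold for {m!r} must be in [0, 15], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "MarkerThresholds":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def call_positivity(
    cells: pd.DataFrame,
    thresholds: MarkerThresholds = MarkerThresholds(),
    markers: Sequence[str] = THRESHOLDED_MARKERS,
) -> pd.DataFrame:
    """Add boolean ``pos_<marker>`` columns: normalized signal strictly above cut.

    Raises if a required normalized column is missing or contains NaN (naming
    the offending marker and cells).
    """
    out = cells.copy()
    for m in markers:
        col = norm_col(m)
        if col not in out.columns:
            raise KeyError(f"normalized signal missing for marker {m!r} (column {col!r})")
        x = out[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = out.loc[np.isnan(x), "cell_id"].tolist()[:5]
            raise ValueError(f"NaN normalized value for marker {m!r} at cell(s) {bad}")
        out[pos_col(m)] = x > getattr(thresholds, m)
    return out


def eph_group_from_flags(er_high, pr_pos, her2_pos) -> np.ndarray:
    """The fixed (ER, PR, HER2) -> group bijection: 1 + 4*[ERm/s] + 2*[PR+] + [HER2+]."""
    return (
        1
        + 4 * np.asarray(er_high, dtype=int)
        + 2 * np.asarray(pr_pos, dtype=int)
        + np.asarray(her2_pos, dtype=int)
    )


def assign_eph(cells: pd.DataFrame) -> pd.DataFrame:
    """Assign ``eph_group`` (1-8) and ``eph_ki67_class`` (1-16) from positivity flags."""
    for m in ("er", "pr", "her2", "ki67"):
        if pos_col(m) not in cells.columns:
            raise KeyError(f"positivity column {pos_col(m)!r} missing; run call_positivity first")
    out = cells.copy()
    group = eph_group_from_flags(out[pos_col("er")], out[pos_col("pr")], out[pos_col("her2")])
    out["eph_group"] = group
    out["eph_ki67_class"] = 2 * (group - 1) + 1 + out[pos_col("ki67")].to_numpy(dtype=int)
    return out


@dataclass(frozen=True)
class SubtypeRules:
    """Surrogate-subtype rule parameters (St. Gallen consensus conventions).

    ER/PR positivity for subtyping is >= 1% stained cells on IHC (clinical
    convention); the Luminal A / Luminal B split uses Ki67 < 20% and
    PR >= 20%.  All four are configurable because the consensus leaves the
    exact Ki67 cut to the laboratory.
    """

    er_pos_min_percent: float = 1.0
    pr_pos_min_percent: float = 1.0
    ki67_cut_percent: float = 20.0
    pr_cut_percent: float = 20.0


def assign_surrogate_subtype(
    meta: pd.DataFrame, rules: SubtypeRules = SubtypeRules()
) -> pd.DataFrame:
    """Derive the IHC-surrogate subtype for every core from its IHC scores.

    HER2-positive means IHC 3+ or FISH-amplified (2+ must already be
    FISH-resolved).  Rules: LumA = ER+, HER2−, Ki67 < cut, PR >= cut;
    LumB = other ER+ HER2−; LumB_HER2pos = ER+ HER2+; HER2 = ER− PR− HER2+;
    TNBC = ER− PR− HER2−.
    """
    out = meta.copy()
    unresolved = (out["ihc_her2"] == "2+") & (out["fish_result"] == "NA")
    if unresolved.any():
        raise ValueError(
            f"HER2 2+ core(s) {out.loc[unresolved, 'core_id'].tolist()} unresolved by FISH"
        )
    her2_pos = (out["ihc_her2"] == "3+") | (out["fish_result"] == "amplified")
    er_pos = out["ihc_er_percent"].to_numpy(dtype=float) >= rules.er_pos_min_percent
    pr_pos = out["ihc_pr_percent"].to_numpy(dtype=float) >= rules.pr_pos_min_percent
    ki67_low = out["ihc_ki67_percent"].to_numpy(dtype=float) < rules.ki67_cut_percent
    pr_high = out["ihc_pr_percent"].to_numpy(dtype=float) >= rules.pr_cut_percent

    subtype = np.full(len(out), "", dtype=object)
    lum = er_pos & ~her2_pos
    subtype[lum & ki67_low & pr_high] = "LumA"
    subtype[lum & ~(ki67_low & pr_high)] = "LumB"
    subtype[er_pos & her2_pos] = "LumB_HER2pos"
    subtype[~er_pos & ~pr_pos & her2_pos] = "HER2"
    subtype[~er_pos & ~pr_pos & ~her2_pos] = "TNBC"
    unclassified = subtype == ""
    if unclassified.any():
        # ER− PR+ cores do not fit the five surrogate categories
        raise ValueError(
            f"core(s) {out.loc[unclassified, 'core_id'].tolist()} do not match any "
            "surrogate subtype rule (ER-negative, PR-positive?)"
        )
    out["subtype"] = subtype
    return out


@dataclass
class CoreSummary:
    """Per-core composition and marker summary.

    ``class_fractions`` are fractions of the 16 EPH×Ki67 classes over cancer
    cells (sum to 1 for a non-empty core); positive fractions are over cancer
    cells; CD8/CD20 densities are percentages of all QC-passing segmented
    cells; quantiles summarize the per-cell normalized P53/P16/P21 signal
    distributions in cancer cells.
    """

    core_id: str
    n_cancer_cells: int
    empty: bool
    class_fractions: np.ndarray  # length 16, NaN if empty
    ki67_pos_fraction: float
    p53_pos_fraction: float
    p16_pos_fraction: float
    p21_pos_fraction: float
    cd8_density_pct: float
    cd20_density_pct: float
    signal_quantiles: dict  # marker -> {q50, q75, q99}

    def to_row(self) -> dict:
        row = {
            "core_id": self.core_id,
            "n_cancer_cells": self.n_cancer_cells,
            "empty": self.empty,
            "ki67_pos_fraction": self.ki67_pos_fraction,
            "p53_pos_fraction": self.p53_pos_fraction,
            "p16_pos_fraction": self.p16_pos_fraction,
            "p21_pos_fraction": self.p21_pos_fraction,
            "cd8_density_pct": self.cd8_density_pct,
            "cd20_density_pct": self.cd20_density_pct,
        }
        for k in range(N_CLASSES):
            row[f"class_{k + 1:02d}_fraction"] = self.class_fractions[k]
        for m, qs in self.signal_quantiles.items():
            for q, v in qs.items():
                row[f"norm_{m}_{q}"] = v
        return row


def class_fraction_vector(classes: np.ndarray) -> np.ndarray:
    """Fractions of the 16 EPH×Ki67 classes in a vector of class indices."""
    classes = np.asarray(classes, dtype=int)
    if classes.size == 0:
        return np.full(N_CLASSES, np.nan)
    counts = np.bincount(classes, minlength=N_CLASSES + 1)[1 : N_CLASSES + 1]
    return counts / classes.size


def summarize_core(
    cancer_cells: pd.DataFrame,
    all_cells: pd.DataFrame,
    core_id: str,
) -> CoreSummary:
    """Summarize one core: class composition and positive fractions over its
    cancer cells, immune densities over all its QC-passing segmented cells.

    A core with zero cancer cells is flagged ``empty``; its fractions are NaN
    (undefined), not 0.
    """
    cc = cancer_cells[cancer_cells["core_id"] == core_id]
    ac = all_cells[all_cells["core_id"] == core_id]

    empty = len(cc) == 0
    fractions = class_fraction_vector(cc["eph_ki67_class"].to_numpy()) if not empty else np.full(N_CLASSES, np.nan)

    def frac(df, marker):
        return float(df[pos_col(marker)].mean()) if len(df) else float("nan")

    quantiles = {}
    for m in ("p53", "p16", "p21"):
        if empty or norm_col(m) not in cc.columns:
            quantiles[m] = {"q50": float("nan"), "q75": float("nan"), "q99": float("nan")}
        else:
            x = cc[norm_col(m)].to_numpy(dtype=float)
            quantiles[m] = {
                "q50": float(np.percentile(x, 50)),
                "q75": float(np.percentile(x, 75)),
                "q99": float(np.percentile(x, 99)),
            }

    n_all = len(ac)
    return CoreSummary(
        core_id=core_id,
        n_cancer_cells=len(cc),
        empty=empty,
        class_fractions=fractions,
        ki67_pos_fraction=frac(cc, "ki67"),
        p53_pos_fraction=frac(cc, "p53"),
        p16_pos_fraction=frac(cc, "p16"),
        p21_pos_fraction=frac(cc, "p21"),
        cd8_density_pct=100.0 * frac(ac, "cd8") if n_all else float("nan"),
        cd20_density_pct=100.0 * frac(ac, "cd20") if n_all else float("nan"),
        signal_quantiles=quantiles,
    )


def summarize_cores(
    cancer_cells: pd.DataFrame,
    all_cells: pd.DataFrame,
    core_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summaries for every core present in ``all_cells``, as a tidy DataFrame."""
    rows = []
    for core_id in all_cells["core_id"].unique():
        rows.append(summarize_core(cancer_cells, all_cells, core_id).to_row())
    df = pd.DataFrame(rows)
    if core_meta is not None:
        cols = [c for c in ("core_id", "case_id", "subtype") if c in core_meta.columns]
        df = core_meta[cols].merge(df, on="core_id", how="right")
    return df


def label_populations(
    cells: pd.DataFrame, cancer_index: pd.Index | None = None
) -> pd.DataFrame:
    """Label every QC-passing cell as cancer / CD8 / CD20 / other.

    Immune identity takes precedence over the cancer gate (a CD8+ cell inside
    a tumor region is still a lymphocyte); a cell positive for both immune
    markers is assigned to the one with the higher normalized signal.
    """
    out = cells.copy()
    label = np.full(len(out), "other", dtype=object)
    if cancer_index is not None:
        label[out.index.isin(cancer_index)] = "cancer"
    elif "population_label" in out.columns:
        label[(out["population_label"] == "cancer").to_numpy()] = "cancer"
    cd8 = out[pos_col("cd8")].to_numpy(dtype=bool)
    cd20 = out[pos_col("cd20")].to_numpy(dtype=bool)
    both = cd8 & cd20
    cd8_wins = out[norm_col("cd8")].to_numpy(dtype=float) >= out[norm_col("cd20")].to_numpy(dtype=float)
    label[cd8 & ~both] = "CD8"
    label[cd20 & ~both] = "CD20"
    label[both & cd8_wins] = "CD8"
    label[both & ~cd8_wins] = "CD20"
    out["population_label"] = label
    return out
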