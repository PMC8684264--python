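"""QC/size gating, annotation-based inclusion/exclusion, PCK gating and min-max normalization.

Gate order is QC -> size -> region/PCK, so every rejected cell has a single
unambiguous reason.  Normalization rescales each marker independently to 0-15
using the min and max observed over all QC-passing segmented cells of the
dataset (before any cancer gating), because the immune thresholds apply to all
cells, not just the cancer population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    MARKERS,
    NORMALIZED_MARKERS,
    RegionSet,
    norm_col,
    raw_col,
)


@dataclass(frozen=True)
class GatingConfig:
    """Cell-inclusion thresholds.

    Size gates are strict (``>``) and the PCK gate inclusive (``>=``), matching
    the conventions of the upstream quantification: cancer epithelial cells are
    larger than 90 px perimeter / 400 px area / 10 px nuclear area, and
    epithelial identity in luminal and HER2+ cores is called at raw
    pan-cytokeratin signal of at least 1500.
    """

    min_perimeter_px: float = 90.0
    min_cell_area_px: float = 400.0
    min_nuclear_area_px: float = 10.0
    pck_raw_min: float = 1500.0
    pck_gated_subtypes: frozenset = frozenset({"LumA", "LumB", "LumB_HER2pos", "HER2"})
    annotation_gated_subtypes: frozenset = frozenset({"TNBC"})

    def __post_init__(self):
        for name in ("min_perimeter_px", "min_cell_area_px", "min_nuclear_area_px", "pck_raw_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NormalizationSpec:
    """Fitted per-marker min/max recorded for reproducibility.

    ``marker_minmax[m] = (observed_min, observed_max)`` over the normalization
    population; degenerate markers (max == min) are listed so downstream
    consumers know their normalized values are identically 0.
    """

    out_min: float = 0.0
    out_max: float = 15.0
    marker_minmax: dict = field(default_factory=dict)
    degenerate_markers: list = field(default_factory=list)
    fitted: bool = False

    def __post_init__(self):
        if not self.out_min < self.out_max:
            raise ValueError("out_min must be < out_max")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "out_min": self.out_min,
                    "out_max": self.out_max,
                    "marker_minmax": {k: list(v) for k, v in self.marker_minmax.items()},
                    "degenerate_markers": self.degenerate_markers,
                    "fitted": self.fitted,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "NormalizationSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            out_min=d["out_min"],
            out_max=d["out_max"],
            marker_minmax={k: tuple(v) for k, v in d["marker_minmax"].items()},
            degenerate_markers=list(d["degenerate_markers"]),
            fitted=d["fitted"],
        )


class RenormalizationError(RuntimeError):
    """Raised when normalization is applied to already-normalized data."""


def normalize_markers(
    cells: pd.DataFrame,
    markers: Sequence[str] = NORMALIZED_MARKERS,
    spec: NormalizationSpec | None = None,
) -> tuple[pd.DataFrame, NormalizationSpec]:
    """Min-max normalize each marker to [out_min, out_max] (default 0-15).

    The min/max of each marker is fitted on QC-passing cells (the normalization
    population) unless a previously fitted ``spec`` is supplied; the transform
    is then applied to every row.  A marker whose observed max equals its min is
    degenerate: all its normalized values are set to 0 and a warning is issued.

    Returns the table with ``norm_<marker>`` columns added and the fitted spec.
    Re-normalizing a table that already carries normalized columns raises.
    """
    present = [m for m in markers if norm_col(m) in cells.columns]
    if present:
        raise RenormalizationError(
            f"table already carries normalized columns for {present}; "
            "re-normalization is forbidden"
        )
    missing = [m for m in markers if raw_col(m) not in cells.columns]
    if missing:
        raise KeyError(f"raw signal column(s) missing for marker(s) {missing}")

    out = cells.copy()
    fit_pop = out[out["qc_pass"]] if "qc_pass" in out.columns else out
    if spec is not None and spec.fitted:
        fitted = spec
    else:
        out_min = spec.out_min if spec is not None else 0.0
        out_max = spec.out_max if spec is not None else 15.0
        fitted = NormalizationSpec(out_min=out_min, out_max=out_max)
        for m in markers:
            x = fit_pop[raw_col(m)].to_numpy(dtype=float)
            lo, hi = float(np.min(x)), float(np.max(x))
            fitted.marker_minmax[m] = (lo, hi)
            if hi == lo:
                fitted.degenerate_markers.append(m)
        fitted.fitted = True

    for m in markers:
        lo, hi = fitted.marker_minmax[m]
        x = out[raw_col(m)].to_numpy(dtype=float)
        if hi == lo:
            warnings.warn(
                f"marker {m!r} is degenerate (max == min == {lo}); normalized values set to 0",
                stacklevel=2,
            )
            out[norm_col(m)] = 0.0
        else:
            out[norm_col(m)] = fitted.out_min + (fitted.out_max - fitted.out_min) * (x - lo) / (hi - lo)
    return out, fitted


def qc_and_size_gate(
    cells: pd.DataFrame, gating: GatingConfig = GatingConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep QC-passing cells strictly above all three size thresholds.

    Returns ``(kept, rejects)``; rejects carry the first failed rule
    (checked in order qc, perimeter, cell_area, nuclear_area) in a
    ``reject_reason`` column.  ``kept + rejected == input`` always.
    """
    reason = np.full(len(cells), "", dtype=object)
    qc = cells["qc_pass"].to_numpy(dtype=bool)
    reason[~qc] = "qc"
    perim_ok = cells["perimeter_px"].to_numpy(dtype=float) > gating.min_perimeter_px
    area_ok = cells["cell_area_px"].to_numpy(dtype=float) > gating.min_cell_area_px
    nuc_ok = cells["nuclear_area_px"].to_numpy(dtype=float) > gating.min_nuclear_area_px
    reason[(reason == "") & ~perim_ok] = "perimeter"
    reason[(reason == "") & ~area_ok] = "cell_area"
    reason[(reason == "") & ~nuc_ok] = "nuclear_area"

    kept = cells[reason == ""].copy()
    rejects = cells[reason != ""].copy()
    rejects["reject_reason"] = reason[reason != ""]
    return kept, rejects


class AnnotationMissingError(ValueError):
    """A core that requires tumor annotations has none."""


def select_cancer_population(
    cells: pd.DataFrame,
    core_meta: pd.DataFrame,
    regions: RegionSet | None = None,
    gating: GatingConfig = GatingConfig(),
) -> pd.DataFrame:
    """Select the cancer-cell population, per core, according to its subtype.

    Luminal and HER2+ cores: QC/size-gated cells with raw PCK >= 1500 that do
    not fall inside a benign-duct exclusion polygon.  TNBC cores (whose cells
    express PCK too weakly for a threshold): QC/size-gated cells inside a
    manually annotated tumor-inclusion polygon.  The returned cells carry
    ``population_label == 'cancer'``.
    """
    if "subtype" not in core_meta.columns or core_meta["subtype"].isna().any():
        raise ValueError("core metadata must carry a subtype for every core")
    regions = regions if regions is not None else RegionSet()

    gated, _ = qc_and_size_gate(cells, gating)
    kept_parts = []
    subtype_of = dict(zip(core_meta["core_id"], core_meta["subtype"]))
    for core_id, sub in gated.groupby("core_id", sort=False):
        subtype = subtype_of.get(str(core_id))
        if subtype is None:
            raise ValueError(f"core {core_id!r} absent from core metadata")
        x = sub["centroid_x"].to_numpy(dtype=float)
        y = sub["centroid_y"].to_numpy(dtype=float)
        if subtype in gating.annotation_gated_subtypes:
            include = regions.subset(label="include_tumor", core_id=str(core_id))
            if len(include) == 0:
                raise AnnotationMissingError(
                    f"TNBC core {core_id!r} has no include_tumor annotation"
                )
            keep = regions.contains(x, y, "include_tumor", core_id=str(core_id))
        elif subtype in gating.pck_gated_subtypes:
            keep = sub[raw_col("pck")].to_numpy(dtype=float) >= gating.pck_raw_min
            excl = regions.contains(x, y, "exclude_benign", core_id=str(core_id))
            keep &= ~excl
        else:
            raise ValueError(f"core {core_id!r} has unrecognized subtype {subtype!r}")
        kept_parts.append(sub[keep])

    kept = (
        pd.concat(kept_parts, ignore_index=False).sort_index()
        if kept_parts
        else gated.iloc[0:0]
    )
    kept = kept.copy()
    kept["population_label"] = "cancer"
    return kept


def select_all_cells_for_immune(cells: pd.DataFrame) -> pd.DataFrame:
    """All segmented QC-passing cells (cancer and stromal alike) — the
    population for immune quantification.  No size, PCK or region gating."""
    return cells[cells["qc_pass"]].copy()
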