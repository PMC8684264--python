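"""Domain types and readers/writers for cell tables, core metadata and region annotations.

The single-cell table is carried as a :class:`pandas.DataFrame` with one row per
segmented cell and a fixed canonical column vocabulary (see :data:`CELL_BASE_COLUMNS`
and the ``raw_<marker>`` / ``norm_<marker>`` / ``pos_<marker>`` families).  Readers
bind arbitrary CSV headers to that vocabulary through a ``schema_config`` mapping, so
a deposited file with its own column names can be ingested without code changes.

Coordinates are 0-based pixel centres, y increasing downward (image convention);
distances are Euclidean in pixels and converted to micrometres with the configured
pixel size (0.293 um/px by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

#: default physical pixel size of the imaging platform, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.293

#: protein markers quantified per cell (compartment-resolved upstream)
MARKERS = ("er", "pr", "her2", "ki67", "p53", "p21", "p16", "pck", "cd8", "cd20")

#: markers thresholded on the normalized 0-15 scale (PCK is gated on raw signal)
NORMALIZED_MARKERS = ("er", "pr", "her2", "ki67", "p53", "p21", "p16", "cd8", "cd20")

CELL_BASE_COLUMNS = (
    "cell_id",
    "core_id",
    "centroid_x",
    "centroid_y",
    "perimeter_px",
    "cell_area_px",
    "nuclear_area_px",
    "qc_pass",
)

CELL_NUMERIC_COLUMNS = (
    "centroid_x",
    "centroid_y",
    "perimeter_px",
    "cell_area_px",
    "nuclear_area_px",
)

SUBTYPES = ("LumA", "LumB", "LumB_HER2pos", "HER2", "TNBC")
HER2_IHC_LEVELS = ("0", "1+", "2+", "3+")
FISH_RESULTS = ("amplified", "not_amplified", "NA")
INTENSITY_LEVELS = ("neg", "weak", "moderate", "strong")
P53_STATUSES = ("normal", "null", "OE")
P16_STATUSES = ("normal", "OE")

REGION_LABELS = ("exclude_benign", "include_tumor")

CORE_META_COLUMNS = (
    "core_id",
    "case_id",
    "pair_id",
    "ihc_er_percent",
    "ihc_er_intensity",
    "ihc_pr_percent",
    "ihc_pr_intensity",
    "ihc_her2",
    "fish_result",
    "ihc_ki67_percent",
    "ihc_p53",
    "ihc_p16",
)


class SchemaError(ValueError):
    """A required column is missing or cannot be bound via the schema map."""


class IntegrityError(ValueError):
    """Row-level inconsistency: duplicate ids, unparseable numerics, invalid codes."""


class GeometryError(ValueError):
    """An annotation polygon violates the geometry contract."""


def raw_col(marker: str) -> str:
    return f"raw_{marker}"


def norm_col(marker: str) -> str:
    return f"norm_{marker}"


def pos_col(marker: str) -> str:
    return f"pos_{marker}"


@dataclass(frozen=True)
class Region:
    """One annotated region: a labelled simple polygon in pixel coordinates."""

    label: str
    polygon: Polygon
    core_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise GeometryError(
                f"unknown region label {self.label!r}; allowed labels: {REGION_LABELS}"
            )
        if len(self.polygon.exterior.coords) < 4:  # closed ring: n vertices + repeat
            raise GeometryError("polygon must have at least 3 vertices")
        if not self.polygon.is_valid:
            raise GeometryError("polygon is not simple (self-intersecting?)")


class RegionSet:
    """A collection of labelled annotation polygons with point-membership queries.

    Boundary points count as inside (inclusive gating is deterministic and, for
    inclusion regions, conservative).
    """

    def __init__(self, regions: Iterable[Region] = ()):
        self.regions: list[Region] = list(regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def subset(self, label: str | None = None, core_id: str | None = None) -> "RegionSet":
        out = [
            r
            for r in self.regions
            if (label is None or r.label == label)
            and (core_id is None or r.core_id is None or r.core_id == core_id)
        ]
        return RegionSet(out)

    def contains(
        self, x: np.ndarray, y: np.ndarray, label: str, core_id: str | None = None
    ) -> np.ndarray:
        """Boolean mask: is point (x, y) inside (or on the boundary of) any region
        with the given label (optionally restricted to one core)?"""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        mask = np.zeros(x.shape, dtype=bool)
        pts = shapely.points(x, y)
        for region in self.subset(label=label, core_id=core_id):
            mask |= shapely.covers(region.polygon, pts)
        return mask


def _resolve_columns(
    df: pd.DataFrame, required: Sequence[str], schema_config: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename CSV headers to canonical names and check the required set."""
    if schema_config:
        missing_src = [v for v in schema_config.values() if v not in df.columns]
        if missing_src:
            raise SchemaError(
                f"schema_config refers to absent CSV columns: {missing_src}"
            )
        df = df.rename(columns={v: k for k, v in schema_config.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return df


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], context: str) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise IntegrityError(
                f"{context}: column {col!r} has unparseable numeric values at rows {rows}"
            )
        if coerced.isna().any():
            rows = df.index[coerced.isna()].tolist()[:5]
            raise IntegrityError(f"{context}: column {col!r} has missing values at rows {rows}")
        df[col] = coerced.astype(float)


def read_cell_table(
    path,
    schema_config: Mapping[str, str] | None = None,
    markers: Sequence[str] = MARKERS,
) -> pd.DataFrame:
    """Read a per-cell CSV into the canonical cell table.

    Parameters
    ----------
    path
        CSV file with a header row, one row per segmented cell.
    schema_config
        Optional mapping ``canonical_name -> csv_header`` binding the file's
        actual headers (e.g. the deposited supplementary table's) to the
        canonical vocabulary.  Canonical names are the base columns plus
        ``raw_<marker>``.
    markers
        Markers whose raw signal columns are required.

    Row order is preserved; any unparseable numeric field raises rather than
    becoming a silent NA.
    """
    df = pd.read_csv(path)
    required = list(CELL_BASE_COLUMNS) + [raw_col(m) for m in markers]
    df = _resolve_columns(df, required, schema_config)

    _coerce_numeric(df, CELL_NUMERIC_COLUMNS, "cell table")
    _coerce_numeric(df, [raw_col(m) for m in markers], "cell table")

    for m in markers:
        if (df[raw_col(m)] < 0).any():
            raise IntegrityError(f"cell table: negative raw signal for marker {m!r}")
    if not np.isfinite(df[["centroid_x", "centroid_y"]].to_numpy()).all():
        raise IntegrityError("cell table: non-finite centroid coordinates")

    df["cell_id"] = df["cell_id"].astype(str)
    df["core_id"] = df["core_id"].astype(str)
    if df["qc_pass"].dtype != bool:
        df["qc_pass"] = (
            df["qc_pass"].astype(str).str.strip().str.lower().map(
                {"true": True, "1": True, "false": False, "0": False}
            )
        )
        if df["qc_pass"].isna().any():
            raise IntegrityError("cell table: qc_pass values must be boolean")
        df["qc_pass"] = df["qc_pass"].astype(bool)

    dup = df.duplicated(subset=["core_id", "cell_id"])
    if dup.any():
        first = df.loc[dup, ["core_id", "cell_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate cell_id {first['cell_id']!r} within core {first['core_id']!r}"
        )
    # normalized/positivity columns, if present (round-tripped tables), keep as-is
    return df.reset_index(drop=True)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write the canonical cell table to CSV (lossless round trip at float precision)."""
    cells.to_csv(path, index=False)


def _check_category(df: pd.DataFrame, col: str, allowed: Sequence[str], context: str) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        raise IntegrityError(
            f"{context}: column {col!r} has invalid value(s) "
            f"{sorted(df.loc[bad, col].unique().tolist())}; allowed: {list(allowed)}"
        )


def read_core_metadata(
    path, schema_config: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read the per-core IHC score table.

    HER2 2+ (equivocal) cores must carry a FISH resolution; a 2+ row with
    ``fish_result == 'NA'`` is a validation error because the equivocal IHC
    score alone cannot determine HER2 status.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _resolve_columns(df, CORE_META_COLUMNS, schema_config)

    _coerce_numeric(df, ["ihc_er_percent", "ihc_pr_percent", "ihc_ki67_percent"], "core metadata")
    for col in ("ihc_er_percent", "ihc_pr_percent", "ihc_ki67_percent"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise IntegrityError(f"core metadata: {col} outside [0, 100]")

    for col in ("core_id", "case_id", "pair_id"):
        df[col] = df[col].astype(str)
    _check_category(df, "ihc_er_intensity", INTENSITY_LEVELS, "core metadata")
    _check_category(df, "ihc_pr_intensity", INTENSITY_LEVELS, "core metadata")
    _check_category(df, "ihc_her2", HER2_IHC_LEVELS, "core metadata")
    _check_category(df, "fish_result", FISH_RESULTS, "core metadata")
    _check_category(df, "ihc_p53", P53_STATUSES, "core metadata")
    _check_category(df, "ihc_p16", P16_STATUSES, "core metadata")

    unresolved = (df["ihc_her2"] == "2+") & (df["fish_result"] == "NA")
    if unresolved.any():
        cores = df.loc[unresolved, "core_id"].tolist()
        raise IntegrityError(
            f"HER2 2+ (equivocal) core(s) {cores} lack a FISH result; equivocal IHC "
            "must be resolved by FISH"
        )

    dup = df.duplicated(subset=["core_id"])
    if dup.any():
        raise IntegrityError(f"duplicate core_id {df.loc[dup, 'core_id'].iloc[0]!r}")

    if "subtype" in df.columns:
        nonempty = df["subtype"] != ""
        _check_category(df.loc[nonempty], "subtype", SUBTYPES, "core metadata")
        df.loc[~nonempty, "subtype"] = pd.NA
    return df.reset_index(drop=True)


def write_core_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_annotations(path) -> RegionSet:
    """Read a GeoJSON FeatureCollection of annotation polygons.

    Every feature must carry a ``label`` property from the allowed vocabulary
    (``exclude_benign`` for benign ducts, ``include_tumor`` for manually
    annotated tumor regions) and may carry a ``core_id`` binding the region
    to one TMA core.  Rings must be explicitly closed (first vertex repeated)
    and simple.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeometryError("annotation file must be a GeoJSON FeatureCollection")
    regions = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        label = props.get("label")
        if label not in REGION_LABELS:
            raise GeometryError(
                f"unknown region label {label!r}; allowed labels: {REGION_LABELS}"
            )
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise GeometryError(f"unsupported geometry type {geom.get('type')!r}")
        rings = geom.get("coordinates") or []
        if not rings:
            raise GeometryError("polygon with no rings")
        exterior = rings[0]
        if len(exterior) < 4 or exterior[0] != exterior[-1]:
            raise GeometryError("open ring: polygon exterior must repeat its first vertex")
        poly = Polygon(exterior, holes=rings[1:])
        regions.append(Region(label=label, polygon=poly, core_id=props.get("core_id")))
    return RegionSet(regions)


def write_annotations(regions: RegionSet, path) -> None:
    feats = []
    for r in regions:
        props = {"label": r.label}
        if r.core_id is not None:
            props["core_id"] = r.core_id
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in r.polygon.exterior.coords]],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_core_summaries(summaries: pd.DataFrame, path) -> None:
    """Write per-core summaries (subtype, 16 class fractions, positive fractions,
    immune densities, per-class mean equitability) with a deterministic column order."""
    lead = [c for c in ("core_id", "case_id", "subtype", "n_cancer_cells", "empty") if c in summaries.columns]
    rest = sorted(c for c in summaries.columns if c not in lead)
    summaries[lead + rest].to_csv(path, index=False)


def read_core_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def um_to_px(distance_um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> int:
    """Convert a radius in micrometres to pixels.

    With the platform's native pixel size the conventional rounded pixel radii
    are used (30 um -> 100 px, 100 um -> 341 px); any other pixel size rounds
    the exact quotient.
    """
    if math.isclose(pixel_size_um, DEFAULT_PIXEL_SIZE_UM, rel_tol=1e-9):
        printed = {30.0: 100, 100.0: 341}
        if float(distance_um) in printed:
            return printed[float(distance_um)]
    return int(round(distance_um / pixel_size_um))
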