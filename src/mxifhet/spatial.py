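"""Radius neighborhoods, co-occurrence composition, Shannon equitability and immune neighborhoods.

Neighborhoods are Euclidean discs around each cell centroid (radius inclusive,
central cell excluded) and are always computed within a single TMA core —
cells never neighbor across cores.  The two conventional radii are 30 um
(100 px) and 100 um (341 px) at the platform pixel size.

Heterogeneity of a neighborhood is the Shannon equitability

    E_H = H / ln(S),   H = -sum_i p_i ln p_i

with ``p_i`` the neighbor class proportions and ``S`` the number of species in
scope.  E_H is 1 when all in-scope species are present in equal abundance and
is defined as 0 when only one species is in scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

IMMUNE_CLASSES = ("cancer", "CD8", "CD20")


@dataclass(frozen=True)
class DiversitySpec:
    """How the species count S entering E_H = H/ln(S) is determined.

    ``present_in_core`` (default) uses the classes observed anywhere in the
    core, making E_H comparable across central classes within a core;
    ``present_in_neighborhood`` uses only classes observed among the
    neighbors; ``fixed_panel`` uses an explicit class list.
    """

    species_scope: str = "present_in_core"
    class_scheme: str = "EPH8"
    fixed_classes: tuple = ()

    def __post_init__(self):
        if self.species_scope not in ("present_in_core", "present_in_neighborhood", "fixed_panel"):
            raise ValueError(f"unknown species_scope {self.species_scope!r}")
        if self.species_scope == "fixed_panel" and not self.fixed_classes:
            raise ValueError("fixed_panel scope requires an explicit class list")


def class_column(class_scheme: str) -> str:
    if class_scheme == "EPH8":
        return "eph_group"
    if class_scheme == "EPHKi67_16":
        return "eph_ki67_class"
    if class_scheme == "immune3":
        return "population_label"
    raise ValueError(f"unknown class scheme {class_scheme!r}")


def find_neighbors(centroids: np.ndarray, radius_px: float) -> list[np.ndarray]:
    """Indices of all *other* cells within ``radius_px`` (inclusive) of each cell.

    The relation is symmetric; the query uses a KD-tree and is verified
    elsewhere against brute force.
    """
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array")
    if len(pts) == 0:
        return []
    tree = cKDTree(pts)
    lists = tree.query_ball_point(pts, r=radius_px)
    return [np.array([j for j in lst if j != i], dtype=int) for i, lst in enumerate(lists)]


def find_neighbors_bruteforce(centroids: np.ndarray, radius_px: float) -> list[np.ndarray]:
    """O(n^2) reference implementation of :func:`find_neighbors`."""
    pts = np.asarray(centroids, dtype=float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    r2 = float(radius_px) ** 2
    out = []
    for i in range(len(pts)):
        mask = d2[i] <= r2
        mask[i] = False
        out.append(np.flatnonzero(mask).astype(int))
    return out


def _neighbor_count_matrix(
    xy: np.ndarray, class_idx: np.ndarray, n_classes: int, radius_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell neighbor counts by class via the symmetric pair list."""
    n = len(xy)
    counts = np.zeros((n, n_classes), dtype=np.int64)
    if n == 0:
        return counts, counts.sum(axis=1)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius_px, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        np.add.at(counts, (i, class_idx[j]), 1)
        np.add.at(counts, (j, class_idx[i]), 1)
    return counts, counts.sum(axis=1)


def shannon_equitability(counts, n_species: int | None = None) -> float:
    """E_H of one neighborhood count vector.

    ``n_species`` defaults to the number of distinct classes with a positive
    count (``present_in_neighborhood`` scope).  All-zero counts are undefined
    and raise; a single in-scope species gives 0 by convention.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero counts: equitability undefined")
    s = int(n_species) if n_species is not None else int((c > 0).sum())
    if s < 1:
        raise ValueError("species count must be >= 1")
    if s == 1:
        return 0.0
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(s)


def _equitability_rows(counts: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorized E_H per row; NaN where the row is empty, 0 where S == 1."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
        eh = np.where(s > 1, h / np.log(np.maximum(s, 2)), 0.0)
    eh[totals[:, 0] == 0] = np.nan
    return eh


def neighborhood_composition(
    cells: pd.DataFrame,
    class_scheme: str = "EPH8",
    radius_px: float = 100.0,
    diversity: DiversitySpec | None = None,
) -> pd.DataFrame:
    """Per-cell neighborhood profile at one radius, per core.

    Returns one row per cell: its core, class, radius, ``n_neighbors``,
    per-class neighbor counts (``nbr_<class>``) and the Shannon equitability of
    the neighborhood (NaN — undefined — for isolated cells).
    """
    diversity = diversity or DiversitySpec(class_scheme=class_scheme)
    col = class_column(class_scheme)
    if col not in cells.columns:
        raise KeyError(f"class column {col!r} missing from cell table")

    all_classes = sorted(pd.unique(cells[col]).tolist(), key=str)
    if diversity.species_scope == "fixed_panel":
        all_classes = list(diversity.fixed_classes)
    class_pos = {c: k for k, c in enumerate(all_classes)}

    parts = []
    for core_id, sub in cells.groupby("core_id", sort=False):
        xy = sub[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
        cls = sub[col].to_numpy()
        cls_idx = np.array([class_pos[c] for c in cls], dtype=int)
        counts, n_nbr = _neighbor_count_matrix(xy, cls_idx, len(all_classes), radius_px)

        if diversity.species_scope == "present_in_core":
            s = np.full(len(sub), len(np.unique(cls_idx)))
        elif diversity.species_scope == "present_in_neighborhood":
            s = (counts > 0).sum(axis=1)
        else:  # fixed_panel
            s = np.full(len(sub), len(all_classes))
        eh = _equitability_rows(counts.astype(float), s.astype(float))

        part = pd.DataFrame(
            {
                "cell_id": sub["cell_id"].to_numpy(),
                "core_id": core_id,
                "central_class": cls,
                "radius_px": radius_px,
                "n_neighbors": n_nbr,
                "equitability": eh,
            }
        )
        for c in all_classes:
            part[f"nbr_{c}"] = counts[:, class_pos[c]]
        parts.append(part)
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def aggregate_equitability(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and n of E_H per central class, excluding undefined profiles."""
    rows = []
    for cls, sub in profiles.groupby("central_class", sort=True):
        vals = sub["equitability"].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "central_class": cls,
                "n": len(vals),
                "mean_equitability": float(vals.mean()) if len(vals) else float("nan"),
                "sd_equitability": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def cumulative_neighborhood_profile(
    cells: pd.DataFrame,
    class_scheme: str = "EPH8",
    radius_px: float = 100.0,
    classes: Sequence | None = None,
) -> pd.DataFrame:
    """Pooled central-class x neighbor-class proportion matrix across cores.

    Neighbor counts are accumulated per core (neighborhoods never span cores),
    pooled over every cell of each central class, then row-normalized; each
    defined row sums to 1.
    """
    col = class_column(class_scheme)
    all_classes = list(classes) if classes is not None else sorted(pd.unique(cells[col]).tolist(), key=str)
    class_pos = {c: k for k, c in enumerate(all_classes)}
    pooled = np.zeros((len(all_classes), len(all_classes)), dtype=np.int64)
    for _, sub in cells.groupby("core_id", sort=False):
        xy = sub[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
        cls_idx = np.array([class_pos[c] for c in sub[col]], dtype=int)
        counts, _ = _neighbor_count_matrix(xy, cls_idx, len(all_classes), radius_px)
        np.add.at(pooled, cls_idx, counts)
    totals = pooled.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        props = np.where(totals > 0, pooled / np.maximum(totals, 1), np.nan)
    return pd.DataFrame(props, index=pd.Index(all_classes, name="central_class"), columns=all_classes)


def immune_neighborhood(cells: pd.DataFrame, radius_px: float = 341.0) -> pd.DataFrame:
    """Neighborhood composition around each CD8/CD20 lymphocyte at 100 um.

    ``cells`` must carry ``population_label`` in {cancer, CD8, CD20, other}.
    For each central immune cell the fractions of cancer/CD8/CD20 among its
    labelled neighbors are reported ('other' cells are not counted as a
    species); a lymphocyte with no labelled neighbor is undefined (NaN).
    """
    labelled = cells[cells["population_label"].isin(IMMUNE_CLASSES)]
    prof = neighborhood_composition(
        labelled,
        class_scheme="immune3",
        radius_px=radius_px,
        diversity=DiversitySpec(class_scheme="immune3", species_scope="fixed_panel", fixed_classes=IMMUNE_CLASSES),
    )
    prof = prof[prof["central_class"].isin(("CD8", "CD20"))].reset_index(drop=True)
    n = prof["n_neighbors"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in IMMUNE_CLASSES:
            prof[f"frac_{c}"] = np.where(n > 0, prof[f"nbr_{c}"] / n, np.nan)
    return prof
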