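"""Synthetic TMA generator: per-cell tables, core metadata and annotations with known truth.

The generator emulates the structure the analysis assumes: 1.1 mm cores with a
few thousand segmented cells each, class-conditional marker intensities
calibrated so that the printed cut-points on the dataset-normalized 0-15 scale
recover the intended positivity, uniform or Thomas-cluster spatial point
patterns (optionally class-pure clusters), paired cores with identical or
shifted class compositions, scattered or aggregated lymphocyte infiltrates,
and benign-duct / tumor-region annotations.

Intensities are drawn on a latent 0-15 scale (negatives: scaled Beta below the
cut-point with a guard band; positives: cut-point plus a gamma tail, truncated
at saturation) and converted to raw counts by a per-marker affine scale.  So
that dataset-global min-max normalization is exactly invertible, the generator
pins per-marker anchors — the lowest-signal negative cell to the detector
floor (0) and the highest-signal positive cell to saturation (15) — and emits
any marker with no positive cell in the dataset as uniform background.  Ground
truth (population, class, intended positivity, gate flags) travels in a
separate manifest, never in the cell table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .classify import MarkerThresholds, N_CLASSES
from .io import (
    DEFAULT_PIXEL_SIZE_UM,
    MARKERS,
    NORMALIZED_MARKERS,
    Region,
    RegionSet,
    raw_col,
    write_annotations,
    write_cell_table,
    write_core_metadata,
)

#: default raw-count scale per marker (raw = scale * latent + offset)
RAW_SCALE = {
    "er": 180.0, "pr": 210.0, "her2": 240.0, "ki67": 160.0,
    "p53": 190.0, "p21": 170.0, "p16": 200.0, "cd8": 150.0, "cd20": 150.0,
}
RAW_OFFSET = {m: 0.0 for m in RAW_SCALE}


class InfeasibleIntensityModel(ValueError):
    """The class-conditional intensity model cannot respect the cut-point."""


@dataclass(frozen=True)
class IntensityModel:
    """Class-conditional latent intensity distributions for one marker.

    Negative cells: ``neg_upper * Beta(neg_beta)`` — concentrated below the
    cut-point with a relative guard band.  Positive cells: ``pos_lower +
    Gamma(pos_shape, pos_scale)`` truncated at 15.  ``leak_rate`` is the
    probability a cell draws from the wrong side (default 0: thresholding
    after global normalization recovers the intended positivity exactly).
    """

    threshold: float
    guard: float = 0.05
    neg_beta: tuple = (1.5, 3.0)
    pos_shape: float = 2.0
    pos_scale: float | None = None  # default: (15 - pos_lower) / 8
    leak_rate: float = 0.0

    @property
    def neg_upper(self) -> float:
        if self.threshold == 0.0:
            return 0.0  # point mass at zero (no signal)
        return self.threshold * (1.0 - self.guard)

    @property
    def pos_lower(self) -> float:
        return max(self.threshold * (1.0 + self.guard), self.threshold + 0.05)

    def validate(self) -> None:
        if self.neg_upper > self.threshold:
            raise InfeasibleIntensityModel(
                f"negative class located above threshold ({self.neg_upper} > {self.threshold})"
            )
        if self.pos_lower < self.threshold:
            raise InfeasibleIntensityModel(
                f"positive class located below threshold ({self.pos_lower} < {self.threshold})"
            )
        if self.pos_lower >= 15.0:
            raise InfeasibleIntensityModel("positive class has no room below saturation")

    def draw(self, positive: np.ndarray, rng: np.random.Generator, hot: bool = False) -> np.ndarray:
        """Latent values for cells with the given intended positivity."""
        self.validate()
        positive = np.asarray(positive, dtype=bool)
        if self.leak_rate > 0:
            flip = rng.random(positive.shape) < self.leak_rate
            positive = positive ^ flip
        n = positive.size
        out = np.empty(n, dtype=float)
        neg = ~positive
        out[neg] = self.neg_upper * rng.beta(*self.neg_beta, size=int(neg.sum()))
        scale = self.pos_scale
        if scale is None:
            scale = (15.0 - self.pos_lower) / (3.0 if hot else 8.0)
        pos_vals = self.pos_lower + rng.gamma(self.pos_shape, scale, size=int(positive.sum()))
        out[positive] = np.minimum(pos_vals, 15.0)
        return out


@dataclass(frozen=True)
class ThomasClusterModel:
    """Thomas process on the core disc: Poisson parents, Gaussian offspring."""

    parent_rate: float | None = None  # expected parents per core; None -> n/offspring_mean
    cluster_sd_px: float = 80.0
    offspring_mean: float = 60.0


@dataclass(frozen=True)
class ImmuneSpec:
    """Lymphocyte content of a core: fractions of all cells, spatial pattern."""

    cd8_frac: float = 0.02
    cd20_frac: float = 0.015
    pattern: str = "scattered"  # or "aggregated"

    def __post_init__(self):
        if self.pattern not in ("scattered", "aggregated"):
            raise ValueError(f"unknown immune pattern {self.pattern!r}")


#: per-subtype defaults for P53/P16/P21 positive fractions among cancer cells
MARKER_POS_FRACS = {
    "LumA": {"p53": 0.05, "p16": 0.05, "p21": 0.20},
    "LumB": {"p53": 0.15, "p16": 0.10, "p21": 0.35},
    "LumB_HER2pos": {"p53": 0.20, "p16": 0.15, "p21": 0.20},
    "HER2": {"p53": 0.30, "p16": 0.30, "p21": 0.15},
    "TNBC": {"p53": 0.60, "p16": 0.50, "p21": 0.15},
}

#: IHC score templates consistent with the surrogate-subtype rules
IHC_TEMPLATES = {
    "LumA": dict(ihc_er_percent=90, ihc_er_intensity="strong", ihc_pr_percent=80,
                 ihc_pr_intensity="strong", ihc_her2="0", fish_result="NA",
                 ihc_ki67_percent=10, ihc_p53="normal", ihc_p16="normal"),
    "LumB": dict(ihc_er_percent=80, ihc_er_intensity="moderate", ihc_pr_percent=5,
                 ihc_pr_intensity="weak", ihc_her2="1+", fish_result="NA",
                 ihc_ki67_percent=35, ihc_p53="normal", ihc_p16="normal"),
    "LumB_HER2pos": dict(ihc_er_percent=60, ihc_er_intensity="moderate", ihc_pr_percent=10,
                         ihc_pr_intensity="weak", ihc_her2="3+", fish_result="NA",
                         ihc_ki67_percent=25, ihc_p53="normal", ihc_p16="normal"),
    "HER2": dict(ihc_er_percent=0, ihc_er_intensity="neg", ihc_pr_percent=0,
                 ihc_pr_intensity="neg", ihc_her2="3+", fish_result="NA",
                 ihc_ki67_percent=40, ihc_p53="OE", ihc_p16="OE"),
    "TNBC": dict(ihc_er_percent=0, ihc_er_intensity="neg", ihc_pr_percent=0,
                 ihc_pr_intensity="neg", ihc_her2="0", fish_result="NA",
                 ihc_ki67_percent=60, ihc_p53="OE", ihc_p16="OE"),
}


@dataclass
class CoreSpec:
    """Full recipe for one synthetic TMA core."""

    core_id: str
    case_id: str
    pair_id: str
    subtype: str
    n_cells: int = 1200
    class_fractions: dict = field(default_factory=lambda: {1: 1.0})
    spatial_model: str | ThomasClusterModel = "uniform_disc"
    cluster_by_class: bool = False
    immune: ImmuneSpec = field(default_factory=ImmuneSpec)
    other_frac: float = 0.12
    benign_frac: float = 0.0
    marker_pos_fracs: dict | None = None  # p53/p16/p21; default by subtype
    p53_hot: bool = False  # high-intensity P53 stratum (some P53-OE TNBC)
    intensity_models: dict | None = None  # marker -> IntensityModel overrides
    size_fail_frac: float = 0.03
    qc_fail_frac: float = 0.02
    core_diameter_um: float = 1100.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if not all(1 <= int(k) <= N_CLASSES for k in self.class_fractions):
            raise ValueError("class labels must be in 1..16")

    @property
    def radius_px(self) -> float:
        return (self.core_diameter_um / 2.0) / self.pixel_size_um

    def fraction_vector(self) -> np.ndarray:
        v = np.zeros(N_CLASSES)
        for k, f in self.class_fractions.items():
            v[int(k) - 1] = f
        return v


@dataclass
class CoreBundle:
    cells: pd.DataFrame
    metadata: pd.DataFrame
    regions: RegionSet
    truth: dict


# --- geometry -------------------------------------------------------------

def _uniform_disc(n: int, radius: float, center: tuple, rng) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _thomas_positions(n: int, model: ThomasClusterModel, radius: float, center: tuple, rng) -> np.ndarray:
    if model.parent_rate is not None:
        n_parents = max(1, int(rng.poisson(model.parent_rate)))
    else:
        n_parents = max(1, int(round(n / model.offspring_mean)))
    parents = _uniform_disc(n_parents, 0.85 * radius, center, rng)
    assign = rng.integers(0, n_parents, size=n)
    pts = parents[assign] + rng.normal(0.0, model.cluster_sd_px, size=(n, 2))
    # clip to the disc by radial clamping (keeps cluster geometry intact)
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    over = d > radius * 0.999
    if over.any():
        shrink = (radius * 0.999) / d[over]
        pts[over] = center + (pts[over] - np.asarray(center)) * shrink[:, None]
    return pts


def _disc_polygon(center: tuple, radius: float, n_vertices: int = 48) -> Polygon:
    # circumscribed so every point within `radius` of the centre is covered
    rr = radius / np.cos(np.pi / n_vertices) * 1.001
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    coords = [(center[0] + rr * np.cos(t), center[1] + rr * np.sin(t)) for t in theta]
    coords.append(coords[0])
    return Polygon(coords)


# --- intensity finalization ----------------------------------------------

def finalize_intensities(cells: pd.DataFrame, intended_pos: dict, markers=NORMALIZED_MARKERS) -> pd.DataFrame:
    """Pin per-marker anchors so dataset-global min-max normalization is the
    identity on the latent scale, then convert latent values to raw counts.

    ``intended_pos[m]`` is the boolean intended-positivity vector aligned with
    ``cells``.  A marker with no intended-positive cell is emitted as uniform
    background (all zero -> degenerate -> normalized to 0: all negative).  A
    marker with positives but no QC-passing negative cell cannot survive
    fitted min-max normalization and raises.
    """
    out = cells.copy()
    qc = out["qc_pass"].to_numpy(dtype=bool)
    for m in markers:
        col = f"latent_{m}"
        v = out[col].to_numpy(dtype=float).copy()
        pos = np.asarray(intended_pos[m], dtype=bool)
        if not pos.any():
            v[:] = 0.0
        else:
            neg_qc = ~pos & qc
            pos_qc = pos & qc
            if not neg_qc.any() or not pos_qc.any():
                raise InfeasibleIntensityModel(
                    f"marker {m!r}: need at least one QC-passing negative and positive "
                    "cell to anchor global min-max normalization"
                )
            lo = np.flatnonzero(neg_qc)[np.argmin(v[neg_qc])]
            hi = np.flatnonzero(pos_qc)[np.argmax(v[pos_qc])]
            v[lo] = 0.0   # detector floor
            v[hi] = 15.0  # saturation
        out[raw_col(m)] = RAW_OFFSET[m] + RAW_SCALE[m] * v
        out.drop(columns=[col], inplace=True)
    return out


# --- core generation ------------------------------------------------------

def _class_positivity(classes: np.ndarray) -> dict:
    """Intended ER/PR/HER2/Ki67 positivity implied by 16-class labels."""
    g = (classes - 1) // 2 + 1
    return {
        "er": g >= 5,
        "pr": ((g - 1) // 2) % 2 == 1,
        "her2": (g - 1) % 2 == 1,
        "ki67": classes % 2 == 0,
    }


def generate_core(
    spec: CoreSpec,
    seed: int | None = None,
    thresholds: MarkerThresholds = MarkerThresholds(),
    finalize: bool = True,
) -> CoreBundle:
    """Generate one core: cells, metadata row, annotations and ground truth.

    Fully deterministic given ``seed``.  With ``finalize=True`` (standalone
    use) anchor pinning and raw conversion happen over this core alone;
    :func:`generate_tma` defers finalization to the whole bundle because
    normalization is dataset-global.
    """
    rng = np.random.default_rng(seed)
    R = spec.radius_px
    center = (R, R)

    n_cd8 = int(round(spec.immune.cd8_frac * spec.n_cells))
    n_cd20 = int(round(spec.immune.cd20_frac * spec.n_cells))
    n_benign = int(round(spec.benign_frac * spec.n_cells))
    n_other = int(round(spec.other_frac * spec.n_cells))
    n_cancer = spec.n_cells - n_cd8 - n_cd20 - n_benign - n_other
    if n_cancer <= 0:
        raise ValueError("n_cells too small for the requested non-cancer fractions")

    # cancer class labels: multinomial from the spec fractions
    fracs = spec.fraction_vector()
    counts = rng.multinomial(n_cancer, fracs)
    classes = np.repeat(np.arange(1, N_CLASSES + 1), counts)
    rng.shuffle(classes)

    # positions
    if isinstance(spec.spatial_model, ThomasClusterModel):
        if spec.cluster_by_class:
            xy_cancer = np.empty((n_cancer, 2))
            for c in np.unique(classes):
                mask = classes == c
                xy_cancer[mask] = _thomas_positions(
                    int(mask.sum()), spec.spatial_model, R, center, rng
                )
        else:
            xy_cancer = _thomas_positions(n_cancer, spec.spatial_model, R, center, rng)
    elif spec.spatial_model == "uniform_disc":
        xy_cancer = _uniform_disc(n_cancer, R, center, rng)
    else:
        raise ValueError(f"unknown spatial model {spec.spatial_model!r}")

    if spec.immune.pattern == "aggregated" and (n_cd8 + n_cd20) > 0:
        agg_model = ThomasClusterModel(parent_rate=3.0, cluster_sd_px=50.0)
        xy_cd8 = _thomas_positions(n_cd8, agg_model, R, center, rng) if n_cd8 else np.empty((0, 2))
        xy_cd20 = _thomas_positions(n_cd20, agg_model, R, center, rng) if n_cd20 else np.empty((0, 2))
    else:
        xy_cd8 = _uniform_disc(n_cd8, R, center, rng)
        xy_cd20 = _uniform_disc(n_cd20, R, center, rng)
    xy_other = _uniform_disc(n_other, R, center, rng)

    regions = []
    if n_benign > 0:
        duct_center = center + 0.55 * R * np.array([np.cos(a := rng.uniform(0, 2 * np.pi)), np.sin(a)])
        xy_benign = _uniform_disc(n_benign, 140.0, tuple(duct_center), rng)
        regions.append(Region("exclude_benign", _disc_polygon(tuple(duct_center), 150.0), core_id=spec.core_id))
    else:
        xy_benign = np.empty((0, 2))
    if spec.subtype == "TNBC":
        regions.append(Region("include_tumor", _disc_polygon(center, R), core_id=spec.core_id))

    population = np.array(
        ["cancer"] * n_cancer + ["CD8"] * n_cd8 + ["CD20"] * n_cd20
        + ["benign"] * n_benign + ["other"] * n_other, dtype=object
    )
    xy = np.vstack([xy_cancer, xy_cd8, xy_cd20, xy_benign, xy_other])
    n = len(population)
    is_cancer = population == "cancer"
    is_benign = population == "benign"

    # morphology: cancer and benign epithelium pass the size gate, lymphocytes
    # and stroma are smaller and fail on perimeter; a configured fraction of
    # cancer cells fails one randomly chosen size rule
    perim = np.where(is_cancer | is_benign,
                     95.0 + rng.gamma(3.0, 20.0, n), rng.uniform(40.0, 88.0, n))
    area = np.where(is_cancer | is_benign,
                    410.0 + rng.gamma(4.0, 80.0, n), 150.0 + rng.gamma(2.0, 50.0, n))
    nuc = np.where(is_cancer | is_benign,
                   12.0 + rng.gamma(3.0, 15.0, n), 4.0 + rng.gamma(2.0, 6.0, n))
    size_pass = is_cancer | is_benign
    fail_idx = np.flatnonzero(is_cancer)
    fail_idx = fail_idx[rng.random(len(fail_idx)) < spec.size_fail_frac]
    rule = rng.integers(0, 3, size=len(fail_idx))
    perim[fail_idx[rule == 0]] = rng.uniform(40.0, 90.0, int((rule == 0).sum()))
    area[fail_idx[rule == 1]] = rng.uniform(100.0, 400.0, int((rule == 1).sum()))
    nuc[fail_idx[rule == 2]] = rng.uniform(1.0, 10.0, int((rule == 2).sum()))
    size_pass[fail_idx] = False
    qc_pass = rng.random(n) >= spec.qc_fail_frac

    # intended positivity per marker
    cls_full = np.zeros(n, dtype=int)
    cls_full[is_cancer] = classes
    eph_pos = _class_positivity(classes)
    pos_fracs = dict(MARKER_POS_FRACS[spec.subtype])
    if spec.marker_pos_fracs:
        pos_fracs.update(spec.marker_pos_fracs)
    intended = {}
    for m in ("er", "pr", "her2", "ki67"):
        vec = np.zeros(n, dtype=bool)
        vec[is_cancer] = eph_pos[m]
        intended[m] = vec
    for m in ("p53", "p16", "p21"):
        vec = np.zeros(n, dtype=bool)
        vec[is_cancer] = rng.random(n_cancer) < pos_fracs[m]
        intended[m] = vec
    intended["cd8"] = population == "CD8"
    intended["cd20"] = population == "CD20"

    # latent intensities on the 0-15 scale
    models = {m: IntensityModel(threshold=getattr(thresholds, m)) for m in NORMALIZED_MARKERS}
    if spec.intensity_models:
        models.update(spec.intensity_models)
    latent = {}
    for m in NORMALIZED_MARKERS:
        hot = spec.p53_hot and m == "p53"
        latent[m] = models[m].draw(intended[m], rng, hot=hot)

    # raw PCK: epithelial (cancer in PCK-gated subtypes, benign ducts) above the
    # 1500-count gate; TNBC cancer cells express PCK weakly; stroma/lymphocytes low
    pck = rng.uniform(0.0, 800.0, n)
    epithelial = (is_cancer & (spec.subtype != "TNBC")) | is_benign
    pck[epithelial] = 1500.0 + rng.gamma(2.0, 400.0, int(epithelial.sum()))
    pck[is_cancer & (spec.subtype == "TNBC")] = rng.uniform(0.0, 300.0, int((is_cancer & (spec.subtype == "TNBC")).sum()))

    cells = pd.DataFrame(
        {
            "cell_id": [f"{spec.core_id}_c{i:05d}" for i in range(n)],
            "core_id": spec.core_id,
            "centroid_x": xy[:, 0],
            "centroid_y": xy[:, 1],
            "perimeter_px": perim,
            "cell_area_px": area,
            "nuclear_area_px": nuc,
            "qc_pass": qc_pass,
            raw_col("pck"): pck,
        }
    )
    for m in NORMALIZED_MARKERS:
        cells[f"latent_{m}"] = latent[m]

    # shuffle row order so population blocks don't leak through ordering
    order = rng.permutation(n)
    cells = cells.iloc[order].reset_index(drop=True)
    population = population[order]
    cls_full = cls_full[order]
    size_pass = size_pass[order]
    intended = {m: v[order] for m, v in intended.items()}

    meta = pd.DataFrame([{
        "core_id": spec.core_id,
        "case_id": spec.case_id,
        "pair_id": spec.pair_id,
        **IHC_TEMPLATES[spec.subtype],
        "subtype": spec.subtype,
    }])

    truth = {
        "core_id": spec.core_id,
        "subtype": spec.subtype,
        "n_cells": int(n),
        "n_cancer": int(n_cancer),
        "class_fractions_spec": {str(k): float(v) for k, v in spec.class_fractions.items()},
        "class_counts_realized": {str(c): int((classes == c).sum()) for c in np.unique(classes)},
        "population": population.tolist(),
        "eph_ki67_class": cls_full.tolist(),
        "size_pass": size_pass.tolist(),
        "qc_pass": cells["qc_pass"].tolist(),
        "cell_id": cells["cell_id"].tolist(),
        "intended_positivity": {m: v.tolist() for m, v in intended.items()},
    }

    if finalize:
        cells = finalize_intensities(cells, intended)
    return CoreBundle(cells=cells, metadata=meta, regions=RegionSet(regions), truth=truth)


@dataclass
class TMABundle:
    cells: pd.DataFrame
    metadata: pd.DataFrame
    regions: RegionSet
    manifest: dict

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_cell_table(self.cells, os.path.join(outdir, "cells.csv"))
        write_core_metadata(self.metadata, os.path.join(outdir, "cores.csv"))
        write_annotations(self.regions, os.path.join(outdir, "regions.geojson"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.manifest, fh)


def generate_tma(
    specs: Sequence[CoreSpec],
    seed: int | None = None,
    thresholds: MarkerThresholds = MarkerThresholds(),
) -> TMABundle:
    """Generate a full TMA bundle from per-core specs.

    Per-core generation uses child seeds spawned deterministically from
    ``seed``; intensity anchoring runs once over the concatenated dataset
    because min-max normalization is dataset-global.
    """
    rng = np.random.default_rng(seed)
    core_seeds = rng.integers(0, 2**31 - 1, size=len(specs))
    bundles = [
        generate_core(s, seed=int(cs), thresholds=thresholds, finalize=False)
        for s, cs in zip(specs, core_seeds)
    ]
    cells = pd.concat([b.cells for b in bundles], ignore_index=True)
    intended = {
        m: np.concatenate([np.asarray(b.truth["intended_positivity"][m], dtype=bool) for b in bundles])
        for m in NORMALIZED_MARKERS
    }
    cells = finalize_intensities(cells, intended)
    meta = pd.concat([b.metadata for b in bundles], ignore_index=True)
    regions = RegionSet([r for b in bundles for r in b.regions])
    manifest = {
        "seed": seed,
        "n_cores": len(specs),
        "cores": {b.truth["core_id"]: b.truth for b in bundles},
    }
    return TMABundle(cells=cells, metadata=meta, regions=regions, manifest=manifest)


# --- scenarios ------------------------------------------------------------

#: class-fraction templates per subtype (group-major, Ki67-minor class indices)
CLASS_TEMPLATES = {
    # LumA: ER moderate/strong, PR+ groups 7 and 3 prominent, low Ki67
    "LumA": {13: 0.38, 14: 0.04, 9: 0.20, 10: 0.03, 5: 0.16, 6: 0.02, 1: 0.14, 2: 0.03},
    # LumB: PR-negative groups 1 and 5, higher proliferative fraction
    "LumB": {9: 0.30, 10: 0.16, 1: 0.28, 2: 0.18, 5: 0.04, 13: 0.04},
    # LumB HER2+: groups 1 and 2 plus some PR+ HER2+/- (3, 4)
    "LumB_HER2pos": {1: 0.24, 2: 0.16, 3: 0.14, 4: 0.10, 5: 0.10, 6: 0.10, 7: 0.08, 8: 0.08},
    # HER2+ (non-luminal): groups 1 and 2 only
    "HER2": {1: 0.22, 2: 0.20, 3: 0.30, 4: 0.28},
    # TNBC: group 1 dominated, highest Ki67
    "TNBC": {1: 0.42, 2: 0.52, 5: 0.03, 6: 0.03},
}


def _jitter_fractions(fracs: dict, rng, concentration: float = 400.0) -> dict:
    keys = sorted(fracs)
    alpha = np.array([fracs[k] for k in keys]) * concentration
    sample = rng.dirichlet(alpha)
    return {k: float(v) for k, v in zip(keys, sample)}


def default_tma_specs(seed: int = 0, n_cells: int = 1200) -> list[CoreSpec]:
    """The default scenario: five subtypes, paired cores per case, one
    heterogeneous LumA pair, a P53-high TNBC stratum, immune-rich HER2+ cores
    (one aggregated, one scattered), a benign duct on one LumA core."""
    rng = np.random.default_rng(seed)
    plan = [("LumA", 3), ("LumB", 3), ("LumB_HER2pos", 1), ("HER2", 2), ("TNBC", 2)]
    specs: list[CoreSpec] = []
    case_no = 0
    for subtype, n_cases in plan:
        for i in range(n_cases):
            case_no += 1
            case_id = f"case_{case_no:03d}"
            base = _jitter_fractions(CLASS_TEMPLATES[subtype], rng)
            for side in ("a", "b"):
                fr = dict(base)
                if subtype == "LumA" and i == 0 and side == "b":
                    # one deliberately heterogeneous pair: shift mass 13 -> 1
                    fr = shift_fractions(fr, 13, 1, 0.30)
                else:
                    fr = _jitter_fractions(base, rng, concentration=2000.0)
                immune = ImmuneSpec()
                if subtype == "HER2":
                    immune = ImmuneSpec(
                        cd8_frac=0.07, cd20_frac=0.05,
                        pattern="aggregated" if i == 0 else "scattered",
                    )
                specs.append(
                    CoreSpec(
                        core_id=f"spot_{case_no:03d}{side}",
                        case_id=case_id,
                        pair_id=case_id,
                        subtype=subtype,
                        n_cells=n_cells,
                        class_fractions=fr,
                        spatial_model=(
                            ThomasClusterModel() if subtype in ("LumB_HER2pos",) else "uniform_disc"
                        ),
                        cluster_by_class=subtype == "LumB_HER2pos",
                        immune=immune,
                        benign_frac=0.04 if (subtype == "LumA" and i == 1 and side == "a") else 0.0,
                        p53_hot=subtype == "TNBC" and i == 0,
                    )
                )
    return specs


def null_pair_specs(
    subtype: str, fractions: dict, n_pairs: int, n_cells: int, id_prefix: str = "null"
) -> list[CoreSpec]:
    """Paired cores drawn from one multinomial — the null of the paired test."""
    specs = []
    for k in range(n_pairs):
        for side in ("a", "b"):
            specs.append(
                CoreSpec(
                    core_id=f"{id_prefix}_{k:04d}{side}",
                    case_id=f"{id_prefix}_case_{k:04d}",
                    pair_id=f"{id_prefix}_case_{k:04d}",
                    subtype=subtype,
                    n_cells=n_cells,
                    class_fractions=dict(fractions),
                )
            )
    return specs


def sample_class_vector(fractions: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n class labels (1..16) from a class-fraction map — the elementary
    sampling step used by the paired-test calibration simulations."""
    v = np.zeros(N_CLASSES)
    for k, f in fractions.items():
        v[int(k) - 1] = f
    counts = rng.multinomial(n, v / v.sum())
    out = np.repeat(np.arange(1, N_CLASSES + 1), counts)
    rng.shuffle(out)
    return out


def shift_fractions(fractions: dict, source: int, target: int, mass: float) -> dict:
    """Move absolute probability mass ``mass`` (capped at the source fraction)
    from the source class to the target class — the planted between-core effect."""
    fr = dict(fractions)
    moved = min(mass, fr.get(source, 0.0))
    fr[source] = fr.get(source, 0.0) - moved
    fr[target] = fr.get(target, 0.0) + moved
    return fr
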