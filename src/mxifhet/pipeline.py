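"""End-to-end orchestration: simulate -> preprocess -> classify -> spatial -> stats.

`run_all` is idempotent given the config and inputs; every stage logs its
in/out counts and the full configuration is serialized into a provenance
record next to the outputs.  No stage mutates a prior stage's outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import classify, preprocess, spatial, stats, synthetic
from .io import (
    DEFAULT_PIXEL_SIZE_UM,
    RegionSet,
    read_annotations,
    read_cell_table,
    read_core_metadata,
    um_to_px,
    write_core_summaries,
)

log = logging.getLogger("mxifhet")


@dataclass
class RunConfig:
    """One config for the whole pipeline.

    Either ``scenario`` (synthetic input, with ``n_cells`` per core) or the
    three input paths must be given.  Radii are configured in micrometres and
    converted with ``pixel_size_um``.
    """

    outdir: str = "mxifhet_out"
    scenario: str | None = None  # default | null_pairs | clustered
    cells_path: str | None = None
    meta_path: str | None = None
    annotations_path: str | None = None
    schema_config: dict | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 1200
    thresholds: classify.MarkerThresholds = field(default_factory=classify.MarkerThresholds)
    gating: preprocess.GatingConfig = field(default_factory=preprocess.GatingConfig)
    subtype_rules: classify.SubtypeRules = field(default_factory=classify.SubtypeRules)
    radii_um: tuple = (30.0, 100.0)
    diversity: spatial.DiversitySpec = field(default_factory=spatial.DiversitySpec)
    alpha: float = 0.01
    n_perm: int = 10_000
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "thresholds" in kw:
            kw["thresholds"] = classify.MarkerThresholds(**kw["thresholds"])
        if "gating" in kw:
            kw["gating"] = preprocess.GatingConfig(**kw["gating"])
        if "subtype_rules" in kw:
            kw["subtype_rules"] = classify.SubtypeRules(**kw["subtype_rules"])
        if "diversity" in kw:
            kw["diversity"] = spatial.DiversitySpec(**kw["diversity"])
        if "radii_um" in kw:
            kw["radii_um"] = tuple(kw["radii_um"])
        return cls(**kw)

    def to_provenance(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run (also written to ``outdir``)."""

    config: RunConfig
    all_cells: pd.DataFrame
    cancer_cells: pd.DataFrame
    rejects: pd.DataFrame
    norm_spec: preprocess.NormalizationSpec
    core_summaries: pd.DataFrame
    profiles: pd.DataFrame
    equitability_by_class: pd.DataFrame
    cumulative_profiles: dict
    immune_profiles: pd.DataFrame
    immune_densities: pd.DataFrame
    paired_screen: stats.PairedScreenResult
    subtype_tally: pd.DataFrame


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        if config.scenario == "default":
            specs = synthetic.default_tma_specs(seed=config.seed, n_cells=config.n_cells)
        elif config.scenario == "null_pairs":
            specs = synthetic.null_pair_specs(
                "LumB", synthetic.CLASS_TEMPLATES["LumB"], n_pairs=5, n_cells=config.n_cells
            )
        elif config.scenario == "clustered":
            specs = [
                dataclasses.replace(
                    s,
                    spatial_model=synthetic.ThomasClusterModel(),
                    cluster_by_class=True,
                )
                for s in synthetic.default_tma_specs(seed=config.seed, n_cells=config.n_cells)
            ]
        else:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        bundle = synthetic.generate_tma(specs, seed=config.seed, thresholds=config.thresholds)
        return bundle.cells, bundle.metadata, bundle.regions, bundle.manifest

    for name in ("cells_path", "meta_path"):
        path = getattr(config, name)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"{name} missing or does not exist: {path!r}")
    cells = read_cell_table(config.cells_path, schema_config=config.schema_config)
    meta = read_core_metadata(config.meta_path)
    if config.annotations_path:
        if not os.path.exists(config.annotations_path):
            raise FileNotFoundError(f"annotations_path does not exist: {config.annotations_path!r}")
        regions = read_annotations(config.annotations_path)
    else:
        regions = RegionSet()
    return cells, meta, regions, None


def run_all(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write every artifact under ``config.outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    cells, meta, regions, manifest = _load_inputs(config)
    log.info("loaded %d cells, %d cores", len(cells), len(meta))

    if "subtype" not in meta.columns or meta["subtype"].isna().any():
        meta = classify.assign_surrogate_subtype(meta, config.subtype_rules)

    # normalization is fitted once, on all QC-passing cells of the dataset
    cells, norm_spec = preprocess.normalize_markers(cells, spec=None)
    norm_spec.to_json(os.path.join(config.outdir, "normalization_spec.json"))

    cells = classify.call_positivity(cells, config.thresholds)
    all_cells = preprocess.select_all_cells_for_immune(cells)
    cancer = preprocess.select_cancer_population(cells, meta, regions, config.gating)
    _, rejects = preprocess.qc_and_size_gate(cells, config.gating)
    log.info("gates: %d QC-passing cells, %d cancer cells, %d size/QC rejects",
             len(all_cells), len(cancer), len(rejects))

    cancer = classify.assign_eph(cancer)
    all_cells = classify.label_populations(all_cells, cancer_index=cancer.index)

    summaries = classify.summarize_cores(cancer, all_cells, meta)

    radii_px = [um_to_px(r, config.pixel_size_um) for r in config.radii_um]
    profiles = pd.concat(
        [
            spatial.neighborhood_composition(
                cancer, class_scheme=config.diversity.class_scheme,
                radius_px=r, diversity=config.diversity,
            )
            for r in radii_px
        ],
        ignore_index=True,
    )
    eq_by_class = spatial.aggregate_equitability(profiles[profiles["radius_px"] == radii_px[0]])
    cumulative = {
        subtype: spatial.cumulative_neighborhood_profile(
            cancer[cancer["core_id"].isin(meta.loc[meta["subtype"] == subtype, "core_id"])],
            class_scheme=config.diversity.class_scheme,
            radius_px=radii_px[0],
        )
        for subtype in meta["subtype"].unique()
    }
    immune_r = um_to_px(100.0, config.pixel_size_um)
    immune_profiles = spatial.immune_neighborhood(all_cells, radius_px=immune_r)
    immune_densities = stats.immune_density(all_cells)

    screen = stats.run_paired_core_screen(
        cancer, meta, alpha=config.alpha, n_perm=config.n_perm, seed=config.seed
    )
    tally = screen.subtype_tally(meta) if screen.results else pd.DataFrame(
        columns=["subtype", "n_significant", "n_cases", "fraction_significant"]
    )

    # artifacts (written once per stage; later stages never touch them)
    cancer.to_csv(os.path.join(config.outdir, "classified_cancer_cells.csv"), index=False)
    rejects.to_csv(os.path.join(config.outdir, "rejected_cells.csv"), index=False)
    write_core_summaries(summaries, os.path.join(config.outdir, "core_summaries.csv"))
    profiles.to_csv(os.path.join(config.outdir, "neighborhood_profiles.csv"), index=False)
    eq_by_class.to_csv(os.path.join(config.outdir, "equitability_by_class.csv"), index=False)
    immune_profiles.to_csv(os.path.join(config.outdir, "immune_neighborhoods.csv"), index=False)
    immune_densities.to_csv(os.path.join(config.outdir, "immune_densities.csv"), index=False)
    screen.to_frame().to_csv(os.path.join(config.outdir, "paired_core_tests.csv"), index=False)
    tally.to_csv(os.path.join(config.outdir, "paired_core_tally.csv"), index=False)
    provenance = {"config": config.to_provenance(), "counts": {
        "cells_in": int(len(cells)), "qc_passing": int(len(all_cells)),
        "cancer_cells": int(len(cancer)), "rejected": int(len(rejects)),
        "paired_cases_tested": len(screen.results),
    }}
    if manifest is not None:
        with open(os.path.join(config.outdir, "truth.json"), "w") as fh:
            json.dump(manifest, fh)
    with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2)

    return PipelineResult(
        config=config,
        all_cells=all_cells,
        cancer_cells=cancer,
        rejects=rejects,
        norm_spec=norm_spec,
        core_summaries=summaries,
        profiles=profiles,
        equitability_by_class=eq_by_class,
        cumulative_profiles=cumulative,
        immune_profiles=immune_profiles,
        immune_densities=immune_densities,
        paired_screen=screen,
        subtype_tally=tally,
    )
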