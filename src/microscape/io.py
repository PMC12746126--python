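"""File I/O, configuration, and end-to-end pipeline orchestration.

Coordinates are micrometers with the image convention (origin top-left,
y increasing downward).  Tables are comma-separated UTF-8 CSV with headers;
polygons travel as GeoJSON (μm, CCW outer rings); gene sets as GMT.
Every pipeline run emits a manifest with input checksums, a config hash,
and per-stage row counts so identical reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, mapping as shapely_mapping, shape as shapely_shape

from . import __version__, cellstate, gating, regions, signatures, spatial
from .errors import StageError

logger = logging.getLogger("microscape")

MANDATORY_CELL_COLUMNS = ("cell_id", "x", "y")


def read_cell_table(path) -> pd.DataFrame:
    """Load and validate a single-cell feature table (CSV, μm coordinates)."""
    table = pd.read_csv(path)
    missing = [c for c in MANDATORY_CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing mandatory columns: {missing}")
    for coord in ("x", "y"):
        if not pd.api.types.is_numeric_dtype(table[coord]):
            raise ValueError(f"column {coord!r} must be numeric (μm)")
        if not np.all(np.isfinite(table[coord])):
            raise ValueError(f"column {coord!r} contains non-finite coordinates")
    dup = table["cell_id"][table["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_ids: {sorted(set(dup.astype(str)))[:10]}")
    marker_cols = [
        c
        for c in table.columns
        if c not in MANDATORY_CELL_COLUMNS and not c.startswith("true_")
    ]
    if not marker_cols:
        raise ValueError("cell table needs at least one marker column")
    return table


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_annotations(path) -> dict[str, Polygon]:
    """GeoJSON FeatureCollection -> {domain_id: Polygon} (coordinates in μm)."""
    with open(path) as fh:
        geo = json.load(fh)
    out: dict[str, Polygon] = {}
    for i, feature in enumerate(geo.get("features", [])):
        geom = shapely_shape(feature["geometry"])
        name = feature.get("properties", {}).get("domain_id", f"domain_{i}")
        if not isinstance(geom, Polygon):
            raise ValueError(f"annotation {name!r} is not a simple polygon")
        out[name] = geom
    return out


def write_polygons(polygons, path, ids=None) -> None:
    """Write polygons as a GeoJSON FeatureCollection with CCW outer rings."""
    features = []
    for i, poly in enumerate(polygons):
        poly = Polygon(poly.exterior.coords[::-1]) if not poly.exterior.is_ccw else poly
        name = ids[i] if ids is not None else f"polygon_{i}"
        features.append(
            {
                "type": "Feature",
                "properties": {"domain_id": name, "area_um2": poly.area},
                "geometry": shapely_mapping(poly),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# configuration and manifest


@dataclass
class PipelineConfig:
    """Paths and parameter blocks for an end-to-end run."""

    out_dir: str
    seed: int = 0
    cell_table: str | None = None  # omit to simulate a tissue
    gates: str | None = None
    rules: str | None = None
    annotations: str | None = None
    counts: str | None = None
    mr_metadata: str | None = None
    gene_sets: str | None = None
    simulate: Mapping = field(default_factory=dict)
    region_params: Mapping = field(default_factory=dict)
    spatial_params: Mapping = field(default_factory=dict)
    signature_params: Mapping = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in self.__dict__.items()
        }


def file_checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    input_checksums: dict
    stage_rows: dict
    started: str
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages in dependency order, writing outputs and a manifest.

    Stage order: load/simulate -> gate -> phenotype -> regions -> cell state
    -> spatial summaries -> signatures (when count inputs are given).  Any
    stage failure aborts with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    checksums = {}
    for attr in ("cell_table", "gates", "rules", "annotations", "counts",
                 "mr_metadata", "gene_sets"):
        path = getattr(config, attr)
        if path:
            checksums[attr] = file_checksum(path)
    stage_rows: dict[str, int] = {}

    # --- load or simulate -------------------------------------------------
    stage = "load"
    try:
        if config.cell_table:
            table = read_cell_table(config.cell_table)
            if not config.gates:
                raise ValueError("gates file is required with a supplied cell table")
            gates = None
        else:
            from . import synth

            stage = "simulate"
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            tissue_cfg = synth.default_tissue_config(**sim)
            table, truth = synth.generate_tissue(tissue_cfg)
            gates = truth.gates
            gates.to_yaml(out_dir / "gates.yaml")
        stage_rows[stage] = len(table)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- gating + phenotyping --------------------------------------------
    stage = "gating"
    try:
        if gates is None:
            gates = gating.GateConfig.from_yaml(config.gates)
        markers = [m for m in gates if m in table.columns]
        scaled = gating.scale_table(table, gates, markers)
        stage_rows[stage] = len(scaled)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "phenotype"
    try:
        rules = (
            gating.PhenotypeRuleTree.from_yaml(config.rules)
            if config.rules
            else gating.default_rule_tree()
        )
        flags = gating.positivity_frame(scaled)
        scaled["phenotype"] = gating.classify_cells(flags, rules)
        stage_rows[stage] = int(scaled["phenotype"].ne(gating.OTHER_LABEL).sum())
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- regions ----------------------------------------------------------
    stage = "regions"
    try:
        model = regions.RegionModel(**dict(config.region_params))
        xy = scaled[["x", "y"]].to_numpy()
        tumor_xy = xy[(scaled["phenotype"] == "Tumor").to_numpy()]
        vessel_xy = xy[(scaled["phenotype"] == "Endothelial").to_numpy()]
        debris = (
            scaled["true_debris"].to_numpy(dtype=bool)
            if "true_debris" in scaled.columns
            else None
        )
        polygons = regions.reconstruct_tumor_boundaries(tumor_xy, model)
        scaled["region"] = regions.assign_regions(
            xy, polygons, model, vessel_cells=vessel_xy, debris_flags=debris
        ).to_numpy()
        write_polygons(polygons, out_dir / "tumor_boundaries.geojson")
        if config.annotations:
            scaled["domain"] = regions.assign_domains(
                xy, read_annotations(config.annotations)
            ).to_numpy()
        elif "true_domain" in scaled.columns:
            scaled["domain"] = scaled["true_domain"]
        group_col = "domain" if "domain" in scaled.columns else "region"
        comp = regions.regional_composition(scaled["region"], scaled["phenotype"])
        comp.to_csv(out_dir / "regional_composition.csv")
        stage_rows[stage] = len(polygons)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- cell state -------------------------------------------------------
    stage = "cellstate"
    try:
        have_mpi = all(f"scaled_{m}" in scaled.columns for m in cellstate.MPI_MARKERS)
        if have_mpi:
            calls = cellstate.mpi_from_table(scaled)
            scaled["mpi"] = calls["mpi"]
            scaled["qcc"] = calls["qcc"]
            comp = cellstate.state_composition(calls, scaled[group_col])
            comp.to_csv(out_dir / "state_composition.csv", index=False)
            stage_rows[stage] = len(calls)
        else:
            stage_rows[stage] = 0
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- spatial summaries ------------------------------------------------
    stage = "spatial"
    try:
        params = dict(config.spatial_params)
        radius = float(params.get("radius", spatial.DEFAULT_RADIUS))
        tumor_mask = (scaled["phenotype"] == "Tumor").to_numpy()
        if tumor_mask.sum() > 0 and (~tumor_mask).sum() > 0:
            comp = spatial.neighborhood_composition(
                xy[tumor_mask], xy[~tumor_mask],
                scaled["phenotype"].to_numpy()[~tumor_mask], radius=radius,
            )
            comp.to_csv(out_dir / "tumor_neighborhood.csv")
        if tumor_mask.sum() >= spatial.KDE_MIN_CELLS:
            dmap = spatial.kde_map(
                xy[tumor_mask],
                grid_spacing=float(params.get("grid_spacing", 25.0)),
            )
            np.savetxt(out_dir / "tumor_kde.tsv", dmap.density, delimiter="\t")
            with open(out_dir / "tumor_kde.json", "w") as fh:
                json.dump(
                    {
                        "origin": dmap.origin,
                        "grid_spacing": dmap.grid_spacing,
                        "clip_value": dmap.clip_value,
                        "mask_value": dmap.mask_value,
                    },
                    fh,
                )
        stage_rows[stage] = int(tumor_mask.sum())
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- signatures -------------------------------------------------------
    if config.counts:
        stage = "signatures"
        try:
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            meta = pd.read_csv(config.mr_metadata, sep="\t", index_col=0)
            sets = signatures.read_gmt(config.gene_sets)
            params = dict(config.signature_params)
            normalized, size_factors = signatures.size_factor_normalize(counts)
            expr = signatures.log_transform(normalized)
            scores = signatures.ssgsea_matrix(
                expr, sets, alpha=float(params.get("alpha", signatures.DEFAULT_ALPHA))
            )
            scaled_scores = signatures.scale_scores(
                scores, method=params.get("scale", "minmax")
            )
            scores.to_csv(out_dir / "signature_scores.tsv", sep="\t")
            scaled_scores.to_csv(out_dir / "signature_scores_scaled.tsv", sep="\t")
            size_factors.to_csv(out_dir / "size_factors.tsv", sep="\t")
            if len(sets) >= 2 and "compartment" in meta.columns:
                names = list(sets)
                strata = meta.loc[scores.columns, "compartment"].to_numpy()
                corr = signatures.stratified_correlation(
                    scores.loc[names[0]], scores.loc[names[1]], strata
                )
                corr.to_csv(out_dir / "stratified_correlation.csv")
            stage_rows[stage] = scores.shape[1]
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    write_cell_table(scaled, out_dir / "cells_annotated.csv")
    manifest = RunManifest(
        version=__version__,
        config_hash=config_hash(config),
        seed=config.seed,
        input_checksums=checksums,
        stage_rows=stage_rows,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
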