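"""End-to-end orchestration: simulator -> segmentation -> scoring -> stats.

``run_screen`` turns a plate (simulated or rendered) into per-field PNLA
results, per-well aggregates, Z'-based plate QC, robust-Z normalisation and
hit calls, persisting every stage as CSV when an output directory is given.
``run_lmp_timecourse`` produces the compound x timepoint puncta-positivity
matrix and the early/late/none kinetic class per compound.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import organoid as organoid_mod
from . import pnla, punctatrack, screenstats, segment
from .config import RunConfig
from .synthcells import (COMPOUND, NEGATIVE_CONTROL, POSITIVE_CONTROL,
                         PlateSimulation, PlateSpec, TimeCourseSpec,
                         simulate_plate, simulate_timecourse)
from .types import FieldImage

logger = logging.getLogger(__name__)


def score_field(image: FieldImage, config: RunConfig,
                puncta_threshold: float | None = None) -> pnla.PnlaResult:
    """Segment one field and compute its PNLA readouts.

    ``puncta_threshold`` overrides the per-field automatic marker threshold;
    the plate workflow fixes it once per plate (below) the way a screening
    module runs with a single configured threshold.
    """
    nuclei = segment.find_round_objects(
        image.channels[config.nucleus_channel], *config.nucleus_diameter_px,
        roundness_min=config.roundness_min,
        pixel_size_um=image.pixel_size_um)
    rings = pnla.build_perinuclear_rings(nuclei, config.shrink_px,
                                         config.grow_px)
    marker = image.channels[config.marker_channel]
    puncta = segment.detect_puncta(
        marker, intensity_threshold=puncta_threshold,
        diameter_min_px=config.puncta_diameter_px[0],
        diameter_max_px=config.puncta_diameter_px[1],
        roundness_min=config.puncta_roundness_min,
        pixel_size_um=image.pixel_size_um)
    return pnla.pnla_score(puncta, rings, marker_image=marker,
                           membership=config.ring_membership)


def plate_puncta_threshold(sim: PlateSimulation, config: RunConfig) -> float:
    """One marker threshold for the whole plate: the median of the per-field
    automatic thresholds over the negative-control wells.

    Auto-thresholding every field separately injects a common-mode area
    shift into each field's puncta; fixing the threshold per plate mirrors
    how a screening module is configured once and keeps wells comparable.
    """
    thresholds = []
    for ws in sim.wells.values():
        if ws.role != NEGATIVE_CONTROL:
            continue
        for img, _ in ws.fields:
            marker = img.channels[config.marker_channel]
            med = float(np.median(marker))
            floor = med + 6.0 * 1.4826 * float(
                np.median(np.abs(marker - med)))
            from skimage.filters import threshold_otsu
            thresholds.append(max(float(threshold_otsu(marker, nbins=256)),
                                  floor))
    return float(np.median(thresholds))


@dataclass
class ScreenRunResult:
    field_table: pd.DataFrame
    well_table: pd.DataFrame
    plate_stats: screenstats.PlateStats
    screen: screenstats.ScreenResult
    hits: list
    config: RunConfig

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (("fields.csv", self.field_table),
                         ("wells.csv", self.well_table),
                         ("screen.csv", self.screen.to_frame().reset_index())):
            p = outdir / name
            df.assign(config_hash=self.config.config_hash).to_csv(
                p, index=False)
            written.append(p)
        ps = self.plate_stats
        qc = pd.DataFrame([{
            "mu_pos": ps.mu_pos, "sigma_pos": ps.sigma_pos,
            "mu_neg": ps.mu_neg, "sigma_neg": ps.sigma_neg,
            "z_factor": ps.z_factor, "included": ps.included,
            "in_qc_band": ps.in_qc_band,
            "config_hash": self.config.config_hash,
        }])
        p = outdir / "plate_qc.csv"
        qc.to_csv(p, index=False)
        written.append(p)
        p = outdir / "config.yaml"
        self.config.to_yaml(p)
        written.append(p)
        return written


def run_screen(plate: PlateSpec | PlateSimulation,
               config: RunConfig | None = None) -> ScreenRunResult:
    """Score a whole plate and call hits.

    Raises before any scoring if the layout lacks control wells.
    """
    config = config or RunConfig()
    if isinstance(plate, PlateSpec):
        spec = plate
    else:
        spec = plate.spec
    roles = list(spec.roles.values())
    for role in (NEGATIVE_CONTROL, POSITIVE_CONTROL):
        if roles.count(role) < 2:
            raise ValueError(f"plate layout lacks {role} wells")
    sim = simulate_plate(spec) if isinstance(plate, PlateSpec) else plate

    t0 = time.perf_counter()
    threshold = plate_puncta_threshold(sim, config)
    rows = []
    for well in sorted(sim.wells):
        ws = sim.wells[well]
        for i, (img, _truth) in enumerate(ws.fields):
            res = score_field(img, config, puncta_threshold=threshold)
            row = {"well": well, "field": i, "role": ws.role,
                   "compound": ws.compound or ""}
            row.update(res.to_dict())
            rows.append(row)
    field_table = pd.DataFrame(rows)

    well_table = (field_table
                  .groupby(["well", "role", "compound"], as_index=False)
                  .agg(pnla_px2=("pnla_px2", "mean"),
                       pnla_um2=("pnla_um2", "mean"),
                       n_cells=("n_cells", "sum"),
                       n_puncta_total=("n_puncta_total", "sum"),
                       n_puncta_in_rings=("n_puncta_in_rings", "sum"),
                       perinuclear_fraction=("perinuclear_fraction", "mean"))
                  .sort_values("well", ignore_index=True))

    pos = well_table.loc[well_table.role == POSITIVE_CONTROL, "pnla_px2"]
    neg = well_table.loc[well_table.role == NEGATIVE_CONTROL, "pnla_px2"]
    plate_stats = screenstats.PlateStats.from_controls(
        pos.values, neg.values, qc_band=config.qc_band)

    comp = well_table[well_table.role == COMPOUND]
    screen = screenstats.robust_z_scores(
        pd.Series(comp.pnla_px2.values, index=comp.compound.values),
        scale=config.mad_scale, hit_threshold=config.hit_threshold)
    hits = screenstats.call_hits(screen, config.hit_threshold)
    logger.info("run_screen: %d wells, %d fields, Z'=%.3f, %d hit(s), "
                "%.1f s (config %s)", len(sim.wells), len(field_table),
                plate_stats.z_factor, len(hits),
                time.perf_counter() - t0, config.config_hash)

    result = ScreenRunResult(field_table, well_table, plate_stats, screen,
                             hits, config)
    if config.output_dir:
        result.write(config.output_dir)
    return result


@dataclass
class LmpRunResult:
    matrix: pd.DataFrame                  # compounds x timepoints, % positive
    dead_matrix: pd.DataFrame             # compounds x timepoints, % dead
    classes: dict[str, str]               # compound -> early | late | none
    config: RunConfig

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (("lmp_matrix.csv", self.matrix),
                         ("dead_matrix.csv", self.dead_matrix)):
            p = outdir / name
            df.to_csv(p)
            written.append(p)
        p = outdir / "lmp_classes.csv"
        pd.Series(self.classes, name="class").rename_axis("compound") \
            .to_frame().to_csv(p)
        written.append(p)
        return written


def run_lmp_timecourse(series_by_compound: Mapping[str, TimeCourseSpec]
                       | Mapping[str, Sequence],
                       config: RunConfig | None = None) -> LmpRunResult:
    """Score LMP time courses and classify each compound's kinetics."""
    config = config or RunConfig()
    matrices: dict[str, pd.Series] = {}
    dead: dict[str, pd.Series] = {}
    classes: dict[str, str] = {}
    for compound, series in series_by_compound.items():
        if isinstance(series, TimeCourseSpec):
            ts = [t for t in series.timepoints_h]
            if max(ts) < config.lmp_split_h:
                raise ValueError(
                    f"time course for {compound} does not span "
                    f"{config.lmp_split_h} h; classification refused")
            series = simulate_timecourse(series)
        readouts = punctatrack.timecourse_readouts(
            series, min_puncta=config.min_puncta,
            max_radius_px=config.max_cell_radius_px,
            area_factor=config.dead_area_factor,
            intensity_factor=config.dead_intensity_factor)
        classes[compound] = punctatrack.classify_lmp_kinetics(
            readouts, split_h=config.lmp_split_h)
        matrices[compound] = pd.Series(
            {r.t_h: r.pct_puncta_positive for r in readouts})
        dead[compound] = pd.Series({r.t_h: r.pct_dead for r in readouts})
    matrix = pd.DataFrame(matrices).T.rename_axis("compound")
    dead_matrix = pd.DataFrame(dead).T.rename_axis("compound")
    result = LmpRunResult(matrix, dead_matrix, classes, config)
    if config.output_dir:
        result.write(config.output_dir)
    return result


def run_organoid_growth(manifest: pd.DataFrame,
                        config: RunConfig | None = None,
                        image_loader=None) -> pd.DataFrame:
    """Measure % area change for every manifest row.

    The manifest needs columns ``well, drug, concentration, path_d1,
    path_d3`` (paths to single-channel TIFFs), or preloaded arrays in
    ``image_d1``/``image_d3`` columns. ``image_loader`` overrides how paths
    are read (defaults to ``tifffile.imread``).
    """
    config = config or RunConfig()
    if image_loader is None:
        import tifffile
        image_loader = tifffile.imread
    records = []
    for _, row in manifest.iterrows():
        img1 = row["image_d1"] if "image_d1" in row else \
            image_loader(row["path_d1"])
        img3 = row["image_d3"] if "image_d3" in row else \
            image_loader(row["path_d3"])
        rec = organoid_mod.measure_growth(
            img1, img3, well=str(row.get("well", "")),
            drug=str(row.get("drug", "")),
            concentration=float(row.get("concentration", float("nan"))),
            bh_radius_px=config.bh_radius_px,
            dilate_px=config.organoid_dilate_px,
            min_area_px=config.organoid_min_area_px)
        records.append(rec.__dict__)
    df = pd.DataFrame(records)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.assign(config_hash=config.config_hash).to_csv(
            out / "organoid_growth.csv", index=False)
    return df
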