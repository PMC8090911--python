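"""Single-cell puncta classification over time courses.

Covers the three live-imaging readouts of the screen's secondary
characterisation: lysosomal membrane permeabilization (a cell is
galectin-puncta positive when it carries >= 3 puncta), cell death (small,
bright nuclei), and tandem-fluorescence autophagy flux (yellow
autophagosomes vs red autolysosomes, the GFP being quenched at acidic pH).
Puncta are attributed to cells by growing nucleus labels into disjoint
territories; each timepoint is scored independently (no tracking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from . import segment
from .synthcells import TimepointSimulation
from .types import FieldImage, LabelMask

MIN_PUNCTA_POSITIVE = 3
DEAD_AREA_FACTOR = 0.5
DEAD_INTENSITY_FACTOR = 1.5
MAX_CELL_RADIUS_PX = 40.0
FLUX_RATIO_THRESHOLD = 0.5
LMP_SPLIT_H = 12.0

YELLOW, RED, UNCLASSIFIABLE = "yellow", "red", "unclassifiable"


@dataclass
class CellAssignment:
    """Punctum -> cell attribution via grown nucleus territories."""

    territories: LabelMask
    assignments: dict[int, int]        # punctum label -> cell label
    unassigned: list[int]              # punctum labels outside any territory

    def counts_per_cell(self) -> dict[int, int]:
        counts = {int(lab): 0 for lab in self.territories.ids}
        for cell in self.assignments.values():
            counts[cell] += 1
        return counts


def assign_puncta_to_cells(puncta: LabelMask, nuclei: LabelMask,
                           max_radius_px: float = MAX_CELL_RADIUS_PX
                           ) -> CellAssignment:
    """Attribute each punctum to the territory containing its centroid."""
    if puncta.shape != nuclei.shape:
        raise ValueError("puncta and nuclei have different image geometry")
    territories = segment.grow_labels_without_touching(nuclei, max_radius_px)
    terr = territories.labels
    assignments: dict[int, int] = {}
    unassigned: list[int] = []
    for prop in measure.regionprops(puncta.labels):
        r = min(int(np.floor(prop.centroid[0] + 0.5)), terr.shape[0] - 1)
        c = min(int(np.floor(prop.centroid[1] + 0.5)), terr.shape[1] - 1)
        cell = int(terr[r, c])
        if cell > 0:
            assignments[int(prop.label)] = cell
        else:
            unassigned.append(int(prop.label))
    return CellAssignment(territories, assignments, unassigned)


def classify_lmp_positive(puncta_count: int,
                          min_puncta: int = MIN_PUNCTA_POSITIVE) -> bool:
    """Puncta-positive iff the cell carries ``min_puncta`` or more puncta."""
    if puncta_count < 0:
        raise ValueError("puncta_count must be >= 0")
    return puncta_count >= min_puncta


def detect_dead_cells(nucleus_image: np.ndarray, nuclei: LabelMask,
                      area_factor: float = DEAD_AREA_FACTOR,
                      intensity_factor: float = DEAD_INTENSITY_FACTOR
                      ) -> dict[int, bool]:
    """Flag nuclei that are both shrunken and brightly stained.

    Dead iff area < ``area_factor`` x field-median nucleus area AND mean
    intensity > ``intensity_factor`` x field-median mean intensity (the
    conjunction keeps merely-small or merely-bright nuclei alive).
    """
    if nuclei.n_labels == 0:
        raise ValueError("empty nucleus mask")
    props = measure.regionprops(nuclei.labels,
                                intensity_image=np.asarray(nucleus_image))
    areas = np.array([p.area for p in props], dtype=float)
    means = np.array([p.intensity_mean for p in props])
    med_area, med_int = np.median(areas), np.median(means)
    return {int(p.label): bool(a < area_factor * med_area
                               and m > intensity_factor * med_int)
            for p, a, m in zip(props, areas, means)}


@dataclass
class TimepointReadout:
    """Per-timepoint aggregates of one field/site."""

    t_h: float
    pct_puncta_positive: float         # among live cells
    pct_dead: float                    # among all detected cells
    n_cells: int
    yellow_count: float = float("nan")  # mean puncta per cell (flux assay)
    red_count: float = float("nan")


def _score_timepoint(t_h: float, image: FieldImage,
                     puncta_channel: str = "organelle",
                     min_puncta: int = MIN_PUNCTA_POSITIVE,
                     max_radius_px: float = MAX_CELL_RADIUS_PX,
                     area_factor: float = DEAD_AREA_FACTOR,
                     intensity_factor: float = DEAD_INTENSITY_FACTOR
                     ) -> TimepointReadout:
    nuc_img = image.channels["nucleus"]
    nuclei = segment.find_round_objects(
        nuc_img, *segment.NUCLEUS_DIAMETER_RANGE_PX,
        pixel_size_um=image.pixel_size_um)
    n_cells = nuclei.n_labels
    if n_cells == 0:
        return TimepointReadout(t_h, float("nan"), float("nan"), 0)
    dead = detect_dead_cells(nuc_img, nuclei, area_factor, intensity_factor)
    puncta = segment.detect_puncta(image.channels[puncta_channel],
                                   pixel_size_um=image.pixel_size_um)
    assignment = assign_puncta_to_cells(puncta, nuclei, max_radius_px)
    counts = assignment.counts_per_cell()
    live = [lab for lab in counts if not dead[lab]]
    n_dead = sum(dead.values())
    if live:
        pos = sum(classify_lmp_positive(counts[lab], min_puncta)
                  for lab in live)
        pct_pos = 100.0 * pos / len(live)
    else:
        pct_pos = float("nan")
    return TimepointReadout(t_h, pct_pos, 100.0 * n_dead / n_cells, n_cells)


def timecourse_readouts(series: Sequence[TimepointSimulation]
                        | Sequence[tuple[float, FieldImage]],
                        min_puncta: int = MIN_PUNCTA_POSITIVE,
                        max_radius_px: float = MAX_CELL_RADIUS_PX,
                        area_factor: float = DEAD_AREA_FACTOR,
                        intensity_factor: float = DEAD_INTENSITY_FACTOR
                        ) -> list[TimepointReadout]:
    """Score every timepoint of a series: % puncta-positive live cells and
    % dead cells (of all cells detected in the site)."""
    if len(series) == 0:
        raise ValueError("empty timepoint series")
    out = []
    for item in series:
        if isinstance(item, TimepointSimulation):
            t, img = item.t_h, item.image
        else:
            t, img = item
        out.append(_score_timepoint(t, img, min_puncta=min_puncta,
                                    max_radius_px=max_radius_px,
                                    area_factor=area_factor,
                                    intensity_factor=intensity_factor))
    return out


def classify_lmp_kinetics(readouts: Sequence[TimepointReadout],
                          min_rise_factor: float = 2.0,
                          min_abs_pct: float = 10.0,
                          split_h: float = LMP_SPLIT_H) -> str:
    """Classify a compound's LMP kinetics as ``early``/``late``/``none``.

    Puncta formation counts as "evident" once the % of puncta-positive live
    cells reaches max(``min_rise_factor`` x the first-timepoint baseline,
    ``min_abs_pct``). Onset strictly before ``split_h`` hours is early; at
    or after it is late; no onset is none. The series must span the split
    time.
    """
    ts = [r.t_h for r in readouts]
    if not ts or min(ts) >= split_h or max(ts) < split_h:
        raise ValueError(
            f"series must span {split_h} h to classify LMP kinetics")
    baseline = readouts[0].pct_puncta_positive
    if np.isnan(baseline):
        baseline = 0.0
    threshold = max(min_rise_factor * baseline, min_abs_pct)
    for r in sorted(readouts, key=lambda r: r.t_h):
        if not np.isnan(r.pct_puncta_positive) \
                and r.pct_puncta_positive >= threshold:
            return "early" if r.t_h < split_h else "late"
    return "none"


def classify_flux_puncta(gfp_image: np.ndarray, rfp_image: np.ndarray,
                         puncta: LabelMask,
                         ratio_threshold: float = FLUX_RATIO_THRESHOLD
                         ) -> dict[int, str]:
    """Classify tandem-fluorescence puncta as yellow (autophagosome) or red
    (autolysosome: GFP quenched, mean GFP / mean RFP below the threshold)."""
    gfp = np.asarray(gfp_image, dtype=float)
    rfp = np.asarray(rfp_image, dtype=float)
    if gfp.shape != rfp.shape or gfp.shape != puncta.shape:
        raise ValueError("channels and puncta must share geometry")
    out: dict[int, str] = {}
    for prop in measure.regionprops(puncta.labels):
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        mean_rfp = rfp[rr, cc].mean()
        if mean_rfp == 0.0:
            out[int(prop.label)] = UNCLASSIFIABLE
            continue
        ratio = gfp[rr, cc].mean() / mean_rfp
        out[int(prop.label)] = RED if ratio < ratio_threshold else YELLOW
    return out


def flux_counts_per_cell(classes: Mapping[int, str],
                         assignment: CellAssignment) -> tuple[float, float]:
    """Mean yellow and red puncta per cell for one field."""
    n_cells = assignment.territories.n_labels
    if n_cells == 0:
        return float("nan"), float("nan")
    yellow = sum(1 for lab, cls in classes.items()
                 if cls == YELLOW and lab in assignment.assignments)
    red = sum(1 for lab, cls in classes.items()
              if cls == RED and lab in assignment.assignments)
    return yellow / n_cells, red / n_cells


def readouts_to_frame(readouts_by_compound: Mapping[str,
                                                    Sequence[TimepointReadout]]
                      ) -> pd.DataFrame:
    """Long-format table (compound, t_h, pct_positive, pct_dead, ...)."""
    rows = []
    for compound, readouts in readouts_by_compound.items():
        for r in readouts:
            rows.append({"compound": compound, "t_h": r.t_h,
                         "pct_positive": r.pct_puncta_positive,
                         "pct_dead": r.pct_dead, "n_cells": r.n_cells,
                         "yellow": r.yellow_count, "red": r.red_count})
    return pd.DataFrame(rows)
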