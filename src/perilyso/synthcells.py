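"""Seeded synthetic-microscopy generator with full ground truth.

Emulates the image statistics the screening analysis assumes: Hoechst-like
nuclear disks, diffraction-limited organelle puncta whose radial placement
relative to the nucleus follows a tunable perinuclear bias, plate layouts
with DMSO-like negative and lapatinib-like positive control wells, drug-class
dependent puncta time courses with cell death, tandem-fluorescence (GFP/RFP)
puncta, and dark-on-bright transmitted-light organoid image pairs.

The perinuclear phenotype is modelled as *clustered* placement: perinuclear
puncta coalesce around a few per-cell cluster centres inside a band just
outside the nucleus, so that accumulation produces larger merged spots —
the physical basis of an area-based perinuclear accumulation readout.
Peripheral puncta are dispersed with a minimum spacing and stay resolvable.

All randomness flows from a single top-level seed through
:class:`numpy.random.SeedSequence` spawning (one child stream per well, then
per field), so identical specs give bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .types import DEFAULT_PIXEL_SIZE_UM, FieldImage

# Rendering constants (16-bit-friendly intensity units).
BACKGROUND_LEVEL = 100.0
NUCLEUS_AMPLITUDE = 900.0
PUNCTUM_AMPLITUDE = 600.0
DEAD_RADIUS_FACTOR = 0.5     # dead nuclei shrink to half radius
DEAD_INTENSITY_FACTOR = 2.0  # and stain twice as brightly

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
COMPOUND = "compound"


# ---------------------------------------------------------------------------
# specs and ground truth


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic two-channel field.

    ``perinuclear_bias`` is the probability that a punctum is placed in the
    perinuclear band (``perinuclear_band_px`` outside the nucleus boundary);
    the remainder go to a peripheral cytoplasm annulus. The default bias of
    0.1 represents the untreated, invasion-prone peripheral phenotype.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 8
    nucleus_radius_range: tuple[float, float] = (12.0, 16.0)
    puncta_per_cell_range: tuple[int, int] = (8, 16)
    perinuclear_bias: float = 0.1
    punctum_sigma_px: float = 1.2
    noise_sd: float = 8.0
    seed: int = 0
    # placement geometry (px outside the nucleus boundary)
    perinuclear_band_px: tuple[float, float] = (0.0, 23.0)
    peripheral_band_px: tuple[float, float] = (28.0, 63.0)
    min_punctum_spacing_px: float = 6.0
    clusters_per_cell: int = 2
    cluster_sigma_px: float = 2.5
    dead_fraction: float = 0.0
    #: keep nuclei this far from the image edge so their expanded
    #: territories are not removed as border objects downstream
    edge_clearance_px: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.perinuclear_bias <= 1.0:
            raise ValueError("perinuclear_bias must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_range[0] > self.nucleus_radius_range[1]:
            raise ValueError("invalid nucleus_radius_range")
        if self.puncta_per_cell_range[0] > self.puncta_per_cell_range[1]:
            raise ValueError("invalid puncta_per_cell_range")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Punctum:
    center: tuple[float, float]          # (row, col)
    area_px: float                       # nominal half-maximum area
    radial_class: str                    # "perinuclear" | "peripheral"
    cell_index: int


@dataclass
class GroundTruth:
    """Generator-side record of every rendered object."""

    nucleus_centers: np.ndarray          # (N, 2) float, (row, col)
    nucleus_radii: np.ndarray            # (N,)
    puncta: list[Punctum]
    dead_flags: np.ndarray               # (N,) bool

    @property
    def n_cells(self) -> int:
        return len(self.nucleus_radii)

    @property
    def n_puncta(self) -> int:
        return len(self.puncta)

    @property
    def puncta_centers(self) -> np.ndarray:
        if not self.puncta:
            return np.empty((0, 2))
        return np.array([p.center for p in self.puncta])

    @property
    def perinuclear_fraction(self) -> float:
        if not self.puncta:
            return float("nan")
        k = sum(p.radial_class == "perinuclear" for p in self.puncta)
        return k / len(self.puncta)

    def puncta_per_cell(self) -> np.ndarray:
        counts = np.zeros(self.n_cells, dtype=int)
        for p in self.puncta:
            counts[p.cell_index] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"object_id": i + 1, "type": "nucleus", "x": c[1], "y": c[0],
             "area_px": math.pi * r**2, "class": "dead" if d else "live"}
            for i, (c, r, d) in enumerate(
                zip(self.nucleus_centers, self.nucleus_radii, self.dead_flags))
        ]
        rows += [
            {"object_id": self.n_cells + j + 1, "type": "punctum",
             "x": p.center[1], "y": p.center[0], "area_px": p.area_px,
             "class": p.radial_class}
            for j, p in enumerate(self.puncta)
        ]
        return pd.DataFrame(rows, columns=["object_id", "type", "x", "y",
                                           "area_px", "class"])


# ---------------------------------------------------------------------------
# field rendering


def _place_nuclei(spec: FieldSpec, rng: np.random.Generator,
                  max_retries: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centres and radii."""
    h, w = spec.image_shape
    centers: list[np.ndarray] = []
    radii: list[float] = []
    gap = 6.0  # clearance so nuclei are separable round objects
    margin = 1.0 + spec.edge_clearance_px
    for _ in range(spec.n_cells):
        r = rng.uniform(*spec.nucleus_radius_range)
        if h - 2 * (r + margin) <= 0 or w - 2 * (r + margin) <= 0:
            raise RuntimeError(
                f"image {h}x{w} too small for nuclei of radius {r:.0f} px "
                f"with {spec.edge_clearance_px:.0f} px edge clearance")
        for attempt in range(max_retries):
            c = np.array([rng.uniform(r + margin, h - r - margin),
                          rng.uniform(r + margin, w - r - margin)])
            if all(np.hypot(*(c - c0)) > r + r0 + gap
                   for c0, r0 in zip(centers, radii)):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping nuclei of "
                f"radius ~{r:.0f} px in a {h}x{w} field after {max_retries} "
                "retries per cell; reduce n_cells or the nucleus radius")
    if centers:
        return np.array(centers), np.array(radii)
    return np.empty((0, 2)), np.empty(0)


def _render_disks(shape: tuple[int, int], centers: np.ndarray,
                  radii: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    img = np.zeros(shape)
    for (cr, cc), r, a in zip(centers, radii, amplitudes):
        r0, r1 = int(max(0, cr - r - 2)), int(min(shape[0], cr + r + 3))
        c0, c1 = int(max(0, cc - r - 2)), int(min(shape[1], cc + r + 3))
        yy, xx = np.ogrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1][np.hypot(yy - cr, xx - cc) <= r] = a
    return img


def _render_spots(shape: tuple[int, int], centers: np.ndarray,
                  sigma: float, amplitudes: np.ndarray) -> np.ndarray:
    img = np.zeros(shape)
    ext = int(math.ceil(4 * sigma))
    for (cr, cc), a in zip(centers, amplitudes):
        r0, r1 = int(max(0, cr - ext)), int(min(shape[0], cr + ext + 1))
        c0, c1 = int(max(0, cc - ext)), int(min(shape[1], cc + ext + 1))
        yy, xx = np.ogrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += a * np.exp(
            -((yy - cr) ** 2 + (xx - cc) ** 2) / (2 * sigma**2))
    return img


def _clip_to_interior(p: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return np.clip(p, 1.0, np.array(shape, dtype=float) - 2.0)


def _place_puncta_for_cell(spec: FieldSpec, rng: np.random.Generator,
                           center: np.ndarray, radius: float, count: int,
                           cell_index: int,
                           placed_peripheral: list[np.ndarray]
                           ) -> list[Punctum]:
    h, w = spec.image_shape
    b0, b1 = spec.perinuclear_band_px
    p0, p1 = spec.peripheral_band_px
    # per-cell cluster centres in the perinuclear band (accumulation sites)
    n_clu = max(1, spec.clusters_per_cell)
    ang = rng.uniform(0, 2 * math.pi, n_clu)
    rad = radius + rng.uniform(b0 + 3.0, max(b0 + 3.0, b1 - 3.0), n_clu)
    clusters = center + np.stack([rad * np.sin(ang), rad * np.cos(ang)], 1)

    half_max_r = spec.punctum_sigma_px * math.sqrt(2 * math.log(2))
    area = math.pi * half_max_r**2

    puncta: list[Punctum] = []
    for _ in range(count):
        if rng.random() < spec.perinuclear_bias:
            k = rng.integers(n_clu)
            pos = clusters[k] + rng.normal(0.0, spec.cluster_sigma_px, 2)
            # clamp radially into the band so the class stays consistent
            d = np.hypot(*(pos - center))
            lo, hi = radius + b0 + 0.25, radius + b1 - 0.25
            if d < 1e-9:
                pos = center + np.array([lo, 0.0])
            elif not lo <= d <= hi:
                pos = center + (pos - center) * (np.clip(d, lo, hi) / d)
            pos = _clip_to_interior(pos, (h, w))
        else:
            # resample (not clip) so the radial distance, and with it the
            # ground-truth class, is never silently altered at image edges
            for _ in range(200):
                a = rng.uniform(0, 2 * math.pi)
                d = radius + rng.uniform(p0, p1)
                pos = center + d * np.array([math.sin(a), math.cos(a)])
                in_bounds = (1 <= pos[0] <= h - 2) and (1 <= pos[1] <= w - 2)
                if in_bounds and all(
                        np.hypot(*(pos - q)) >= spec.min_punctum_spacing_px
                        for q in placed_peripheral):
                    break
            pos = _clip_to_interior(pos, (h, w))
            placed_peripheral.append(pos)
        dist_out = np.hypot(*(pos - center)) - radius
        cls = "perinuclear" if b0 <= dist_out <= b1 else "peripheral"
        puncta.append(Punctum((float(pos[0]), float(pos[1])), area, cls,
                              cell_index))
    return puncta


def render_cell_field(
    spec: FieldSpec,
    rng: np.random.Generator | None = None,
    puncta_counts: Sequence[int] | None = None,
    dead_flags: Sequence[bool] | None = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field (``nucleus`` + ``organelle``).

    ``puncta_counts`` and ``dead_flags`` override the per-cell draws (used by
    the time-course simulator); otherwise counts are uniform in
    ``puncta_per_cell_range`` and death is Bernoulli(``dead_fraction``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    centers, radii = _place_nuclei(spec, rng)

    if dead_flags is None:
        dead = rng.random(spec.n_cells) < spec.dead_fraction
    else:
        dead = np.asarray(dead_flags, dtype=bool)

    if puncta_counts is None:
        lo, hi = spec.puncta_per_cell_range
        counts = rng.integers(lo, hi + 1, spec.n_cells)
    else:
        counts = np.asarray(puncta_counts, dtype=int)

    puncta: list[Punctum] = []
    peripheral_positions: list[np.ndarray] = []  # field-wide spacing
    for i in range(spec.n_cells):
        puncta += _place_puncta_for_cell(spec, rng, centers[i], radii[i],
                                         int(counts[i]), i,
                                         peripheral_positions)

    eff_radii = np.where(dead, radii * DEAD_RADIUS_FACTOR, radii)
    amps = np.where(dead, NUCLEUS_AMPLITUDE * DEAD_INTENSITY_FACTOR,
                    NUCLEUS_AMPLITUDE)
    nuc = _render_disks((h, w), centers, eff_radii, amps)
    nuc = ndi.gaussian_filter(nuc, 1.0)
    nuc += BACKGROUND_LEVEL
    if spec.noise_sd > 0:
        nuc += rng.normal(0.0, spec.noise_sd, (h, w))

    org = _render_spots((h, w), np.array([p.center for p in puncta]).reshape(-1, 2),
                        spec.punctum_sigma_px,
                        np.full(len(puncta), PUNCTUM_AMPLITUDE))
    org += BACKGROUND_LEVEL
    if spec.noise_sd > 0:
        org += rng.normal(0.0, spec.noise_sd, (h, w))

    image = FieldImage({"nucleus": np.clip(nuc, 0, 65535),
                        "organelle": np.clip(org, 0, 65535)},
                       pixel_size_um=spec.pixel_size_um)
    truth = GroundTruth(centers, radii, puncta, dead)
    return image, truth


def render_flux_field(
    spec: FieldSpec,
    red_fraction: float,
    quench_factor: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[FieldImage, GroundTruth, np.ndarray]:
    """Render a tandem-fluorescence (mRFP-GFP) reporter field.

    Every punctum carries full RFP signal; in acidified (``red``) puncta the
    GFP amplitude is quenched by ``quench_factor``. Returns the field with
    ``gfp``/``rfp``/``nucleus`` channels, the ground truth and the boolean
    red flags per punctum.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    image, truth = render_cell_field(spec, rng=rng)
    h, w = spec.image_shape
    centers = truth.puncta_centers
    red = rng.random(truth.n_puncta) < red_fraction
    rfp_amp = np.full(truth.n_puncta, PUNCTUM_AMPLITUDE)
    gfp_amp = np.where(red, PUNCTUM_AMPLITUDE * quench_factor,
                       PUNCTUM_AMPLITUDE)
    chans = {}
    for name, amps in (("gfp", gfp_amp), ("rfp", rfp_amp)):
        img = _render_spots((h, w), centers, spec.punctum_sigma_px, amps)
        img += BACKGROUND_LEVEL
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, (h, w))
        chans[name] = np.clip(img, 0, 65535)
    chans["nucleus"] = image.channels["nucleus"]
    return (FieldImage(chans, pixel_size_um=spec.pixel_size_um), truth, red)


# ---------------------------------------------------------------------------
# plates


@dataclass(frozen=True)
class PlateSpec:
    """Layout and effect sizes of one simulated screening plate.

    ``roles`` maps well ids to ``negative_control`` / ``positive_control`` /
    ``compound``; compound wells take their perinuclear bias from
    ``effect_map`` via ``compounds`` (well -> compound id; defaults to the
    well id). Control biases mimic DMSO (peripheral) and lapatinib
    (perinuclear) phenotypes.
    """

    roles: Mapping[str, str]
    compounds: Mapping[str, str] | None = None
    effect_map: Mapping[str, float] | None = None
    negative_bias: float = 0.1
    positive_bias: float = 0.9
    fields_per_well: int = 4
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    n_rows: int | None = None
    n_cols: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {NEGATIVE_CONTROL, POSITIVE_CONTROL, COMPOUND}
        for well, role in self.roles.items():
            if role not in valid:
                raise ValueError(f"unknown role {role!r} for well {well}")
        for role in (NEGATIVE_CONTROL, POSITIVE_CONTROL):
            n = sum(r == role for r in self.roles.values())
            if n < 2:
                raise ValueError(f"need >=2 wells with role {role}, got {n}")
        if self.n_rows is not None and self.n_cols is not None:
            if len(self.roles) != self.n_rows * self.n_cols:
                raise ValueError(
                    "role map does not cover the full plate geometry "
                    f"({len(self.roles)} wells for a "
                    f"{self.n_rows}x{self.n_cols} plate)")
        if self.effect_map:
            for cid, b in self.effect_map.items():
                if not 0.0 <= b <= 1.0:
                    raise ValueError(f"effect_map bias for {cid} not in [0,1]")

    def compound_id(self, well: str) -> str:
        if self.compounds and well in self.compounds:
            return self.compounds[well]
        return well

    def bias_for(self, well: str) -> float:
        role = self.roles[well]
        if role == NEGATIVE_CONTROL:
            return self.negative_bias
        if role == POSITIVE_CONTROL:
            return self.positive_bias
        cid = self.compound_id(well)
        if self.effect_map and cid in self.effect_map:
            return self.effect_map[cid]
        return self.negative_bias


@dataclass
class WellSimulation:
    well: str
    role: str
    compound: str | None
    bias: float
    fields: list[tuple[FieldImage, GroundTruth]]


@dataclass
class PlateSimulation:
    spec: PlateSpec
    wells: dict[str, WellSimulation]


def _well_names(n_rows: int, n_cols: int) -> list[str]:
    return [f"{chr(ord('A') + r)}{c + 1:02d}"
            for r in range(n_rows) for c in range(n_cols)]


def make_screen_plate(
    n_compounds: int,
    active_compounds: Mapping[str, float] | None = None,
    n_control_wells: int = 2,
    fields_per_well: int = 4,
    field_spec: FieldSpec | None = None,
    seed: int = 0,
) -> PlateSpec:
    """Convenience layout: controls first, then ``C001``.. compound wells.

    ``active_compounds`` maps compound ids (``C001`` style) to planted
    perinuclear biases; the rest stay at the negative-control bias.
    """
    n_wells = n_compounds + 2 * n_control_wells
    n_cols = 12
    n_rows = math.ceil(n_wells / n_cols)
    names = _well_names(n_rows, n_cols)[:n_wells]
    roles: dict[str, str] = {}
    compounds: dict[str, str] = {}
    for i, wname in enumerate(names):
        if i < n_control_wells:
            roles[wname] = NEGATIVE_CONTROL
        elif i < 2 * n_control_wells:
            roles[wname] = POSITIVE_CONTROL
        else:
            roles[wname] = COMPOUND
            compounds[wname] = f"C{i - 2 * n_control_wells + 1:03d}"
    return PlateSpec(roles=roles, compounds=compounds,
                     effect_map=dict(active_compounds or {}),
                     fields_per_well=fields_per_well,
                     field_spec=field_spec or FieldSpec(), seed=seed)


def simulate_plate(spec: PlateSpec) -> PlateSimulation:
    """Render every field of every well with well/field bookkeeping."""
    ss = np.random.SeedSequence(spec.seed)
    wells: dict[str, WellSimulation] = {}
    well_streams = ss.spawn(len(spec.roles))
    for wss, well in zip(well_streams, sorted(spec.roles)):
        role = spec.roles[well]
        bias = spec.bias_for(well)
        fspec = replace(spec.field_spec, perinuclear_bias=bias)
        fields = []
        for i, fss in enumerate(wss.spawn(spec.fields_per_well)):
            img, truth = render_cell_field(fspec,
                                           rng=np.random.default_rng(fss))
            img.well, img.field = well, i
            fields.append((img, truth))
        comp = spec.compound_id(well) if role == COMPOUND else None
        wells[well] = WellSimulation(well, role, comp, bias, fields)
    return PlateSimulation(spec, wells)


# ---------------------------------------------------------------------------
# time courses


#: Logistic puncta-rate profiles per drug class: expected puncta per cell as
#: a function of time. "early" LMP becomes evident before 12 h, "late" after.
_PROFILE_T50_H = {"early_LMP": 6.0, "late_LMP": 20.0}


@dataclass(frozen=True)
class TimeCourseSpec:
    """Drug-class dependent puncta/death kinetics for live imaging."""

    timepoints_h: tuple[float, ...] = tuple(float(t) for t in range(0, 49, 2))
    puncta_class: str = "none"           # early_LMP | late_LMP | none
    baseline_rate: float = 0.4           # puncta per cell at t=0
    max_rate: float = 6.0                # plateau puncta per cell
    rise_width_h: float = 2.0
    death_final_fraction: float = 0.1    # linear ramp 0 -> final
    field_spec: FieldSpec = field(default_factory=lambda: FieldSpec(
        image_shape=(320, 320), n_cells=20, puncta_per_cell_range=(0, 0)))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints_h) == 0:
            raise ValueError("timepoints_h must not be empty")
        if self.puncta_class not in ("early_LMP", "late_LMP", "none"):
            raise ValueError(f"unknown puncta class {self.puncta_class!r}")
        if self.baseline_rate < 0 or self.max_rate < self.baseline_rate:
            raise ValueError("rates must satisfy 0 <= baseline <= max")
        if not 0.0 <= self.death_final_fraction <= 1.0:
            raise ValueError("death_final_fraction must lie in [0, 1]")
        if list(self.timepoints_h) != sorted(self.timepoints_h):
            raise ValueError("timepoints_h must be increasing")

    def rate_at(self, t_h: float) -> float:
        """Expected puncta per cell at time ``t_h`` (monotone for LMP)."""
        if self.puncta_class == "none":
            return self.baseline_rate
        t50 = _PROFILE_T50_H[self.puncta_class]
        s = 1.0 / (1.0 + math.exp(-(t_h - t50) / self.rise_width_h))
        return self.baseline_rate + (self.max_rate - self.baseline_rate) * s

    def death_at(self, t_h: float) -> float:
        t_max = max(self.timepoints_h)
        if t_max == 0:
            return self.death_final_fraction
        return self.death_final_fraction * (t_h / t_max)


@dataclass
class TimepointSimulation:
    t_h: float
    image: FieldImage
    truth: GroundTruth


def simulate_timecourse(spec: TimeCourseSpec) -> list[TimepointSimulation]:
    """Render one field per timepoint; timepoints are independent (the
    analysis scores each timepoint on its own, without tracking)."""
    ss = np.random.SeedSequence(spec.seed)
    out = []
    for tss, t in zip(ss.spawn(len(spec.timepoints_h)), spec.timepoints_h):
        rng = np.random.default_rng(tss)
        n = spec.field_spec.n_cells
        counts = rng.poisson(spec.rate_at(t), n)
        dead = rng.random(n) < spec.death_at(t)
        img, truth = render_cell_field(spec.field_spec, rng=rng,
                                       puncta_counts=counts, dead_flags=dead)
        out.append(TimepointSimulation(float(t), img, truth))
    return out


# ---------------------------------------------------------------------------
# organoids


@dataclass(frozen=True)
class OrganoidSpec:
    """A dark organoid on a bright transmitted-light background, imaged at
    day 1 and day 3 with ``area_d3 = growth_factor * area_d1`` and optional
    thin invasive protrusions at day 3."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.7
    area_d1_px: float = 7000.0
    growth_factor: float = 1.5
    n_protrusions: int = 0
    protrusion_length_px: float = 40.0
    protrusion_width_px: float = 7.0
    background_level: float = 3000.0
    organoid_level: float = 1800.0
    noise_sd: float = 0.0
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_factor < 0:
            raise ValueError("growth_factor must be >= 0")
        if self.organoid_level >= self.background_level:
            raise ValueError("organoid must be darker than the background")
        r3 = math.sqrt(self.area_d1_px * max(self.growth_factor, 1.0) / math.pi)
        reach = r3 + (self.protrusion_length_px if self.n_protrusions else 0)
        if 2 * (reach + 5) > min(self.image_shape):
            raise ValueError("organoid does not fit in the image")


@dataclass
class OrganoidTruth:
    mask_d1: np.ndarray
    mask_d3: np.ndarray
    mask_d3_core: np.ndarray   # day-3 body without protrusions

    @property
    def area_d1_px(self) -> int:
        return int(self.mask_d1.sum())

    @property
    def area_d3_px(self) -> int:
        return int(self.mask_d3.sum())


def _organoid_mask(spec: OrganoidSpec, radius: float,
                   protrusions: bool, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(yy - cr, xx - cc) <= radius
    if protrusions and spec.n_protrusions > 0:
        for k in range(spec.n_protrusions):
            ang = 2 * math.pi * k / spec.n_protrusions + rng.uniform(-0.1, 0.1)
            u = np.array([math.sin(ang), math.cos(ang)])
            base = np.array([cr, cc]) + (radius - 1.0) * u
            tip = base + spec.protrusion_length_px * u
            # pixels within half-width of the segment base->tip
            pv = np.stack([yy - base[0], xx - base[1]], axis=-1).astype(float)
            seg = tip - base
            t = np.clip((pv @ seg) / (seg @ seg), 0.0, 1.0)
            dist = np.hypot(pv[..., 0] - t * seg[0], pv[..., 1] - t * seg[1])
            mask |= dist <= spec.protrusion_width_px / 2.0
    return mask


def render_organoid_pair(
    spec: OrganoidSpec,
) -> tuple[FieldImage, FieldImage, OrganoidTruth]:
    """Render the day-1 / day-3 transmitted-light image pair plus truth."""
    rng = np.random.default_rng(spec.seed)
    r1 = math.sqrt(spec.area_d1_px / math.pi)
    r3 = r1 * math.sqrt(spec.growth_factor)
    m1 = _organoid_mask(spec, r1, protrusions=False, rng=rng)
    m3_core = _organoid_mask(spec, r3, protrusions=False, rng=rng)
    m3 = _organoid_mask(spec, r3, protrusions=True, rng=rng)
    imgs = []
    for m in (m1, m3):
        img = np.full(spec.image_shape, spec.background_level)
        img[m] = spec.organoid_level
        if spec.smooth_sigma > 0:
            img = ndi.gaussian_filter(img, spec.smooth_sigma)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, spec.image_shape)
        imgs.append(FieldImage({"transmitted": img},
                               pixel_size_um=spec.pixel_size_um))
    return imgs[0], imgs[1], OrganoidTruth(m1, m3, m3_core)


# ---------------------------------------------------------------------------
# on-disk output (16-bit TIFF + CSV sidecar + YAML spec)


def write_field(image: FieldImage, truth: GroundTruth | None,
                outdir: str | Path, basename: str,
                spec: FieldSpec | None = None) -> list[Path]:
    """Write per-channel 16-bit TIFFs, a ground-truth CSV sidecar and the
    generating spec as YAML. Returns the written paths."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, ch in image.channels.items():
        p = outdir / f"{basename}_{name}.tif"
        tifffile.imwrite(p, np.clip(ch, 0, 65535).astype(np.uint16),
                         resolution=(1e4 / image.pixel_size_um,
                                     1e4 / image.pixel_size_um))
        written.append(p)
    if truth is not None:
        p = outdir / f"{basename}_truth.csv"
        df = truth.to_dataframe()
        df.insert(1, "well", image.well)
        df.insert(2, "field", image.field)
        df.to_csv(p, index=False)
        written.append(p)
    if spec is not None:
        p = outdir / f"{basename}_spec.yaml"
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in spec.__dict__.items()}
        p.write_text(yaml.safe_dump(d, sort_keys=True))
        written.append(p)
    return written
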