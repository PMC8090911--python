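"""Plate quality control, robust normalisation and hit calling.

* ``z_factor``: Z'-factor ``1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|`` between
  positive and negative control wells (sample standard deviations, ddof=1).
* ``plate_qc``: plates are included iff Z' > 0; an annotation records
  whether Z' falls in the (0, 0.5) band recommended for complex phenotypic
  assays.
* ``robust_z_scores``: ``(x_i - median(X_all)) / MAD(X_all)``. The default
  uses the raw MAD exactly as the formula reads; ``scale="normal"`` applies
  the 1.4826 consistency factor so that the MAD estimates the standard
  deviation of Gaussian data (the convention of the HTS robust-Z
  literature, and the workflow default for hit calling).
* ``call_hits``: a compound is a hit iff its robust Z is >= the threshold
  (default 2, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: MAD scale factor making it a consistent estimator of sigma for normals.
MAD_NORMAL_CONSISTENCY = 1.4826

QC_BAND = (0.0, 0.5)
HIT_THRESHOLD_DEFAULT = 2.0


def z_factor(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Z'-factor of a plate from its positive/negative control readouts."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >=2 values per control arm")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("control means are equal: Z' separation undefined")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1))
                 / abs(mu_p - mu_n))


@dataclass
class PlateStats:
    """Control summaries and QC verdict for one plate."""

    mu_pos: float
    sigma_pos: float
    mu_neg: float
    sigma_neg: float
    z_factor: float
    included: bool
    in_qc_band: bool
    qc_band: tuple[float, float] = QC_BAND
    plate_id: str | None = None

    @classmethod
    def from_controls(cls, pos_values: Sequence[float],
                      neg_values: Sequence[float],
                      plate_id: str | None = None,
                      qc_band: tuple[float, float] = QC_BAND) -> "PlateStats":
        pos = np.asarray(pos_values, dtype=float)
        neg = np.asarray(neg_values, dtype=float)
        z = z_factor(pos, neg)
        included, in_band = plate_qc(z, qc_band)
        return cls(float(pos.mean()), float(pos.std(ddof=1)),
                   float(neg.mean()), float(neg.std(ddof=1)),
                   z, included, in_band, qc_band, plate_id)


def plate_qc(z: float,
             qc_band: tuple[float, float] = QC_BAND) -> tuple[bool, bool]:
    """(included, in_band): include iff Z' > 0; annotate the (0, 0.5) band."""
    included = z > 0.0
    in_band = qc_band[0] < z < qc_band[1]
    return included, in_band


@dataclass
class ScreenResult:
    """Per-compound robust Z scores and hit flags."""

    scores: pd.Series                 # index: compound id
    median: float
    mad: float
    scale: str
    hit_threshold: float = HIT_THRESHOLD_DEFAULT

    @property
    def hits(self) -> list:
        return call_hits(self, self.hit_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "robust_z": self.scores,
            "hit": self.scores >= self.hit_threshold,
        }).rename_axis("compound")


def robust_z_scores(values_by_compound: Mapping | pd.Series,
                    scale: str = "raw",
                    hit_threshold: float = HIT_THRESHOLD_DEFAULT
                    ) -> ScreenResult:
    """Robust Z normalisation of per-compound readouts.

    ``scale="raw"`` divides by the plain MAD as the printed formula does;
    ``scale="normal"`` multiplies the MAD by 1.4826 first.
    """
    s = pd.Series(values_by_compound, dtype=float)
    if s.size < 3:
        raise ValueError("need >=3 compound values for robust normalisation")
    if scale not in ("raw", "normal"):
        raise ValueError(f"unknown MAD scale {scale!r}")
    med = float(np.median(s.values))
    mad = float(np.median(np.abs(s.values - med)))
    if mad == 0.0:
        raise ValueError("degenerate dispersion: MAD of the readouts is 0")
    if scale == "normal":
        mad *= MAD_NORMAL_CONSISTENCY
    return ScreenResult((s - med) / mad, med, mad, scale, hit_threshold)


def call_hits(result: ScreenResult | pd.Series,
              threshold: float = HIT_THRESHOLD_DEFAULT) -> list:
    """Compounds with robust Z at or above the threshold (inclusive)."""
    scores = result.scores if isinstance(result, ScreenResult) else result
    return list(scores.index[scores >= threshold])


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


def compare_two_conditions(a_values: Sequence[float],
                           b_values: Sequence[float],
                           equal_var: bool = False) -> TTestResult:
    """Two-sample t-test (Welch by default; ``equal_var=True`` pools)."""
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 values per arm")
    if a.std() == 0.0 and b.std() == 0.0:
        if np.array_equal(np.sort(a), np.sort(b)) or a.mean() == b.mean():
            return TTestResult(0.0, 1.0)
        raise ValueError("degenerate input: both arms have zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue))


def plot_screen_scores(result: ScreenResult,
                       control_scores: Mapping[str, Iterable[float]]
                       | None = None,
                       threshold: float | None = None,
                       ax=None):
    """Dot plot of robust Z scores: compounds black, controls grey, with a
    red line at the hit threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    thr = result.hit_threshold if threshold is None else threshold
    x = np.arange(result.scores.size)
    ax.scatter(x, result.scores.values, s=12, c="black", label="compounds")
    offset = result.scores.size
    if control_scores:
        shades = {"negative_control": "0.7", "positive_control": "0.4"}
        for role, vals in control_scores.items():
            vals = np.asarray(list(vals), dtype=float)
            xs = offset + np.arange(vals.size)
            ax.scatter(xs, vals, s=12, c=shades.get(role, "0.5"), label=role)
            offset += vals.size
    ax.axhline(thr, color="red", lw=1)
    ax.set_xlabel("well")
    ax.set_ylabel("robust Z")
    ax.legend(frameon=False, fontsize=8)
    return ax
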