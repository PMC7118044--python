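"""In-vitro densitometry.

Tritium-standards calibration of autoradiograms to specific-binding density
(pmol/mg, total minus nonspecific), and fixed-threshold percent-positive-area
quantification of DAB immunohistochemistry sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError

__all__ = [
    "StandardsCurve",
    "SectionQuant",
    "calibrate_standards",
    "quantify_autoradiogram",
    "ihc_percent_area",
]

#: DAB positivity convention: a pixel is positive when at or darker than the
#: threshold on the 8-bit grey scale
IHC_THRESHOLD_DEFAULT = 170


@dataclass(frozen=True)
class StandardsCurve:
    """Monotone piecewise-linear map from grey intensity to activity (kBq/mg)."""

    grey: np.ndarray
    activity: np.ndarray

    def __call__(self, grey_values) -> np.ndarray:
        return np.interp(np.asarray(grey_values, dtype=float), self.grey, self.activity)

    def inverse(self, activity_values) -> np.ndarray:
        return np.interp(np.asarray(activity_values, dtype=float), self.activity, self.grey)

    def in_range(self, grey_values) -> np.ndarray:
        g = np.asarray(grey_values, dtype=float)
        return (g >= self.grey[0]) & (g <= self.grey[-1])


def calibrate_standards(points) -> StandardsCurve:
    """Fit the tritium-standards calibration.

    ``points`` is an iterable of (grey intensity, known activity kBq/mg)
    pairs, at least three, strictly monotone in both coordinates; the
    calibration is their piecewise-linear interpolant. Queries outside the
    calibrated grey range are clamped to the end values (flag with
    :meth:`StandardsCurve.in_range`).
    """
    pts = sorted((float(g), float(a)) for g, a in points)
    if len(pts) < 3:
        raise ConfigurationError("need at least 3 standards points")
    grey = np.array([g for g, _ in pts])
    act = np.array([a for _, a in pts])
    if np.any(np.diff(grey) <= 0) or np.any(np.diff(act) <= 0):
        raise ConfigurationError("standards must be strictly monotone")
    return StandardsCurve(grey, act)


@dataclass
class SectionQuant:
    region: str
    tb_pmol_mg: float
    nb_pmol_mg: float
    specific_pmol_mg: float
    n_replicates: int


def _roi_masks(rois: np.ndarray, roi_names: dict[int, str] | None):
    rois = np.asarray(rois)
    labels = [int(v) for v in np.unique(rois) if v != 0]
    names = roi_names or {}
    return [(names.get(lab, str(lab)), rois == lab) for lab in labels]


def quantify_autoradiogram(
    tb_images,
    nb_images,
    rois: np.ndarray,
    curve: StandardsCurve,
    molar_activity: float,
    roi_names: dict[int, str] | None = None,
) -> list[SectionQuant]:
    """Specific binding density per ROI from TB and NB autoradiograms.

    ``tb_images`` / ``nb_images`` are single sections or replicate lists
    (triplicate in the study design) calibrated with the same standards.
    The ROI-mean grey maps through the standards curve to activity (kBq/mg)
    and through the decay-corrected molar activity (GBq/umol) to density:
    pmol/mg = (kBq/mg) / (GBq/umol). Specific = TB - NB, averaged over
    replicates.
    """
    if molar_activity <= 0:
        raise ConfigurationError("molar activity must be positive")
    tb_list = tb_images if isinstance(tb_images, (list, tuple)) else [tb_images]
    nb_list = nb_images if isinstance(nb_images, (list, tuple)) else [nb_images]
    if len(tb_list) != len(nb_list):
        raise ConfigurationError("need matching TB/NB replicate counts")
    for img in (*tb_list, *nb_list):
        if np.asarray(img).shape != np.asarray(rois).shape:
            raise ConfigurationError("ROI mask does not match the image grid")

    out = []
    for name, mask in _roi_masks(rois, roi_names):
        tb_vals, nb_vals = [], []
        for tb, nb in zip(tb_list, nb_list):
            tb_act = float(curve(np.asarray(tb, dtype=float)[mask].mean()))
            nb_act = float(curve(np.asarray(nb, dtype=float)[mask].mean()))
            tb_vals.append(tb_act / molar_activity)
            nb_vals.append(nb_act / molar_activity)
        tb_d = float(np.mean(tb_vals))
        nb_d = float(np.mean(nb_vals))
        out.append(SectionQuant(name, tb_d, nb_d, tb_d - nb_d, len(tb_list)))
    return out


def ihc_percent_area(
    img_8bit: np.ndarray,
    roi: np.ndarray,
    threshold: int = IHC_THRESHOLD_DEFAULT,
) -> float:
    """Percent of ROI pixels at or below the positivity threshold.

    ``img_8bit`` is an 8-bit grayscale DAB section; darker pixels (grey value
    <= threshold, default 170 of 255) count as immunopositive. ``roi`` is a
    boolean mask; replicate sections are averaged by the caller.
    """
    img = np.asarray(img_8bit)
    roi = np.asarray(roi, dtype=bool)
    if img.shape != roi.shape:
        raise ConfigurationError("ROI mask does not match the image")
    n = int(roi.sum())
    if n == 0:
        raise ConfigurationError("empty ROI")
    return 100.0 * float(np.count_nonzero(img[roi] <= threshold)) / n


def quantify_sections_table(quants: list[SectionQuant]) -> pd.DataFrame:
    """Tidy table of per-ROI autoradiography results."""
    return pd.DataFrame([q.__dict__ for q in quants])
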