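"""Standardized radiomic feature extraction.

Per VOI this package computes exactly 480 radiomic features — 50 intensity,
22 morphology and 408 texture — plus the 5 standard PET metrics (SUVmean,
SUVpeak, SUVmax, tumor volume in mL, and total lesion uptake = SUVmean x
volume).  Feature names are stable and listed in :data:`FEATURE_NAMES`;
:func:`feature_dictionary` maps every name to its family and aggregation
tag.  Degenerate values (e.g. moments of a constant VOI) are emitted as 0
and recorded in a flags mapping rather than dropped, keeping feature tables
rectangular.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..delineation import suv_peak
from ..volume import PETVolume, VOI
from .discretize import DEFAULT_BIN_WIDTH_SUV, DiscretizedVOI, discretize
from .intensity import INTENSITY_FEATURE_NAMES, intensity_features
from .morphology import MORPHOLOGY_FEATURE_NAMES, morphology_features
from .texture import TEXTURE_FEATURE_NAMES, texture_features

__all__ = [
    "StandardPETMetrics",
    "standard_pet_metrics",
    "extract_features",
    "extract_feature_table",
    "feature_dictionary",
    "discretize",
    "DiscretizedVOI",
    "FEATURE_NAMES",
    "STANDARD_METRIC_NAMES",
]

logger = logging.getLogger(__name__)

#: the 480 radiomic feature names in deterministic column order
FEATURE_NAMES: list[str] = (
    list(INTENSITY_FEATURE_NAMES)
    + list(MORPHOLOGY_FEATURE_NAMES)
    + list(TEXTURE_FEATURE_NAMES)
)

STANDARD_METRIC_NAMES = ["suv_mean", "suv_peak", "suv_max", "volume_ml", "total_lesion_uptake"]

assert len(FEATURE_NAMES) == 480, len(FEATURE_NAMES)


@dataclass
class StandardPETMetrics:
    """The five routine PET uptake metrics of a lesion."""

    suv_mean: float
    suv_peak: float
    suv_max: float
    volume_ml: float
    total_lesion_uptake: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STANDARD_METRIC_NAMES}


def standard_pet_metrics(volume: PETVolume, voi: VOI) -> StandardPETMetrics:
    """SUVmean/peak/max, voxel-count volume (mL) and total lesion uptake."""
    x = voi.values_in(volume)
    peak, _ = suv_peak(volume, voi.mask)
    vol_ml = voi.volume_ml
    mean = float(x.mean())
    return StandardPETMetrics(
        suv_mean=mean,
        suv_peak=peak,
        suv_max=float(x.max()),
        volume_ml=vol_ml,
        total_lesion_uptake=mean * vol_ml,
    )


def _crop_to_voi(volume: PETVolume, voi: VOI) -> tuple[PETVolume, VOI]:
    """Crop both grids to the VOI bounding box plus the peak-sphere radius.

    Keeps SUV-peak sphere means identical to the full-grid computation while
    making texture and peak searches independent of the scene size.
    """
    idx = np.argwhere(voi.mask)
    pad = [int(np.ceil(6.3 / s)) + 1 for s in volume.spacing_mm]
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, voi.mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    cropped_vol = PETVolume(
        volume.values[sl], volume.spacing_mm, unit=volume.unit,
        injected_dose_MBq=volume.injected_dose_MBq,
        body_weight_kg=volume.body_weight_kg,
    )
    cropped_voi = VOI(
        voi.mask[sl], voi.spacing_mm,
        threshold_fraction=voi.threshold_fraction, pvc=voi.pvc,
        peak_suv=voi.peak_suv, background_suv=voi.background_suv,
        label=voi.label,
    )
    return cropped_vol, cropped_voi


def extract_features(
    volume: PETVolume,
    voi: VOI,
    bin_width: float = DEFAULT_BIN_WIDTH_SUV,
) -> tuple[pd.Series, dict]:
    """Extract the full 480-feature vector plus standard metrics for one VOI.

    Returns ``(series, flags)`` where ``series`` holds the 480 radiomic
    features followed by the 5 standard metrics, and ``flags`` records any
    degenerate-value substitutions.
    """
    flags: dict = {}
    volume, voi = _crop_to_voi(volume, voi)
    disc = discretize(volume.values, voi.mask, bin_width)
    out: dict[str, float] = {}
    out.update(
        intensity_features(
            volume, voi, disc.voi_levels(), disc.n_levels, flags=flags
        )
    )
    out.update(
        morphology_features(voi.mask, voi.spacing_mm, volume.values, flags=flags)
    )
    out.update(texture_features(disc.levels, disc.mask))
    out.update(standard_pet_metrics(volume, voi).as_dict())
    series = pd.Series(out, dtype=float)[FEATURE_NAMES + STANDARD_METRIC_NAMES]
    bad = series.index[~np.isfinite(series.to_numpy())].tolist()
    if bad:
        flags["nonfinite"] = bad
        series[bad] = 0.0
    return series, flags


def extract_feature_table(
    subjects: dict[str, tuple[PETVolume, VOI]],
    bin_width: float = DEFAULT_BIN_WIDTH_SUV,
) -> pd.DataFrame:
    """One row per subject: 480 radiomic + 5 standard columns + provenance.

    ``subjects`` maps subject id to its (volume, VOI) pair for one chosen
    (threshold fraction, PVC) configuration.  Subjects whose extraction
    fails are dropped with a logged warning.
    """
    rows = {}
    provenance = {}
    for sid, (vol, voi) in subjects.items():
        try:
            series, _ = extract_features(vol, voi, bin_width)
        except Exception as exc:  # degenerate lesions: drop, keep going
            logger.warning("dropping subject %s: %s", sid, exc)
            continue
        rows[sid] = series
        provenance[sid] = {
            "threshold_fraction": voi.threshold_fraction,
            "pvc": voi.pvc,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    prov = pd.DataFrame.from_dict(provenance, orient="index")
    return pd.concat([table, prov], axis=1)


def feature_dictionary() -> dict[str, dict[str, str]]:
    """Map feature name -> {family, aggregation} for all 485 columns."""
    d = {}
    for name in INTENSITY_FEATURE_NAMES:
        d[name] = {"family": "intensity", "aggregation": "3d"}
    for name in MORPHOLOGY_FEATURE_NAMES:
        d[name] = {"family": "morphology", "aggregation": "3d"}
    for name in TEXTURE_FEATURE_NAMES:
        agg = name.rsplit("_", 2)
        tag = name.split("_")[-1]
        if name.endswith(("2d_avg", "2d_mrg", "25d_avg", "25d_mrg", "3d_avg", "3d_mrg")):
            tag = "_".join(name.rsplit("_", 2)[1:])
        d[name] = {"family": "texture", "aggregation": tag}
    for name in STANDARD_METRIC_NAMES:
        d[name] = {"family": "standard_pet", "aggregation": "3d"}
    return d


def save_feature_dictionary(path: str | Path) -> None:
    Path(path).write_text(json.dumps(feature_dictionary(), indent=2))
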