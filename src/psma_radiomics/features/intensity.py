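"""Intensity features: statistics, peaks, histogram, intensity-volume histogram.

50 features in four groups:

* 18 intensity-based statistics on the continuous SUVs of the VOI;
* 2 peak intensities (local: 1-mL sphere mean at the hottest voxel;
  global: maximum 1-mL sphere mean over the VOI);
* 23 intensity-histogram features on the discretized gray levels;
* 7 intensity-volume-histogram (IVH) features on continuous intensities,
  using the intensity fraction gamma(x) = (x - min) / (max - min) and the
  volume fraction nu(f) = fraction of VOI voxels with gamma >= f.

Features that are undefined on degenerate VOIs (zero variance, max = min)
are emitted as 0 and recorded in the ``flags`` mapping.
"""

from __future__ import annotations

import numpy as np

from ..delineation import sphere_means, suv_peak
from ..volume import PETVolume, VOI

__all__ = ["intensity_features", "INTENSITY_FEATURE_NAMES"]


def _moments(x: np.ndarray) -> dict[str, float]:
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    skew = float(((x - mean) ** 3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float(((x - mean) ** 4).mean() / sd**4 - 3.0) if sd > 0 else 0.0
    return {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt}


def _distribution_stats(x: np.ndarray, prefix: str) -> dict[str, float]:
    m = _moments(x)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sd = np.sqrt(m["variance"])
    mean = m["mean"]
    inner = x[(x >= p10) & (x <= p90)]
    stats = {
        "mean": mean,
        "variance": m["variance"],
        "skewness": m["skewness"],
        "kurtosis": m["kurtosis"],
        "median": float(p50),
        "min": float(x.min()),
        "p10": float(p10),
        "p90": float(p90),
        "max": float(x.max()),
        "iqr": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mad": float(np.abs(x - mean).mean()),
        "rmad": float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0,
        "medad": float(np.abs(x - p50).mean()),
        "cov": float(sd / mean) if mean != 0 else 0.0,
        "qcod": float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0,
        "energy": float((x**2).sum()),
        "rms": float(np.sqrt((x**2).mean())),
    }
    return {f"{prefix}_{k}": v for k, v in stats.items()}


def _histogram_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    x = levels.astype(float)
    out = _distribution_stats(x, "ih")
    # histogram-specific features replace energy/rms with entropy/uniformity etc.
    del out["ih_energy"], out["ih_rms"]
    counts = np.bincount(levels, minlength=n_levels + 1)[1:].astype(float)
    p = counts / counts.sum()
    nz = p > 0
    out["ih_mode"] = float(np.argmax(counts) + 1)  # ties -> lowest level
    out["ih_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["ih_uniformity"] = float((p**2).sum())
    # histogram gradient (one-sided at the ends)
    if n_levels > 1:
        grad = np.empty(n_levels)
        grad[0] = counts[1] - counts[0]
        grad[-1] = counts[-1] - counts[-2]
        if n_levels > 2:
            grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
        out["ih_max_gradient"] = float(grad.max())
        out["ih_max_gradient_level"] = float(np.argmax(grad) + 1)
        out["ih_min_gradient"] = float(grad.min())
        out["ih_min_gradient_level"] = float(np.argmin(grad) + 1)
    else:
        out["ih_max_gradient"] = 0.0
        out["ih_max_gradient_level"] = 1.0
        out["ih_min_gradient"] = 0.0
        out["ih_min_gradient_level"] = 1.0
    return out


def _ivh_features(x: np.ndarray, flags: dict) -> dict[str, float]:
    vmin, vmax = float(x.min()), float(x.max())
    if vmax == vmin:
        flags["ivh"] = "undefined: constant VOI"
        return {
            "ivh_v10": 0.0, "ivh_v90": 0.0, "ivh_v10_minus_v90": 0.0,
            "ivh_i10": 0.0, "ivh_i90": 0.0, "ivh_i10_minus_i90": 0.0,
            "ivh_auc": 0.0,
        }
    gamma = (x - vmin) / (vmax - vmin)

    def nu(f: float) -> float:
        return float((gamma >= f).mean())

    # intensity at volume fraction f: intensity of the rank-ceil(f*n) hottest voxel
    sorted_desc = np.sort(x)[::-1]
    n = x.size

    def intensity_at(f: float) -> float:
        k = max(1, int(np.ceil(f * n)))
        return float(sorted_desc[k - 1])

    v10, v90 = nu(0.10), nu(0.90)
    i10, i90 = intensity_at(0.10), intensity_at(0.90)
    return {
        "ivh_v10": v10,
        "ivh_v90": v90,
        "ivh_v10_minus_v90": v10 - v90,
        "ivh_i10": i10,
        "ivh_i90": i90,
        "ivh_i10_minus_i90": i10 - i90,
        "ivh_auc": float(gamma.mean()),  # exact integral of nu(f) over [0, 1]
    }


def intensity_features(
    volume: PETVolume, voi: VOI, disc_levels: np.ndarray | None = None,
    n_levels: int | None = None, flags: dict | None = None,
) -> dict[str, float]:
    """All 50 intensity features of a VOI.

    ``disc_levels``/``n_levels`` supply the discretized gray levels for the
    intensity-histogram group (computed on the fly with the default 0.25 SUV
    bin width when omitted).
    """
    flags = flags if flags is not None else {}
    x = voi.values_in(volume)
    out = _distribution_stats(x, "stat")
    if np.sqrt(out["stat_variance"]) == 0:
        flags["stat"] = "undefined moments: constant VOI (set to 0)"

    # peak intensities: sphere means over the full grid, restricted to the VOI
    means = sphere_means(volume)
    hottest = np.where(voi.mask, volume.values, -np.inf)
    center = np.unravel_index(int(np.argmax(hottest)), volume.shape)
    out["peak_local"] = float(means[center])
    out["peak_global"], _ = suv_peak(volume, voi.mask)

    if disc_levels is None:
        from .discretize import discretize

        d = discretize(volume.values, voi.mask)
        disc_levels, n_levels = d.voi_levels(), d.n_levels
    out.update(_histogram_features(np.asarray(disc_levels), int(n_levels)))
    out.update(_ivh_features(x, flags))
    return {name: out[name] for name in INTENSITY_FEATURE_NAMES}


INTENSITY_FEATURE_NAMES = (
    [f"stat_{k}" for k in [
        "mean", "variance", "skewness", "kurtosis", "median", "min", "p10",
        "p90", "max", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
        "energy", "rms"]]
    + ["peak_local", "peak_global"]
    + [f"ih_{k}" for k in [
        "mean", "variance", "skewness", "kurtosis", "median", "min", "p10",
        "p90", "max", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod",
        "mode", "entropy", "uniformity", "max_gradient", "max_gradient_level",
        "min_gradient", "min_gradient_level"]]
    + ["ivh_v10", "ivh_v90", "ivh_v10_minus_v90", "ivh_i10", "ivh_i90",
       "ivh_i10_minus_i90", "ivh_auc"]
)
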