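"""First-order intensity statistics of the in-mask voxels.

Eighteen features. Entropy and Uniformity are computed on the fixed-bin-width
discretised histogram; all others on the raw in-mask intensities.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_FEATURE_NAMES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)


def firstorder_features(values: np.ndarray, levels: np.ndarray, voxel_volume_mm3: float) -> dict:
    """First-order features from raw in-mask ``values`` and discrete ``levels``.

    ``levels`` are the positive in-mask bin indices from
    :func:`~thyropet.radiomics.preprocess.discretise`.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty mask")
    counts = np.bincount(np.asarray(levels, dtype=np.int64))[1:]
    p = counts[counts > 0] / x.size

    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m = x - mean
        skew = (m**3).mean() / var**1.5
        kurt = (m**4).mean() / var**2  # Pearson kurtosis (normal -> 3)
    else:
        skew, kurt = 0.0, 0.0
    energy = float((x**2).sum())
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": float(kurt),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(median),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "TotalEnergy": float(voxel_volume_mm3 * energy),
        "Uniformity": float((p**2).sum()),
        "Variance": float(var),
    }
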