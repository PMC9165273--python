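"""3-D texture matrices and their standardised features.

All matrices are computed on the fixed-bin-width discretised level array
(positive integers inside the mask, 0 outside):

* GLCM — grey level co-occurrence, distance 1, the 13 unique 3-D directions,
  symmetric; the 24 features are averaged over directions.
* GLRLM — grey level run length along the same 13 directions, averaged.
* GLSZM — grey level size zone, 26-connected zones.
* GLDM — grey level dependence, 26-neighbourhood, dependence tolerance
  alpha = 0; the dependence size counts the centre voxel (sizes start at 1).
* NGTDM — neighbouring grey tone difference, 26-neighbourhood.

Feature definitions follow the IBSI/pyradiomics catalogue; degenerate inputs
(single grey level, single voxel) take the documented convention values
rather than silently becoming zero.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).eps

#: the 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13 = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)

_OFFSETS_26 = tuple(d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0))

GLCM_FEATURE_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURE_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURE_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM_FEATURE_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_FEATURE_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _shifted_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Aligned views (a, b) with b displaced by +d from a."""
    sl_a, sl_b = [], []
    for axis, step in enumerate(d):
        n = levels.shape[axis]
        if step == 0:
            sl_a.append(slice(0, n))
            sl_b.append(slice(0, n))
        elif step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        else:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, direction: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (levels 1..n_levels)."""
    a, b = _shifted_pairs(levels, direction)
    valid = (a > 0) & (b > 0)
    av, bv = a[valid] - 1, b[valid] - 1
    mat = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(mat, (av, bv), 1.0)
    return mat + mat.T


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (px * i).sum()
    mu_y = (py * i).sum()
    sd_x = np.sqrt((px * (i - mu_x) ** 2).sum())
    sd_y = np.sqrt((py * (i - mu_y) ** 2).sum())

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxpy = np.outer(px, py)
    m = pxpy > 0
    hxy1 = float(-(p[m] * np.log2(pxpy[m])).sum())
    hxy2 = float(-(pxpy[m] * np.log2(pxpy[m])).sum())

    if sd_x > 0 and sd_y > 0:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 1.0  # degenerate single-level convention

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)), restricted to present levels
    keep = px > 0
    if keep.sum() > 1:
        pk = p[keep][:, py > 0]
        qv = (pk / py[py > 0]) @ pk.T / px[keep][:, None]
        eig = np.sort(np.abs(np.linalg.eigvals(qv)))
        mcc = float(np.sqrt(max(float(eig[-2]), 0.0)))
    else:
        mcc = 1.0  # single-level convention

    da = (k_diff * p_diff).sum()
    inv_var_mask = (ii != jj)
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": float(da),
        "DifferenceEntropy": float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2).sum()),
        "JointAverage": float(mu_x),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": float((px * (i - mu_x) ** 2).sum()),
    }


def glcm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """GLCM features, averaged over the 13 symmetric directions."""
    if n_levels is None:
        n_levels = int(levels.max())
    per_direction = []
    for d in DIRECTIONS_13:
        mat = glcm_matrix(levels, d, n_levels)
        total = mat.sum()
        if total == 0:
            continue  # no valid pairs along this direction (e.g. single voxel)
        per_direction.append(_glcm_features_one(mat / total))
    if not per_direction:
        return {name: float("nan") for name in GLCM_FEATURE_NAMES}
    return {
        name: float(np.mean([f[name] for f in per_direction])) for name in GLCM_FEATURE_NAMES
    }


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(levels: np.ndarray, direction: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Run-length counts P(i, l) for one direction (runs break outside the mask)."""
    arr = np.asarray(levels)
    max_run = max(arr.shape)
    mat = np.zeros((n_levels, max_run), dtype=float)
    d = np.asarray(direction)
    # run starts: in-mask voxels whose predecessor along d differs (or is out)
    padded = np.pad(arr, 1)
    core = tuple(slice(1, 1 + n) for n in arr.shape)
    pred = np.roll(padded, shift=tuple(d), axis=(0, 1, 2))[core]
    starts = np.argwhere((arr > 0) & (pred != arr))
    for start in starts:
        level = arr[tuple(start)]
        length = 1
        pos = start + d
        while (
            np.all(pos >= 0)
            and np.all(pos < arr.shape)
            and arr[tuple(pos)] == level
        ):
            length += 1
            pos = pos + d
        mat[level - 1, length - 1] += 1.0
    return mat


def _rl_style_features(mat: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas.

    ``prefix`` chooses the naming family: "Run" (GLRLM) or zone (GLSZM).
    """
    total = mat.sum()
    if total == 0:
        names = GLRLM_FEATURE_NAMES if prefix == "Run" else GLSZM_FEATURE_NAMES
        return {name: float("nan") for name in names}
    ng, ns = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, ns + 1, dtype=float)[None, :]
    p = mat / total
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    nz = p > 0

    gln = (mat.sum(axis=1) ** 2).sum() / total
    sln = (mat.sum(axis=0) ** 2).sum() / total
    values = {
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / total,
        "GrayLevelVariance": (p * (i - mu_i) ** 2).sum(),
        "HighGrayLevel": (mat * i**2).sum() / total,
        "LowGrayLevel": (mat / i**2).sum() / total,
        "Long": (mat * s**2).sum() / total,
        "Short": (mat / s**2).sum() / total,
        "LongHigh": (mat * s**2 * i**2).sum() / total,
        "LongLow": (mat * s**2 / i**2).sum() / total,
        "ShortHigh": (mat * i**2 / s**2).sum() / total,
        "ShortLow": (mat / (i**2 * s**2)).sum() / total,
        "SizeNonUniformity": sln,
        "SizeNonUniformityNormalized": sln / total,
        "SizeVariance": (p * (s - mu_s) ** 2).sum(),
        "Percentage": total / n_voxels,
        "Entropy": -(p[nz] * np.log2(p[nz])).sum(),
    }
    if prefix == "Run":
        mapping = {
            "GrayLevelNonUniformity": "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
            "GrayLevelVariance": "GrayLevelVariance",
            "HighGrayLevelRunEmphasis": "HighGrayLevel",
            "LongRunEmphasis": "Long",
            "LongRunHighGrayLevelEmphasis": "LongHigh",
            "LongRunLowGrayLevelEmphasis": "LongLow",
            "LowGrayLevelRunEmphasis": "LowGrayLevel",
            "RunEntropy": "Entropy",
            "RunLengthNonUniformity": "SizeNonUniformity",
            "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
            "RunPercentage": "Percentage",
            "RunVariance": "SizeVariance",
            "ShortRunEmphasis": "Short",
            "ShortRunHighGrayLevelEmphasis": "ShortHigh",
            "ShortRunLowGrayLevelEmphasis": "ShortLow",
        }
    else:
        mapping = {
            "GrayLevelNonUniformity": "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
            "GrayLevelVariance": "GrayLevelVariance",
            "HighGrayLevelZoneEmphasis": "HighGrayLevel",
            "LargeAreaEmphasis": "Long",
            "LargeAreaHighGrayLevelEmphasis": "LongHigh",
            "LargeAreaLowGrayLevelEmphasis": "LongLow",
            "LowGrayLevelZoneEmphasis": "LowGrayLevel",
            "SizeZoneNonUniformity": "SizeNonUniformity",
            "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
            "SmallAreaEmphasis": "Short",
            "SmallAreaHighGrayLevelEmphasis": "ShortHigh",
            "SmallAreaLowGrayLevelEmphasis": "ShortLow",
            "ZoneEntropy": "Entropy",
            "ZonePercentage": "Percentage",
            "ZoneVariance": "SizeVariance",
        }
    return {name: float(values[key]) for name, key in mapping.items()}


def glrlm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """GLRLM features, averaged over the 13 directions."""
    if n_levels is None:
        n_levels = int(levels.max())
    n_voxels = int((levels > 0).sum())
    per_direction = [
        _rl_style_features(glrlm_matrix(levels, d, n_levels), n_voxels, "Run")
        for d in DIRECTIONS_13
    ]
    return {
        name: float(np.nanmean([f[name] for f in per_direction]))
        for name in GLRLM_FEATURE_NAMES
    }


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Size-zone counts P(i, s): 26-connected zones per grey level."""
    if n_levels is None:
        n_levels = int(levels.max())
    n_voxels = int((levels > 0).sum())
    mat = np.zeros((n_levels, max(n_voxels, 1)), dtype=float)
    for level in range(1, n_levels + 1):
        binary = levels == level
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        for size in sizes:
            mat[level - 1, size - 1] += 1.0
    return mat


def glszm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    n_voxels = int((levels > 0).sum())
    return _rl_style_features(glszm_matrix(levels, n_levels), n_voxels, "Zone")


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, alpha: int = 0, n_levels: int | None = None) -> np.ndarray:
    """Dependence counts P(i, d).

    For each in-mask voxel, d = 1 + number of 26-neighbours inside the mask
    whose level differs by at most ``alpha`` (the centre voxel itself counts,
    so sizes start at 1).
    """
    if n_levels is None:
        n_levels = int(levels.max())
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        a, b = _shifted_pairs(levels, d)
        both = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        contrib = np.zeros(levels.shape, dtype=np.int64)
        sl_a = tuple(
            slice(0, n - 1) if step == 1 else slice(1, n) if step == -1 else slice(0, n)
            for step, n in zip(d, levels.shape)
        )
        contrib[sl_a] = both
        dep += contrib
    mat = np.zeros((n_levels, 27), dtype=float)
    np.add.at(mat, (levels[mask] - 1, dep[mask]), 1.0)
    return mat


def gldm_features(levels: np.ndarray, alpha: int = 0, n_levels: int | None = None) -> dict:
    mat = gldm_matrix(levels, alpha, n_levels)
    total = mat.sum()
    if total == 0:
        return {name: float("nan") for name in GLDM_FEATURE_NAMES}
    ng, nd = mat.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    d = np.arange(1, nd + 1, dtype=float)[None, :]
    p = mat / total
    mu_i = (p * i).sum()
    mu_d = (p * d).sum()
    nz = p > 0
    dn = (mat.sum(axis=0) ** 2).sum() / total
    return {
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "DependenceNonUniformity": float(dn),
        "DependenceNonUniformityNormalized": float(dn / total),
        "DependenceVariance": float((p * (d - mu_d) ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / total),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / total),
        "LargeDependenceEmphasis": float((mat * d**2).sum() / total),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * d**2 * i**2).sum() / total),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * d**2 / i**2).sum() / total),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / total),
        "SmallDependenceEmphasis": float((mat / d**2).sum() / total),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * i**2 / d**2).sum() / total),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (i**2 * d**2)).sum() / total),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, n_levels: int | None = None):
    """Per-level (n_i, p_i, s_i) of the neighbouring grey tone difference matrix."""
    if n_levels is None:
        n_levels = int(levels.max())
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        a, b = _shifted_pairs(levels, d)
        both = (a > 0) & (b > 0)
        sl_a = tuple(
            slice(0, n - 1) if step == 1 else slice(1, n) if step == -1 else slice(0, n)
            for step, n in zip(d, levels.shape)
        )
        add_sum = np.zeros(levels.shape, dtype=float)
        add_cnt = np.zeros(levels.shape, dtype=np.int64)
        add_sum[sl_a] = np.where(both, b, 0)
        add_cnt[sl_a] = both
        nb_sum += add_sum
        nb_cnt += add_cnt
    n_vox = int(mask.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(nb_cnt > 0, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    diff = np.where(mask & (nb_cnt > 0), np.abs(levels - avg), 0.0)
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    np.add.at(n_i, levels[mask] - 1, 1.0)
    np.add.at(s_i, levels[mask] - 1, diff[mask])
    p_i = n_i / n_vox
    return n_i, p_i, s_i


def ngtdm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(levels, n_levels)
    n_vox = n_i.sum()
    present = p_i > 0
    ivals = np.arange(1, len(p_i) + 1, dtype=float)
    ngp = int(present.sum())

    p_pres = p_i[present]
    s_pres = s_i[present]
    i_pres = ivals[present]

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_pres, p_pres, indexing="ij")
        ii_, jj_ = np.meshgrid(i_pres, i_pres, indexing="ij")
        contrast = (
            (pi_ * pj_ * (ii_ - jj_) ** 2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_vox)
        )
        busy_den = np.abs(ii_ * pi_ - jj_ * pj_).sum()
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_pres, s_pres, indexing="ij")
        complexity = (
            np.abs(ii_ - jj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)
        ).sum() / n_vox
        strength_num = ((pi_ + pj_) * (ii_ - jj_) ** 2).sum()
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }
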