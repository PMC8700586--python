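"""ROI mask algebra and per-ROI histogram summary statistics.

Eight summary variables per (map, region) pair: mean, variance, 25th/75th
quantile, median, skewness, kurtosis and Shannon entropy of the binned value
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

SUMMARY_VARIABLES = (
    "mean", "variance", "q25", "q75", "median", "skewness", "kurtosis", "entropy",
)


class MaskValidationError(ValueError):
    """ROI masks violate the nesting convention."""


class ROIValidationError(ValueError):
    """ROI selects too few usable voxels for summary statistics."""


@dataclass
class ROIMaskSet:
    """Tumor sub-region masks in the radiological convention.

    ``total`` is the whole lesion and contains both ``enhancing`` and
    ``necrotic``; ``non_enhancing`` is derived by subtraction and is pairwise
    disjoint from the other two sub-regions. ``brain`` (optional) is the
    tissue mask of the whole slab.
    """

    total: np.ndarray
    enhancing: np.ndarray
    necrotic: np.ndarray
    brain: Optional[np.ndarray] = None
    non_enhancing: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=bool)
        self.enhancing = np.asarray(self.enhancing, dtype=bool)
        self.necrotic = np.asarray(self.necrotic, dtype=bool)
        if self.brain is not None:
            self.brain = np.asarray(self.brain, dtype=bool)
        self.non_enhancing = derive_nonenhancing(self)

    def region(self, name: str) -> np.ndarray:
        return {
            "total": self.total,
            "enhancing": self.enhancing,
            "necrotic": self.necrotic,
            "non_enhancing": self.non_enhancing,
        }[name]


def derive_nonenhancing(maskset: ROIMaskSet) -> np.ndarray:
    """Non-enhancing region: total lesion minus (enhancing plus necrotic).

    Raises if the sub-region masks are not subsets of the total mask — masks
    must be nested; nothing is silently clipped.
    """
    total = np.asarray(maskset.total, dtype=bool)
    enhancing = np.asarray(maskset.enhancing, dtype=bool)
    necrotic = np.asarray(maskset.necrotic, dtype=bool)
    if np.any(enhancing & ~total):
        raise MaskValidationError("enhancing mask extends outside the total mask")
    if np.any(necrotic & ~total):
        raise MaskValidationError("necrotic mask extends outside the total mask")
    return total & ~enhancing & ~necrotic


@dataclass(frozen=True)
class SummaryStats:
    """The eight ROI summary variables of one map/region pair.

    ``skewness``/``kurtosis`` are the moment estimators g1 = m3 / m2^(3/2)
    and m4 / m2^2 (normal reference 3, non-excess); they are ``None`` when
    the ROI is constant (m2 = 0). ``entropy`` is the Shannon entropy (bits)
    of the fixed-range value histogram.
    """

    mean: float
    variance: float
    q25: float
    q75: float
    median: float
    skewness: Optional[float]
    kurtosis: Optional[float]
    entropy: float
    n_voxels: int

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "variance": self.variance, "q25": self.q25,
            "q75": self.q75, "median": self.median,
            "skewness": np.nan if self.skewness is None else self.skewness,
            "kurtosis": np.nan if self.kurtosis is None else self.kurtosis,
            "entropy": self.entropy, "n_voxels": self.n_voxels,
        }


def histogram_entropy(values: np.ndarray, hist_range: Tuple[float, float] = (0.0, 1.0),
                      n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the value histogram over a fixed range.

    Empty bins contribute zero; the maximum is log2(n_bins) (8 bits at the
    default 256 bins).
    """
    counts, _ = np.histogram(values, bins=n_bins, range=hist_range)
    n = counts.sum()
    if n == 0:
        raise ROIValidationError("no values inside the histogram range")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def roi_summary(
    map_values: np.ndarray,
    mask: np.ndarray,
    hist_range: Tuple[float, float] = (0.0, 1.0),
    n_bins: int = 256,
) -> SummaryStats:
    """Summary variables of the finite map values inside ``mask``.

    Variance is the unbiased sample variance; quantiles use linear
    interpolation between closest order statistics. Voxels with undefined
    (non-finite) map values are excluded first.
    """
    map_values = np.asarray(map_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x = map_values[mask]
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ROIValidationError(
            f"ROI has {x.size} finite voxels; >=2 required for summary statistics"
        )
    m2 = float(np.mean((x - x.mean()) ** 2))
    if m2 == 0.0:
        skew = kurt = None
        entropy = 0.0
    else:
        m3 = float(np.mean((x - x.mean()) ** 3))
        m4 = float(np.mean((x - x.mean()) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
        entropy = histogram_entropy(x, hist_range, n_bins)
    q25, median, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return SummaryStats(
        mean=float(x.mean()),
        variance=float(x.var(ddof=1)),
        q25=float(q25),
        q75=float(q75),
        median=float(median),
        skewness=skew,
        kurtosis=kurt,
        entropy=entropy,
        n_voxels=int(x.size),
    )
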