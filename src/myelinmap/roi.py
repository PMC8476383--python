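"""ROI statistics and rater-reliability measures.

ROI extraction reports, per labeled region, the voxel count and the mean
and population SD of the R1 map (the SD describes the voxel population of
the ROI, so it divides by n).  Reliability of repeated manual ROI
placement is quantified by the intraclass correlation coefficient from a
two-way ANOVA decomposition (subjects x raters) and by Bland-Altman bias
and 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import check_same_geometry

__all__ = [
    "RoiStats",
    "RatingMatrix",
    "BlandAltman",
    "UndefinedStatisticError",
    "roi_statistics",
    "icc",
    "bland_altman",
]


class UndefinedStatisticError(ValueError):
    """Statistic undefined for the given data (e.g. zero total variance)."""


@dataclass(frozen=True)
class RoiStats:
    region: str
    side: str
    label_value: int
    n_voxels: int
    r1_mean: float
    r1_sd: float
    n_excluded: int = 0


def roi_statistics(
    r1_map: nib.Nifti1Image,
    labels: nib.Nifti1Image,
    label_table: pd.DataFrame | None = None,
    exclude: np.ndarray | None = None,
) -> list[RoiStats]:
    """Per-label voxel count, mean and population SD of R1.

    ``exclude`` is a boolean mask of voxels to drop (e.g. clipped/flagged
    T1 estimates); dropped voxels are counted per ROI.  Label 0 is
    background and skipped.
    """
    check_same_geometry(r1_map, labels)
    r1 = np.asarray(r1_map.dataobj, dtype=float)
    lab = np.asarray(labels.dataobj).astype(int)
    if exclude is not None and exclude.shape != lab.shape:
        raise ValueError("exclude mask geometry does not match the label map")
    names: dict[int, tuple[str, str]] = {}
    if label_table is not None:
        names = {
            int(row.label_value): (str(row.region), str(row.side))
            for row in label_table.itertuples(index=False)
        }
    out: list[RoiStats] = []
    for value in np.unique(lab):
        if value == 0:
            continue
        mask = lab == value
        kept = mask if exclude is None else (mask & ~exclude)
        n_excl = int(mask.sum() - kept.sum())
        if not kept.any():
            raise UndefinedStatisticError(
                f"label {value} has no usable voxels ({n_excl} excluded)"
            )
        values = r1[kept]
        region, side = names.get(int(value), (f"label_{value}", "midline"))
        out.append(
            RoiStats(
                region=region,
                side=side,
                label_value=int(value),
                n_voxels=int(values.size),
                r1_mean=float(values.mean()),
                r1_sd=float(values.std(ddof=0)),
                n_excluded=n_excl,
            )
        )
    return out


@dataclass
class RatingMatrix:
    """Subjects x raters grid of one region's measurements."""

    values: np.ndarray
    raters: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rating matrix must be 2-D (subjects x raters)")

    def complete(self) -> np.ndarray:
        """Drop subjects with any missing rating (with a warning)."""
        keep = ~np.isnan(self.values).any(axis=1)
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} subject(s) with missing ratings",
                stacklevel=2,
            )
        vals = self.values[keep]
        if vals.shape[0] < 2 or vals.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        return vals


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, columns=raters):
    between-subjects MSB, between-raters MSJ, residual MSE.  Sample
    (n-1 style) conventions throughout, as unbiased mean squares require."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msb = ss_rows / (n - 1)
    msj = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msb, msj, mse


def icc(
    matrix: RatingMatrix | np.ndarray,
    variant: str = "agreement",
    measure: str = "single",
) -> float:
    """Intraclass correlation coefficient of a subjects x raters matrix.

    Default is the two-way random-effects, absolute-agreement, single-
    measure coefficient ICC(2,1):

        (MSB - MSE) / (MSB + (k-1) MSE + k (MSJ - MSE) / n)

    ``variant="consistency"`` drops the rater-mean term (ICC(3,1)), and
    ``measure="average"`` gives the reliability of the k-rater mean.
    """
    if not isinstance(matrix, RatingMatrix):
        matrix = RatingMatrix(matrix)
    values = matrix.complete()
    n, k = values.shape
    if np.ptp(values) == 0:
        raise UndefinedStatisticError("all ratings identical: ICC undefined (0/0)")
    msb, msj, mse = _mean_squares(values)
    if variant == "agreement":
        if measure == "single":
            denom = msb + (k - 1) * mse + k * (msj - mse) / n
        elif measure == "average":
            denom = msb + (msj - mse) / n
        else:
            raise ValueError(f"unknown measure {measure!r}")
    elif variant == "consistency":
        if measure == "single":
            denom = msb + (k - 1) * mse
        elif measure == "average":
            denom = msb
        else:
            raise ValueError(f"unknown measure {measure!r}")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0:
        raise UndefinedStatisticError("zero denominator: ICC undefined")
    return float((msb - mse) / denom)


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement of paired measurements."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(pairs) -> BlandAltman:
    """Bland-Altman agreement of paired measurements (m1, m2).

    Differences d = m1 - m2; bias = mean(d); limits of agreement
    bias +- 1.96 * SD(d) (sample SD).  Plot coordinates are the pair
    means against d.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need an (n >= 2) x 2 array of measurement pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )
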