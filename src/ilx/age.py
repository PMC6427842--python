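"""Transcriptome-based developmental age estimation.

Class-I age-responsive marker genes increase linearly in (log2) expression
between 46 and 54 hours of development.  Given a calibration — per-marker
slope (log2 units / h, strictly positive) and intercept at 46 h — each
sample's developmental age is the least-squares solution of the inverse
regression problem

    age = argmin_a  sum_m ( x_m - (intercept_m + slope_m * (a - 46)) )^2,

solved in closed form: a = 46 + sum_m s_m r_m / sum_m s_m^2 with
r_m = x_m - intercept_m.  The standard error follows from the residual
spread across markers.  Estimates outside the calibration window are
reported but flagged, since linearity is only asserted inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, PhenotypeTable, ValidationError

WINDOW_H = (46.0, 54.0)


@dataclass
class AgeCalibration:
    """Marker calibration: per-marker slope and intercept at the window start."""

    table: pd.DataFrame  # index gene_id, columns slope, intercept
    window_h: tuple[float, float] = WINDOW_H

    def __post_init__(self) -> None:
        for col in ("slope", "intercept"):
            if col not in self.table.columns:
                raise ValidationError(f"calibration missing column {col!r}")
        slopes = self.table["slope"].to_numpy(dtype=float)
        if (slopes <= 0).any():
            bad = list(self.table.index[slopes <= 0])[:5]
            raise ValidationError(
                f"age markers must increase with age; non-positive slope for {bad}")
        if len(self.table) < 10:
            warnings.warn(f"only {len(self.table)} calibration markers; "
                          "estimates may be unstable", stacklevel=2)

    @property
    def marker_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class AgeEstimates:
    """Per-sample estimated developmental age with uncertainty."""

    table: pd.DataFrame  # index sample_id: estimated_age_h, se_h, n_markers, in_window

    def ages(self) -> pd.Series:
        return self.table["estimated_age_h"]


def estimate_sample_ages(dataset: ExpressionDataset,
                         calibration: AgeCalibration,
                         weighted: bool = False) -> AgeEstimates:
    """Estimate each sample's developmental age from the marker calibration.

    ``weighted=True`` applies slope-squared weights in the residual metric
    (steep markers, which are the most age-informative, count more); the
    default is unweighted least squares across markers.  Markers absent from
    the dataset are skipped with a warning; no
    marker present is an error.
    """
    present = calibration.marker_ids.intersection(dataset.gene_ids)
    missing = calibration.marker_ids.difference(dataset.gene_ids)
    if len(present) == 0:
        raise ValidationError("no calibration marker present in the dataset")
    if len(missing) > 0:
        warnings.warn(f"{len(missing)} calibration marker(s) absent from dataset",
                      stacklevel=2)
    if len(present) < 10:
        warnings.warn(f"only {len(present)} markers usable for age estimation",
                      stacklevel=2)
    lo, hi = calibration.window_h
    cal = calibration.table.loc[present]
    slopes = cal["slope"].to_numpy(dtype=float)
    intercepts = cal["intercept"].to_numpy(dtype=float)
    X = dataset.matrix.loc[present].to_numpy(dtype=float)  # markers x samples
    resid0 = X - intercepts[:, None]

    w = slopes ** 2 if weighted else np.ones_like(slopes)
    denom = float(np.sum(w * slopes ** 2))
    delta = (w * slopes) @ resid0 / denom  # hours past window start
    ages = lo + delta

    fitted = intercepts[:, None] + slopes[:, None] * delta[None, :]
    rss = np.sum(w[:, None] * (X - fitted) ** 2, axis=0)
    m = len(present)
    if m > 1:
        sigma2 = rss / (m - 1)
        se = np.sqrt(sigma2 / denom)
    else:
        se = np.full_like(ages, np.nan)

    table = pd.DataFrame({
        "estimated_age_h": ages,
        "se_h": se,
        "n_markers": m,
        "in_window": (ages >= lo) & (ages <= hi),
    }, index=dataset.sample_ids)
    return AgeEstimates(table=table)


def age_contrast_summary(estimates: AgeEstimates, samples: pd.DataFrame):
    """Two-way ANOVA of estimated age ~ aS * genotype with per-cell means.

    Returns the :class:`~ilx.phenostats.AnovaResult` decomposing the
    developmental-delay signal into transgene, background and interaction
    components.
    """
    from .phenostats import two_way_anova

    df = samples.copy()
    df["estimated_age_h"] = estimates.table.loc[df.index, "estimated_age_h"]
    table = pd.DataFrame({
        "line": df.index,
        "genotype": df["genotype"].to_numpy(),
        "aS": df["aS"].to_numpy(),
        "replicate": df["batch"].to_numpy(),
        "phenotype_name": "estimated_age_h",
        "value": df["estimated_age_h"].to_numpy(),
        "duration_s": np.nan,
    })
    return two_way_anova(PhenotypeTable(table=table), "estimated_age_h")
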