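"""GC-MS volatile quantification and chemotype statistics.

Headspace GC-MS peak areas are normalized to a co-extracted internal
standard (anisole-D8) and converted to concentrations through per-compound
linear calibration curves (response ratio = a * amount + b).  Compounds
without an authentic standard are quantified semi-quantitatively against a
fallback curve (the (+)-valencene curve in the original study design).
Downstream statistics are compositional: per-sample percentage profiles,
stage-relative changes of group means, and a centered PCA of the
concentration matrix.

Units: calibration curves are fitted on the amount of analyte in the
extraction vial (µg) versus the analyte/IS area ratio; quantified
concentrations are µg per g fresh weight (vial amount / tissue mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ConcentrationTable",
    "fit_calibration",
    "quantify",
    "composition",
    "relative_change",
    "pca",
]

META_COLS = ["sample_id", "cultivar", "stage", "replicate"]
PEAK_COLS = META_COLS + ["compound", "peak_area", "is_area", "tissue_mass"]


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of analyte/IS response ratio on analyte amount (µg/vial)."""

    compound: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def invert(self, ratio: float) -> float:
        """Back-calculate amount from a response ratio (may be negative)."""
        return (ratio - self.intercept) / self.slope


@dataclass
class ConcentrationTable:
    """Samples x compounds concentrations in µg/g FW with sample metadata.

    ``wide`` is indexed by sample_id with (cultivar, stage, replicate)
    metadata columns followed by one column per compound; ``modes`` records
    per compound whether an authentic standard ('standard') or the fallback
    curve ('semi-quantitative') was used.
    """

    wide: pd.DataFrame
    modes: dict[str, str] = field(default_factory=dict)
    clamped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def compounds(self) -> list[str]:
        return [c for c in self.wide.columns if c not in META_COLS[1:]]

    def values(self) -> pd.DataFrame:
        return self.wide[self.compounds]

    def meta(self) -> pd.DataFrame:
        return self.wide[META_COLS[1:]]


def fit_calibration(
    standards: pd.DataFrame, compound: str = ""
) -> CalibrationCurve:
    """Fit a calibration line by ordinary least squares.

    ``standards`` needs columns concentration / analyte_area / is_area
    (concentration = amount of analyte in the calibration vial, µg).
    """
    required = {"concentration", "analyte_area", "is_area"}
    missing = required - set(standards.columns)
    if missing:
        raise ValueError(f"standards table missing columns {sorted(missing)}")
    conc = standards["concentration"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need >=2 distinct calibration concentrations")
    if (standards["is_area"] <= 0).any():
        raise ValueError("internal-standard areas must be positive")
    ratio = (standards["analyte_area"] / standards["is_area"]).to_numpy(float)
    res = stats.linregress(conc, ratio)
    if res.slope <= 0:
        raise ValueError(f"non-positive calibration slope for {compound!r}")
    # two points define an exact line: r is then 1 by construction even if
    # linregress reports nan residual structure
    r2 = 1.0 if len(conc) == 2 else float(res.rvalue) ** 2
    return CalibrationCurve(
        compound=compound,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def quantify(
    peaks: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    fallback: CalibrationCurve | None = None,
) -> ConcentrationTable:
    """Convert a long peak table into a wide concentration table (µg/g FW).

    concentration = max(0, (peak_area/is_area - b) / a) / tissue_mass.
    Below-intercept ratios clamp to 0 and are flagged; compounds served by
    the fallback curve are flagged semi-quantitative.
    """
    missing = set(PEAK_COLS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    bad_is = peaks.loc[peaks["is_area"] <= 0, "sample_id"]
    if len(bad_is):
        raise ValueError(
            f"non-positive internal-standard area in sample(s) "
            f"{sorted(set(bad_is))}"
        )
    if (peaks["tissue_mass"] <= 0).any():
        raise ValueError("tissue_mass must be positive")

    modes: dict[str, str] = {}
    clamped: list[tuple[str, str]] = []
    rows = []
    for _, r in peaks.iterrows():
        comp = r["compound"]
        if comp in curves:
            curve = curves[comp]
            modes[comp] = "standard"
        elif fallback is not None:
            curve = fallback
            modes[comp] = "semi-quantitative"
        else:
            raise ValueError(f"no calibration curve or fallback for {comp!r}")
        ratio = r["peak_area"] / r["is_area"]
        amount = curve.invert(ratio)
        if amount < 0:
            amount = 0.0
            clamped.append((r["sample_id"], comp))
        rows.append(
            {
                "sample_id": r["sample_id"],
                "cultivar": r["cultivar"],
                "stage": r["stage"],
                "replicate": r["replicate"],
                "compound": comp,
                "conc": amount / r["tissue_mass"],
            }
        )
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["sample_id", "cultivar", "stage", "replicate"],
        columns="compound",
        values="conc",
        sort=False,
    ).reset_index().set_index("sample_id")
    wide.columns.name = None
    return ConcentrationTable(wide=wide, modes=modes, clamped=clamped)


def composition(
    conc: ConcentrationTable, compound_class: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample percentage profile over a compound class.

    Rows sum to 100; samples with an all-zero class total are excluded (and
    listed in the result's ``attrs['excluded']``).
    """
    comps = conc.compounds if compound_class is None else list(compound_class)
    if not comps:
        raise ValueError("compound class is empty")
    unknown = set(comps) - set(conc.compounds)
    if unknown:
        raise ValueError(f"unknown compound(s) {sorted(unknown)}")
    vals = conc.wide[comps]
    totals = vals.sum(axis=1)
    keep = totals > 0
    pct = vals.loc[keep].div(totals[keep], axis=0) * 100.0
    pct.attrs["excluded"] = list(totals.index[~keep])
    return pct


def relative_change(
    conc: ConcentrationTable,
    compound: str,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
) -> float:
    """Percent difference of group means: 100 * (mean_a - mean_b) / mean_b.

    Groups are (cultivar, stage) cells; ``group_b`` is the reference, so the
    result reads "a relative to b" (74 => a is 74% higher than b).
    """
    if compound not in conc.compounds:
        raise ValueError(f"unknown compound {compound!r}")

    def _mean(group: tuple[str, str]) -> float:
        cultivar, stage = group
        sel = (conc.wide["cultivar"] == cultivar) & (conc.wide["stage"] == stage)
        if not sel.any():
            raise ValueError(f"no replicates for group {group}")
        return float(conc.wide.loc[sel, compound].mean())

    mean_a, mean_b = _mean(group_a), _mean(group_b)
    if mean_b == 0:
        raise ValueError(f"reference group {group_b} has zero mean")
    return 100.0 * (mean_a - mean_b) / mean_b


def pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> dict[str, object]:
    """Principal component analysis of a samples x compounds matrix.

    Eigen-decomposition of the covariance (or correlation, when scaled)
    structure via SVD of the centered data.  Signs are fixed by making each
    loading vector's largest-magnitude entry positive.  Returns scores,
    loadings (compounds x components) and percent variance per component.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >=2 samples and >=2 compounds")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if len(zero):
            names = [matrix.columns[i] for i in zero]
            raise ValueError(f"zero-variance compound(s) under scaling: {names}")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic signs
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return {
        "scores": pd.DataFrame(U * s, index=matrix.index, columns=comps),
        "loadings": pd.DataFrame(Vt.T, index=matrix.columns, columns=comps),
        "percent_variance": pd.Series(pct, index=comps),
    }
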