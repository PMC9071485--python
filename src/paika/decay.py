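"""mRNA decay kinetics from transcription-shutoff time courses.

After transcription is switched off (actinomycin-D chase), remaining mRNA
follows first-order kinetics dC/dt = -K*C, so ln(C/C0) = -K*t.  Fitting a
through-origin line to -ln(C/C0) against time gives the decay rate constant
K (per hour) and the half-life t1/2 = ln2 / K.  Relative qPCR quantification
uses the standard 2^-ddCt method against an internal control gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DecaySeries",
    "DecayFit",
    "QpcrMeasurement",
    "normalize_series",
    "fit_decay",
    "fit_decay_table",
    "half_life",
    "ddct_fold_change",
]

LN2 = math.log(2.0)


@dataclass
class DecaySeries:
    """Relative-abundance time course for one gene, normalized so C(0) = 1."""

    gene_id: str
    timepoints: np.ndarray  # hours, first must be 0, strictly increasing
    rel_abundance: np.ndarray  # positive, rel_abundance[0] == 1
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if self.timepoints.shape != self.rel_abundance.shape:
            raise ValueError(f"{self.gene_id}: timepoints/abundance length mismatch")
        if self.timepoints.size < 2:
            raise ValueError(f"{self.gene_id}: need at least 2 timepoints")
        if self.timepoints[0] != 0:
            raise ValueError(f"{self.gene_id}: first timepoint must be 0 h")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError(f"{self.gene_id}: timepoints must be strictly increasing")
        if np.any(self.rel_abundance <= 0):
            raise ValueError(f"{self.gene_id}: abundances must be positive")
        if not math.isclose(self.rel_abundance[0], 1.0, rel_tol=1e-9):
            raise ValueError(f"{self.gene_id}: abundance at t=0 must be 1 after normalization")


@dataclass
class DecayFit:
    """Fitted first-order decay for one gene.

    ``t_half`` is +inf when k_decay <= 0 (an apparently stabilized
    transcript); by construction t_half * k_decay == ln 2 whenever
    k_decay > 0.
    """

    gene_id: str
    k_decay: float  # per hour
    t_half: float  # hours; inf when k_decay <= 0
    r_squared: float
    n_points: int
    intercept: Optional[float] = None  # only for the free-intercept diagnostic fit

    def summary(self) -> str:
        t_half = f"{self.t_half:.3f} h" if math.isfinite(self.t_half) else "inf (stabilized)"
        lines = [
            f"First-order decay fit: {self.gene_id}",
            f"  k_decay   {self.k_decay:.4f} /h",
            f"  t_half    {t_half}",
            f"  r^2       {self.r_squared:.4f}" if math.isfinite(self.r_squared) else "  r^2       n/a",
            f"  n points  {self.n_points}",
        ]
        if self.intercept is not None:
            lines.append(f"  intercept {self.intercept:.4f}")
        return "\n".join(lines)


@dataclass
class QpcrMeasurement:
    """Raw qPCR cycle thresholds for one sample: target and internal control."""

    sample_id: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        for name, ct in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.sample_id}: {name} must be finite and positive")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def normalize_series(
    raw: Sequence[float],
    timepoints: Sequence[float],
    gene_id: str = "",
    replicate_id: Optional[str] = None,
) -> DecaySeries:
    """Scale a raw abundance time course so the value at t=0 is 1."""
    raw = np.asarray(raw, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size == 0 or timepoints[0] != 0:
        raise ValueError(f"{gene_id}: series must start at t=0")
    if raw.size == 0 or raw[0] <= 0:
        raise ValueError(f"{gene_id}: abundance at t=0 must be positive")
    return DecaySeries(gene_id, timepoints, raw / raw[0], replicate_id)


def fit_decay(series: DecaySeries, through_origin: bool = True) -> DecayFit:
    """Fit ln(C/C0) = -K*t by least squares.

    The default regression is constrained through the origin, matching the
    kinetic model (C/C0 = 1 at t = 0 by construction); a free-intercept
    variant is available for diagnostics.  r^2 is computed relative to the
    fitted model (uncentred for the through-origin fit).  A non-positive
    slope is not an error: the fit is returned with t_half = +inf.
    """
    t = series.timepoints
    y = -np.log(series.rel_abundance)
    if through_origin:
        if np.allclose(y, 0.0):
            # perfectly constant series: zero decay, zero residual
            return DecayFit(series.gene_id, 0.0, math.inf, float("nan"), t.size)
        res = sm.OLS(y, t[:, None]).fit()
        k = float(res.params[0])
        r2 = float(res.rsquared)
        intercept = None
    else:
        res = sm.OLS(y, sm.add_constant(t)).fit()
        intercept, k = (float(p) for p in res.params)
        r2 = float(res.rsquared)
    return DecayFit(series.gene_id, k, half_life(k), r2, t.size, intercept)


def fit_decay_table(
    table: pd.DataFrame,
    through_origin: bool = True,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Fit decay for every gene in a long-format table.

    ``table`` needs columns gene, timepoint_h, value and optionally
    replicate.  By default replicate values are averaged per timepoint before
    normalization and fitting (one line per gene); with ``per_replicate`` each
    replicate is fitted separately.
    """
    required = {"gene", "timepoint_h", "value"}
    if missing := required - set(table.columns):
        raise ValueError(f"decay table missing columns: {sorted(missing)}")
    group_cols = ["gene", "replicate"] if per_replicate and "replicate" in table.columns else ["gene"]
    rows = []
    for keys, sub in table.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        mean = sub.groupby("timepoint_h", sort=True)["value"].mean()
        series = normalize_series(
            mean.to_numpy(), mean.index.to_numpy(), gene_id=str(keys[0]),
            replicate_id=str(keys[1]) if len(keys) > 1 else None,
        )
        fit = fit_decay(series, through_origin=through_origin)
        row = {
            "gene": keys[0],
            "k_decay": fit.k_decay,
            "t_half": fit.t_half,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        }
        if len(keys) > 1:
            row["replicate"] = keys[1]
        rows.append(row)
    return pd.DataFrame(rows)


def half_life(k_decay: float) -> float:
    """t1/2 = ln2 / K for K > 0; +inf for K <= 0 (no net decay)."""
    if k_decay <= 0:
        return math.inf
    return LN2 / k_decay


def ddct_fold_change(sample: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression of sample vs control by the 2^-ddCt method."""
    ddct = sample.delta_ct - control.delta_ct
    return float(2.0 ** (-ddct))
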