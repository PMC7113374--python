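"""Single-hit multitarget survival model for radiation dose-response data.

Seed survival after acute irradiation is modelled with the single-hit
multitarget equation

    S(D) = 1 - (1 - exp(-D / D0)) ** m

where ``D`` is the absorbed dose (Gy), ``D0`` is the dose reducing survival
to 1/e (~37%) on the exponential tail, and ``m`` is the extrapolation
number (the zero-dose intercept of the back-extrapolated tail).  The
shoulder dose

    Dq = D0 * ln(m)

marks the downward bend of the curve and is the basis for placing
treatment doses of different radiation qualities on a common effective
scale (e.g. 50% and 75% of Dq).

Fertility is summarised as the fraction of fertilized ovules out of all
ovules scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DegenerateFitError, ParameterDomainError

__all__ = [
    "DoseResponsePoint",
    "MultitargetFit",
    "FertilitySummary",
    "predict_survival",
    "fit_multitarget",
    "compute_dq",
    "effective_dose",
    "fertility_ratio",
    "read_dose_response_csv",
    "read_fertility_csv",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """One observed dose-survival point, as a fraction or as raw counts.

    When counts are supplied they take precedence and ``survival`` is
    recomputed as ``n_survived / n_total``.
    """

    dose: float
    survival: float = None  # type: ignore[assignment]
    n_total: int | None = None
    n_survived: int | None = None
    se: float | None = None

    def __post_init__(self):
        if self.dose < 0:
            raise ParameterDomainError(f"dose must be >= 0, got {self.dose}")
        if self.n_total is not None:
            if self.n_total <= 0:
                raise ParameterDomainError("n_total must be > 0")
            if self.n_survived is None or not (0 <= self.n_survived <= self.n_total):
                raise ParameterDomainError(
                    "n_survived must satisfy 0 <= n_survived <= n_total"
                )
            object.__setattr__(self, "survival", self.n_survived / self.n_total)
        if self.survival is None:
            raise ParameterDomainError("either survival or counts are required")
        if not 0.0 <= self.survival <= 1.0:
            raise ParameterDomainError(f"survival must be in [0,1], got {self.survival}")

    @classmethod
    def from_counts(cls, dose: float, n_survived: int, n_total: int) -> "DoseResponsePoint":
        return cls(dose=dose, n_total=n_total, n_survived=n_survived)


@dataclass(frozen=True)
class MultitargetFit:
    """Fitted single-hit multitarget parameters.

    Attributes
    ----------
    d0 : dose (Gy) conferring 37% survival on the exponential tail
    m : extrapolation number (>= 1)
    dq : shoulder dose, ``d0 * ln(m)``
    rss : residual sum of squares of the fit
    converged : whether the optimizer reported success
    """

    d0: float
    m: float
    dq: float
    rss: float
    converged: bool
    n_points: int = 0

    def predict(self, dose):
        return predict_survival(dose, self.d0, self.m)

    def to_dict(self) -> dict:
        return {
            "D0": self.d0,
            "m": self.m,
            "Dq": self.dq,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class FertilitySummary:
    n_fertilized: int
    n_ovules: int
    fertility: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "fertility", fertility_ratio(self.n_fertilized, self.n_ovules)
        )


def _check_params(d0: float, m: float) -> None:
    if not d0 > 0:
        raise ParameterDomainError(f"D0 must be > 0, got {d0}")
    if not m >= 1:
        raise ParameterDomainError(f"m must be >= 1, got {m}")


def predict_survival(dose, d0: float, m: float):
    """Survival fraction at ``dose`` under the single-hit multitarget model.

    Accepts a scalar or array dose; returns the same shape.  Monotone
    non-increasing in dose, equal to 1 at dose 0.
    """
    _check_params(d0, m)
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ParameterDomainError("dose must be >= 0")
    with np.errstate(over="ignore"):
        s = 1.0 - np.power(-np.expm1(-dose_arr / d0), m)
    s = np.clip(s, 0.0, 1.0)
    return float(s) if np.isscalar(dose) or dose_arr.ndim == 0 else s


def compute_dq(d0: float, m: float) -> float:
    """Shoulder dose Dq = D0 * ln(m); zero exactly when m = 1."""
    _check_params(d0, m)
    return d0 * math.log(m)


def effective_dose(dq: float, fraction: float) -> float:
    """A treatment dose expressed as ``fraction`` of the shoulder dose Dq."""
    if not dq > 0:
        raise ParameterDomainError(f"Dq must be > 0, got {dq}")
    if not 0.0 < fraction <= 1.0:
        raise ParameterDomainError(f"fraction must be in (0,1], got {fraction}")
    return fraction * dq


def fertility_ratio(n_fertilized: int, n_ovules: int) -> float:
    """Fraction of fertilized ovules out of all ovules scored."""
    if n_ovules <= 0:
        raise ParameterDomainError("n_ovules must be > 0")
    if not 0 <= n_fertilized <= n_ovules:
        raise ParameterDomainError("need 0 <= n_fertilized <= n_ovules")
    return n_fertilized / n_ovules


def fit_multitarget(
    points: Sequence[DoseResponsePoint],
    init: tuple[float, float] | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    weight_by_se: bool = False,
) -> MultitargetFit:
    """Least-squares fit of (D0, m) to observed dose-survival points.

    Parameters
    ----------
    points : observed dose-survival data; at least 3 distinct doses.
    init : optional (D0, m) starting values; defaults to
        (max dose / 3, 5).
    bounds : optional ((D0_lo, m_lo), (D0_hi, m_hi)); defaults to
        D0 in (1e-6, inf), m in [1, 1e3).
    weight_by_se : inverse-variance weighting of residuals using the
        per-point standard errors (points lacking an SE get weight 1).

    Returns a :class:`MultitargetFit` with the shoulder dose filled in.
    Raises :class:`DegenerateFitError` when all survivals are identical.
    """
    doses = np.array([p.dose for p in points], dtype=float)
    survs = np.array([p.survival for p in points], dtype=float)
    if len(np.unique(doses)) < 3:
        raise ParameterDomainError("need >= 3 distinct doses to fit two parameters")
    if np.ptp(survs) == 0.0:
        raise DegenerateFitError(
            "all observed survivals are equal; (D0, m) are unidentifiable"
        )
    if weight_by_se:
        ses = np.array(
            [p.se if p.se and p.se > 0 else 1.0 for p in points], dtype=float
        )
        w = 1.0 / ses
    else:
        w = np.ones_like(survs)

    if init is None:
        init = (max(doses.max() / 3.0, 1e-3), 5.0)
    if bounds is None:
        lo, hi = (1e-6, 1.0), (np.inf, 1e3)
    else:
        lo, hi = bounds

    def residuals(theta):
        d0, m = theta
        return w * (survs - predict_survival(doses, d0, m))

    res = least_squares(residuals, x0=np.asarray(init, float), bounds=(lo, hi))
    d0, m = float(res.x[0]), float(res.x[1])
    rss = float(np.sum((survs - predict_survival(doses, d0, m)) ** 2))
    return MultitargetFit(
        d0=d0,
        m=m,
        dq=compute_dq(d0, m),
        rss=rss,
        converged=bool(res.success),
        n_points=len(points),
    )


def read_dose_response_csv(path: str | Path) -> list[DoseResponsePoint]:
    """Read dose-response points from CSV.

    Accepts either ``dose_gy,n_total,n_survived`` (counts) or
    ``dose_gy,survival`` (fractions); counts take precedence when both
    column sets are present.
    """
    df = pd.read_csv(path)
    if "dose_gy" not in df.columns:
        raise ValueError(f"{path}: missing required column 'dose_gy'")
    points = []
    counts = {"n_total", "n_survived"}.issubset(df.columns)
    for _, row in df.iterrows():
        if counts and not (pd.isna(row["n_total"]) or pd.isna(row["n_survived"])):
            points.append(
                DoseResponsePoint.from_counts(
                    float(row["dose_gy"]), int(row["n_survived"]), int(row["n_total"])
                )
            )
        elif "survival" in df.columns:
            points.append(
                DoseResponsePoint(dose=float(row["dose_gy"]), survival=float(row["survival"]))
            )
        else:
            raise ValueError(f"{path}: row lacks both counts and a survival fraction")
    return points


def read_fertility_csv(path: str | Path) -> dict[str, FertilitySummary]:
    """Read per-sample fertility counts from CSV ``sample,n_fertilized,n_ovules``."""
    df = pd.read_csv(path)
    return {
        str(row["sample"]): FertilitySummary(
            n_fertilized=int(row["n_fertilized"]), n_ovules=int(row["n_ovules"])
        )
        for _, row in df.iterrows()
    }
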