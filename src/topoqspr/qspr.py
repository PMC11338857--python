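"""QSPR regression: three single-descriptor model families fitted by OLS.

For a physicochemical property ``P`` and a topological index ``TI``:

* linear       ``P = A + b*TI``
* quadratic    ``P = A + b*TI + c*TI^2``
* logarithmic  ``P = A + b*ln(TI)``

fitted by ordinary least squares, with the statistics conventionally reported
for such models: the (multiple) correlation r, the coefficient of
determination r^2, the overall F statistic with (k, n-k-1) degrees of freedom,
and its upper-tail p-value.

The exponential indices take values up to ~1e114 on the linear scale, so their
linear and quadratic designs are numerically meaningless (or overflow
outright).  Any design whose condition number exceeds a documented threshold
raises :class:`DegenerateFitError` carrying the diagnostic — never silent
zero coefficients.  Their logarithmic models instead regress on the exact
integer ``ln`` values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import dataset as _dataset
from .dataset import PROPERTY_NAMES, Source
from .indices import INDEX_NAMES

__all__ = [
    "Family",
    "RegressionSpec",
    "FitResult",
    "ConditionDiagnostic",
    "DegenerateFitError",
    "condition_check",
    "fit",
    "f_pvalue",
    "predict",
    "fit_all",
    "ModelTable",
]

Family = Literal["linear", "quadratic", "logarithmic"]

#: designs with a 2-norm condition number above this raise DegenerateFitError
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class RegressionSpec:
    family: Family
    property_name: str
    index_name: str
    source: Source = "computed"

    def __post_init__(self):
        if self.family not in ("linear", "quadratic", "logarithmic"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class ConditionDiagnostic:
    condition_number: float
    limit: float
    passed: bool


class DegenerateFitError(ValueError):
    """Raised when the regression design is rank deficient or ill conditioned."""

    def __init__(self, message: str, diagnostic: ConditionDiagnostic):
        super().__init__(message)
        self.diagnostic = diagnostic


@dataclass(frozen=True)
class FitResult:
    """One fitted model in the published tables' row layout.

    ``r`` is signed by the slope for the single-predictor families and is the
    (non-negative) multiple correlation for the quadratic family.
    """

    family: Family
    n: int
    A: float
    b: float
    c: Optional[float]
    r: float
    r2: float
    F: float
    p: float
    residuals: np.ndarray = field(repr=False, compare=False)

    @property
    def k(self) -> int:
        return 2 if self.family == "quadratic" else 1

    def row(self, decimals: int = 3) -> Dict[str, Union[int, float, str]]:
        """Row rounded the way the published tables print (3 decimals)."""
        rnd = lambda v: round(v, decimals)
        return {
            "N": self.n,
            "A": rnd(self.A),
            "b": rnd(self.b),
            "c": rnd(self.c) if self.c is not None else "",
            "r": rnd(self.r),
            "r2": rnd(self.r2),
            "F": rnd(self.F),
            "P": rnd(self.p),
        }


def condition_check(design: np.ndarray, limit: float = CONDITION_LIMIT) -> ConditionDiagnostic:
    """2-norm condition number of the design matrix against the documented limit."""
    design = np.asarray(design, dtype=float)
    if not np.all(np.isfinite(design)):
        return ConditionDiagnostic(math.inf, limit, False)
    sv = np.linalg.svd(design, compute_uv=False)
    cond = math.inf if sv[-1] == 0 else float(sv[0] / sv[-1])
    return ConditionDiagnostic(cond, limit, cond <= limit)


def f_pvalue(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution at ``F``."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if F < 0:
        raise ValueError(f"F statistic must be non-negative, got {F}")
    return float(stats.f.sf(F, df1, df2))


def _design(family: Family, x: np.ndarray) -> np.ndarray:
    if family == "linear":
        cols = [x]
    elif family == "quadratic":
        cols = [x, x * x]
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic family requires strictly positive index values")
        cols = [np.log(x)]
    return sm.add_constant(np.column_stack(cols))


def fit(
    spec: Union[RegressionSpec, Family],
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_is_log: bool = False,
) -> FitResult:
    """Ordinary least squares for one model family.

    ``x_is_log`` feeds already-logged values to the logarithmic family (used
    for the exponential indices whose ln is carried exactly).
    """
    family: Family = spec.family if isinstance(spec, RegressionSpec) else spec
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    k = 2 if family == "quadratic" else 1
    n = len(x)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for the {family} family")
    if family == "logarithmic" and x_is_log:
        X = sm.add_constant(np.column_stack([x]))
    else:
        X = _design(family, x)
    diag = condition_check(X)
    if not diag.passed or np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError(
            f"{family} design is ill conditioned "
            f"(condition {diag.condition_number:.3g} > {diag.limit:.3g})",
            diag,
        )
    res = sm.OLS(y, X).fit()
    params = res.params
    r2 = float(res.rsquared)
    F = float(res.fvalue)
    p = f_pvalue(F, k, n - k - 1)
    c = float(params[2]) if family == "quadratic" else None
    r = math.sqrt(max(r2, 0.0))
    if family != "quadratic" and params[1] < 0:
        r = -r
    return FitResult(
        family=family,
        n=n,
        A=float(params[0]),
        b=float(params[1]),
        c=c,
        r=r,
        r2=r2,
        F=F,
        p=p,
        residuals=np.asarray(res.resid),
    )


def predict(result: FitResult, x0: float) -> float:
    """Evaluate the fitted family's equation at ``x0``."""
    if result.family == "linear":
        return result.A + result.b * x0
    if result.family == "quadratic":
        return result.A + result.b * x0 + result.c * x0 * x0
    if x0 <= 0:
        raise ValueError("logarithmic model requires a positive index value")
    return result.A + result.b * math.log(x0)


@dataclass
class ModelTable:
    """All 6 x 6 x 3 fits for one input source.

    ``fits[(index, property, family)]`` is a :class:`FitResult` or, where the
    design is degenerate (the exponential indices under the linear and
    quadratic families), the :class:`DegenerateFitError` itself.
    """

    source: Source
    fits: Dict[Tuple[str, str, str], Union[FitResult, DegenerateFitError]]

    def result(self, index: str, prop: str, family: Family):
        return self.fits[(index, prop, family)]

    def to_frame(self, index_name: str) -> pd.DataFrame:
        """Per-index table in the published layout (one block per family)."""
        rows = []
        for family in ("linear", "quadratic", "logarithmic"):
            for prop in PROPERTY_NAMES:
                res = self.fits[(index_name, prop, family)]
                if isinstance(res, DegenerateFitError):
                    rows.append(
                        {"Family": family, "Property": prop, "N": 15,
                         "A": "degenerate", "b": "", "c": "", "r": "", "r2": "",
                         "F": "", "P": "",
                         "Note": f"condition {res.diagnostic.condition_number:.3g}"}
                    )
                else:
                    rows.append({"Family": family, "Property": prop, **res.row(), "Note": ""})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Full-precision JSON of every fit."""
        payload = {}
        for (idx, prop, family), res in sorted(self.fits.items()):
            key = f"{idx}|{prop}|{family}"
            if isinstance(res, DegenerateFitError):
                payload[key] = {
                    "degenerate": True,
                    "condition_number": res.diagnostic.condition_number,
                }
            else:
                payload[key] = {
                    "n": res.n, "A": res.A, "b": res.b, "c": res.c,
                    "r": res.r, "r2": res.r2, "F": res.F, "p": res.p,
                }
        return json.dumps(payload, indent=1)


def fit_all(source: Source = "computed") -> ModelTable:
    """Fit every (index, property, family) combination for one input source.

    Exponential-index logarithmic models use the exact integer ln values when
    the source is ``computed``; their linear/quadratic designs are recorded as
    degenerate rather than silently producing zero coefficients.
    """
    idx_mat, props = _dataset.regression_input_table(source)
    fits: Dict[Tuple[str, str, str], Union[FitResult, DegenerateFitError]] = {}
    for index_name in INDEX_NAMES:
        x_lin = idx_mat[index_name].to_numpy(dtype=float)
        for family in ("linear", "quadratic", "logarithmic"):
            if family == "logarithmic":
                x = _dataset.ln_index_column(source, index_name).to_numpy(dtype=float)
                log_ready = True
            else:
                x = x_lin
                log_ready = False
            for prop in PROPERTY_NAMES:
                y = props[prop].to_numpy(dtype=float)
                try:
                    res = fit(family, x, y, x_is_log=log_ready)
                except DegenerateFitError as exc:
                    res = exc
                fits[(index_name, prop, family)] = res
    return ModelTable(source=source, fits=fits)
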