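"""The six degree-based topological indices.

Additive indices (edge sums over the partition):

* ``ABC-R``  — sum of ``(sqrt(ds+dt-2) - 1) / sqrt(ds*dt)``, the difference of
  the atom-bond-connectivity and Randic indices;
* ``GA``     — sum of ``2*sqrt(ds*dt) / (ds+dt)``, geometric over arithmetic
  mean of the endpoint degrees (each term in ``(0, 1]``);
* ``SDD``    — sum of ``(ds^2 + dt^2) / (ds*dt)`` (each term >= 2 by AM-GM).

Multiplicative exponential indices, astronomically large and therefore carried
as exact integer natural logarithms:

* ``EPi1``   — product over vertices of ``e^(d^2)``, so ``ln EPi1 = sum d^2``;
* ``EPi2``   — product over edges of ``e^(ds*dt)``, so ``ln EPi2 = sum ds*dt``.
  (The defining display writes the product over vertices, but its term uses
  two endpoint degrees; the worked example fixes the edge-product reading.)

Multiplicative geometric-arithmetic index:

* ``GAPi``   — by the literal formula a per-edge product of terms <= 1, hence
  itself <= 1; the worked example instead multiplies, over *distinct* edge
  classes, frequency x GA-term (giving 570.213 for thalidomide).  Both are
  implemented; the class-wise form is the default because only it reproduces
  the published computations.  See :func:`ga_pi_classwise` /
  :func:`ga_pi_edgewise`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

from .molgraph import MolecularGraph, degree_spectrum, edge_partition, validate_partition

__all__ = [
    "IndexValue",
    "INDEX_NAMES",
    "abc_r",
    "ga",
    "sdd",
    "e_pi1",
    "e_pi2",
    "ga_pi_classwise",
    "ga_pi_edgewise",
    "compute_all",
]

INDEX_NAMES = ("ABC-R", "GA", "EPi1", "EPi2", "GAPi", "SDD")

#: ln threshold above which the linear-scale value is not materialised
#: (float64 overflows just above ln = 709.78)
_OVERFLOW_LN = 700.0

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class IndexValue:
    """A named index result.

    ``ln_value`` is always present; ``linear_value`` only while representable
    in double precision.  For the exponential indices ``ln_value`` is an exact
    integer computed in integer arithmetic.
    """

    index_name: str
    ln_value: float
    linear_value: Optional[float] = None

    def __post_init__(self):
        if self.linear_value is not None and self.linear_value > 0:
            assert math.isclose(
                self.linear_value, math.exp(self.ln_value), rel_tol=1e-12
            )

    @property
    def scientific(self) -> Tuple[float, int]:
        """Render as (mantissa in [1, 10), decimal exponent)."""
        log10 = self.ln_value / _LN10
        exponent = math.floor(log10)
        mantissa = 10.0 ** (log10 - exponent)
        if mantissa >= 10.0:  # guard boundary rounding
            mantissa /= 10.0
            exponent += 1
        return mantissa, exponent

    def rendered(self, sig: int = 6) -> str:
        """Scientific-notation string, e.g. ``1.46766E45``."""
        mantissa, exponent = self.scientific
        return f"{mantissa:.{sig - 1}f}E{exponent}"

    @classmethod
    def from_linear(cls, name: str, value: float) -> "IndexValue":
        if value <= 0:
            raise ValueError(f"{name}: linear value must be positive, got {value}")
        return cls(name, math.log(value), value)

    @classmethod
    def from_ln(cls, name: str, ln_value: float) -> "IndexValue":
        linear = math.exp(ln_value) if ln_value < _OVERFLOW_LN else None
        return cls(name, float(ln_value), linear)


DegreePair = Tuple[int, int]


def _edge_sum(part: Mapping[DegreePair, int], term) -> float:
    validate_partition(part)
    return float(sum(f * term(ds, dt) for (ds, dt), f in part.items()))


def abc_r(part: Mapping[DegreePair, int]) -> IndexValue:
    """Difference of the atom-bond-connectivity and Randic indices."""
    value = _edge_sum(
        part, lambda ds, dt: (math.sqrt(ds + dt - 2) - 1.0) / math.sqrt(ds * dt)
    )
    # ABC-R can be negative (e.g. K2 gives -1), so bypass the log carrier
    return IndexValue("ABC-R", math.log(abs(value)) if value > 0 else float("nan"), value)


def ga(part: Mapping[DegreePair, int]) -> IndexValue:
    """Geometric-arithmetic index; each edge contributes a term in (0, 1]."""
    value = _edge_sum(part, lambda ds, dt: 2.0 * math.sqrt(ds * dt) / (ds + dt))
    return IndexValue.from_linear("GA", value)


def sdd(part: Mapping[DegreePair, int]) -> IndexValue:
    """Symmetric division degree index; each edge contributes >= 2."""
    value = _edge_sum(part, lambda ds, dt: (ds * ds + dt * dt) / (ds * dt))
    return IndexValue.from_linear("SDD", value)


def e_pi1(spectrum: Mapping[int, int]) -> IndexValue:
    """First multiplicative exponential Zagreb index, ln = sum of squared degrees."""
    if not spectrum or any(d < 1 or c < 1 for d, c in spectrum.items()):
        raise ValueError(f"invalid degree spectrum {spectrum}")
    ln = sum(d * d * count for d, count in spectrum.items())
    return IndexValue.from_ln("EPi1", ln)


def e_pi2(part: Mapping[DegreePair, int]) -> IndexValue:
    """Second multiplicative exponential Zagreb index, ln = sum over edges of ds*dt."""
    validate_partition(part)
    ln = sum(f * ds * dt for (ds, dt), f in part.items())
    return IndexValue.from_ln("EPi2", ln)


def ga_pi_classwise(
    part: Mapping[DegreePair, int], factor_decimals: Optional[int] = 4
) -> IndexValue:
    """Multiplicative GA index, class-wise operational form (the default).

    Product over *distinct* degree classes of ``frequency x 2 sqrt(ds dt)/(ds+dt)``,
    the computation the published worked example performs.  The published
    tables evaluate each class factor to four decimal places before
    multiplying (thalidomide: ``3.4641 x 4 x 5.8788 x 7 = 570.213``); this
    arithmetic reproduces the printed column digit-for-digit and is the
    default.  Pass ``factor_decimals=None`` for the full-precision product.
    """
    validate_partition(part)
    value = 1.0
    for (ds, dt), f in sorted(part.items()):
        factor = f * 2.0 * math.sqrt(ds * dt) / (ds + dt)
        if factor_decimals is not None:
            factor = round(factor, factor_decimals)
        value *= factor
    return IndexValue.from_linear("GAPi", value)


def ga_pi_edgewise(part: Mapping[DegreePair, int]) -> IndexValue:
    """Multiplicative GA index, literal per-edge product.

    Every term lies in ``(0, 1]`` so the product does too — irreconcilable
    with the published class-wise value (570.213 for thalidomide); provided
    as the named variant of record.
    """
    validate_partition(part)
    ln = sum(
        f * math.log(2.0 * math.sqrt(ds * dt) / (ds + dt)) for (ds, dt), f in part.items()
    )
    return IndexValue.from_ln("GAPi(edgewise)", ln)


def compute_all(g: MolecularGraph) -> Dict[str, IndexValue]:
    """All six indices of a molecular graph (GAPi in class-wise form)."""
    part = edge_partition(g)
    spec = degree_spectrum(g)
    return {
        "ABC-R": abc_r(part),
        "GA": ga(part),
        "EPi1": e_pi1(spec),
        "EPi2": e_pi2(part),
        "GAPi": ga_pi_classwise(part),
        "SDD": sdd(part),
    }
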