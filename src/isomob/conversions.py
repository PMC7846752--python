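"""Linear isotope-scale transfer functions.

Enamel carbonate δ¹⁸O is measured against V-PDB; comparison with water data
requires the V-SMOW scale, and estimating the drinking water ingested during
enamel mineralisation requires a second, empirically calibrated linear map
from carbonate V-SMOW values to environmental water (δ¹⁸Odw).  Both maps are
affine with fixed published constants, so means shift through them exactly and
spreads scale by the slope magnitude.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "VPDB_TO_VSMOW_SLOPE",
    "VPDB_TO_VSMOW_INTERCEPT",
    "DW_SLOPE",
    "DW_INTERCEPT",
    "vpdb_to_vsmow",
    "vsmow_to_vpdb",
    "vsmow_to_drinking_water",
    "drinking_water_to_vsmow",
    "propagate_scale",
    "IsotopeScaleConverter",
]

# δ18Oca(V-SMOW) = 1.03091 · δ18Oca(V-PDB) + 30.91
VPDB_TO_VSMOW_SLOPE: float = 1.03091
VPDB_TO_VSMOW_INTERCEPT: float = 30.91

# δ18Odw = 1.59 · δ18Oca(V-SMOW) − 48.634  (enamel carbonate → drinking water)
DW_SLOPE: float = 1.59
DW_INTERCEPT: float = -48.634

TransformName = Literal["vpdb_to_vsmow", "vsmow_to_vpdb", "vsmow_to_dw", "dw_to_vsmow"]


def _check_finite(x, name: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def vpdb_to_vsmow(d18O_vpdb):
    """Convert δ¹⁸O from the V-PDB to the V-SMOW scale (‰).

    Accepts scalars or array-likes; returns the same shape at full precision.
    """
    x = _check_finite(d18O_vpdb, "d18O_vpdb")
    out = VPDB_TO_VSMOW_SLOPE * x + VPDB_TO_VSMOW_INTERCEPT
    return float(out) if np.isscalar(d18O_vpdb) or out.ndim == 0 else out


def vsmow_to_vpdb(d18O_vsmow):
    """Exact algebraic inverse of :func:`vpdb_to_vsmow`."""
    x = _check_finite(d18O_vsmow, "d18O_vsmow")
    out = (x - VPDB_TO_VSMOW_INTERCEPT) / VPDB_TO_VSMOW_SLOPE
    return float(out) if np.isscalar(d18O_vsmow) or out.ndim == 0 else out


def vsmow_to_drinking_water(d18O_vsmow):
    """Estimate drinking-water δ¹⁸O (‰ V-SMOW) from carbonate δ¹⁸O on V-SMOW."""
    x = _check_finite(d18O_vsmow, "d18O_vsmow")
    out = DW_SLOPE * x + DW_INTERCEPT
    return float(out) if np.isscalar(d18O_vsmow) or out.ndim == 0 else out


def drinking_water_to_vsmow(d18O_dw):
    """Exact algebraic inverse of :func:`vsmow_to_drinking_water`."""
    x = _check_finite(d18O_dw, "d18O_dw")
    out = (x - DW_INTERCEPT) / DW_SLOPE
    return float(out) if np.isscalar(d18O_dw) or out.ndim == 0 else out


_TRANSFORMS: dict[str, tuple] = {
    "vpdb_to_vsmow": (vpdb_to_vsmow, VPDB_TO_VSMOW_SLOPE),
    "vsmow_to_vpdb": (vsmow_to_vpdb, 1.0 / VPDB_TO_VSMOW_SLOPE),
    "vsmow_to_dw": (vsmow_to_drinking_water, DW_SLOPE),
    "dw_to_vsmow": (drinking_water_to_vsmow, 1.0 / DW_SLOPE),
}


def propagate_scale(mean: float, sd: float, transform: TransformName) -> tuple[float, float]:
    """Push a ``mean ± sd`` summary through one of the affine scale maps.

    The mean maps exactly; the standard deviation scales by ``|slope|``
    (ordinary linear error propagation; the intercept drops out).
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {sorted(_TRANSFORMS)}")
    if not np.isfinite(sd) or sd < 0:
        raise ValueError(f"sd must be finite and >= 0, got {sd!r}")
    func, slope = _TRANSFORMS[transform]
    return func(mean), abs(slope) * sd


_INVERSE_OF = {
    "vpdb_to_vsmow": "vsmow_to_vpdb",
    "vsmow_to_vpdb": "vpdb_to_vsmow",
    "vsmow_to_dw": "dw_to_vsmow",
    "dw_to_vsmow": "vsmow_to_dw",
}


class IsotopeScaleConverter(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer wrapping one affine scale map.

    Parameters
    ----------
    mapping : {"vpdb_to_vsmow", "vsmow_to_vpdb", "vsmow_to_dw", "dw_to_vsmow"}
        Which map to apply element-wise.
    """

    def __init__(self, mapping: TransformName = "vpdb_to_vsmow"):
        self.mapping = mapping

    def fit(self, X, y=None):
        if self.mapping not in _TRANSFORMS:
            raise ValueError(f"unknown mapping {self.mapping!r}")
        self.n_features_in_ = np.atleast_2d(np.asarray(X, dtype=float)).shape[1]
        return self

    def transform(self, X):
        func, _ = _TRANSFORMS[self.mapping]
        return func(np.asarray(X, dtype=float))

    def inverse_transform(self, X):
        func, _ = _TRANSFORMS[_INVERSE_OF[self.mapping]]
        return func(np.asarray(X, dtype=float))
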