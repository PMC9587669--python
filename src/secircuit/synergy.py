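"""Chou-Talalay median-effect fitting and combination-index analysis.

The median-effect model relates dose D to fraction affected fa through
fa / (1 - fa) = (D / Dm)^m, with Dm the dose for half effect and m the
sigmoidicity. Fitting is ordinary least squares of log10(fa/(1-fa)) on
log10(D) after fa = 1 - viability and clipping to [eps, 1-eps]. The
combination index at an observed combination effect fa is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa),   Dx(fa) = Dm * (fa/(1-fa))^(1/m)

(the two-term, mutually exclusive form, CompuSyn's classic isobologram
default; the three-term conservative variant is available via
``conservative=True``). CI < 1 indicates synergy, 1 additivity, > 1
antagonism. Viability is assumed normalized to the untreated control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger("secircuit")

FA_EPS = 0.005


def _clip_fa(fa: np.ndarray, eps: float = FA_EPS) -> np.ndarray:
    return np.clip(np.asarray(fa, dtype=float), eps, 1.0 - eps)


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters for one drug."""

    drug_id: str
    m: float
    dm: float
    r2: float
    n_points: int

    def fa_at(self, dose) -> np.ndarray:
        """Predicted fraction affected: fa = 1 / (1 + (Dm/D)^m)."""
        d = np.asarray(dose, dtype=float)
        return 1.0 / (1.0 + (self.dm / d) ** self.m)

    def dose_for_effect(self, fa: float) -> float:
        return dose_for_effect(self, fa)


class MedianEffectModel(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the median-effect (Chou) model.

    ``fit(doses, viability)`` converts viability to fraction affected,
    drops non-informative points (fa outside (eps, 1-eps) after clipping
    when ``strict_inclusion``), and least-squares fits the linearized
    model. Fitted attributes: ``m_``, ``dm_``, ``r2_``, ``n_points_``.
    ``predict(doses)`` returns predicted viability.
    """

    def __init__(self, drug_id: str = "", eps: float = FA_EPS,
                 strict_inclusion: bool = True):
        self.drug_id = drug_id
        self.eps = eps
        self.strict_inclusion = strict_inclusion

    def fit(self, doses, viability):
        d = np.asarray(doses, dtype=float)
        v = np.asarray(viability, dtype=float)
        if d.shape != v.shape:
            raise ValueError("doses and viability must have the same length")
        if (d <= 0).any():
            raise ValueError("doses must be > 0")
        fa = 1.0 - np.clip(v, 0.0, 1.0)
        if self.strict_inclusion:
            keep = (fa > self.eps) & (fa < 1.0 - self.eps)
        else:
            keep = np.ones_like(fa, dtype=bool)
        d, fa = d[keep], _clip_fa(fa[keep], self.eps)
        if d.size < 2:
            raise ValueError(
                f"median-effect fit needs >= 2 informative doses, got {d.size}"
            )
        x = np.log10(d)
        y = np.log10(fa / (1.0 - fa))
        res = stats.linregress(x, y)
        if res.slope <= 0:
            warnings.warn(
                f"median-effect slope m = {res.slope:.3g} <= 0 for "
                f"{self.drug_id or 'drug'}: non-monotone dose response",
                stacklevel=2,
            )
        self.m_ = float(res.slope)
        self.dm_ = float(10.0 ** (-res.intercept / res.slope))
        self.r2_ = float(res.rvalue ** 2)
        self.n_points_ = int(d.size)
        return self

    def predict(self, doses) -> np.ndarray:
        return 1.0 - self.fit_result().fa_at(doses)

    def fit_result(self) -> MedianEffectFit:
        if not hasattr(self, "m_"):
            raise ValueError("MedianEffectModel is not fitted")
        return MedianEffectFit(
            drug_id=self.drug_id, m=self.m_, dm=self.dm_,
            r2=self.r2_, n_points=self.n_points_,
        )


def median_effect_fit(doses, viabilities, drug_id: str = "") -> MedianEffectFit:
    """Functional wrapper over :class:`MedianEffectModel`."""
    return MedianEffectModel(drug_id=drug_id).fit(doses, viabilities).fit_result()


def dose_for_effect(fit: MedianEffectFit, fa: float, eps: float = FA_EPS) -> float:
    """Dx(fa) = Dm * (fa / (1 - fa))^(1/m)."""
    if not (eps < fa < 1.0 - eps):
        raise ValueError(f"fa must lie in ({eps}, {1.0 - eps}), got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


@dataclass(frozen=True)
class CombinationRecord:
    dose_1: float
    dose_2: float
    fa_combo: float
    ci: float


def combination_index(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    dose_1: float,
    dose_2: float,
    fa_combo: float,
    conservative: bool = False,
    eps: float = FA_EPS,
) -> float:
    """Combination index of one (dose_1, dose_2, observed fa) point."""
    fa = float(_clip_fa(np.array(fa_combo), eps))
    dx1 = dose_for_effect(fit_1, fa, eps=eps)
    dx2 = dose_for_effect(fit_2, fa, eps=eps)
    ci = dose_1 / dx1 + dose_2 / dx2
    if conservative:
        ci += (dose_1 * dose_2) / (dx1 * dx2)
    return float(ci)


def combination_table(
    fit_1: MedianEffectFit,
    fit_2: MedianEffectFit,
    combos: pd.DataFrame,
    conservative: bool = False,
) -> pd.DataFrame:
    """Per-point CI for a combination table (dose_1, dose_2, viability)."""
    out = combos.copy()
    fa = _clip_fa(1.0 - out["viability"].to_numpy(float))
    out["fa"] = fa
    out["ci"] = [
        combination_index(fit_1, fit_2, d1, d2, f, conservative=conservative)
        for d1, d2, f in zip(out["dose_1"], out["dose_2"], fa)
    ]
    return out
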