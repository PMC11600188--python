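"""Solvatochromic dye–protein binding: single-class-of-sites model with
fluorescence enhancement.

The dye is essentially non-fluorescent in water and brightens on binding a
plasma protein.  With a protein carrying ``n`` equivalent binding sites the
complex concentration [PL] obeys the mass-balance system

    [PL] = n * P0 * L_f / (K_d + L_f),      L_f = L_tot - [PL]

where ``P0`` is the total protein concentration (uM), ``L_tot`` the total dye
concentration (uM), ``K_d`` the per-site dissociation constant (uM) and
``L_f`` the free-dye concentration.  Eliminating ``L_f`` gives a quadratic in
[PL] whose physical root lies in ``[0, min(n*P0, L_tot)]``.

Measured fluorescence is modelled as

    FI = u * (L_f + alpha * [PL])

with ``u`` the fluorescence per uM of free dye and ``alpha`` the
fold-enhancement of a bound dye molecule over a free one (dimensionless;
values of several hundred are typical for plasma proteins).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError

__all__ = [
    "BindingParams",
    "TitrationSeries",
    "BindingFit",
    "predict_complex",
    "predict_fluorescence",
    "estimate_alpha",
    "fit_binding",
    "scatchard_transform",
]

VARY_DYE = "vary_dye_fixed_protein"
VARY_PROTEIN = "vary_protein_fixed_dye"


@dataclass(frozen=True)
class BindingParams:
    """Equilibrium parameters of the dye-protein interaction.

    Attributes
    ----------
    k_d : float
        Dissociation constant in uM (> 0).
    n : float
        Maximum number of dye molecules bound per protein molecule (> 0).
    alpha : float
        Fluorescence fold-enhancement of bound versus free dye (> 0).
    """

    k_d: float
    n: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("k_d", "n", "alpha"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass
class TitrationSeries:
    """An ordered fluorescence titration.

    ``mode`` records which concentration was varied: the dissociation
    constant is fitted from a vary-dye series at fixed protein, while the
    enhancement coefficient alpha is extrapolated from a vary-protein series
    at fixed low dye.
    """

    protein0: np.ndarray
    dye_total: np.ndarray
    fi: np.ndarray
    mode: str
    fi_free_unit: float = 1.0

    def __post_init__(self) -> None:
        self.protein0 = np.asarray(self.protein0, dtype=float)
        self.dye_total = np.asarray(self.dye_total, dtype=float)
        self.fi = np.asarray(self.fi, dtype=float)
        if not (self.protein0.shape == self.dye_total.shape == self.fi.shape):
            raise ValueError("protein0, dye_total and fi must have equal length")
        if np.any(self.protein0 < 0) or np.any(self.dye_total < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(self.fi < 0) or not np.all(np.isfinite(self.fi)):
            raise ValueError("fluorescence values must be finite and nonnegative")
        if self.mode not in (VARY_DYE, VARY_PROTEIN):
            raise ValueError(f"unknown titration mode {self.mode!r}")
        if self.mode == VARY_DYE and np.unique(self.protein0).size > 1:
            raise ValueError("vary-dye series must hold protein0 fixed")
        if self.mode == VARY_PROTEIN and np.unique(self.dye_total).size > 1:
            raise ValueError("vary-protein series must hold dye_total fixed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein0_uM": self.protein0,
                "dye_total_uM": self.dye_total,
                "fi": self.fi,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode: str, fi_free_unit: float = 1.0) -> "TitrationSeries":
        df = pd.read_csv(path, comment="#")
        return cls(
            protein0=df["protein0_uM"].to_numpy(),
            dye_total=df["dye_total_uM"].to_numpy(),
            fi=df["fi"].to_numpy(),
            mode=mode,
            fi_free_unit=fi_free_unit,
        )


def predict_complex(params: BindingParams, protein0, dye_total) -> np.ndarray | float:
    """Concentration of the fluorescence-enhanced complex [PL] in uM.

    Solves the mass balance exactly: [PL] is the smaller root of

        [PL]^2 - (n*P0 + L_tot + K_d)*[PL] + n*P0*L_tot = 0

    which is the unique root in ``[0, min(n*P0, L_tot)]``.  Vectorised over
    ``protein0`` and ``dye_total``.
    """
    p0 = np.asarray(protein0, dtype=float)
    lt = np.asarray(dye_total, dtype=float)
    if np.any(p0 < 0) or np.any(lt < 0):
        raise ValueError("concentrations must be nonnegative")
    s = params.n * p0  # total site concentration
    b = s + lt + params.k_d
    disc = b * b - 4.0 * s * lt
    # Numerically stable smaller root: 2*q/(b + sqrt(disc))
    pl = 2.0 * s * lt / (b + np.sqrt(np.maximum(disc, 0.0)))
    if pl.ndim == 0:
        return float(pl)
    return pl


def predict_fluorescence(
    params: BindingParams,
    protein0,
    dye_total,
    fi_free_unit: float = 1.0,
    include_free_baseline: bool = True,
) -> np.ndarray | float:
    """Model fluorescence FI = u*(L_f + alpha*[PL]).

    ``include_free_baseline=False`` drops the free-dye term, for instruments
    or dyes where free-dye emission is below detection.
    """
    pl = np.asarray(predict_complex(params, protein0, dye_total), dtype=float)
    lf = np.asarray(dye_total, dtype=float) - pl
    fi = fi_free_unit * (params.alpha * pl + (lf if include_free_baseline else 0.0))
    if fi.ndim == 0:
        return float(fi)
    return fi


def estimate_alpha(series: TitrationSeries, reference_fi: float | None = None) -> float:
    """Extrapolate the fluorescence-enhancement coefficient alpha.

    From a vary-protein series at one fixed low dye concentration, FI is
    regressed on 1/protein0; the y-intercept is the fluorescence at
    notionally infinite protein (all dye bound) and alpha is that intercept
    divided by the free-dye fluorescence at the same dye concentration.

    The zero-protein point of the series supplies the free-dye reference
    unless ``reference_fi`` is given explicitly.
    """
    if series.mode != VARY_PROTEIN:
        raise ValueError("estimate_alpha requires a vary-protein series")
    nonzero = series.protein0 > 0
    p0 = series.protein0[nonzero]
    fi = series.fi[nonzero]
    if np.unique(p0).size < 3:
        raise FitError("need >= 3 distinct nonzero protein concentrations")
    if reference_fi is None:
        zero = ~nonzero
        if not np.any(zero):
            raise FitError("no zero-protein reference point and no reference_fi given")
        reference_fi = float(np.mean(series.fi[zero]))
    res = stats.linregress(1.0 / p0, fi)
    intercept = float(res.intercept)
    if intercept <= 0 or reference_fi <= 0:
        raise FitError(
            f"nonpositive intercept ({intercept:.4g}) or reference FI "
            f"({reference_fi:.4g}); cannot form enhancement ratio"
        )
    return intercept / reference_fi


@dataclass
class BindingFit:
    """Result of the nonlinear titration fit."""

    params: BindingParams
    residual_norm: float
    converged: bool
    degenerate: bool
    n_starts: int
    message: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def k_d(self) -> float:
        return self.params.k_d

    @property
    def n(self) -> float:
        return self.params.n


def fit_binding(
    series: TitrationSeries,
    alpha: float,
    include_free_baseline: bool = True,
    kd_starts: Sequence[float] | None = None,
    n_starts: Sequence[float] = (0.3, 1.0, 3.0),
) -> BindingFit:
    """Fit (K_d, n) by nonlinear least squares with alpha held fixed.

    Minimises sum((FI_obs - FI_model)^2) over log-parameters to keep both
    strictly positive.  Multi-start initialisation: K_d starts log-spaced
    across the dye-concentration range crossed with a few n starts; the best
    converged solution wins.  Degenerate (no protein response) series are
    flagged, never silently returned as a fit.
    """
    if series.mode != VARY_DYE:
        raise ValueError("fit_binding requires a vary-dye series at fixed protein")
    if series.fi.size < 5:
        raise FitError("need >= 5 titration points")
    p0 = series.protein0
    lt = series.dye_total
    fi = series.fi
    u = series.fi_free_unit

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, n = np.exp(theta)
        params = BindingParams(kd, n, alpha)
        return (
            np.asarray(
                predict_fluorescence(params, p0, lt, u, include_free_baseline)
            )
            - fi
        )

    pos = lt[lt > 0]
    if kd_starts is None:
        kd_starts = np.geomspace(pos.min(), pos.max(), 5)

    best = None
    any_converged = False
    for kd0, n0 in itertools.product(kd_starts, n_starts):
        try:
            sol = optimize.least_squares(
                residuals,
                x0=np.log([kd0, n0]),
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=2000,
            )
        except (ValueError, FloatingPointError):
            continue
        any_converged = any_converged or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all optimiser starts failed")

    kd_hat, n_hat = np.exp(best.x)
    rss = float(2.0 * best.cost)
    # Null model: no binding response at all (FI follows the free-dye line).
    null_pred = u * lt if include_free_baseline else np.zeros_like(lt)
    rss_null = float(np.sum((null_pred - fi) ** 2))
    scale = max(1.0, float(np.sum(fi**2)))
    degenerate = (rss_null - rss) <= 1e-10 * scale or n_hat < 1e-8

    return BindingFit(
        params=BindingParams(float(kd_hat), float(n_hat), alpha),
        residual_norm=np.sqrt(rss),
        converged=bool(any_converged),
        degenerate=bool(degenerate),
        n_starts=len(list(kd_starts)) * len(list(n_starts)),
        message=str(best.message),
        residuals=best.fun,
    )


def scatchard_transform(
    series: TitrationSeries, alpha: float, fi_free_unit: float | None = None
) -> pd.DataFrame:
    """Scatchard coordinates (bound, bound/free) recovered from fluorescence.

    Inverting FI = u*(L_f + alpha*[PL]) with L_f = L_tot - [PL] gives
    bound = (FI/u - L_tot)/(alpha - 1).  For single-class-of-sites data the
    points fall on a line of slope -1/K_d with bound-axis intercept n*P0.
    """
    if alpha == 1.0:
        raise ValueError("alpha = 1 leaves bound/free unidentifiable from FI")
    u = series.fi_free_unit if fi_free_unit is None else fi_free_unit
    bound = (series.fi / u - series.dye_total) / (alpha - 1.0)
    free = series.dye_total - bound
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(free > 0, bound / free, np.nan)
    return pd.DataFrame({"bound_uM": bound, "free_uM": free, "bound_over_free": ratio})
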