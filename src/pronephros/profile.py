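"""In-focus axial dye profiling along the duct (the core imaging algorithm).

At every axis pixel the duct wall (GFP channel) is sampled over an outer
circular ROI of diameter D1; the slice where the mean GFP is maximal,
``N_max``, is the in-focus depth of the duct at that position.  Because the
duct drifts in z along its length, the raw ``N_max`` sequence is smoothed by
an ordinary-least-squares cubic in the pixel x coordinate and rounded back
to an integer slice, ``<N_max>``.  The dye intensity is then read as the
mean over an inner ROI of diameter D2 at slice ``<N_max>`` and plotted
against the cumulative distance along the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axis import AxisPixels, circular_mask
from .errors import FitError, GeometryError
from .stacks import DYE, GFP, ZStack

__all__ = [
    "UreterProfile",
    "slice_of_max_gfp",
    "smooth_nmax_cubic",
    "extract_profile",
]

DEFAULT_D1 = 15
DEFAULT_D2 = 7


def _round_half_up(values) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


@dataclass
class UreterProfile:
    """Ordered per-position samples along the duct plus the fitted focus
    curve.

    ``samples`` columns: i, x, y, s_um (cumulative distance), n_max_raw,
    n_max_smooth, fi_gfp (mean GFP in the D1 ROI at the raw-max slice),
    fi_dye (mean dye in the D2 ROI at the smoothed slice).
    """

    samples: pd.DataFrame
    d1: int
    d2: int
    cubic_coefficients: np.ndarray | None  # ascending powers, or None (no fit)
    subject: str = ""
    group: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def cumulative_distance(self) -> np.ndarray:
        return self.samples["s_um"].to_numpy()

    @property
    def fi_dye(self) -> np.ndarray:
        return self.samples["fi_dye"].to_numpy()

    def to_csv(self, path, header_comment: str | None = None) -> None:
        df = self.samples.copy()
        df.insert(0, "subject", self.subject)
        df.insert(1, "group", self.group)
        with open(path, "w", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, d1: int = DEFAULT_D1, d2: int = DEFAULT_D2) -> "UreterProfile":
        df = pd.read_csv(path, comment="#")
        subject = str(df["subject"].iloc[0]) if "subject" in df else ""
        group = str(df["group"].iloc[0]) if "group" in df else ""
        return cls(
            samples=df.drop(columns=[c for c in ("subject", "group") if c in df]),
            d1=d1,
            d2=d2,
            cubic_coefficients=None,
            subject=subject,
            group=group,
        )


def slice_of_max_gfp(
    stack: ZStack, center: tuple, d1: int = DEFAULT_D1
) -> tuple[int, float]:
    """The slice index maximising mean GFP over the D1 ROI at ``center``.

    Ties are broken toward the lowest slice index.  Returns
    ``(N_max, FI_GFP)`` with ``FI_GFP`` the winning mean.
    """
    xs, ys = circular_mask(center, d1, stack.image_shape)
    if xs.size == 0:
        raise GeometryError(f"D1 ROI at {center} is empty after clipping")
    means = stack.channel(GFP)[:, ys, xs].mean(axis=1)
    n_max = int(np.argmax(means))  # argmax returns the first (lowest) maximum
    return n_max, float(means[n_max])


def smooth_nmax_cubic(
    x_values,
    n_max_values,
    n_slices: int,
    order: int = 3,
    allow_fallback: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS polynomial smoothing of the in-focus slice sequence.

    Fits ``N_max`` as a cubic in the regressor (typically the pixel x
    coordinate), evaluates it at every position, rounds half-up and clamps
    to ``[0, n_slices - 1]``.

    Returns ``(coefficients, smoothed)`` with coefficients in ascending
    powers.  Fewer distinct regressor values than ``order + 1`` raise
    ``FitError`` unless ``allow_fallback`` permits dropping to the highest
    supported order.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(n_max_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_values and n_max_values must be equal-length 1D")
    n_distinct = np.unique(x).size
    eff_order = order
    if n_distinct < order + 1:
        if not allow_fallback:
            raise FitError(
                f"only {n_distinct} distinct regressor value(s); a cubic needs "
                f"{order + 1}. Pass allow_fallback=True to fit the highest "
                "supported order instead."
            )
        eff_order = n_distinct - 1
    if eff_order == 0:
        coeffs = np.zeros(order + 1)
        coeffs[0] = float(np.mean(y))
    else:
        poly = np.polynomial.Polynomial.fit(x, y, deg=eff_order).convert()
        coeffs = np.zeros(order + 1)
        coeffs[: poly.coef.size] = poly.coef
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    smoothed = np.clip(_round_half_up(fitted), 0, n_slices - 1)
    return coeffs, smoothed


def extract_profile(
    stack: ZStack,
    axis: AxisPixels,
    d1: int = DEFAULT_D1,
    d2: int = DEFAULT_D2,
    regressor: str = "x",
    allow_fallback: bool = False,
    subject: str = "",
    group: str = "",
) -> UreterProfile:
    """Run the full per-position algorithm along a rasterized axis.

    Parameters
    ----------
    regressor : {"x", "s"}
        Independent variable of the cubic focus fit: the pixel x coordinate
        (as in the original procedure) or the cumulative distance, which is
        preferable for strongly curved or vertical axes.

    Single-slice stacks skip the fit and use slice 0 everywhere.
    """
    if regressor not in ("x", "s"):
        raise ValueError("regressor must be 'x' or 's'")
    h, w = stack.image_shape
    pix = axis.pixels
    if np.any(pix[:, 0] < 0) or np.any(pix[:, 0] >= w) or np.any(
        pix[:, 1] < 0
    ) or np.any(pix[:, 1] >= h):
        raise GeometryError("axis pixels fall outside the image")

    gfp = stack.channel(GFP)
    dye = stack.channel(DYE)

    n = len(pix)
    n_max_raw = np.empty(n, dtype=int)
    fi_gfp = np.empty(n)
    for i, (x, y) in enumerate(pix):
        n_max_raw[i], fi_gfp[i] = slice_of_max_gfp(stack, (x, y), d1)

    if stack.n_slices == 1:
        coeffs = None
        n_max_smooth = np.zeros(n, dtype=int)
    else:
        reg = pix[:, 0].astype(float) if regressor == "x" else axis.cumulative_distance
        coeffs, n_max_smooth = smooth_nmax_cubic(
            reg, n_max_raw, stack.n_slices, allow_fallback=allow_fallback
        )

    fi_dye = np.empty(n)
    for i, (x, y) in enumerate(pix):
        xs, ys = circular_mask((x, y), d2, stack.image_shape)
        if xs.size == 0:
            raise GeometryError(f"D2 ROI at {(x, y)} is empty after clipping")
        fi_dye[i] = dye[n_max_smooth[i], ys, xs].mean()

    samples = pd.DataFrame(
        {
            "i": np.arange(n),
            "x": pix[:, 0],
            "y": pix[:, 1],
            "s_um": axis.cumulative_distance,
            "n_max_raw": n_max_raw,
            "n_max_smooth": n_max_smooth,
            "fi_gfp": fi_gfp,
            "fi_dye": fi_dye,
        }
    )
    return UreterProfile(
        samples=samples,
        d1=d1,
        d2=d2,
        cubic_coefficients=coeffs,
        subject=subject,
        group=group,
    )
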