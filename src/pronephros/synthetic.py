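"""Ground-truth-known synthetic inputs for every pipeline stage.

Three generators:

* ``generate_tube_zstack`` — a curved fluorescent tube in a two-channel
  z-stack.  The duct wall is painted in the GFP channel as an annular shell
  around a smooth 3D centerline (the transgenic duct label); the lumen is
  filled in the dye channel with an axial intensity profile
  ``entry + slope*s + baseline`` plus optional hematuria-like Gaussian
  spikes.  The wall brightness is modulated by a Gaussian of the axial
  offset from the centerline plane, emulating confocal sectioning so that
  the in-focus slice is well defined.  Both channels are blurred by an
  isotropic Gaussian PSF and optionally perturbed by clipped additive
  Gaussian noise.

* ``generate_titration`` — fluorescence titrations from the exact
  mass-balance binding model, for round-trip tests of the affinity fit.

* ``generate_electropherogram`` — Gaussian-peak traces whose raw areas are
  divided by a power-law detector falloff ``a * t**b``, so that the ladder
  calibration stage must multiply it back.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .axis import PolylineAxis
from .binding import BindingParams, TitrationSeries, VARY_DYE, VARY_PROTEIN, predict_fluorescence
from .epg import LadderPeak, PowerLawCalibration, Trace
from .errors import GeometryError
from .stacks import ZStack

__all__ = [
    "TubeScenario",
    "TubeGeometry",
    "SCENARIOS",
    "generate_tube_zstack",
    "generate_titration",
    "generate_electropherogram",
    "make_study_case",
    "EpgSimulation",
]

INTACT = "intact"
IMPAIRED = "impaired"

#: ROI diameters (px) matched to the default phantom at 1 um/px: the outer
#: disk encompasses the duct's outer circumference (2 * 10 um), the inner
#: disk stays inside the lumen (2 * 7 um) with margin for focus rounding.
STUDY_D1 = 21
STUDY_D2 = 7


@dataclass(frozen=True)
class TubeScenario:
    """Axial dye profile of one glomerular/tubular condition.

    The four quadrants of the taxonomy map onto (entry level, slope sign):
    both functions intact -> flat and low; glomerular leak with working
    reabsorption -> high entry, falling along the duct; tubular failure
    alone -> low entry, rising; both impaired -> high entry, rising.
    """

    glomerular_status: str
    tubular_status: str
    entry_intensity: float  # dye units at the glomerular end
    axial_slope: float  # dye units per um (may be negative)
    baseline: float = 0.0  # background dye units
    spike_positions: tuple = ()  # axial positions (um) of hematuria spikes
    spike_amplitude: float = 0.0
    spike_sigma: float = 5.0  # um

    def __post_init__(self) -> None:
        if self.entry_intensity < 0 or self.baseline < 0:
            raise ValueError("entry_intensity and baseline must be >= 0")
        for status in (self.glomerular_status, self.tubular_status):
            if status not in (INTACT, IMPAIRED):
                raise ValueError(f"status must be intact/impaired, got {status!r}")

    def profile(self, s) -> np.ndarray:
        """Ground-truth dye intensity at axial position(s) ``s`` (um)."""
        s = np.asarray(s, dtype=float)
        out = self.entry_intensity + self.axial_slope * s + self.baseline
        for pos in self.spike_positions:
            out = out + self.spike_amplitude * np.exp(
                -((s - pos) ** 2) / (2.0 * self.spike_sigma**2)
            )
        return np.maximum(out, 0.0)


#: Default profile parameters for the four quadrants.  Dye units are
#: arbitrary detector counts; entry levels and slopes are chosen so that,
#: over a duct of a few hundred um, the impaired conditions are well
#: separated from the healthy flat-low profile.
SCENARIOS: dict[str, TubeScenario] = {
    "healthy": TubeScenario(INTACT, INTACT, entry_intensity=20.0, axial_slope=0.0, baseline=10.0),
    "glomerular": TubeScenario(IMPAIRED, INTACT, entry_intensity=200.0, axial_slope=-0.5, baseline=10.0),
    "tubular": TubeScenario(INTACT, IMPAIRED, entry_intensity=15.0, axial_slope=0.5, baseline=10.0),
    "combined": TubeScenario(IMPAIRED, IMPAIRED, entry_intensity=200.0, axial_slope=0.3, baseline=10.0),
}


@dataclass(frozen=True)
class TubeGeometry:
    """Physical layout of the synthetic duct phantom.

    Control points are in physical um, (x, y, z), with strictly increasing
    x: the duct runs across the field and the centerline is the graph of
    cubic splines y(x) and z(x) through the control points (with exactly
    four control points, not-a-knot end conditions make z(x) a single cubic
    polynomial, the smooth z drift the focus fit is built for).  The default
    z spacing matches a typical confocal acquisition on a 10x objective.
    """

    image_shape: tuple = (40, 256, 256)  # (n_slices, height, width)
    pixel_size_xy: float = 1.0  # um/px
    z_interval: float = 3.947  # um
    centerline_control_points: tuple = (
        (24.0, 128.0, 60.0),
        (93.0, 110.0, 80.0),
        (162.0, 146.0, 100.0),
        (232.0, 128.0, 70.0),
    )
    tube_outer_radius: float = 10.0  # um
    tube_inner_radius: float = 7.0  # um
    psf_sigma: float = 1.0  # um
    noise_sd: float = 0.0  # intensity units
    seed: int = 0
    wall_intensity: float = 1000.0
    wall_focus_sigma: float = 4.0  # um, confocal sectioning of the wall

    def __post_init__(self) -> None:
        if not self.tube_inner_radius < self.tube_outer_radius:
            raise GeometryError("tube_inner_radius must be < tube_outer_radius")
        pts = np.asarray(self.centerline_control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise GeometryError("need >= 2 (x, y, z) control points")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise GeometryError("control-point x coordinates must strictly increase")
        n_slices, h, w = self.image_shape
        r = self.tube_outer_radius
        x_max = (w - 1) * self.pixel_size_xy
        y_max = (h - 1) * self.pixel_size_xy
        z_max = (n_slices - 1) * self.z_interval
        ok = (
            (pts[:, 0] >= r) & (pts[:, 0] <= x_max - r)
            & (pts[:, 1] >= r) & (pts[:, 1] <= y_max - r)
            & (pts[:, 2] >= r) & (pts[:, 2] <= z_max - r)
        )
        if not np.all(ok):
            raise GeometryError(
                "centerline control points must stay >= tube_outer_radius from "
                f"all image borders; offending points: {pts[~ok].tolist()}"
            )


def _sample_centerline(
    geometry: TubeGeometry, pad: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense centerline samples (N, 3) in um, their 2D (xy) arc length s
    (N,), and a boolean mask of samples inside the nominal (unpadded) span.

    The centerline is sampled as (x, y(x), z(x)) on a half-pixel x grid;
    ``pad`` extends the tube by spline extrapolation beyond both ends so
    that ROI disks centered on the first/last axis pixels still sit on
    tube, not on background.  Axial position s is the in-plane (xy) arc
    length measured from the unpadded start — the same convention the
    measurement pipeline uses for cumulative distance.
    """
    pts = np.asarray(geometry.centerline_control_points, dtype=float)
    y_of_x = CubicSpline(pts[:, 0], pts[:, 1])
    z_of_x = CubicSpline(pts[:, 0], pts[:, 2])
    step = geometry.pixel_size_xy / 2.0
    x = np.arange(pts[0, 0] - pad, pts[-1, 0] + pad + step / 2, step)
    samples = np.column_stack([x, y_of_x(x), z_of_x(x)])
    d_xy = np.linalg.norm(np.diff(samples[:, :2], axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d_xy)])
    inside = (x >= pts[0, 0]) & (x <= pts[-1, 0])
    s = s - s[inside][0]
    return samples, s, inside


def generate_tube_zstack(
    geometry: TubeGeometry, scenario: TubeScenario
) -> tuple[ZStack, PolylineAxis, pd.DataFrame]:
    """Render the phantom.

    Returns ``(stack, ground_truth_axis, ground_truth_profile)`` where the
    axis is the centerline projected to pixel coordinates and the profile
    table has columns ``s_um`` and ``dye_intensity`` along the centerline.
    """
    n_slices, h, w = geometry.image_shape
    px = geometry.pixel_size_xy
    pad = geometry.tube_outer_radius  # keep end ROIs on painted tube
    samples, s_axial, inside = _sample_centerline(geometry, pad=pad)

    # Nearest centerline sample for every pixel, in-plane.
    tree = cKDTree(samples[:, :2])
    margin = geometry.tube_outer_radius + 3.0 * geometry.psf_sigma
    x_lo = max(0, int(np.floor((samples[:, 0].min() - margin) / px)))
    x_hi = min(w - 1, int(np.ceil((samples[:, 0].max() + margin) / px)))
    y_lo = max(0, int(np.floor((samples[:, 1].min() - margin) / px)))
    y_hi = min(h - 1, int(np.ceil((samples[:, 1].max() + margin) / px)))
    yy, xx = np.mgrid[y_lo : y_hi + 1, x_lo : x_hi + 1]
    coords = np.column_stack([xx.ravel() * px, yy.ravel() * px])
    d_xy, idx = tree.query(coords, workers=-1)
    d_xy = d_xy.reshape(xx.shape)
    z_c = samples[idx, 2].reshape(xx.shape)
    s_pix = s_axial[idx].reshape(xx.shape)
    lumen_value = scenario.profile(s_pix)

    voxels = np.zeros((2, n_slices, h, w), dtype=np.float64)
    r_in = geometry.tube_inner_radius
    r_out = geometry.tube_outer_radius
    two_sf2 = 2.0 * geometry.wall_focus_sigma**2
    for k in range(n_slices):
        dz = k * geometry.z_interval - z_c
        rho2 = d_xy * d_xy + dz * dz
        wall = (rho2 >= r_in * r_in) & (rho2 <= r_out * r_out)
        lumen = rho2 < r_in * r_in
        gfp = np.where(wall, geometry.wall_intensity * np.exp(-(dz * dz) / two_sf2), 0.0)
        dye = np.where(lumen, lumen_value, 0.0)
        voxels[0, k, y_lo : y_hi + 1, x_lo : x_hi + 1] = gfp
        voxels[1, k, y_lo : y_hi + 1, x_lo : x_hi + 1] = dye

    if geometry.psf_sigma > 0:
        sig = (
            geometry.psf_sigma / geometry.z_interval,
            geometry.psf_sigma / px,
            geometry.psf_sigma / px,
        )
        for c in range(2):
            voxels[c] = gaussian_filter(voxels[c], sigma=sig)

    if geometry.noise_sd > 0:
        rng = np.random.default_rng(geometry.seed)
        voxels += rng.normal(0.0, geometry.noise_sd, size=voxels.shape)
    np.clip(voxels, 0.0, None, out=voxels)

    stack = ZStack(
        voxels=voxels,
        channel_labels=("GFP", "dye"),
        pixel_size_xy=px,
        z_interval=geometry.z_interval,
    )

    # Ground-truth axis: projected centerline (unpadded span) in pixel
    # coordinates, thinned to drop consecutive samples rounding to the same
    # pixel.
    verts_px = samples[inside, :2] / px
    rounded = np.floor(verts_px + 0.5).astype(int)
    keep = np.concatenate([[True], np.any(np.diff(rounded, axis=0) != 0, axis=1)])
    axis = PolylineAxis(verts_px[keep])

    truth = pd.DataFrame(
        {
            "s_um": s_axial[inside],
            "dye_intensity": scenario.profile(s_axial[inside]),
        }
    ).reset_index(drop=True)
    return stack, axis, truth


def make_study_case(
    scenario: str | TubeScenario,
    seed: int,
    image_shape: tuple = (40, 256, 256),
    **geometry_overrides,
) -> tuple[ZStack, PolylineAxis, pd.DataFrame, TubeGeometry, TubeScenario]:
    """A randomized phantom for one subject: per-seed jitter of the duct's
    lateral wiggle and z drift, with the scenario's profile unchanged.

    ``scenario`` is a key of ``SCENARIOS`` or an explicit ``TubeScenario``.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    n_slices, h, w = image_shape
    px = geometry_overrides.get("pixel_size_xy", 1.0)
    z_int = geometry_overrides.get("z_interval", 3.947)
    r_out = geometry_overrides.get("tube_outer_radius", 10.0)
    x = np.linspace(24.0, (w - 1) * px - 24.0, 4)
    y = (h - 1) * px / 2.0 + rng.uniform(-25.0, 25.0, size=4)
    # Gentle axial drift: the duct wanders by tens of um in depth over its
    # length, never steeply enough for the focus disk to straddle slices.
    z_max = (n_slices - 1) * z_int
    usable_lo, usable_hi = r_out + 2.0, z_max - r_out - 2.0
    if usable_hi <= usable_lo:
        raise GeometryError(f"stack of {n_slices} slices too shallow for the tube")
    amp = min(15.0, (usable_hi - usable_lo) / 4.0)
    z_mid = rng.uniform(usable_lo + amp, usable_hi - amp)
    z = z_mid + rng.uniform(-amp, amp, size=4)
    geometry = TubeGeometry(
        image_shape=image_shape,
        centerline_control_points=tuple(map(tuple, np.column_stack([x, y, z]))),
        seed=seed,
        **geometry_overrides,
    )
    stack, axis, truth = generate_tube_zstack(geometry, scenario)
    return stack, axis, truth, geometry, scenario


def generate_titration(
    params: BindingParams,
    protein0_grid: Sequence[float],
    dye_total_grid: Sequence[float],
    fi_free_unit: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Fluorescence titration from the exact mass-balance model.

    The full product of the two grids is generated.  The mode is inferred
    from which grid varies; ``noise_sd = 0`` gives exact model values, and
    a round trip through the binding fit then recovers the parameters.
    """
    p_grid = np.asarray(protein0_grid, dtype=float)
    d_grid = np.asarray(dye_total_grid, dtype=float)
    if np.any(p_grid < 0) or np.any(d_grid < 0):
        raise ValueError("concentrations must be nonnegative")
    pairs = np.array(list(itertools.product(p_grid, d_grid)))
    p0, lt = pairs[:, 0], pairs[:, 1]
    fi = np.asarray(predict_fluorescence(params, p0, lt, fi_free_unit), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fi = np.maximum(fi + rng.normal(0.0, noise_sd, size=fi.shape), 0.0)
    mode = VARY_PROTEIN if np.unique(d_grid).size == 1 else VARY_DYE
    return TitrationSeries(
        protein0=p0, dye_total=lt, fi=fi, mode=mode, fi_free_unit=fi_free_unit
    )


@dataclass
class EpgSimulation:
    """A synthetic electropherogram run: sample + co-run ladder."""

    sample: Trace
    ladder_trace: Trace
    ladder_peaks: list
    decay: PowerLawCalibration
    band_truth: pd.DataFrame  # mw_kda, amount, time_s


def _gaussian_peaks(
    time: np.ndarray, centers: np.ndarray, areas: np.ndarray, sigma: float
) -> np.ndarray:
    signal = np.zeros_like(time)
    norm = sigma * np.sqrt(2.0 * np.pi)
    for c, a in zip(centers, areas):
        signal += (a / norm) * np.exp(-((time - c) ** 2) / (2.0 * sigma**2))
    return signal


def generate_electropherogram(
    bands: Sequence[tuple],
    ladder: Sequence[tuple],
    decay_exponent: float = -0.5,
    seed: int = 0,
    decay_scale: float = 1.0,
    peak_sigma: float = 0.4,
    noise_sd: float = 0.0,
    time_pad: float = 5.0,
    dt: float = 0.02,
) -> EpgSimulation:
    """Synthesize sample and ladder traces with a detector falloff.

    Parameters
    ----------
    bands : sequence of (mw_kda, amount) for the sample.
    ladder : sequence of (mw_kda, amount, time_s); migration times must be
        strictly increasing with MW.
    decay_exponent, decay_scale : the falloff r(t) = decay_scale * t**
        decay_exponent.  Every true peak area ``amount`` is divided by
        r(t_peak) before painting, so time correction must multiply it back.

    Band migration times are interpolated from the ladder on the standard
    log(MW)-vs-time axis.
    """
    if len(ladder) == 0:
        raise ValueError("ladder must not be empty")
    lad = sorted(ladder, key=lambda p: p[0])
    mw_l = np.array([p[0] for p in lad], dtype=float)
    amt_l = np.array([p[1] for p in lad], dtype=float)
    t_l = np.array([p[2] for p in lad], dtype=float)
    if len(lad) > 1 and (np.any(np.diff(t_l) <= 0) or np.any(np.diff(mw_l) <= 0)):
        raise ValueError("ladder migration times must strictly increase with MW")

    decay = PowerLawCalibration(
        a=decay_scale, b=decay_exponent, t_min=float(t_l.min()), t_max=float(t_l.max())
    )
    time = np.arange(t_l.min() - time_pad, t_l.max() + time_pad + dt / 2, dt)

    if bands:
        mw_b = np.array([b[0] for b in bands], dtype=float)
        amt_b = np.array([b[1] for b in bands], dtype=float)
        t_b = np.interp(np.log(mw_b), np.log(mw_l), t_l)
    else:
        t_b = np.empty(0)
        amt_b = np.empty(0)

    sample_signal = _gaussian_peaks(time, t_b, amt_b / decay(np.maximum(t_b, dt)), peak_sigma)
    ladder_signal = _gaussian_peaks(time, t_l, amt_l / decay(t_l), peak_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sample_signal = np.maximum(sample_signal + rng.normal(0, noise_sd, time.shape), 0.0)
        ladder_signal = np.maximum(ladder_signal + rng.normal(0, noise_sd, time.shape), 0.0)

    peaks = [
        LadderPeak(
            mw_kda=float(mw),
            amount_ng=float(amt),
            time_s=float(t),
            raw_area=float(amt / decay(t)),
            corrected_area=float(amt),
        )
        for mw, amt, t in zip(mw_l, amt_l, t_l)
    ]
    return EpgSimulation(
        sample=Trace(time, sample_signal, label="sample"),
        ladder_trace=Trace(time, ladder_signal, label="ladder"),
        ladder_peaks=peaks,
        decay=decay,
        band_truth=pd.DataFrame({"mw_kda": [b[0] for b in bands],
                                 "amount": [b[1] for b in bands],
                                 "time_s": t_b}),
    )
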