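"""Transverse-localization analysis of exit-facet intensity images.

Implements the measurement chain used to characterize transverse Anderson
localization in nanostructured fibers: ensemble/azimuthally averaged
intensity profiles about the beam centroid, exponential-tail fits
``I ~ exp(-2|r|/xi)`` for the localization length xi, inversion of the
transverse-localization relation ``xi = l* exp(pi k_perp l*^2 / 2)``
(with ``k_perp = 2/omega_0``) for the transport mean free path l*,
hotspot FWHM extraction, and the ring-pattern image-transport demo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from . import bpm, fibergen
from .bpm import OpticalField, PropagationConfig, intensity_image, make_gaussian_beam

__all__ = [
    "IntensityProfile",
    "LocalizationFit",
    "TransportEstimate",
    "NotLocalizedError",
    "average_log_profile",
    "fit_localization_length",
    "invert_mean_free_path",
    "xi_sweep",
    "hotspot_fwhm",
    "transport_ring_image",
]


class NotLocalizedError(RuntimeError):
    """Profile has no decaying exponential tail (slope >= 0)."""


@dataclass
class IntensityProfile:
    r: np.ndarray
    I: np.ndarray
    averaging: Literal["azimuthal", "axis-cut"]
    n_realizations: int

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")
        if np.any(self.I < 0):
            raise ValueError("intensity must be non-negative")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.r, self.I]), delimiter=",",
                   header="r_um,intensity", comments="")

    @classmethod
    def from_csv(cls, path, averaging="azimuthal", n_realizations=1):
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1], averaging, n_realizations)


@dataclass
class LocalizationFit:
    xi: float
    window: tuple[float, float]
    slope_stderr: float
    xi_stderr: float
    r_squared: float


@dataclass
class TransportEstimate:
    l_star: float
    k_perp: float
    omega_0: float
    xi: float


def _centroid(img: np.ndarray) -> tuple[float, float]:
    tot = img.sum()
    n = img.shape[0]
    idx = np.arange(n)
    cy = (img.sum(axis=1) * idx).sum() / tot
    cx = (img.sum(axis=0) * idx).sum() / tot
    return cy, cx


def _radial_average(
    img: np.ndarray, spacing: float, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    n = img.shape[0]
    y, x = np.indices(img.shape)
    r = np.hypot(y - center[0], x - center[1]) * spacing
    nbins = n // 2
    edges = np.arange(nbins + 1) * spacing
    which = np.clip(np.digitize(r.ravel(), edges) - 1, 0, nbins - 1)
    sums = np.bincount(which, weights=img.ravel(), minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    # mean pixel radius per bin, not the bin center: thin annuli on a square
    # lattice have a clustered radius distribution that would bias the profile
    r_sums = np.bincount(which, weights=r.ravel(), minlength=nbins)
    ok = counts > 0
    return r_sums[ok] / counts[ok], sums[ok] / counts[ok]


def average_log_profile(
    images: Sequence[np.ndarray],
    grid_spacing: float,
    averaging: Literal["azimuthal", "axis-cut"] = "azimuthal",
) -> IntensityProfile:
    """Ensemble-averaged radial intensity profile about per-image centroids.

    Linear intensities are averaged (over azimuth for ``azimuthal``, over
    the folded horizontal cut through the centroid for ``axis-cut``) and
    over realizations; the logarithm is for the caller to take when
    fitting, which matches plotting log(<I>) rather than <log I>.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    shape = np.asarray(images[0]).shape
    acc = None
    for img in images:
        img = np.asarray(img, dtype=float)
        if img.shape != shape:
            raise ValueError("images must share a common grid")
        if img.sum() <= 0:
            raise ValueError("all-zero image cannot be profiled")
        cy, cx = _centroid(img)
        if averaging == "azimuthal":
            r, prof = _radial_average(img, grid_spacing, (cy, cx))
        elif averaging == "axis-cut":
            row = img[int(round(cy))]
            x = (np.arange(shape[1]) - cx) * grid_spacing
            nbins = shape[1] // 2
            edges = np.arange(nbins + 1) * grid_spacing
            which = np.clip(np.digitize(np.abs(x), edges) - 1, 0, nbins - 1)
            sums = np.bincount(which, weights=row, minlength=nbins)
            counts = np.bincount(which, minlength=nbins)
            ok = counts > 0
            r = (0.5 * (edges[:-1] + edges[1:]))[ok]
            prof = sums[ok] / counts[ok]
        else:
            raise ValueError(f"unknown averaging {averaging!r}")
        acc = prof if acc is None else acc[: len(prof)] + prof[: len(acc)]
        r_common = r
    nmin = len(acc)
    return IntensityProfile(
        r=r_common[:nmin], I=acc / len(images), averaging=averaging,
        n_realizations=len(images),
    )


def default_fit_window(profile: IntensityProfile) -> tuple[float, float]:
    """Tail window: from where I falls to 10% of peak out to 10x the floor.

    The noise floor is taken as the median intensity over the outer 10% of
    the radial range (clipped away from zero).
    """
    I = profile.I
    peak = I.max()
    tail = I[int(0.9 * len(I)):]
    floor = max(float(np.median(tail)), peak * 1e-12)
    below = np.nonzero(I <= 0.1 * peak)[0]
    r_min = profile.r[below[0]] if len(below) else profile.r[len(I) // 4]
    above_floor = np.nonzero(I >= 10.0 * floor)[0]
    r_max = profile.r[above_floor[-1]] if len(above_floor) else profile.r[-1]
    if r_max <= r_min:  # degenerate (e.g. noiseless profile): use full tail
        r_max = profile.r[-1]
    return float(r_min), float(r_max)


def fit_localization_length(
    profile: IntensityProfile,
    window: tuple[float, float] | None = None,
) -> LocalizationFit:
    """Least-squares line on (r, ln I) over the tail window; xi = -2/slope."""
    if window is None:
        window = default_fit_window(profile)
    r_min, r_max = window
    sel = (profile.r >= r_min) & (profile.r <= r_max) & (profile.I > 0)
    if sel.sum() < 10:
        raise ValueError(
            f"fit window [{r_min:.3g}, {r_max:.3g}] um holds only "
            f"{int(sel.sum())} positive samples (need >= 10)"
        )
    r = profile.r[sel]
    logI = np.log(profile.I[sel])
    res = stats.linregress(r, logI)
    if res.slope >= 0:
        raise NotLocalizedError(
            f"profile does not decay over [{r_min:.3g}, {r_max:.3g}] um "
            f"(slope {res.slope:+.3g} per um)"
        )
    xi = -2.0 / res.slope
    xi_err = 2.0 * res.stderr / res.slope**2
    return LocalizationFit(
        xi=float(xi),
        window=(float(r_min), float(r_max)),
        slope_stderr=float(res.stderr),
        xi_stderr=float(xi_err),
        r_squared=float(res.rvalue**2),
    )


def forward_xi(l_star: float, omega_0: float) -> float:
    """xi = l* exp(pi k_perp l*^2 / 2) with k_perp = 2/omega_0."""
    k_perp = 2.0 / omega_0
    return l_star * math.exp(math.pi * k_perp * l_star**2 / 2.0)


def invert_mean_free_path(xi: float, omega_0: float) -> TransportEstimate:
    """Solve the strictly increasing map l* -> l* exp(pi k_perp l*^2/2) = xi.

    Bracketed root-finding to 1e-9 relative; the map is a bijection of
    (0, inf) onto itself so the root is unique.
    """
    if xi <= 0 or omega_0 <= 0:
        raise ValueError("xi and omega_0 must be positive")
    k_perp = 2.0 / omega_0
    hi = min(xi, math.sqrt(2.0 * math.log(max(xi, 2.0)) / (math.pi * k_perp)) + 1.0)
    while forward_xi(hi, omega_0) < xi:
        hi *= 2.0
    l = optimize.brentq(
        lambda l: forward_xi(l, omega_0) - xi, 1e-300, hi, xtol=1e-15, rtol=1e-12
    )
    est = TransportEstimate(l_star=float(l), k_perp=k_perp, omega_0=omega_0, xi=xi)
    assert abs(forward_xi(est.l_star, omega_0) - xi) <= 1e-9 * xi
    return est


def _ensemble_exit_images(
    lengths: Sequence[float],
    wavelength: float,
    n_seeds: int,
    base_seed: int,
    density: float,
    fiber_radius: float,
    omega_0: float,
    size_range: tuple[float, float],
    step_dz: float,
    n_matrix: float,
) -> dict[float, list[np.ndarray]]:
    """Propagate an ensemble once to max(lengths), snapshotting each length."""
    lengths = sorted(lengths)
    spacing = min(
        bpm.default_grid_spacing(wavelength, n_matrix),
        fibergen.max_raster_spacing(size_range),
    )
    images: dict[float, list[np.ndarray]] = {L: [] for L in lengths}
    for s in range(n_seeds):
        seed = int(np.random.default_rng([base_seed, s]).integers(0, 2**31 - 1))
        pop = fibergen.sample_void_population(
            density=density, size_range=size_range, fiber_radius=fiber_radius,
            seed=seed,
        )
        cs = fibergen.rasterize_cross_section(
            pop, grid_spacing=spacing, n_matrix=n_matrix,
            margin=2.0 + 5 * wavelength,
        )
        npix = cs.index_map.shape[0]
        beam = make_gaussian_beam(omega_0, (0.0, 0.0), wavelength, spacing, npix)
        cfg = PropagationConfig(
            step_dz=step_dz, total_length=lengths[-1],
            boundary_width=5 * wavelength, reference_index=n_matrix,
            snapshot_every=step_dz,
        )
        z_prev = 0.0
        fld = beam
        for L in lengths:
            cfg_seg = PropagationConfig(
                step_dz=step_dz, total_length=L - z_prev,
                boundary_width=cfg.boundary_width, reference_index=n_matrix,
                single_precision=True,
            )
            if L > z_prev:
                try:
                    fld, _ = bpm.propagate(fld, cs, cfg_seg)
                except ValueError as exc:
                    raise ValueError(
                        f"propagation refused at L={L} um, lambda={wavelength} "
                        f"um, seed={seed}: {exc}"
                    ) from exc
            images[L].append(intensity_image(fld))
            z_prev = L
    return images


def xi_sweep(
    lengths: Sequence[float],
    wavelengths: Sequence[float],
    n_seeds: int = 8,
    base_seed: int = 0,
    density: float = 2.2,
    fiber_radius: float = 10.0,
    omega_0: float = 2.0,
    size_range: tuple[float, float] = fibergen.DEFAULT_SIZE_RANGE,
    step_dz: float = 0.1,
    n_matrix: float = fibergen.N_FIBROIN,
    per_seed: bool = False,
) -> pd.DataFrame:
    """Fit xi for each (fiber length, wavelength) over a disorder ensemble.

    For each wavelength the same ensemble of void populations (derived from
    ``base_seed``) is propagated once to the longest length with the exit
    field captured at every requested length.  By default the linear
    intensities are ensemble- and azimuthally averaged before the tail fit
    (one row per (L, lambda)); with ``per_seed`` each realization is fitted
    separately (one row per (L, lambda, seed)), which is the estimator used
    for ensemble-mean xi trends.  The fit window is capped at the fiber
    radius: beyond the rim the image is absorber-shaped background, not a
    localization tail.
    """
    if not lengths or not wavelengths:
        raise ValueError("lengths and wavelengths must be non-empty")
    rows = []

    def _fit_row(profile, L, lam, seed):
        r_lo, r_hi = default_fit_window(profile)
        window = (r_lo, min(r_hi, fiber_radius))
        base = dict(L_um=L, lambda_um=lam, seed=seed, n_seeds=n_seeds)
        try:
            fit = fit_localization_length(profile, window=window)
            return dict(base, xi_um=fit.xi, xi_stderr=fit.xi_stderr,
                        r2=fit.r_squared)
        except (NotLocalizedError, ValueError):
            return dict(base, xi_um=np.nan, xi_stderr=np.nan, r2=np.nan)

    for lam in wavelengths:
        images = _ensemble_exit_images(
            lengths, lam, n_seeds, base_seed, density, fiber_radius, omega_0,
            size_range, step_dz, n_matrix,
        )
        spacing = min(
            bpm.default_grid_spacing(lam, n_matrix),
            fibergen.max_raster_spacing(size_range),
        )
        for L in sorted(lengths):
            if per_seed:
                for s, img in enumerate(images[L]):
                    prof = average_log_profile([img], spacing)
                    rows.append(_fit_row(prof, L, lam, s))
            else:
                prof = average_log_profile(images[L], spacing)
                rows.append(_fit_row(prof, L, lam, base_seed))
    return pd.DataFrame(rows)


def width_vs_z_ensemble(
    mode: str,
    n_seeds: int = 20,
    L: float = 150.0,
    snapshot_every: float = 25.0,
    wavelength: float = 0.6,
    density: float = 2.2,
    fiber_radius: float = 10.0,
    omega_0: float = 2.0,
    size_range: tuple[float, float] = fibergen.DEFAULT_SIZE_RANGE,
    step_dz: float = 0.1,
    decorrelation_dz: float = 5.0,
    base_seed: int = 0,
    n_matrix: float = fibergen.N_FIBROIN,
) -> pd.DataFrame:
    """Ensemble-mean beam width vs propagation distance for one disorder mode.

    The diffusive-vs-localized dichotomy: with longitudinally ``invariant``
    filamentary voids the mean-square beam width saturates at the
    localization scale, while z-decorrelated ``particulate`` voids (planes
    resampled every ``decorrelation_dz``) keep the spread growing.  Returns
    a tidy table (mode, seed, z_um, width_um).
    """
    spacing = min(
        bpm.default_grid_spacing(wavelength, n_matrix),
        fibergen.max_raster_spacing(size_range),
    )
    rows = []
    for s in range(n_seeds):
        seed = int(np.random.default_rng([base_seed, s]).integers(0, 2**31 - 1))
        pop = fibergen.sample_void_population(
            density=density, size_range=size_range, fiber_radius=fiber_radius,
            seed=seed,
        )
        cs = fibergen.rasterize_cross_section(
            pop, grid_spacing=spacing, n_matrix=n_matrix,
            margin=2.0 + 5 * wavelength,
        )
        if mode == "invariant":
            medium = cs
        else:
            z_planes = np.arange(0.0, L, decorrelation_dz)
            medium = fibergen.longitudinal_index_sequence(
                cs, mode, z_positions=z_planes, seed=seed
            )
        beam = make_gaussian_beam(
            omega_0, (0.0, 0.0), wavelength, spacing, cs.index_map.shape[0]
        )
        cfg = PropagationConfig(
            step_dz=step_dz, total_length=L, boundary_width=5 * wavelength,
            reference_index=n_matrix, snapshot_every=snapshot_every,
            single_precision=True,
        )
        _, snaps = bpm.propagate(beam, medium, cfg)
        rows.append(dict(mode=mode, seed=s, z_um=0.0, width_um=bpm.beam_width(beam)))
        for snap in snaps:
            rows.append(
                dict(mode=mode, seed=s, z_um=snap.z, width_um=bpm.beam_width(snap))
            )
    return pd.DataFrame(rows)


def hotspot_fwhm(
    image: np.ndarray, grid_spacing: float, smooth_px: float = 1.0
) -> tuple[float, tuple[float, float]]:
    """FWHM (μm) of the azimuthally averaged hotspot profile.

    The hotspot is the global maximum of the lightly smoothed image; the
    half-maximum radius is located by linear interpolation between the
    bracketing radial samples.  A plateau maximum (several pixels tied at
    the top after smoothing) raises an ambiguity error.
    """
    img = np.asarray(image, dtype=float)
    sm = ndimage.gaussian_filter(img, smooth_px) if smooth_px else img
    peak = sm.max()
    if peak <= 0:
        raise ValueError("image has no positive maximum")
    tied = np.argwhere(sm >= peak * (1.0 - 1e-9))
    if len(tied) > 1 and np.ptp(tied, axis=0).max() > 2:
        raise ValueError("plateau maximum: hotspot center is ambiguous")
    cy, cx = map(int, tied[0])
    r, prof = _radial_average(img, grid_spacing, (float(cy), float(cx)))
    # anchor the profile at the true peak value so binning does not bias FWHM
    r = np.concatenate([[0.0], r])
    prof = np.concatenate([[img[cy, cx]], prof])
    half = prof[0] / 2.0
    below = np.nonzero(prof <= half)[0]
    if len(below) == 0:
        raise ValueError("profile never falls to half maximum inside the grid")
    j = below[0]
    if j == 0:
        r_half = r[0]
    else:
        f = (prof[j - 1] - half) / (prof[j - 1] - prof[j])
        r_half = r[j - 1] + f * (r[j] - r[j - 1])
    half_extent = img.shape[0] * grid_spacing / 2.0
    center = (
        (cx + 0.5) * grid_spacing - half_extent,
        (cy + 0.5) * grid_spacing - half_extent,
    )
    return float(2.0 * r_half), center


def ring_aperture_mask(
    npix: int,
    spacing: float,
    aperture_diameter: float,
    ring_diameter: float,
    n_apertures: int,
) -> np.ndarray:
    x = (np.arange(npix) + 0.5) * spacing - npix * spacing / 2
    xx, yy = np.meshgrid(x, x)
    mask = np.zeros((npix, npix))
    R = ring_diameter / 2.0
    a = aperture_diameter / 2.0
    for k in range(n_apertures):
        phi = 2.0 * math.pi * k / n_apertures
        mask[(xx - R * math.cos(phi)) ** 2 + (yy - R * math.sin(phi)) ** 2 <= a**2] = 1.0
    return mask


def ring_contrast(
    image: np.ndarray,
    spacing: float,
    ring_diameter: float,
    aperture_diameter: float,
    fiber_radius: float,
) -> float:
    """(mean I in the ring annulus - mean I elsewhere in the fiber) / sum.

    The annulus half-width is one aperture diameter (total width 2x), per
    the analysis convention; the score lies in [-1, 1].
    """
    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    x = (np.arange(n) + 0.5) * spacing - n * spacing / 2
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx, yy)
    R = ring_diameter / 2.0
    w = aperture_diameter
    ring = np.abs(r - R) <= w
    inside = (r <= fiber_radius) & ~ring
    m_ring = img[ring].mean() if ring.any() else 0.0
    m_rest = img[inside].mean() if inside.any() else 0.0
    denom = m_ring + m_rest
    if denom <= 0:
        return 0.0
    return float((m_ring - m_rest) / denom)


def transport_ring_image(
    aperture_diameter: float,
    ring_diameter: float,
    n_apertures: int,
    medium,
    L: float,
    wavelength: float,
    fiber_radius: float,
    step_dz: float = 0.1,
    n_matrix: float = fibergen.N_FIBROIN,
    single_precision: bool = False,
) -> tuple[np.ndarray, float]:
    """Transport a ring of small apertures through the fiber (image demo).

    A wide uniform-phase beam illuminates the aperture mask butt-coupled to
    the entrance facet; the exit intensity and its ring-contrast score are
    returned.  At L = 0 the mask intensity itself is returned.
    """
    if ring_diameter / 2.0 + aperture_diameter > fiber_radius:
        raise ValueError("ring does not fit inside the fiber")
    planes = [medium] if isinstance(medium, fibergen.FiberCrossSection) else list(medium)
    cs0 = planes[0]
    npix = cs0.index_map.shape[0]
    spacing = cs0.grid_spacing
    mask = ring_aperture_mask(
        npix, spacing, aperture_diameter, ring_diameter, n_apertures
    )
    amp = mask.astype(np.complex128)
    p = np.sum(np.abs(amp) ** 2) * spacing**2
    if p <= 0:
        raise ValueError("aperture mask is empty on this grid")
    amp /= math.sqrt(p)
    fld = OpticalField(amp, wavelength, spacing, z=0.0)
    if L <= 0:
        img = intensity_image(fld)
    else:
        cfg = PropagationConfig(
            step_dz=step_dz, total_length=L, boundary_width=5 * wavelength,
            reference_index=n_matrix, single_precision=single_precision,
        )
        fld, _ = bpm.propagate(fld, medium, cfg)
        img = intensity_image(fld)
    score = ring_contrast(img, spacing, ring_diameter, aperture_diameter, fiber_radius)
    return img, score
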