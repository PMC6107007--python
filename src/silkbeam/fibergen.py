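"""Synthetic fiber cross-sections with filamentary or particulate air voids.

The generator emulates the void morphology measured in comet-moth cocoon
fibers and their biomimetic (regenerated silk, PVDF) counterparts: a high
areal density of irregular air voids distributed over the fiber disk
(2.2 voids/μm² for the natural fiber, 5.5 and 17 voids/μm² for the
biomimetic ones), void extents from a couple hundred nanometers up to about
a micron, smaller voids toward the fiber edge and larger ones toward the
center, and an optional void-free sericin band where two fibers join.

Voids are modeled as ellipses (eccentricity up to 0.6) placed by seeded
dart-throwing with strict non-overlap of their bounding circles.  A
cross-section can be extruded along the fiber axis as longitudinally
invariant filaments, slowly morphing filaments, or independently resampled
particulate voids.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VoidSpec",
    "VoidPopulation",
    "FiberCrossSection",
    "PackingError",
    "sample_void_population",
    "rasterize_cross_section",
    "longitudinal_index_sequence",
]

#: default semi-major-axis range (μm): void extents of 0.26–0.8 μm, matching
#: the "hundreds of nanometers to about a micron" scale seen in micrographs
DEFAULT_SIZE_RANGE = (0.13, 0.4)

#: literature real index of silk fibroin in the visible
N_FIBROIN = 1.54
N_AIR = 1.0

_MAX_ATTEMPTS = 10_000


def max_raster_spacing(
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE,
    max_eccentricity: float = 0.6,
) -> float:
    """Coarsest grid spacing that still resolves the smallest ellipse semi-axis."""
    return size_range[0] * math.sqrt(1.0 - max_eccentricity**2)


class PackingError(RuntimeError):
    """Raised when dart-throwing cannot place the requested void density."""

    def __init__(self, requested: float, achieved: float, placed: int):
        self.requested_density = requested
        self.achieved_density = achieved
        self.placed = placed
        super().__init__(
            f"void packing failed: requested {requested:.3g} voids/um^2 but only "
            f"achieved {achieved:.3g} voids/um^2 ({placed} voids placed)"
        )


@dataclass(frozen=True)
class VoidSpec:
    """A single elliptical void in fiber-axis-centered coordinates (μm)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    kind: Literal["filamentary", "particulate"] = "filamentary"

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")

    @property
    def bounding_radius(self) -> float:
        return max(self.semi_axes)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-ellipse test."""
        dx = x - self.center[0]
        dy = y - self.center[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class VoidPopulation:
    voids: tuple[VoidSpec, ...]
    fiber_radius: float
    density: float
    seed: int
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE

    def __len__(self) -> int:
        return len(self.voids)

    @property
    def realized_density(self) -> float:
        return len(self.voids) / (math.pi * self.fiber_radius**2)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fiber_radius_um": self.fiber_radius,
                "density_per_um2": self.density,
                "seed": self.seed,
                "size_range_um": list(self.size_range),
                "voids": [
                    {
                        "center_um": list(v.center),
                        "semi_axes_um": list(v.semi_axes),
                        "orientation_rad": v.orientation,
                        "kind": v.kind,
                    }
                    for v in self.voids
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "VoidPopulation":
        d = json.loads(text)
        voids = tuple(
            VoidSpec(
                center=tuple(v["center_um"]),
                semi_axes=tuple(v["semi_axes_um"]),
                orientation=v["orientation_rad"],
                kind=v["kind"],
            )
            for v in d["voids"]
        )
        return cls(
            voids=voids,
            fiber_radius=d["fiber_radius_um"],
            density=d["density_per_um2"],
            seed=d["seed"],
            size_range=tuple(d["size_range_um"]),
        )


@dataclass
class FiberCrossSection:
    """Rasterized complex refractive-index map of one transverse slice.

    The grid is square with pixel centers at ``(i + 0.5) * grid_spacing``
    offsets from the lower-left corner; the fiber axis pierces the grid
    center.
    """

    index_map: np.ndarray
    grid_spacing: float
    extent: tuple[float, float]
    population: VoidPopulation
    n_matrix: complex = N_FIBROIN
    n_void: complex = N_AIR
    n_background: complex = N_AIR
    sericin_band: tuple[float, float, float, float] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.index_map.shape

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Center-origin pixel-center coordinate arrays (x varies on axis 1)."""
        ny, nx = self.index_map.shape
        x = (np.arange(nx) + 0.5) * self.grid_spacing - self.extent[0] / 2
        y = (np.arange(ny) + 0.5) * self.grid_spacing - self.extent[1] / 2
        return np.meshgrid(x, y)


class _CellGrid:
    """Uniform hash grid for neighbor queries during dart throwing.

    Cell size is 2*max_semi_axis, so any conflicting partner (center
    distance <= r + r_other <= cell) lies in the 3x3 cell neighborhood.
    Cells store (x, y, r) triples under a composite integer key.
    """

    _SHIFT = 1 << 32

    def __init__(self, radius: float, cell: float):
        self.inv_cell = 1.0 / cell
        self.cells: dict[int, list[tuple[float, float, float]]] = {}

    def conflicts(self, x: float, y: float, r: float) -> bool:
        kx = int(math.floor(x * self.inv_cell))
        ky = int(math.floor(y * self.inv_cell))
        get = self.cells.get
        shift = self._SHIFT
        for i in (kx - 1, kx, kx + 1):
            base = i * shift + ky
            for key in (base - 1, base, base + 1):
                bucket = get(key)
                if bucket:
                    for cx, cy, cr in bucket:
                        if (cx - x) ** 2 + (cy - y) ** 2 <= (r + cr) ** 2:
                            return True
        return False

    def add(self, x: float, y: float, r: float) -> None:
        key = (
            int(math.floor(x * self.inv_cell)) * self._SHIFT
            + int(math.floor(y * self.inv_cell))
        )
        self.cells.setdefault(key, []).append((x, y, r))


def sample_void_population(
    density: float,
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE,
    fiber_radius: float = 20.0,
    radial_sorting: bool = True,
    seed: int = 0,
    kind: Literal["filamentary", "particulate"] = "filamentary",
    max_eccentricity: float = 0.6,
) -> VoidPopulation:
    """Draw a non-overlapping random void population for one fiber.

    The void count is Poisson with mean ``density * pi * fiber_radius**2``.
    With ``radial_sorting`` the mean semi-major axis ramps linearly from the
    top of ``size_range`` at the fiber center down to the bottom at the edge,
    reproducing the observed small-at-the-edge / large-at-the-center trend.
    Placement is dart-throwing with strict non-overlap of bounding circles,
    largest voids first; a position that cannot be placed within 10^4
    attempts raises :class:`PackingError` naming the achieved density.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    smin, smax = size_range
    if not (0 < smin <= smax):
        raise ValueError("size_range must satisfy 0 < min <= max")
    if fiber_radius <= 0:
        raise ValueError("fiber_radius must be > 0")

    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density * math.pi * fiber_radius**2))
    if n == 0:
        return VoidPopulation((), fiber_radius, density, seed, size_range)

    # radial positions drawn area-uniformly over the disk
    radial = fiber_radius * np.sqrt(rng.uniform(size=n))
    if radial_sorting:
        mean_size = smax - (smax - smin) * radial / fiber_radius
        sizes = rng.normal(mean_size, (smax - smin) / 4.0)
        sizes = np.clip(sizes, smin, smax)
    else:
        sizes = rng.uniform(smin, smax, size=n)
    ecc = rng.uniform(0.0, max_eccentricity, size=n)
    minor = sizes * np.sqrt(1.0 - ecc**2)
    theta = rng.uniform(0.0, math.pi, size=n)

    # place largest first: helps packing and keeps big voids near the center
    order = np.argsort(-sizes)
    grid = _CellGrid(fiber_radius, cell=2.0 * smax)
    voids: list[VoidSpec] = []
    for k, idx in enumerate(order):
        a = float(sizes[idx])
        r_target = float(radial[idx])
        placed = False
        attempt = 0
        while attempt < _MAX_ATTEMPTS:
            # draw candidate positions in batches; keep the dart's radial
            # coordinate (it encodes the size ramp) and jitter it
            # progressively if the annulus is crowded
            batch = min(128, _MAX_ATTEMPTS - attempt)
            jitter = min(attempt / 1000.0, 1.0) * fiber_radius * 0.5
            rr = np.abs(
                r_target
                + rng.normal(0.0, 0.05 * fiber_radius + jitter, size=batch)
            )
            np.minimum(rr, fiber_radius - a, out=rr)
            phi = rng.uniform(0.0, 2.0 * math.pi, size=batch)
            xs = rr * np.cos(phi)
            ys = rr * np.sin(phi)
            for x, y, r_c in zip(xs, ys, rr):
                if r_c + a > fiber_radius or grid.conflicts(x, y, a):
                    continue
                grid.add(x, y, a)
                voids.append(
                    VoidSpec(
                        center=(float(x), float(y)),
                        semi_axes=(a, float(minor[idx])),
                        orientation=float(theta[idx]),
                        kind=kind,
                    )
                )
                placed = True
                break
            if placed:
                break
            attempt += batch
        if not placed:
            achieved = len(voids) / (math.pi * fiber_radius**2)
            raise PackingError(density, achieved, len(voids))
    return VoidPopulation(tuple(voids), fiber_radius, density, seed, size_range)


def rasterize_cross_section(
    population: VoidPopulation,
    grid_spacing: float,
    n_matrix: complex = N_FIBROIN,
    n_void: complex = N_AIR,
    n_background: complex = N_AIR,
    sericin_band: tuple[float, float, float, float] | None = None,
    margin: float = 2.0,
    extent: float | None = None,
) -> FiberCrossSection:
    """Discretize a void population onto a complex refractive-index grid.

    A pixel takes ``n_void`` iff its center lies inside some void ellipse;
    the rest of the fiber disk is ``n_matrix``; everything outside the disk
    is ``n_background``.  ``sericin_band`` (x0, x1, y0, y1 in μm) is forced
    to ``n_matrix`` regardless of voids, emulating the void-free sericin
    region where two fibers join.
    """
    if population.voids:
        min_semi = min(min(v.semi_axes) for v in population.voids)
        if grid_spacing > min_semi:
            raise ValueError(
                f"grid_spacing {grid_spacing:.3g} um too coarse: must be <= "
                f"smallest void semi-axis {min_semi:.3g} um"
            )
    if margin < 2.0:
        raise ValueError("need >= 2 um of background margin around the fiber")
    if extent is None:
        extent = 2.0 * (population.fiber_radius + margin)
    elif extent < 2.0 * (population.fiber_radius + 2.0):
        raise ValueError("extent leaves < 2 um of margin around the fiber")
    npix = int(round(extent / grid_spacing))
    from scipy.fft import next_fast_len  # FFT-friendly grid for the BPM engine

    npix = next_fast_len(npix)
    extent = npix * grid_spacing

    x = (np.arange(npix) + 0.5) * grid_spacing - extent / 2
    xx, yy = np.meshgrid(x, x)
    index_map = np.full((npix, npix), complex(n_background), dtype=np.complex128)
    inside = xx**2 + yy**2 <= population.fiber_radius**2
    index_map[inside] = complex(n_matrix)

    for v in population.voids:
        rb = v.bounding_radius
        i0 = max(0, int((v.center[0] - rb + extent / 2) / grid_spacing) - 1)
        i1 = min(npix, int((v.center[0] + rb + extent / 2) / grid_spacing) + 2)
        j0 = max(0, int((v.center[1] - rb + extent / 2) / grid_spacing) - 1)
        j1 = min(npix, int((v.center[1] + rb + extent / 2) / grid_spacing) + 2)
        sub = v.contains(xx[j0:j1, i0:i1], yy[j0:j1, i0:i1])
        index_map[j0:j1, i0:i1][sub] = complex(n_void)

    if sericin_band is not None:
        x0, x1, y0, y1 = sericin_band
        band = (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
        index_map[band] = complex(n_matrix)

    return FiberCrossSection(
        index_map=index_map,
        grid_spacing=grid_spacing,
        extent=(extent, extent),
        population=population,
        n_matrix=complex(n_matrix),
        n_void=complex(n_void),
        n_background=complex(n_background),
        sericin_band=sericin_band,
    )


def longitudinal_index_sequence(
    cross_section: FiberCrossSection,
    mode: Literal["invariant", "morphing", "particulate"],
    z_positions: Sequence[float],
    correlation_length: float = 50.0,
    seed: int = 0,
) -> list[FiberCrossSection]:
    """Extrude a cross-section along the fiber axis.

    invariant
        Filamentary voids: the identical map at every z (the comet-moth
        case — voids persist for at least tens of microns unchanged).
    morphing
        Void centers perform a seeded 2D random walk in z whose rms
        transverse displacement reaches one mean void semi-axis after
        ``correlation_length`` of propagation (slow morphing of real
        filaments); sizes stay fixed.
    particulate
        An independent population with the same statistics at every plane
        (3D voids of the regenerated-silk control).
    """
    z = np.asarray(list(z_positions), dtype=float)
    if len(z) == 0:
        raise ValueError("z_positions must be non-empty")
    if mode == "invariant":
        return [cross_section] * len(z)

    pop = cross_section.population
    raster_kw = dict(
        grid_spacing=cross_section.grid_spacing,
        n_matrix=cross_section.n_matrix,
        n_void=cross_section.n_void,
        n_background=cross_section.n_background,
        sericin_band=cross_section.sericin_band,
        extent=cross_section.extent[0],
    )
    if mode == "morphing":
        if correlation_length <= 0:
            raise ValueError("correlation_length must be > 0 for morphing mode")
        rng = np.random.default_rng(seed)
        amp = float(np.mean([v.semi_axes[0] for v in pop.voids])) if pop.voids else 0.0
        out = [cross_section]
        centers = np.array([v.center for v in pop.voids], dtype=float)
        for dz in np.diff(z):
            sigma = amp * math.sqrt(abs(dz) / correlation_length)
            centers = centers + rng.normal(0.0, sigma, size=centers.shape)
            voids = tuple(
                replace(v, center=(float(cx), float(cy)))
                for v, (cx, cy) in zip(pop.voids, centers)
            )
            out.append(
                rasterize_cross_section(replace(pop, voids=voids), **raster_kw)
            )
        return out
    if mode == "particulate":
        out = []
        for i in range(len(z)):
            child = np.random.default_rng([seed, i]).integers(0, 2**31 - 1)
            p = sample_void_population(
                density=pop.density,
                size_range=pop.size_range,
                fiber_radius=pop.fiber_radius,
                radial_sorting=True,
                seed=int(child),
                kind="particulate",
            )
            out.append(rasterize_cross_section(p, **raster_kw))
        return out
    raise ValueError(f"unknown mode {mode!r}")
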