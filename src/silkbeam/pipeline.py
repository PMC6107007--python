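"""End-to-end orchestration: config handling, staged runs, manifests, fixtures.

A run is fully determined by (config, seed): every stochastic stage derives
its effective seed from the global seed, the manifest records the config
hash, per-stage seeds, and a checksum for every artifact so reruns are
byte-reproducible (timestamps excluded by design).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import bpm, fibergen, localization, radiometry, tof

__all__ = [
    "RunConfig",
    "run_localization_experiment",
    "run_radiometry",
    "make_fixtures",
    "save_cross_section_h5",
    "load_cross_section_h5",
    "write_pgm",
]

_DEFAULTS: dict[str, dict[str, Any]] = {
    "global": {"seed": 0, "outdir": "runs", "verbosity": 1},
    "fibergen": {
        "density": 2.2,
        "fiber_radius": 10.0,
        "size_min": 0.13,
        "size_max": 0.4,
        "radial_sorting": True,
        "n_matrix": 1.54,
        "n_void": 1.0,
        "n_background": 1.0,
    },
    "bpm": {
        "omega_0": 2.0,
        "wavelength": 0.6,
        "step_dz": 0.1,
        "grid_spacing": 0.0,  # 0 -> lambda/(4 n_matrix)
    },
    "localization": {
        "lengths": [100.0],
        "wavelengths": [0.6],
        "n_seeds": 3,
    },
    "radiometry": {
        "temperature": 300.0,
        "solar_lo": 0.4,
        "solar_hi": 2.5,
        "thermal_lo": 2.5,
        "thermal_hi": 25.0,
    },
    "tof": {"irf_fwhm": 100.0, "tau": 210.0, "t_range": 4000.0, "dt": 2.0, "snr": 50.0},
}


@dataclass
class RunConfig:
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self):
        merged = {k: dict(v) for k, v in _DEFAULTS.items()}
        for sec, vals in self.sections.items():
            merged.setdefault(sec, {}).update(vals)
        self.sections = merged

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def get(self, section: str, key: str):
        return self.sections[section][key]

    def override(self, section: str, key: str, value) -> None:
        self.sections.setdefault(section, {})[key] = value

    def to_json(self) -> str:
        return json.dumps(self.sections, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @property
    def seed(self) -> int:
        return int(self.get("global", "seed"))


def _child_seed(base: int, *tags: int) -> int:
    return int(np.random.default_rng([base, *tags]).integers(0, 2**31 - 1))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, seeds: dict, files: list[Path]):
    manifest = {
        "config_hash": config.config_hash,
        "config": config.sections,
        "seeds": seeds,
        "artifacts": {p.name: _checksum(p) for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def write_pgm(path: str | Path, image: np.ndarray) -> None:
    """Plain-text (P2) PGM preview of a non-negative 2D array."""
    img = np.asarray(image, dtype=float)
    mx = img.max() if img.max() > 0 else 1.0
    pix = np.round(img / mx * 255).astype(int)
    lines = [f"P2\n{img.shape[1]} {img.shape[0]}\n255"]
    lines += [" ".join(map(str, row)) for row in pix]
    Path(path).write_text("\n".join(lines) + "\n")


def save_cross_section_h5(path: str | Path, cs: fibergen.FiberCrossSection) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("index_map_real", data=cs.index_map.real)
        fh.create_dataset("index_map_imag", data=cs.index_map.imag)
        fh.attrs["grid_spacing_um"] = cs.grid_spacing
        fh.attrs["extent_um"] = cs.extent
        fh.attrs["seed"] = cs.population.seed
        fh.attrs["n_matrix"] = complex(cs.n_matrix)
        fh.attrs["n_void"] = complex(cs.n_void)
        fh.attrs["n_background"] = complex(cs.n_background)
        fh.attrs["population_json"] = cs.population.to_json()


def load_cross_section_h5(path: str | Path) -> fibergen.FiberCrossSection:
    import h5py

    with h5py.File(path, "r") as fh:
        index_map = fh["index_map_real"][()] + 1j * fh["index_map_imag"][()]
        pop = fibergen.VoidPopulation.from_json(fh.attrs["population_json"])
        return fibergen.FiberCrossSection(
            index_map=index_map,
            grid_spacing=float(fh.attrs["grid_spacing_um"]),
            extent=tuple(fh.attrs["extent_um"]),
            population=pop,
            n_matrix=complex(fh.attrs["n_matrix"]),
            n_void=complex(fh.attrs["n_void"]),
            n_background=complex(fh.attrs["n_background"]),
        )


def save_field_h5(path: str | Path, field: "bpm.OpticalField") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("amplitude", data=field.amplitude)
        fh.attrs["wavelength_um"] = field.wavelength
        fh.attrs["grid_spacing_um"] = field.grid_spacing
        fh.attrs["z_um"] = field.z


def load_field_h5(path: str | Path) -> "bpm.OpticalField":
    import h5py

    with h5py.File(path, "r") as fh:
        return bpm.OpticalField(
            amplitude=fh["amplitude"][()],
            wavelength=float(fh.attrs["wavelength_um"]),
            grid_spacing=float(fh.attrs["grid_spacing_um"]),
            z=float(fh.attrs["z_um"]),
        )


def generate_cross_section(config: RunConfig, seed: int | None = None):
    fg = config.sections["fibergen"]
    b = config.sections["bpm"]
    seed = config.seed if seed is None else seed
    pop = fibergen.sample_void_population(
        density=fg["density"],
        size_range=(fg["size_min"], fg["size_max"]),
        fiber_radius=fg["fiber_radius"],
        radial_sorting=fg["radial_sorting"],
        seed=seed,
    )
    spacing = b["grid_spacing"] or min(
        bpm.default_grid_spacing(b["wavelength"], fg["n_matrix"]),
        fibergen.max_raster_spacing((fg["size_min"], fg["size_max"])),
    )
    return fibergen.rasterize_cross_section(
        pop,
        grid_spacing=spacing,
        n_matrix=fg["n_matrix"],
        n_void=fg["n_void"],
        n_background=fg["n_background"],
        margin=2.0 + 5 * b["wavelength"],
    )


def run_localization_experiment(config: RunConfig, outdir: str | Path) -> Path:
    """fibergen -> bpm -> localization chain; emits a xi table + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loc = config.sections["localization"]
    fg = config.sections["fibergen"]
    b = config.sections["bpm"]
    table = localization.xi_sweep(
        lengths=list(loc["lengths"]),
        wavelengths=list(loc["wavelengths"]),
        n_seeds=int(loc["n_seeds"]),
        base_seed=config.seed,
        density=fg["density"],
        fiber_radius=fg["fiber_radius"],
        omega_0=b["omega_0"],
        size_range=(fg["size_min"], fg["size_max"]),
        step_dz=b["step_dz"],
        n_matrix=fg["n_matrix"],
    )
    xi_path = outdir / "xi_table.csv"
    table.to_csv(xi_path, index=False)
    _write_manifest(outdir, config, {"base_seed": config.seed}, [xi_path])
    return xi_path


def run_radiometry(
    spectrum_csv: str | Path, config: RunConfig, outdir: str | Path
) -> Path:
    """Radiometric summary JSON for a spectrum CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rc = config.sections["radiometry"]
    try:
        spectrum = radiometry.Spectrum.from_csv(spectrum_csv)
    except Exception as exc:
        raise ValueError(f"failed to parse {spectrum_csv}: {exc}") from exc
    summary = radiometry.summarize(
        spectrum,
        temperature=rc["temperature"],
        solar_bounds=(rc["solar_lo"], rc["solar_hi"]),
        thermal_bounds=(rc["thermal_lo"], rc["thermal_hi"]),
    )
    out = outdir / "radiometric_summary.json"
    out.write_text(json.dumps(summary.to_dict(), indent=1))
    _write_manifest(outdir, config, {}, [out])
    return out


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the canonical fixture set, bit-reproducible from ``seed``.

    A 2.2 voids/μm² cross-section (HDF5), a flat graybody spectrum
    (ε = 0.88), a τ = 210 fs trace with its 100 fs IRF, and an exact
    ξ = 4.6 μm exponential profile.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    pop = fibergen.sample_void_population(
        density=2.2, fiber_radius=8.0, seed=_child_seed(seed, 0)
    )
    cs = fibergen.rasterize_cross_section(pop, grid_spacing=0.1)
    files["cross_section"] = outdir / "cross_section.h5"
    save_cross_section_h5(files["cross_section"], cs)

    lam = np.round(np.arange(0.4, 20.0 + 1e-9, 0.1), 6)
    graybody = radiometry.Spectrum(
        wavelength=lam,
        reflectance=np.full_like(lam, 0.12),
        transmittance=np.full_like(lam, 0.0),
        emissivity=np.full_like(lam, 0.88),
    )
    files["graybody_spectrum"] = outdir / "graybody_spectrum.csv"
    graybody.to_csv(files["graybody_spectrum"])

    trace = tof.synth_trace(
        irf_fwhm=100.0, tau=210.0, t_range=4000.0, dt=2.0, snr=50.0,
        seed=_child_seed(seed, 1),
    )
    irf = tof.synth_irf(100.0, 4000.0, 2.0, snr=50.0, seed=_child_seed(seed, 2))
    files["tof_trace"] = outdir / "tof_trace.csv"
    files["tof_irf"] = outdir / "tof_irf.csv"
    trace.to_csv(files["tof_trace"])
    irf.to_csv(files["tof_irf"])

    r = np.arange(0.05, 15.0, 0.1)
    prof = np.exp(-2.0 * r / 4.6)
    files["xi_profile"] = outdir / "xi46_profile.csv"
    np.savetxt(
        files["xi_profile"],
        np.column_stack([r, prof]),
        delimiter=",",
        header="r_um,intensity",
        comments="",
    )

    manifest = {
        "seed": seed,
        "files": {k: {"path": p.name, "sha256_16": _checksum(p)} for k, p in files.items()},
    }
    (outdir / "fixtures_manifest.json").write_text(json.dumps(manifest, indent=1))
    return files
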