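"""On-disk formats: TSV for curves/spectra/trajectories, YAML sidecars and
configuration, JSON for relaxation results, multi-page TIFF for image stacks.

All writers produce files the module's own readers round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .decayfit import DecayCurve, InstrumentResponse, MultiExponentialModel
from .errors import FormatError
from .gp import GpMap, SpectralImageStack
from .tdfs import RelaxationResult
from .tres import BandTrajectory, SteadyStateSpectrum, TresSurface

__all__ = [
    "read_decay_tsv",
    "write_decay_tsv",
    "read_irf_tsv",
    "write_irf_tsv",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "write_tres_surface",
    "read_tres_surface",
    "write_fit_models",
    "read_fit_models",
    "write_relaxation_json",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_gp_map_tiff",
    "write_yaml",
    "read_yaml",
]


def write_yaml(data: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_decay_tsv(curve: DecayCurve, path) -> Path:
    """Write a decay as TSV (columns time_ns, counts) with a YAML sidecar
    carrying the wavelength and metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_ns\tcounts\n")
        for t, c in zip(curve.time_grid, curve.counts):
            fh.write(f"{t:.9g}\t{int(c)}\n")
    sidecar = {"wavelength_nm": float(curve.wavelength), **curve.metadata}
    write_yaml(sidecar, path.with_suffix(path.suffix + ".yaml"))
    return path


def read_decay_tsv(path) -> DecayCurve:
    """Read a decay TSV; format violations name the offending line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip().split("\t") != ["time_ns", "counts"]:
        raise FormatError("expected header 'time_ns\\tcounts'", line=1)
    times, counts = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError("expected two tab-separated columns", line=lineno)
        try:
            t = float(parts[0])
        except ValueError:
            raise FormatError(f"bad time value {parts[0]!r}", line=lineno) from None
        try:
            c = int(parts[1])
        except ValueError:
            raise FormatError(
                f"counts must be integers, got {parts[1]!r}", line=lineno
            ) from None
        if c < 0:
            raise FormatError(f"negative count {c}", line=lineno)
        times.append(t)
        counts.append(c)
    times = np.array(times)
    if times.size >= 2:
        steps = np.diff(times)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            bad = int(np.argmax(~np.isclose(steps, steps[0], rtol=1e-6)))
            raise FormatError("non-uniform time grid", line=bad + 3)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    metadata = read_yaml(sidecar_path) if sidecar_path.exists() else {}
    wavelength = metadata.pop("wavelength_nm", float("nan"))
    return DecayCurve(
        wavelength=wavelength, time_grid=times, counts=np.array(counts), metadata=metadata
    )


def write_irf_tsv(irf: InstrumentResponse, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_ns": irf.time_grid, "amplitude": irf.amplitudes})
    df.to_csv(path, sep="\t", index=False)
    write_yaml({"fwhm_ns": float(irf.fwhm)}, path.with_suffix(path.suffix + ".yaml"))
    return path


def read_irf_tsv(path) -> InstrumentResponse:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["time_ns", "amplitude"]:
        raise FormatError("expected header 'time_ns\\tamplitude'", line=1)
    return InstrumentResponse.from_profile(
        df["time_ns"].to_numpy(), df["amplitude"].to_numpy()
    )


_SPECTRUM_COLUMNS = {"wavelength": "wavelength_nm", "wavenumber": "wavenumber_cm1"}


def write_spectrum_tsv(spectrum: SteadyStateSpectrum, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {_SPECTRUM_COLUMNS[spectrum.axis]: spectrum.grid, "intensity": spectrum.intensities}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_spectrum_tsv(path) -> SteadyStateSpectrum:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    for axis, column in _SPECTRUM_COLUMNS.items():
        if cols == [column, "intensity"]:
            return SteadyStateSpectrum(
                axis=axis, grid=df[column].to_numpy(), intensities=df["intensity"].to_numpy()
            )
    raise FormatError(
        "expected columns (wavelength_nm|wavenumber_cm1, intensity)", line=1
    )


def write_trajectory_tsv(trajectory: BandTrajectory, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ns": trajectory.times,
            "nu_max_cm1": trajectory.nu_max,
            "fwhm_cm1": trajectory.fwhm,
            "asymmetry": trajectory.asymmetry,
            "amplitude": trajectory.amplitude,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_trajectory_tsv(path) -> BandTrajectory:
    df = pd.read_csv(Path(path), sep="\t")
    required = ["time_ns", "nu_max_cm1", "fwhm_cm1", "asymmetry"]
    if list(df.columns)[: len(required)] != required:
        raise FormatError(
            "expected columns time_ns, nu_max_cm1, fwhm_cm1, asymmetry", line=1
        )
    amplitude = (
        df["amplitude"].to_numpy()
        if "amplitude" in df.columns
        else np.full(len(df), np.nan)
    )
    return BandTrajectory(
        times=df["time_ns"].to_numpy(),
        nu_max=df["nu_max_cm1"].to_numpy(),
        fwhm=df["fwhm_cm1"].to_numpy(),
        asymmetry=df["asymmetry"].to_numpy(),
        amplitude=amplitude,
    )


def write_tres_surface(surface: TresSurface, path) -> Path:
    """TSV matrix (rows = time slices) plus a YAML axes sidecar."""
    path = Path(path)
    np.savetxt(path, surface.intensity, delimiter="\t")
    write_yaml(
        {
            "wavenumber_cm1": [float(v) for v in surface.wavenumber_grid],
            "time_ns": [float(v) for v in surface.time_grid],
            "provenance": surface.provenance,
        },
        path.with_suffix(path.suffix + ".yaml"),
    )
    return path


def read_tres_surface(path) -> TresSurface:
    path = Path(path)
    intensity = np.loadtxt(path, delimiter="\t")
    axes = read_yaml(path.with_suffix(path.suffix + ".yaml"))
    return TresSurface(
        wavenumber_grid=np.array(axes["wavenumber_cm1"]),
        time_grid=np.array(axes["time_ns"]),
        intensity=np.atleast_2d(intensity),
        provenance=axes.get("provenance", {}),
    )


def _model_to_dict(model: MultiExponentialModel) -> dict:
    return {
        "amplitudes": [float(a) for a in model.amplitudes],
        "lifetimes_ns": [float(t) for t in model.lifetimes],
        "shift_ns": float(model.shift),
        "background": float(model.background),
    }


def write_fit_models(fits, path, reports=None) -> Path:
    """Persist per-wavelength fitted models (and fit quality) as YAML.

    ``fits`` is a sequence of (wavelength_nm, MultiExponentialModel);
    ``reports`` optionally supplies the matching FitReport per entry.
    """
    entries = []
    for i, (wavelength, model) in enumerate(fits):
        entry = {"wavelength_nm": float(wavelength), **_model_to_dict(model)}
        if reports is not None:
            entry["reduced_chi_square"] = float(reports[i].reduced_chi_square)
            entry["converged"] = bool(reports[i].converged)
        entries.append(entry)
    return write_yaml({"fits": entries}, path)


def read_fit_models(path) -> list:
    data = read_yaml(path)
    fits = []
    for entry in data["fits"]:
        fits.append(
            (
                float(entry["wavelength_nm"]),
                MultiExponentialModel(
                    amplitudes=np.array(entry["amplitudes"]),
                    lifetimes=np.array(entry["lifetimes_ns"]),
                    shift=float(entry.get("shift_ns", 0.0)),
                    background=float(entry.get("background", 0.0)),
                ),
            )
        )
    return fits


def write_relaxation_json(result: RelaxationResult, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
    return path


def write_stack_tiff(stack: SpectralImageStack, path) -> Path:
    """Multi-page TIFF (one page per channel) with a YAML channel sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.counts.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages)
    write_yaml(
        {
            "channel_centers_nm": [float(c) for c in stack.channel_centers],
            "channel_width_nm": float(stack.channel_width),
        },
        path.with_suffix(path.suffix + ".yaml"),
    )
    return path


def read_stack_tiff(path) -> SpectralImageStack:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = read_yaml(path.with_suffix(path.suffix + ".yaml"))
    return SpectralImageStack(
        counts=np.moveaxis(np.atleast_3d(pages), 0, 2),
        channel_centers=np.array(meta["channel_centers_nm"]),
        channel_width=float(meta["channel_width_nm"]),
    )


def write_gp_map_tiff(gpmap: GpMap, path) -> Path:
    """32-bit float GP TIFF plus a companion uint8 validity-mask TIFF."""
    path = Path(path)
    tifffile.imwrite(path, gpmap.values.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, gpmap.valid.astype(np.uint8))
    return path
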