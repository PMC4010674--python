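"""Shared data containers and their on-disk format.

The package's exchange object is :class:`CrossSpectra`: complex Hermitian
site-by-site spectral matrices over frequency and experimental condition.
One container format is defined here (HDF5 with named real/imaginary arrays
and a JSON metadata document) and used everywhere; small instances can also
be exported to CSV for inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .core import SpectralGrid

FORMAT_VERSION = 1

__all__ = ["CrossSpectra", "EpochSeries", "FORMAT_VERSION"]


@dataclass
class CrossSpectra:
    """Complex cross-spectral densities indexed [condition, frequency, site, site].

    Invariants (enforced on construction): the site-by-site block is Hermitian
    at every (condition, frequency) and its diagonal is real and non-negative.
    """

    values: np.ndarray
    grid: SpectralGrid
    conditions: list[str]
    sites: list[str]
    n_epochs: np.ndarray | None = None  # per-condition epoch counts, if estimated

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        nc, nf, s1, s2 = self.values.shape
        if s1 != s2 or s1 != len(self.sites):
            raise ValueError("site axes must be square and match site labels")
        if nc != len(self.conditions):
            raise ValueError("condition axis must match condition labels")
        if nf != len(self.grid.freqs):
            raise ValueError("frequency axis must match the grid")
        if not np.allclose(self.values, np.conj(np.swapaxes(self.values, -1, -2)),
                           rtol=1e-8, atol=1e-12 * max(1.0, np.abs(self.values).max())):
            raise ValueError("cross-spectral matrices must be Hermitian")
        diag = np.diagonal(self.values, axis1=-2, axis2=-1)
        if np.any(diag.real < -1e-12 * max(1.0, np.abs(diag).max())):
            raise ValueError("auto-spectra must be non-negative")
        if self.n_epochs is not None:
            self.n_epochs = np.asarray(self.n_epochs, dtype=int)
            if self.n_epochs.shape != (nc,):
                raise ValueError("n_epochs must hold one count per condition")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def save(self, path) -> None:
        meta = {
            "format_version": FORMAT_VERSION,
            "conditions": list(self.conditions),
            "sites": list(self.sites),
            "freqs_hz": self.grid.freqs.tolist(),
            "wavenumbers_per_mm": self.grid.wavenumbers.tolist(),
            "n_epochs": None if self.n_epochs is None else self.n_epochs.tolist(),
        }
        with h5py.File(path, "w") as f:
            f.create_dataset("values_re", data=self.values.real)
            f.create_dataset("values_im", data=self.values.imag)
            f.attrs["metadata"] = json.dumps(meta)

    @classmethod
    def load(cls, path) -> "CrossSpectra":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            if meta.get("format_version") != FORMAT_VERSION:
                raise ValueError(f"unsupported container version {meta.get('format_version')}")
            values = f["values_re"][...] + 1j * f["values_im"][...]
        grid = SpectralGrid(freqs=np.array(meta["freqs_hz"]),
                            wavenumbers=np.array(meta["wavenumbers_per_mm"]))
        n_epochs = meta["n_epochs"]
        return cls(values=values, grid=grid, conditions=meta["conditions"],
                   sites=meta["sites"],
                   n_epochs=None if n_epochs is None else np.array(n_epochs))

    def to_csv(self, path) -> None:
        """Long-format CSV export: one row per (condition, frequency, site pair)."""
        rows = []
        for ci, cond in enumerate(self.conditions):
            for fi, freq in enumerate(self.grid.freqs):
                for i, si in enumerate(self.sites):
                    for j, sj in enumerate(self.sites):
                        v = self.values[ci, fi, i, j]
                        rows.append((cond, freq, si, sj, v.real, v.imag))
        pd.DataFrame(rows, columns=["condition", "freq_hz", "site_a", "site_b",
                                    "real", "imag"]).to_csv(path, index=False)


@dataclass
class EpochSeries:
    """Multichannel epoched time series: array (channels, samples, epochs)."""

    data: np.ndarray
    fs_hz: float
    channels: list[str] = field(default_factory=list)
    units: str = "a.u."

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[..., None]
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, epochs)")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    def save(self, path) -> None:
        meta = {"format_version": FORMAT_VERSION, "fs_hz": self.fs_hz,
                "channels": list(self.channels), "units": self.units}
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["metadata"] = json.dumps(meta)

    @classmethod
    def load(cls, path) -> "EpochSeries":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            data = f["data"][...]
        return cls(data=data, fs_hz=meta["fs_hz"], channels=meta["channels"],
                   units=meta.get("units", "a.u."))
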