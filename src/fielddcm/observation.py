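"""Observation model: from field activity to bipolar ECoG cross-spectra.

Each electrode sees the patch through a Gaussian lead field centred at its
(unknown) position; bipolar sites are differences of neighbouring electrodes,
removing the common reference (and, with it, the spatially uniform k = 0
mode).  Predicted site cross-spectra sum the per-wavenumber population
response, weighted by the population mixing vector Q and the input spectrum,
over the wavenumber grid; site-specific and common channel noise are added on
top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CrossSpectra
from .core import (
    ConnectivityParams,
    SpectralGrid,
    SynapticParams,
    transfer_matrix,
)

__all__ = [
    "SensorModel",
    "NoiseParams",
    "lead_field_ft",
    "site_transfer",
    "input_spectrum",
    "channel_noise",
    "predict_csd",
]


@dataclass
class SensorModel:
    """Electrode geometry, bipolar montage and population mixing weights.

    ``centres`` and ``dispersions`` are per-electrode (mm); ``montage`` maps
    electrodes to bipolar sites (each row one +1 and one -1); ``mix`` holds
    the non-negative contribution weight of each population to the signal.
    ``site_gains``, when set, replaces the spatial lead-field model by one
    scalar gain per site -- the point-source (neural-mass) observation model.
    """

    centres: np.ndarray
    dispersions: np.ndarray
    montage: np.ndarray
    mix: np.ndarray
    patch_length: float = 25.0
    site_gains: np.ndarray | None = None

    def __post_init__(self):
        self.centres = np.asarray(self.centres, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        self.montage = np.asarray(self.montage, dtype=float)
        self.mix = np.asarray(self.mix, dtype=float)
        nq = len(self.centres)
        if self.dispersions.shape != (nq,):
            raise ValueError("one dispersion per electrode required")
        if np.any(self.centres < 0) or np.any(self.centres > self.patch_length):
            raise ValueError("electrode centres must lie on the patch [0, ell]")
        if np.any(self.dispersions <= 0):
            raise ValueError("lead-field dispersions must be positive")
        if self.montage.ndim != 2 or self.montage.shape[1] != nq:
            raise ValueError("montage must be (n_sites, n_electrodes)")
        for row in self.montage:
            if not (np.sum(row == 1) == 1 and np.sum(row == -1) == 1
                    and np.sum(row != 0) == 2 and row.sum() == 0):
                raise ValueError("each montage row needs exactly one +1 and one -1")
        if self.mix.shape != (4,) or np.any(self.mix < 0):
            raise ValueError("mix must be four non-negative weights")
        if self.site_gains is not None:
            self.site_gains = np.asarray(self.site_gains, dtype=float)
            if self.site_gains.shape != (self.montage.shape[0],):
                raise ValueError("one gain per site required")

    @property
    def n_sites(self) -> int:
        return self.montage.shape[0]


@dataclass
class NoiseParams:
    """Input and channel noise spectra: white plus coloured (1/f) components.

    ``g(f) = alpha + beta * (f_ref / f)**exponent`` with f in Hz.  ``alpha_n``
    and ``beta_n`` may be scalars or per-site vectors; the common pair is a
    noise source shared by all sites (rank-one contribution to every entry of
    the cross-spectral matrix).
    """

    alpha_u: float = 1.0
    beta_u: float = 0.0
    alpha_n: float | np.ndarray = 0.0
    beta_n: float | np.ndarray = 0.0
    alpha_common: float = 0.0
    beta_common: float = 0.0
    exponent: float = 1.0
    f_ref: float = 1.0

    def __post_init__(self):
        for name in ("alpha_u", "beta_u", "alpha_common", "beta_common"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("alpha_n", "beta_n"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, v)


def lead_field_ft(phi, k_cyc):
    """Fourier factor of a unit-mass Gaussian lead field of width ``phi``.

    ``E(phi, k) = exp(-2 pi^2 phi^2 k^2)`` with ``k_cyc`` the *cyclic*
    wavenumber (cycles/mm).  Value in (0, 1], even in k, decreasing in |k|
    and in phi.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("lead-field dispersion phi must be positive")
    k_cyc = np.asarray(k_cyc, dtype=float)
    return np.exp(-2.0 * np.pi**2 * phi**2 * k_cyc**2)


def _electrode_factors(sensors: SensorModel, k: np.ndarray) -> np.ndarray:
    """Per-electrode complex sensor factor e^{-i a k} E(phi, k); shape (nq, nk)."""
    k = np.asarray(k, dtype=float)
    phase = np.exp(-1j * np.outer(sensors.centres, k))
    disp = lead_field_ft(sensors.dispersions[:, None], k[None, :] / (2.0 * np.pi))
    return phase * disp


def site_transfer(site: int, k, omega, sensors: SensorModel,
                  syn: SynapticParams, conn: ConnectivityParams):
    """Bipolar site transfer: lead-field difference times the mixed response.

    Returns ``sum_q M[site, q] e^{-i a_q k} E(phi_q, k) * Q . T(k, omega)``,
    broadcasting over ``k`` and ``omega``.
    """
    if not 0 <= site < sensors.n_sites:
        raise IndexError(f"site {site} outside montage with {sensors.n_sites} rows")
    k_b, omega_b = np.broadcast_arrays(np.asarray(k, float), np.asarray(omega, float))
    T = transfer_matrix(k_b, omega_b, syn, conn)
    qt = T @ sensors.mix.astype(complex)
    lf = np.zeros(k_b.shape, dtype=complex)
    for q in np.flatnonzero(sensors.montage[site]):
        w = sensors.montage[site, q]
        lf += w * np.exp(-1j * sensors.centres[q] * k_b) * lead_field_ft(
            sensors.dispersions[q], k_b / (2.0 * np.pi)
        )
    return lf * qt


def input_spectrum(omega, noise: NoiseParams):
    """Spectral density of the spatially white neuronal input, g_u(omega)."""
    f = np.asarray(omega, dtype=float) * 1000.0 / (2.0 * np.pi)
    return noise.alpha_u + noise.beta_u * (noise.f_ref / f) ** noise.exponent


def channel_noise(omega, noise: NoiseParams):
    """Site-specific channel-noise spectra; shape (n_freq, n_sites_or_1)."""
    f = np.atleast_1d(np.asarray(omega, dtype=float)) * 1000.0 / (2.0 * np.pi)
    return (np.asarray(noise.alpha_n)[None, :]
            + np.asarray(noise.beta_n)[None, :]
            * (noise.f_ref / f[:, None]) ** noise.exponent)


def common_noise(omega, noise: NoiseParams):
    f = np.asarray(omega, dtype=float) * 1000.0 / (2.0 * np.pi)
    return noise.alpha_common + noise.beta_common * (noise.f_ref / f) ** noise.exponent


def _site_factors(sensors: SensorModel, k: np.ndarray) -> np.ndarray:
    """Montage-applied sensor factors; shape (n_sites, nk)."""
    if sensors.site_gains is not None:
        # point-source observation model: scalar gain per site, no spatial phase
        return np.repeat(sensors.site_gains[:, None], len(k), axis=1).astype(complex)
    return sensors.montage @ _electrode_factors(sensors, k)


def predict_csd(grid: SpectralGrid, sensors: SensorModel, noise: NoiseParams,
                syn: SynapticParams, conn: ConnectivityParams,
                condition: str = "c0") -> CrossSpectra:
    """Predicted cross-spectral density matrices for one condition.

    ``g_lm(omega) = sum_k Ttilde_l(k, omega) g_u(omega) Ttilde_m(k, omega)*``
    plus site-specific channel noise on the diagonal and a common component on
    every entry.  The result is Hermitian with real non-negative diagonal by
    construction.
    """
    k = grid.wavenumbers
    omega = grid.omegas
    T = transfer_matrix(k[:, None], omega[None, :], syn, conn)  # (nk, nf, 4)
    qt = T @ sensors.mix.astype(complex)  # (nk, nf)
    St = _site_factors(sensors, k)  # (ns, nk)
    resp = St[:, :, None] * qt[None, :, :]  # (ns, nk, nf)
    gu = input_spectrum(omega, noise)
    csd = np.einsum("ikf,jkf,f->fij", resp, np.conj(resp), gu)
    # enforce exact Hermitian symmetry against floating-point asymmetry
    csd = 0.5 * (csd + np.conj(np.swapaxes(csd, -1, -2)))

    ns = sensors.n_sites
    gn = channel_noise(omega, noise)
    if gn.shape[1] not in (1, ns):
        raise ValueError("alpha_n/beta_n must be scalar or one entry per site")
    idx = np.arange(ns)
    csd[:, idx, idx] += gn if gn.shape[1] == ns else np.repeat(gn, ns, axis=1)
    csd += common_noise(omega, noise)[:, None, None]

    sites = [f"site{i}" for i in range(ns)]
    return CrossSpectra(values=csd[None, ...], grid=grid,
                        conditions=[condition], sites=sites)
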