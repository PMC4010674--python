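"""Canonical-microcircuit neural field model and its spatiotemporal transfer functions.

The model describes four coupled neuronal populations per cortical patch --
spiny stellate cells (1), inhibitory interneurons (2), deep pyramidal cells (3)
and superficial pyramidal cells (4) -- each occupying a one-dimensional
periodic manifold of length ``ell`` (mm).  Population depolarisation obeys a
damped second-order (synaptic convolution) equation driven by horizontally
propagating presynaptic input::

    V'' + 2 B V' + B**2 V = B * (K (*) F(V_delayed)) + G u

where ``B = diag(kappa)`` holds inverse synaptic time constants, ``K`` is an
exponentially decaying connectivity kernel with a fixed excitatory/inhibitory
sign pattern, conduction delays are ``|x - x'| * inv_speed`` and ``F`` is a
sigmoid firing-rate function.  Linearising about the zero fixed point and
transforming to wavenumber/frequency space yields, per ``(k, omega)``, a 4x4
linear system whose solution is the population transfer vector ``T(k, omega)``.

Units: time in ms, space in mm.  ``omega`` is angular temporal frequency in
rad/ms (``omega = 2*pi*f/1000`` for ``f`` in Hz) and ``k`` angular wavenumber
in rad/mm.  The Fourier convention is e^{+i omega t} synthesis, under which
time derivatives map to ``+i omega`` and the delayed kernel transform is
``D(k, omega) = alpha (c + i v w) / ((c + i v w)^2 + k^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EDGES",
    "EDGE_NAMES",
    "SIGNS",
    "SynapticParams",
    "ConnectivityParams",
    "SpectralGrid",
    "omega_from_hz",
    "presynaptic_rate",
    "sigmoid_gain",
    "spatial_kernel_ft",
    "jacobian_J",
    "transfer_matrix",
    "transfer_closed_form",
]

#: The ten non-zero directed edges (target, source) of the microcircuit.
EDGES: tuple[tuple[int, int], ...] = (
    (1, 1), (1, 2), (1, 4),
    (2, 1), (2, 2), (2, 3),
    (3, 2), (3, 3),
    (4, 1), (4, 4),
)

EDGE_NAMES: tuple[str, ...] = tuple(f"alpha_{a}{b}" for a, b in EDGES)

#: Sign pattern of the connectivity kernel: self connections are inhibitory,
#: projections from interneurons (population 2) are inhibitory, and the
#: superficial-pyramidal -> spiny-stellate edge (1,4) is inhibitory-signed;
#: the remaining edges are excitatory.
SIGNS: np.ndarray = np.array(
    [
        [-1, -1, 0, -1],
        [+1, -1, +1, 0],
        [0, -1, -1, 0],
        [+1, 0, 0, -1],
    ],
    dtype=float,
)

_EDGE_INDEX = {edge: i for i, edge in enumerate(EDGES)}


def omega_from_hz(freq_hz):
    """Angular temporal frequency (rad/ms) for a frequency in Hz."""
    return 2.0 * np.pi * np.asarray(freq_hz, dtype=float) / 1000.0


@dataclass
class SynapticParams:
    """Synaptic kinetics and firing-rate nonlinearity.

    Parameters
    ----------
    kappa:
        Inverse postsynaptic time constants, one per population (1/ms).
    r:
        Slope of the sigmoid firing-rate function (dimensionless).
    eta:
        Depolarisation at half-maximal firing (same units as V).
    """

    kappa: np.ndarray
    r: float = 0.54
    eta: float = 0.0

    def __post_init__(self):
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.shape != (4,):
            raise ValueError("kappa must have exactly four entries")
        if not np.all(self.kappa > 0):
            raise ValueError("all kappa must be positive")
        if self.r <= 0:
            raise ValueError("sigmoid slope r must be positive")

    @property
    def input_mapping(self) -> np.ndarray:
        """G = (kappa_1, 0, 0, 0): exogenous input drives the stellate layer."""
        return np.array([self.kappa[0], 0.0, 0.0, 0.0])


@dataclass
class ConnectivityParams:
    """Strengths and spatial decays of the ten microcircuit edges.

    ``alpha`` and ``c`` are stored positive in :data:`EDGES` order; the
    excitatory/inhibitory sign pattern is structural (:data:`SIGNS`).
    """

    alpha: np.ndarray
    c: np.ndarray
    inv_speed: float = 1.0 / 0.3  # ms/mm <-> 0.3 m/s conduction speed
    patch_length: float = 25.0  # mm

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        n = len(EDGES)
        if self.alpha.shape != (n,) or self.c.shape != (n,):
            raise ValueError(f"alpha and c must each have {n} entries")
        if not np.all(self.alpha > 0):
            raise ValueError("all alpha must be positive")
        if not np.all(self.c > 0):
            raise ValueError("all spatial decays c must be positive")
        if self.inv_speed < 0:
            raise ValueError("inverse conduction speed must be non-negative")
        if self.patch_length <= 0:
            raise ValueError("patch length must be positive")

    def edge_value(self, edge: tuple[int, int], which: str = "alpha") -> float:
        i = _edge_index(edge)
        return float(self.alpha[i] if which == "alpha" else self.c[i])


def _edge_index(edge: tuple[int, int]) -> int:
    try:
        return _EDGE_INDEX[tuple(edge)]
    except KeyError:
        raise KeyError(
            f"{tuple(edge)} is not a microcircuit edge; valid edges: {EDGES}"
        ) from None


@dataclass
class SpectralGrid:
    """Temporal-frequency and wavenumber grid for spectral predictions.

    ``freqs`` are strictly increasing positive temporal frequencies in Hz;
    ``wavenumbers`` the symmetric set ``k_n = 2 pi n / ell`` (rad/mm) for
    ``n = -N..N``.
    """

    freqs: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.freqs.ndim != 1 or len(self.freqs) == 0:
            raise ValueError("freqs must be a non-empty vector")
        if np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be positive and strictly increasing")
        k = np.sort(self.wavenumbers)
        if len(np.unique(k)) != len(k):
            raise ValueError("duplicate wavenumbers")
        if not np.allclose(np.sort(-k), k):
            raise ValueError("wavenumber set must be closed under negation")

    @classmethod
    def default(
        cls,
        freqs=None,
        patch_length: float = 25.0,
        n_modes: int = 32,
    ) -> "SpectralGrid":
        """Grid with ``k_n = 2 pi n / ell``, ``n = -n_modes..n_modes``."""
        if freqs is None:
            freqs = np.arange(2.0, 101.0, 2.0)
        n = np.arange(-n_modes, n_modes + 1)
        return cls(freqs=np.asarray(freqs, float),
                   wavenumbers=2.0 * np.pi * n / patch_length)

    @property
    def omegas(self) -> np.ndarray:
        return omega_from_hz(self.freqs)


def presynaptic_rate(v, params: SynapticParams):
    """Sigmoid mapping from depolarisation to presynaptic firing rate in (0, 1)."""
    from scipy.special import expit

    v = np.asarray(v, dtype=float)
    return expit(params.r * (v - params.eta))


def sigmoid_gain(params: SynapticParams) -> float:
    """Slope of :func:`presynaptic_rate` at the zero expansion point.

    gamma = r e^{r eta} / (1 + e^{r eta})**2; equals r/4 when eta = 0.
    """
    from scipy.special import expit

    s = expit(params.r * params.eta)
    return float(params.r * s * (1.0 - s))


def spatial_kernel_ft(edge, k, omega, conn: ConnectivityParams):
    """Spatial Fourier transform of one delayed connectivity kernel.

    Transform of ``(alpha/2) exp(-c |x|) exp(-i omega inv_speed |x|)`` over the
    (effectively unbounded) patch::

        D(k, omega) = alpha (c + i v w) / ((c + i v w)**2 + k**2)

    The result is positive-magnitude; the excitatory/inhibitory sign is
    applied structurally in :func:`jacobian_J`.  Hermitian in omega.
    """
    i = _edge_index(edge)
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    z = conn.c[i] + 1j * conn.inv_speed * omega
    return conn.alpha[i] * z / (z * z + k * k)


def _kernel_ft_all(k, omega, conn: ConnectivityParams) -> np.ndarray:
    """D for all ten edges, stacked on the leading axis; broadcasts k, omega."""
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    z = conn.c.reshape((-1,) + (1,) * max(k.ndim, omega.ndim)) + (
        1j * conn.inv_speed * omega
    )
    a = conn.alpha.reshape(z.shape[0:1] + (1,) * (z.ndim - 1))
    return a * z / (z * z + k * k)


def jacobian_J(k, omega, syn: SynapticParams, conn: ConnectivityParams) -> np.ndarray:
    """Coupling matrix J(k, omega) = B D(k, omega) gamma of the linearised field.

    Entry (a, b) is ``kappa_a * gamma * sign_ab * D_ab(k, omega)``; zero
    exactly where the microcircuit has no edge.
    """
    gamma = sigmoid_gain(syn)
    D = _kernel_ft_all(np.asarray(k, float), np.asarray(omega, float), conn)
    J = np.zeros(D.shape[1:] + (4, 4), dtype=complex)
    for i, (a, b) in enumerate(EDGES):
        J[..., a - 1, b - 1] = syn.kappa[a - 1] * gamma * SIGNS[a - 1, b - 1] * D[i]
    return J


def _system_matrix(k, omega, syn: SynapticParams, conn: ConnectivityParams) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    B = np.diag(syn.kappa)
    M = (
        -(omega[..., None, None] ** 2) * np.eye(4)
        + 2j * omega[..., None, None] * B
        + B @ B
    )
    return M - jacobian_J(k, omega, syn, conn)


def transfer_matrix(k, omega, syn: SynapticParams, conn: ConnectivityParams) -> np.ndarray:
    """Population transfer vector T(k, omega) via the 4x4 matrix solve.

    Solves ``(-omega^2 I + 2 i omega B + B^2 - J(k, omega)) T = G`` with
    ``G = (kappa_1, 0, 0, 0)``.  Broadcasts over ``k`` and ``omega``; the
    population axis is last.  Raises on a singular system, reporting the
    offending grid point.
    """
    k_b, omega_b = np.broadcast_arrays(np.asarray(k, float), np.asarray(omega, float))
    M = _system_matrix(k_b, omega_b, syn, conn)
    G = np.broadcast_to(syn.input_mapping.astype(complex), M.shape[:-1])
    try:
        return np.linalg.solve(M, G[..., None])[..., 0]
    except np.linalg.LinAlgError:
        dets = np.abs(np.linalg.det(M))
        idx = np.unravel_index(np.argmin(dets), dets.shape) if dets.ndim else ()
        raise np.linalg.LinAlgError(
            "singular field system at (k, omega) = "
            f"({np.asarray(k_b)[idx]:.6g} rad/mm, {np.asarray(omega_b)[idx]:.6g} rad/ms)"
        ) from None


def transfer_closed_form(k, omega, syn: SynapticParams, conn: ConnectivityParams) -> np.ndarray:
    """Population transfer vector via explicit elimination of the 4x4 system.

    Independent route used to cross-validate :func:`transfer_matrix`.  With
    ``P_a = kappa_a^2 + 2 i omega kappa_a - omega^2 + kappa_a gamma D_aa`` and
    loop products ``R_ab = gamma^2 kappa_a kappa_b D_ab D_ba``::

        W  = P4 (P1 P2 P3 + P1 R23 + P3 R12) + R14 (P2 P3 + R23)
        T1 = kappa_1 P4 (P2 P3 + R23) / W
        T2 = kappa_1 kappa_2 gamma D21 P3 P4 / W
        T3 = -kappa_1 kappa_2 kappa_3 gamma^2 D21 D32 P4 / W
        T4 = kappa_1 kappa_4 gamma D41 (P2 P3 + R23) / W
    """
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    gamma = sigmoid_gain(syn)
    kp = syn.kappa
    D = {edge: spatial_kernel_ft(edge, k, omega, conn) for edge in EDGES}

    P = [
        kp[a] ** 2 + 2j * omega * kp[a] - omega**2 + kp[a] * gamma * D[(a + 1, a + 1)]
        for a in range(4)
    ]
    R12 = gamma**2 * kp[0] * kp[1] * D[(1, 2)] * D[(2, 1)]
    R23 = gamma**2 * kp[1] * kp[2] * D[(2, 3)] * D[(3, 2)]
    R14 = gamma**2 * kp[0] * kp[3] * D[(1, 4)] * D[(4, 1)]

    W = P[3] * (P[0] * P[1] * P[2] + P[0] * R23 + P[2] * R12) + R14 * (P[1] * P[2] + R23)
    if np.any(W == 0):
        raise np.linalg.LinAlgError("vanishing characteristic function W(k, omega)")

    z23 = P[1] * P[2] + R23
    T1 = kp[0] * P[3] * z23 / W
    T2 = kp[0] * kp[1] * gamma * D[(2, 1)] * P[2] * P[3] / W
    T3 = -kp[0] * kp[1] * kp[2] * gamma**2 * D[(2, 1)] * D[(3, 2)] * P[3] / W
    T4 = kp[0] * kp[3] * gamma * D[(4, 1)] * z23 / W
    return np.stack(np.broadcast_arrays(T1, T2, T3, T4), axis=-1)
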