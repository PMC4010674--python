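"""Multi-condition forward predictions: parameters -> cross-spectral arrays.

The production path evaluates the analytic population transfer functions in
their closed (eliminated) form, vectorised over conditions, wavenumbers and
frequencies; the equivalent matrix-solve route in :mod:`fielddcm.core` is
the reference implementation the closed form is validated against.
"""

from __future__ import annotations

import numpy as np

from .containers import CrossSpectra
from .core import EDGES, SpectralGrid
from .priors import (
    ConditionDesign,
    ModelSpec,
    PriorSet,
    apply_condition_effects,
)

__all__ = ["prediction_grid", "predict_conditions", "predict_dataset"]

_EIDX = {edge: i for i, edge in enumerate(EDGES)}


def prediction_grid(spec: ModelSpec, grid: SpectralGrid) -> SpectralGrid:
    """The grid a model is evaluated on: mass variants keep only k = 0."""
    if spec.field:
        return grid
    return SpectralGrid(freqs=grid.freqs, wavenumbers=np.array([0.0]))


def _values(priors: PriorSet, dev: dict[str, float], names) -> np.ndarray:
    out = np.empty(len(names))
    for i, n in enumerate(names):
        p = priors[n]
        d = dev.get(n, 0.0)
        out[i] = p.mean + d if p.additive else p.mean * np.exp(d)
    return out


def predict_conditions(
    deviations: dict[str, float],
    spec: ModelSpec,
    design: ConditionDesign,
    priors: PriorSet,
    grid: SpectralGrid,
    montage: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted CSD array (n_cond, n_freq, n_sites, n_sites) for one model."""
    g = prediction_grid(spec, grid)
    k = g.wavenumbers  # (nk,)
    om = g.omegas  # (nf,)
    nc = design.n_conditions

    nq = sum(1 for n in priors.params if n.startswith("centre_"))
    if montage is None:
        montage = np.zeros((nq // 2, nq))
        for i in range(nq // 2):
            montage[i, 2 * i] = -1.0
            montage[i, 2 * i + 1] = 1.0
    ns = montage.shape[0]

    alpha_names = [f"alpha_{a}{b}" for a, b in EDGES]
    c_names = [f"c_{a}{b}" for a, b in EDGES]
    kappa_names = [f"kappa_{i}" for i in range(1, 5)]
    centre_names = [f"centre_{q}" for q in range(nq)]
    phi_names = [f"phi_{q}" for q in range(nq)]
    mix_names = [f"q_{i}" for i in range(1, 5)]

    alpha = np.empty((nc, len(EDGES)))
    cdec = np.empty((nc, len(EDGES)))
    kappa = np.empty((nc, 4))
    gamma = np.empty(nc)
    invs = np.empty(nc)
    centres = np.empty((nc, nq))
    phis = np.empty((nc, nq))
    mix = np.empty((nc, 4))
    gains = np.empty((nc, ns)) if not spec.field else None
    gu = np.empty((nc, len(om)))
    gn = np.empty((nc, len(om)))
    gcom = np.empty((nc, len(om)))

    f_hz = g.freqs
    for ci in range(nc):
        dev = apply_condition_effects(deviations, spec, design, ci)
        alpha[ci] = _values(priors, dev, alpha_names)
        cdec[ci] = _values(priors, dev, c_names)
        kappa[ci] = _values(priors, dev, kappa_names)
        r, eta = _values(priors, dev, ["r", "eta"])
        e = np.exp(r * eta)
        gamma[ci] = r * e / (1.0 + e) ** 2
        invs[ci] = _values(priors, dev, ["inv_speed"])[0]
        centres[ci] = _values(priors, dev, centre_names)
        phis[ci] = _values(priors, dev, phi_names)
        mix[ci] = _values(priors, dev, mix_names)
        if gains is not None:
            gains[ci] = _values(priors, dev, [f"gain_{i}" for i in range(ns)])
        au, bu, an, bn, ac = _values(
            priors, dev, ["alpha_u", "beta_u", "alpha_n", "beta_n", "alpha_c"]
        )
        gu[ci] = au + bu / f_hz
        gn[ci] = an + bn / f_hz
        gcom[ci] = ac

    T = _closed_form_transfer(k, om, kappa, gamma, alpha, cdec, invs)
    qt2 = np.abs(np.einsum("ckfa,ca->ckf", T, mix)) ** 2  # (nc, nk, nf)

    if gains is None:
        phase = np.exp(-1j * centres[..., None] * k)  # (nc, nq, nk)
        disp = np.exp(-0.5 * (phis[..., None] ** 2) * k**2)
        St = np.einsum("sq,cqk->csk", montage, phase * disp)  # (nc, ns, nk)
    else:
        St = np.repeat(gains[:, :, None].astype(complex), len(k), axis=2)

    csd = np.einsum("cik,cjk,ckf,cf->cfij", St, np.conj(St), qt2, gu,
                    optimize=True)
    csd = 0.5 * (csd + np.conj(np.swapaxes(csd, -1, -2)))
    idx = np.arange(ns)
    csd[:, :, idx, idx] += gn[:, :, None]
    csd += gcom[:, :, None, None]
    return csd


def _closed_form_transfer(k, om, kappa, gamma, alpha, cdec, invs):
    """Vectorised closed-form transfer; returns (nc, nk, nf, 4) complex."""
    # D per edge: (nc, 10, nk, nf)
    z = cdec[:, :, None, None] + 1j * (invs[:, None, None, None] * om[None, None, None, :])
    D = alpha[:, :, None, None] * z / (z * z + (k**2)[None, None, :, None])
    g = gamma[:, None, None]

    def Dn(a, b):
        return D[:, _EIDX[(a, b)]]

    P = [
        kappa[:, a - 1, None, None] ** 2
        + 2j * om[None, None, :] * kappa[:, a - 1, None, None]
        - om[None, None, :] ** 2
        + kappa[:, a - 1, None, None] * g * Dn(a, a)
        for a in (1, 2, 3, 4)
    ]
    k1 = kappa[:, 0, None, None]
    k2 = kappa[:, 1, None, None]
    k3 = kappa[:, 2, None, None]
    k4 = kappa[:, 3, None, None]
    R12 = g**2 * k1 * k2 * Dn(1, 2) * Dn(2, 1)
    R23 = g**2 * k2 * k3 * Dn(2, 3) * Dn(3, 2)
    R14 = g**2 * k1 * k4 * Dn(1, 4) * Dn(4, 1)
    z23 = P[1] * P[2] + R23
    W = P[3] * (P[0] * P[1] * P[2] + P[0] * R23 + P[2] * R12) + R14 * z23
    T1 = k1 * P[3] * z23 / W
    T2 = k1 * k2 * g * Dn(2, 1) * P[2] * P[3] / W
    T3 = -k1 * k2 * k3 * g**2 * Dn(2, 1) * Dn(3, 2) * P[3] / W
    T4 = k1 * k4 * g * Dn(4, 1) * z23 / W
    return np.stack([T1, T2, T3, T4], axis=-1)


def predict_dataset(
    deviations: dict[str, float],
    spec: ModelSpec,
    design: ConditionDesign,
    priors: PriorSet,
    grid: SpectralGrid,
    montage: np.ndarray | None = None,
) -> CrossSpectra:
    """As :func:`predict_conditions`, wrapped in a labelled container."""
    values = predict_conditions(deviations, spec, design, priors, grid, montage)
    return CrossSpectra(
        values=values,
        grid=prediction_grid(spec, grid),
        conditions=list(design.labels),
        sites=[f"site{i}" for i in range(values.shape[-1])],
    )
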