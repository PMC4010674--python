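"""Predefined synthetic studies: recovery of parameters, models and fields.

These are the package's standing in-silico experiments.  Each one generates
data from a known ground truth under the nine-contrast study design, inverts
the candidate models and summarises the outcome.  The reduced frequency grid
(24 frequencies, 4-90 Hz, 16 wavenumber pairs) and the compact free-parameter
set keep a ten-seed study within desk-scale runtimes; docs/methods.md states
the problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpectralGrid
from .inversion import compare_models, variational_laplace
from .priors import (
    ConditionDesign,
    ModelSpec,
    PriorSet,
    build_model_space,
    mass_restriction,
    model_priors,
)
from .synth import (
    DEFAULT_TRUE_DEVIATIONS,
    DEFAULT_TRUE_SENSITIVITIES,
    generate_dataset,
)

__all__ = [
    "study_grid",
    "study_free_set",
    "reduced_priors",
    "parameter_recovery_study",
    "model_recovery_study",
    "field_mass_study",
]


def study_grid() -> SpectralGrid:
    """Reduced spectral grid used by the recovery studies."""
    return SpectralGrid.default(freqs=np.linspace(4.0, 90.0, 24), n_modes=16)


def study_free_set(spec: ModelSpec, n_sites: int = 4) -> set[str]:
    """Free parameters of the recovery studies: the ten coupling strengths,
    the stellate->superficial spatial decay, the input and channel noise
    amplitudes and the model's contrast sensitivities (site gains for the
    mass variant)."""
    keep = {f"alpha_{a}{b}" for a, b in
            [(1, 1), (1, 2), (1, 4), (2, 1), (2, 2), (2, 3),
             (3, 2), (3, 3), (4, 1), (4, 4)]}
    keep |= {"c_41", "alpha_u", "alpha_n"}
    keep |= set(spec.sensitivity_names)
    if not spec.field:
        keep |= {f"gain_{i}" for i in range(n_sites)}
        keep -= {"c_41"}
    return keep


def reduced_priors(spec: ModelSpec, n_sites: int = 4) -> PriorSet:
    pr = model_priors(spec, n_sites=n_sites)
    keep = study_free_set(spec, n_sites)
    return pr.with_fixed([n for n in pr.free_names if n not in keep])


@dataclass
class RecoveryOutcome:
    seeds: list[int]
    sign_recovered: list[bool]
    coverage: list[float]  # per-seed fraction of free parameters covered

    @property
    def sign_rate(self) -> float:
        return float(np.mean(self.sign_recovered))

    @property
    def pooled_coverage(self) -> float:
        return float(np.mean(self.coverage))


def parameter_recovery_study(
    seeds=range(10),
    n_epochs: int = 256,
    max_iter: int = 48,
    design: ConditionDesign | None = None,
) -> RecoveryOutcome:
    """Invert model 7 on data it generated; check sensitivity signs and CIs.

    Ground truth: the default study deviations with positive coupling
    sensitivities on alpha_14/alpha_41 and the negative (disinhibition)
    sensitivity on alpha_44.
    """
    design = ConditionDesign.study() if design is None else design
    spec = build_model_space()[6]
    grid = study_grid()
    priors = reduced_priors(spec)
    truth = dict(DEFAULT_TRUE_DEVIATIONS, **DEFAULT_TRUE_SENSITIVITIES)

    signs, cover = [], []
    for seed in seeds:
        ds = generate_dataset(truth, spec, design, n_epochs=n_epochs,
                              seed=int(seed), grid=grid, priors=priors)
        res = variational_laplace(ds.data, spec, design, priors=priors,
                                  grid=grid, max_iter=max_iter)
        i44 = res.names.index("beta__alpha_44")
        signs.append(bool(res.mean[i44] < 0))
        hits = 0
        for j, name in enumerate(res.names):
            lo, hi = res.interval(name, prob=0.9)
            hits += lo <= truth.get(name, 0.0) <= hi
        cover.append(hits / len(res.names))
    return RecoveryOutcome(seeds=list(seeds), sign_recovered=signs,
                           coverage=cover)


@dataclass
class ModelRecoveryOutcome:
    generating: str
    seeds: list[int]
    winners: list[str]
    relative_f: list[dict[str, float]]

    @property
    def win_rate(self) -> float:
        return float(np.mean([w == self.generating for w in self.winners]))


#: Generating sensitivity patterns of the single-factor recovery studies.
RECOVERY_TRUTHS = {
    "G": {"beta__alpha_44": -0.5},
    "E": {"beta__c_41": 0.4, "beta__c_14": 0.4},
}


def model_recovery_study(
    generating: str = "G",
    seeds=range(10),
    n_epochs: int = 512,
    max_iter: int = 32,
    design: ConditionDesign | None = None,
) -> ModelRecoveryOutcome:
    """Fixed-effects BMC among {G, L, E, null} on single-factor data."""
    design = ConditionDesign.study() if design is None else design
    space = build_model_space()
    candidates = [space[0], space[1], space[2], space[7]]
    gen_spec = {m.name: m for m in candidates}[generating]
    grid = study_grid()
    truth = dict(DEFAULT_TRUE_DEVIATIONS, **RECOVERY_TRUTHS[generating])

    winners, rels = [], []
    for seed in seeds:
        ds = generate_dataset(truth, gen_spec, design, n_epochs=n_epochs,
                              seed=int(seed), grid=grid,
                              priors=reduced_priors(gen_spec))
        results = [
            variational_laplace(ds.data, m, design, priors=reduced_priors(m),
                                grid=grid, max_iter=max_iter)
            for m in candidates
        ]
        bmc = compare_models(results, names=[m.name for m in candidates])
        winners.append(bmc.best)
        rels.append(dict(zip(bmc.names, bmc.relative_log_evidence)))
    return ModelRecoveryOutcome(generating=generating, seeds=list(seeds),
                                winners=winners, relative_f=rels)


@dataclass
class FieldMassOutcome:
    seeds: list[int]
    delta_f: list[float]  # field minus mass

    @property
    def success_rate(self) -> float:
        return float(np.mean([d > 3.0 for d in self.delta_f]))


def field_mass_study(
    seeds=range(10),
    n_epochs: int = 256,
    max_iter: int = 32,
    design: ConditionDesign | None = None,
) -> FieldMassOutcome:
    """Field versus point-source (mass) evidence on field-generated data."""
    design = ConditionDesign.study() if design is None else design
    null = build_model_space()[7]
    null_mass = mass_restriction(null)
    grid = study_grid()
    truth = dict(DEFAULT_TRUE_DEVIATIONS)

    deltas = []
    for seed in seeds:
        ds = generate_dataset(truth, null, design, n_epochs=n_epochs,
                              seed=int(seed), grid=grid,
                              priors=reduced_priors(null))
        rf = variational_laplace(ds.data, null, design,
                                 priors=reduced_priors(null), grid=grid,
                                 max_iter=max_iter)
        rm = variational_laplace(ds.data, null_mass, design,
                                 priors=reduced_priors(null_mass), grid=grid,
                                 max_iter=max_iter)
        deltas.append(float(rf.free_energy - rm.free_energy))
    return FieldMassOutcome(seeds=list(seeds), delta_f=deltas)
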