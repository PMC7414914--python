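"""Seedable simulation of synthetic concentration–response datasets.

Generates curves from the SABRE model with additive Gaussian error on the
0–100 % response scale (sd in percentage points — the absolute-error
convention of "simulate with 5 % random error"; a relative-error mode is
also available).  Named presets reproduce the published simulated designs:

========  ====================================================================
preset    design
========  ====================================================================
fig3      three agonists, Emax-type curves (log EC50 −8/−7/−6, plateaus
          100/90/60 %), no amplification
fig4      non-unity Hill slopes (n = 2.0 and 0.66), otherwise as fig3
fig5      the fig3 response curves plus independently measured log Kds
          (−6.7/−6.6/−5.2) attached as a fixed-Kd table for global fitting
          with one shared gain
fig6      3 compounds (log Kd −6/−7/−5, ε 0.5/0.1/1.0) × 3 readouts of
          increasing amplification (γ = 1, 20, 500)
fig8      biased agonism: two pathways (γ_P1 = 4, γ_P2 = 20), compound 2
          biased (ε_P1 = 0.5, ε_P2 = 0.1), compounds 1 and 3 balanced
========  ====================================================================

The default concentration grid is 11 half-log-spaced points spanning
log EC50 ± 2.5 for each curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fitting import Curve, DoseResponseDataset
from .model import (
    LigandParams,
    ModelSpec,
    ParameterError,
    PathwayParams,
    sabre_response,
)

__all__ = [
    "SimCompound",
    "SimulationScenario",
    "simulate",
    "preset",
    "preset_fit_spec",
    "PRESETS",
]

#: noise level of the published simulated designs (percentage points)
DEFAULT_NOISE_SD = 5.0
#: half-log grid of 11 points centred on each curve's log EC50
GRID_HALFSPAN = 2.5
GRID_STEP = 0.5


@dataclass(frozen=True)
class SimCompound:
    """Generating parameters for one simulated compound.

    ``eps`` is a scalar or a per-pathway mapping.  ``fixed_log_kd``, when
    set, is carried into the dataset as the compound's independently
    "measured" dissociation constant — the value a subsequent fit fixes,
    which need not equal the generating ``log_kd`` (the fig5 design
    generates Emax-style curves but fits with external Kds).
    """

    name: str
    log_kd: float
    eps: float | Mapping[str, float]
    hill_n: float = 1.0
    fixed_log_kd: float | None = None

    def as_ligand(self) -> LigandParams:
        eps = dict(self.eps) if isinstance(self.eps, Mapping) else self.eps
        return LigandParams(log_kd=self.log_kd, eps=eps, hill_n=self.hill_n,
                            name=self.name)


@dataclass(frozen=True)
class SimulationScenario:
    """A complete simulated study: compounds × pathways, grid, noise, seed."""

    compounds: Sequence[SimCompound]
    pathways: Sequence[PathwayParams]
    noise_sd: float = DEFAULT_NOISE_SD
    conc_grid: np.ndarray | None = None  # common grid; None -> per-curve default
    noise_mode: str = "absolute"  # or "relative" (sd = noise_sd % of the value)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.noise_mode not in ("absolute", "relative"):
            raise ParameterError(f"noise_mode must be 'absolute' or 'relative', "
                                 f"got {self.noise_mode!r}")
        if self.conc_grid is not None:
            grid = np.asarray(self.conc_grid, dtype=float)
            if grid.ndim != 1 or np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
                raise ParameterError("conc_grid must be strictly increasing and positive")
            object.__setattr__(self, "conc_grid", grid)


def _default_grid(ligand: LigandParams, pathway: PathwayParams) -> np.ndarray:
    # grid placement only: the eps_r0=0 midpoint formula locates the
    # transition region well enough even for constitutively active systems
    eps = ligand.eps_for(pathway)
    q = max(eps * pathway.gamma - eps + 1.0, 1.0)
    ec50 = ligand.kd / q ** (1.0 / ligand.hill_n)
    log_c = np.log10(ec50) + np.arange(-GRID_HALFSPAN, GRID_HALFSPAN + GRID_STEP / 2,
                                       GRID_STEP)
    return 10.0 ** log_c


def simulate(scenario: SimulationScenario, seed: int | None = None) -> DoseResponseDataset:
    """Generate a dataset: response % = 100·f_resp + Gaussian noise.

    Reproducible per seed (``seed`` overrides ``scenario.seed``); with
    noise_sd = 0 the exact model curves are returned.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    curves = []
    fixed: dict[str, float] = {}
    for pathway in scenario.pathways:
        for cpd in scenario.compounds:
            ligand = cpd.as_ligand()
            # only evaluate compounds parametrized for this pathway
            if isinstance(cpd.eps, Mapping) and pathway.name not in cpd.eps:
                continue
            grid = (scenario.conc_grid if scenario.conc_grid is not None
                    else _default_grid(ligand, pathway))
            truth = 100.0 * sabre_response(grid, ligand, pathway)
            if scenario.noise_sd > 0:
                if scenario.noise_mode == "absolute":
                    noise = rng.normal(0.0, scenario.noise_sd, size=grid.size)
                else:
                    noise = rng.normal(0.0, 1.0, size=grid.size) * (
                        scenario.noise_sd / 100.0) * truth
                resp = truth + noise
            else:
                resp = truth
            curves.append(Curve(cpd.name, pathway.name or "P1", grid, resp))
            if cpd.fixed_log_kd is not None:
                fixed[cpd.name] = cpd.fixed_log_kd
    return DoseResponseDataset(curves=curves, fixed_log_kd=fixed)


# ----------------------------------------------------------------------------
# named presets for the published simulated designs
# ----------------------------------------------------------------------------


def _fig3() -> SimulationScenario:
    # Emax-type generation: Kd plays the role of EC50 (gamma = 1)
    return SimulationScenario(
        compounds=(
            SimCompound("cpd1", log_kd=-8.0, eps=1.0),
            SimCompound("cpd2", log_kd=-7.0, eps=0.9),
            SimCompound("cpd3", log_kd=-6.0, eps=0.6),
        ),
        pathways=(PathwayParams(gamma=1.0, name="P1"),),
    )


def _fig4() -> SimulationScenario:
    return SimulationScenario(
        compounds=(
            SimCompound("cpd1", log_kd=-6.0, eps=1.0, hill_n=2.0),
            SimCompound("cpd2", log_kd=-7.0, eps=0.9, hill_n=0.66),
        ),
        pathways=(PathwayParams(gamma=1.0, name="P1"),),
    )


def _fig5() -> SimulationScenario:
    # same response curves as fig3, but each compound additionally carries an
    # independently measured Kd; the fit fixes those and shares one gamma
    base = _fig3()
    fixed = {"cpd1": -6.7, "cpd2": -6.6, "cpd3": -5.2}
    compounds = tuple(replace(c, fixed_log_kd=fixed[c.name]) for c in base.compounds)
    return replace(base, compounds=compounds)


def _fig6() -> SimulationScenario:
    return SimulationScenario(
        compounds=(
            SimCompound("cpd1", log_kd=-6.0, eps=0.5),
            SimCompound("cpd2", log_kd=-7.0, eps=0.1),
            SimCompound("cpd3", log_kd=-5.0, eps=1.0),
        ),
        pathways=(
            PathwayParams(gamma=1.0, name="readout1"),
            PathwayParams(gamma=20.0, name="readout2"),
            PathwayParams(gamma=500.0, name="readout3"),
        ),
    )


def _fig8() -> SimulationScenario:
    # Kds are treated as known from binding (fixed at the generating values),
    # mirroring the experimental biased-agonism design (2 gammas + 6 eps free)
    return SimulationScenario(
        compounds=(
            SimCompound("cpd1", log_kd=-6.0, eps={"P1": 0.5, "P2": 0.5},
                        fixed_log_kd=-6.0),
            SimCompound("cpd2", log_kd=-7.0, eps={"P1": 0.5, "P2": 0.1},
                        fixed_log_kd=-7.0),
            SimCompound("cpd3", log_kd=-5.0, eps={"P1": 1.0, "P2": 1.0},
                        fixed_log_kd=-5.0),
        ),
        pathways=(
            PathwayParams(gamma=4.0, name="P1"),
            PathwayParams(gamma=20.0, name="P2"),
        ),
    )


PRESETS = {"fig3": _fig3, "fig4": _fig4, "fig5": _fig5, "fig6": _fig6, "fig8": _fig8}


def preset(name: str) -> SimulationScenario:
    """Return the named simulation scenario with its published parameters."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def preset_fit_spec(name: str) -> ModelSpec:
    """The ModelSpec matching each preset's published fitting design.

    fig3: Emax ladder (2 parameters per compound).  fig4: Emax + free
    per-curve Hill n.  fig5: minimal two-state with Kds fixed at their
    measured values, one shared gamma, free eps per compound (n_p = 4).
    fig6: minimal two-state, one eps per compound shared across readouts and
    one gamma per readout (n_p = 9).  fig8: minimal two-state with Kds fixed,
    per-pathway eps (n_p = 8).
    """
    from .model import ParamRule

    if name == "fig3":
        return ModelSpec.emax()
    if name == "fig4":
        # Emax-type fit with a per-curve Hill slope released (gamma stays 1)
        return ModelSpec(rules={
            "log_kd": ParamRule.free("compound"),
            "eps": ParamRule.free("compound_pathway"),
            "eps_r0": ParamRule.fixed(0.0, share="pathway"),
            "gamma": ParamRule.fixed(1.0, share="pathway"),
            "hill_n": ParamRule.free("curve"),
        })
    if name == "fig5":
        return ModelSpec.minimal_two_state(fix_kd=True)
    if name == "fig6":
        return ModelSpec.minimal_two_state(eps_share="compound")
    if name == "fig8":
        return ModelSpec.minimal_two_state(fix_kd=True)
    raise ParameterError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
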