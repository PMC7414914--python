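"""Closed-form evaluation of the SABRE receptor-response model.

SABRE is a unified two-state receptor model that separates the three stages
of receptor signaling into independent parameters:

* binding       — equilibrium dissociation constant ``Kd`` (here on a log10 M
                  scale, ``log_kd``), an ensemble-averaged, experimentally
                  measurable constant;
* activation    — intrinsic efficacy ``eps`` (ε), the fraction of ligand-bound
                  receptors in the active conformation, with ``eps_r0`` (ε_R0)
                  the analogous fraction for ligand-free receptors
                  (constitutive activity);
* transduction  — a pathway-specific post-receptor gain ``gamma`` (γ ≥ 1)
                  that amplifies activation into response through an
                  odds-ratio (hyperbolic) transform.

A Hill coefficient ``n`` applied to the concentration-like terms accommodates
slopes steeper or shallower than simple mass action.  Fractional response is

    f_resp = (ε γ L^n + ε_R0 γ Kd^n)
             / ((ε γ − ε + 1) L^n + (ε_R0 γ − ε_R0 + 1) Kd^n)

Constraining parameters to special values collapses the model through a
nested ladder of classical forms: n = 1 (full four-parameter model),
ε_R0 = 0 (minimal two-state model), γ = 1 (Emax model of partial agonism),
ε = 1 (one-parameter Clark equation).

Everything in this module is a pure in-memory computation on dimensionless
fractional responses; the 0–100 % convention lives at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

__all__ = [
    "ParameterError",
    "SingularMapError",
    "LigandParams",
    "PathwayParams",
    "OperationalParams",
    "ParamRule",
    "ModelSpec",
    "ReducedModel",
    "reduce_model",
    "sabre_response",
    "fraction_active",
    "amplify",
    "derived_ec50_emax",
    "occupancy",
    "inverse_occupancy",
    "response_from_occupancy",
    "operational_response",
    "sabre_to_operational",
    "operational_to_sabre",
    "bias_plot_curve",
    "PARAM_KINDS",
    "LADDER_LEVELS",
]

# ----------------------------------------------------------------------------
# configuration: parameter scales and bounds used throughout the package
# ----------------------------------------------------------------------------

#: bounds for efficacy-like parameters (agonists/antagonists)
EPS_BOUNDS = (0.0, 1.0)
#: gamma is optimized as log10(gamma); the lower bound enforces gamma >= 1
LOG_GAMMA_BOUNDS = (0.0, 6.0)
#: Hill n is optimized as log10(n); default bounds n in [0.1, 10]
LOG_N_BOUNDS = (-1.0, 1.0)
#: default box for free log10 Kd values (molar scale)
LOG_KD_BOUNDS = (-12.0, 0.0)

PARAM_KINDS = ("log_kd", "eps", "eps_r0", "gamma", "hill_n")
LADDER_LEVELS = ("clark", "emax", "minimal_two_state", "full", "full_hill")


class ParameterError(ValueError):
    """A model parameter or input is outside its mathematical domain."""


class SingularMapError(ValueError):
    """A parameter-space transform is undefined at the requested point."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------

EpsLike = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class LigandParams:
    """Per-compound parameters: affinity, efficacy, Hill slope.

    ``eps`` may be a scalar (single pathway) or a mapping from pathway name
    to efficacy (biased-agonism settings, where one ligand carries a distinct
    ε per downstream pathway).
    """

    log_kd: float
    eps: EpsLike
    hill_n: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        _check(math.isfinite(self.log_kd), f"log_kd must be finite, got {self.log_kd}")
        _check(self.hill_n > 0, f"hill_n must be > 0, got {self.hill_n}")
        for key, value in self._eps_items():
            label = f"eps[{key}]" if key is not None else "eps"
            _check(
                EPS_BOUNDS[0] <= value <= EPS_BOUNDS[1],
                f"{label} must lie in [0, 1], got {value}",
            )

    def _eps_items(self):
        if isinstance(self.eps, Mapping):
            return list(self.eps.items())
        return [(None, float(self.eps))]

    @property
    def kd(self) -> float:
        """Dissociation constant in molar."""
        return 10.0 ** self.log_kd

    def eps_for(self, pathway: "PathwayParams | str | None" = None) -> float:
        """Resolve the efficacy for a given pathway (name or PathwayParams)."""
        if not isinstance(self.eps, Mapping):
            return float(self.eps)
        key = pathway.name if isinstance(pathway, PathwayParams) else pathway
        if key is None or key not in self.eps:
            raise ParameterError(
                f"ligand {self.name!r} has per-pathway eps {sorted(self.eps)}; "
                f"cannot resolve pathway {key!r}"
            )
        return float(self.eps[key])


@dataclass(frozen=True)
class PathwayParams:
    """Per-pathway parameters: amplification gain and basal receptor efficacy."""

    gamma: float
    eps_r0: float = 0.0
    name: str | None = None

    def __post_init__(self) -> None:
        _check(self.gamma >= 1.0, f"gamma must satisfy gamma >= 1, got {self.gamma}")
        _check(
            EPS_BOUNDS[0] <= self.eps_r0 <= EPS_BOUNDS[1],
            f"eps_r0 must lie in [0, 1], got {self.eps_r0}",
        )


@dataclass(frozen=True)
class OperationalParams:
    """Parameters of the operational (Black & Leff) comparator model.

    ``tau`` is the transducer ratio; ``alpha`` the Emax scaling factor of the
    fixed-Kd "special edition" variant; ``chi`` (with ``eps``) parametrizes
    the Slack–Hall extension for constitutive activity.
    """

    log_KD: float
    tau: float | None = None
    alpha: float | None = None
    chi: float | None = None
    eps: float | None = None

    def __post_init__(self) -> None:
        _check(math.isfinite(self.log_KD), f"log_KD must be finite, got {self.log_KD}")
        if self.tau is not None:
            _check(self.tau >= 0, f"tau must be >= 0, got {self.tau}")
        if self.chi is not None:
            _check(self.chi >= 0, f"chi must be >= 0, got {self.chi}")
        if self.eps is not None:
            _check(0 <= self.eps <= 1, f"eps must lie in [0, 1], got {self.eps}")

    @property
    def KD(self) -> float:
        return 10.0 ** self.log_KD


# ----------------------------------------------------------------------------
# response evaluation
# ----------------------------------------------------------------------------


def _response_core(conc, kd, eps, eps_r0, gamma, n):
    """Vectorized SABRE response on raw floats; no validation (hot path)."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        x = (conc / kd) ** n
        num = eps * gamma * x + eps_r0 * gamma
        den = (eps * gamma - eps + 1.0) * x + (eps_r0 * gamma - eps_r0 + 1.0)
        plateau = eps * gamma / (eps * gamma - eps + 1.0)
        out = np.where(np.isinf(x), plateau, num / den)
    return out


def _scalar_ok(out: np.ndarray):
    return float(out) if out.ndim == 0 else out


def sabre_response(conc, ligand: LigandParams, pathway: PathwayParams):
    """Fractional response f_resp in [0, 1] at ligand concentration ``conc`` (M).

    Implements the general Hill-extended form; at n=1 this is the full
    four-parameter model, and at eps_r0=0 the minimal two-state model.
    Monotone increasing in conc when eps > eps_r0, decreasing when
    eps < eps_r0 (inverse agonism), constant when equal.
    """
    conc = np.asarray(conc, dtype=float)
    _check(np.all(conc >= 0), "conc must be nonnegative (molar)")
    eps = ligand.eps_for(pathway)
    out = _response_core(conc, ligand.kd, eps, pathway.eps_r0, pathway.gamma, ligand.hill_n)
    return _scalar_ok(out)


def fraction_active(conc, ligand: LigandParams, pathway: PathwayParams):
    """Fraction of receptors in the active conformation (n = 1 form).

    f_act = (eps_r0*Kd + eps*L) / (L + Kd); bounded by min/max of
    (eps_r0, eps).  Defined for unit Hill slope only — the Hill extension
    applies at the level of the composed response, not this intermediate.
    """
    _check(ligand.hill_n == 1.0, f"fraction_active requires hill_n = 1, got {ligand.hill_n}")
    conc = np.asarray(conc, dtype=float)
    _check(np.all(conc >= 0), "conc must be nonnegative (molar)")
    eps = ligand.eps_for(pathway)
    kd = ligand.kd
    out = (pathway.eps_r0 * kd + eps * conc) / (conc + kd)
    return _scalar_ok(out)


def amplify(f_act, gamma: float):
    """Post-receptor amplification: Λ/(Λ + 1/γ) with Λ = f_act/(1−f_act).

    Equals f_act at γ=1 and tends to the limit value 1 as f_act → 1
    (saturation is returned as the limit, not a division error).
    """
    _check(gamma >= 1.0, f"gamma must satisfy gamma >= 1, got {gamma}")
    f = np.asarray(f_act, dtype=float)
    _check(np.all((f >= 0) & (f <= 1)), "f_act must lie in [0, 1]")
    # algebraically Λ/(Λ+1/γ) = f*γ / (f*(γ−1) + 1), finite at f = 1
    out = f * gamma / (f * (gamma - 1.0) + 1.0)
    return _scalar_ok(out)


def derived_ec50_emax(ligand: LigandParams, pathway: PathwayParams):
    """Observed potency and maximal response implied by (Kd, ε, γ, n).

    With no constitutive activity, the concentration–response curve is a
    (Hill) sigmoid with

        EC50 (K_obs)  = Kd / (εγ − ε + 1)^(1/n)
        f_resp,max    = εγ / (εγ − ε + 1)

    For a full agonist (ε = 1, n = 1) the gain is a pure left-shift:
    K_obs = Kd/γ.  Returns ``(K_obs, f_resp_max)``.
    """
    _check(pathway.eps_r0 == 0.0, "derived_ec50_emax requires eps_r0 = 0")
    eps = ligand.eps_for(pathway)
    q = eps * pathway.gamma - eps + 1.0
    k_obs = ligand.kd / q ** (1.0 / ligand.hill_n)
    f_max = eps * pathway.gamma / q
    return k_obs, f_max


def occupancy(conc, log_kd: float, hill_n: float = 1.0):
    """Fractional receptor occupancy L^n / (L^n + Kd^n) (Hill–Langmuir)."""
    _check(hill_n > 0, f"hill_n must be > 0, got {hill_n}")
    conc = np.asarray(conc, dtype=float)
    _check(np.all(conc >= 0), "conc must be nonnegative (molar)")
    kd = 10.0 ** log_kd
    with np.errstate(over="ignore", invalid="ignore"):
        x = (conc / kd) ** hill_n
        out = np.where(np.isinf(x), 1.0, x / (x + 1.0))
    return _scalar_ok(out)


def inverse_occupancy(f_occup, log_kd: float, hill_n: float = 1.0):
    """Concentration producing occupancy ``f_occup``: Kd*(f/(1−f))^(1/n).

    Round-trip inverse of :func:`occupancy`; f_occup = 1 requires infinite
    concentration and is a domain error.
    """
    _check(hill_n > 0, f"hill_n must be > 0, got {hill_n}")
    f = np.asarray(f_occup, dtype=float)
    _check(np.all((f >= 0) & (f < 1)), "f_occup must lie in [0, 1)")
    kd = 10.0 ** log_kd
    out = kd * (f / (1.0 - f)) ** (1.0 / hill_n)
    return _scalar_ok(out)


def response_from_occupancy(f_occup, eps: float, gamma: float):
    """Fractional response as a direct function of occupancy (ε_R0=0, n=1).

    f_resp = εγ f / (ε(γ−1) f + 1).  Identical to evaluating the response
    at the concentration implied by ``inverse_occupancy``; usable for direct
    response-versus-occupancy fitting when experimental Kds are available.
    """
    _check(EPS_BOUNDS[0] <= eps <= EPS_BOUNDS[1], f"eps must lie in [0, 1], got {eps}")
    _check(gamma >= 1.0, f"gamma must satisfy gamma >= 1, got {gamma}")
    f = np.asarray(f_occup, dtype=float)
    _check(np.all((f >= 0) & (f <= 1)), "f_occup must lie in [0, 1]")
    out = eps * gamma * f / (eps * (gamma - 1.0) * f + 1.0)
    return _scalar_ok(out)


# ----------------------------------------------------------------------------
# operational (Black & Leff) comparator model and parameter maps
# ----------------------------------------------------------------------------


def operational_response(conc, params: OperationalParams, variant: str = "basic"):
    """Fractional response under the operational model and its extensions.

    variant="basic":      τL / ((τ+1)L + K_D)
    variant="scaled":     α · τL / ((τ+1)L + K_D)   (fixed-Kd "special edition")
    variant="slack_hall": χ(K_D + εL) / ((K_D + L) + χ(K_D + εL))
    """
    conc = np.asarray(conc, dtype=float)
    _check(np.all(conc >= 0), "conc must be nonnegative (molar)")
    KD = params.KD
    if variant in ("basic", "scaled"):
        _check(params.tau is not None, f"variant {variant!r} requires tau")
        base = params.tau * conc / ((params.tau + 1.0) * conc + KD)
        if variant == "basic":
            return _scalar_ok(base)
        _check(params.alpha is not None, "variant 'scaled' requires alpha")
        return _scalar_ok(params.alpha * base)
    if variant == "slack_hall":
        _check(params.chi is not None and params.eps is not None,
               "variant 'slack_hall' requires chi and eps")
        act = params.chi * (KD + params.eps * conc)
        return _scalar_ok(act / ((KD + conc) + act))
    raise ParameterError(
        f"unknown operational variant {variant!r}; choose basic, scaled or slack_hall"
    )


def sabre_to_operational(log_kd: float, eps: float, gamma: float) -> OperationalParams:
    """Map (Kd, ε, γ) to the fixed-Kd operational parameters (K_D, τ, α).

    K_D = Kd, τ = ε(γ−1), α = γ/(γ−1).  The map is singular at γ = 1
    (no amplification means α is undefined); that case raises.
    """
    _check(EPS_BOUNDS[0] <= eps <= EPS_BOUNDS[1], f"eps must lie in [0, 1], got {eps}")
    _check(gamma >= 1.0, f"gamma must satisfy gamma >= 1, got {gamma}")
    if gamma == 1.0:
        raise SingularMapError("sabre_to_operational is undefined at gamma = 1 (alpha = gamma/(gamma-1))")
    return OperationalParams(log_KD=log_kd, tau=eps * (gamma - 1.0), alpha=gamma / (gamma - 1.0))


def operational_to_sabre(params: OperationalParams) -> tuple[float, float, float]:
    """Inverse map (K_D, τ, α) → (log_kd, ε, γ): ε = τ(α−1), γ = α/(α−1).

    Exact inverse of :func:`sabre_to_operational`.  α ≤ 1 makes γ undefined
    or negative and raises.  Arbitrary (τ, α) pairs can produce ε outside
    [0, 1]; such values are returned unclipped with a warning, since the map
    itself is well-defined there.
    """
    _check(params.tau is not None and params.alpha is not None,
           "operational_to_sabre requires tau and alpha")
    if params.alpha <= 1.0:
        raise SingularMapError(
            f"operational_to_sabre requires alpha > 1 (gamma = alpha/(alpha-1)); got {params.alpha}"
        )
    eps = params.tau * (params.alpha - 1.0)
    gamma = params.alpha / (params.alpha - 1.0)
    if not (EPS_BOUNDS[0] <= eps <= EPS_BOUNDS[1]):
        warnings.warn(
            f"operational_to_sabre produced eps = {eps:.6g} outside [0, 1]; "
            "returned unclipped", stacklevel=2,
        )
    return params.log_KD, eps, gamma


def bias_plot_curve(f_resp_p1, eps_p1: float, eps_p2: float,
                    gamma_p1: float, gamma_p2: float):
    """Response along pathway 2 as a function of response along pathway 1.

    For two pathways driven at the same ligand concentration (hence the same
    occupancy), with ε_R0 = 0 and n = 1:

        f_P2 = ε2 γ2 f_P1 / (ε1 γ1 + [ε2(γ2−1) − ε1(γ1−1)] f_P1)

    Balanced ligands (ε1 = ε2) still give a curvilinear relative-response
    plot whenever γ1 ≠ γ2; equal gains and efficacies give the identity line.
    """
    for label, v in (("eps_p1", eps_p1), ("eps_p2", eps_p2)):
        _check(EPS_BOUNDS[0] <= v <= EPS_BOUNDS[1], f"{label} must lie in [0, 1], got {v}")
    for label, v in (("gamma_p1", gamma_p1), ("gamma_p2", gamma_p2)):
        _check(v >= 1.0, f"{label} must satisfy gamma >= 1, got {v}")
    f1 = np.asarray(f_resp_p1, dtype=float)
    _check(np.all((f1 >= 0) & (f1 <= 1)), "f_resp_p1 must lie in [0, 1]")
    num = eps_p2 * gamma_p2 * f1
    den = eps_p1 * gamma_p1 + (eps_p2 * (gamma_p2 - 1.0) - eps_p1 * (gamma_p1 - 1.0)) * f1
    return _scalar_ok(num / den)


# ----------------------------------------------------------------------------
# model specification: the constraint ladder
# ----------------------------------------------------------------------------

_SHARE_LEVELS = {"curve", "compound", "pathway", "compound_pathway", "global"}

_DEFAULT_SHARE = {
    "log_kd": "compound",
    "eps": "compound_pathway",
    "eps_r0": "pathway",
    "gamma": "pathway",
    "hill_n": "pathway",
}

# canonical fixed values required of each kind when it is constrained at a
# given declared ladder level (Fig.-2-style nesting)
_CANONICAL_FIXED = {"eps": 1.0, "eps_r0": 0.0, "gamma": 1.0, "hill_n": 1.0}

# which kinds are free at each canonical ladder level
_LADDER_FREE = {
    "clark": {"log_kd"},
    "emax": {"log_kd", "eps"},
    "minimal_two_state": {"log_kd", "eps", "gamma"},
    "full": {"log_kd", "eps", "gamma", "eps_r0"},
    "full_hill": {"log_kd", "eps", "gamma", "eps_r0", "hill_n"},
}


@dataclass(frozen=True)
class ParamRule:
    """Status of one parameter kind in a fit: free, or fixed at a value.

    ``share`` declares the grouping over which one free value is shared:
    'compound' (one per compound), 'pathway' (one per pathway),
    'compound_pathway'/'curve' (one per curve), or 'global'.  ``value`` of
    None on a fixed ``log_kd`` means "take the per-compound experimental Kd
    table attached to the dataset".
    """

    status: str  # "free" | "fixed"
    value: float | None = None
    share: str = "curve"

    def __post_init__(self) -> None:
        if self.status not in ("free", "fixed"):
            raise ParameterError(f"status must be 'free' or 'fixed', got {self.status!r}")
        if self.share not in _SHARE_LEVELS:
            raise ParameterError(f"unknown share level {self.share!r}")

    @classmethod
    def free(cls, share: str) -> "ParamRule":
        return cls(status="free", share=share)

    @classmethod
    def fixed(cls, value: float | None, share: str = "global") -> "ParamRule":
        return cls(status="fixed", value=value, share=share)


@dataclass(frozen=True)
class ModelSpec:
    """A full constraint declaration over the five SABRE parameter kinds.

    Instances are usually built via the ladder constructors
    (:meth:`clark` … :meth:`full_hill`) which encode the nested
    simplification scheme; arbitrary rule sets are accepted and validated.
    """

    rules: Mapping[str, ParamRule]
    ladder_level: str | None = None

    def __post_init__(self) -> None:
        missing = [k for k in PARAM_KINDS if k not in self.rules]
        if missing:
            raise ParameterError(f"ModelSpec missing rules for {missing}")
        unknown = [k for k in self.rules if k not in PARAM_KINDS]
        if unknown:
            raise ParameterError(f"ModelSpec has rules for unknown kinds {unknown}")
        if self.ladder_level is not None:
            if self.ladder_level not in LADDER_LEVELS:
                raise ParameterError(
                    f"unknown ladder level {self.ladder_level!r}; choose from {LADDER_LEVELS}"
                )
            reduce_model(self)  # raises on contradiction

    def rule(self, kind: str) -> ParamRule:
        return self.rules[kind]

    # -- ladder constructors --------------------------------------------------

    @classmethod
    def from_ladder(cls, level: str, *, fix_kd: bool = False,
                    eps_share: str = "compound_pathway",
                    hill_share: str = "pathway") -> "ModelSpec":
        """Build the canonical spec for a ladder level.

        ``fix_kd`` pins every compound's log Kd at its experimental value
        from the dataset table (the "connect response to occupancy" designs);
        ``eps_share='compound'`` shares one efficacy per compound across
        pathways (balanced-ligand assumption); ``hill_share`` controls
        whether a freed Hill n is per-assay ('pathway') or per-curve.
        """
        if level not in LADDER_LEVELS:
            raise ParameterError(f"unknown ladder level {level!r}; choose from {LADDER_LEVELS}")
        free = _LADDER_FREE[level]
        rules: dict[str, ParamRule] = {}
        for kind in PARAM_KINDS:
            share = dict(_DEFAULT_SHARE, eps=eps_share, hill_n=hill_share)[kind]
            if kind == "log_kd":
                rules[kind] = (ParamRule.fixed(None, share="compound") if fix_kd
                               else ParamRule.free("compound"))
            elif kind in free:
                rules[kind] = ParamRule.free(share)
            else:
                rules[kind] = ParamRule.fixed(_CANONICAL_FIXED[kind], share=share)
        return cls(rules=rules, ladder_level=level)

    @classmethod
    def clark(cls, **kw) -> "ModelSpec":
        return cls.from_ladder("clark", **kw)

    @classmethod
    def emax(cls, **kw) -> "ModelSpec":
        return cls.from_ladder("emax", **kw)

    @classmethod
    def minimal_two_state(cls, **kw) -> "ModelSpec":
        return cls.from_ladder("minimal_two_state", **kw)

    @classmethod
    def full(cls, **kw) -> "ModelSpec":
        return cls.from_ladder("full", **kw)

    @classmethod
    def full_hill(cls, **kw) -> "ModelSpec":
        return cls.from_ladder("full_hill", **kw)


@dataclass(frozen=True)
class ReducedModel:
    """Canonical ladder level implied by a constraint set, and its free-kind count."""

    ladder_level: str
    n_p: int


def reduce_model(spec: ModelSpec) -> ReducedModel:
    """Infer the canonical nested-model level implied by a ModelSpec.

    The level is set by the most complex freed parameter kind
    (hill_n → full_hill, eps_r0 → full, gamma → minimal_two_state,
    eps → emax, otherwise clark); ``n_p`` counts the free kinds (the
    per-curve adjustable-parameter count of the nesting scheme).  A declared
    ``ladder_level`` that contradicts the statuses — e.g. clark with free
    gamma, or fixed values off their canonical constraints — raises.
    """
    free = {k for k in PARAM_KINDS if spec.rules[k].status == "free"}
    if "hill_n" in free:
        level = "full_hill"
    elif "eps_r0" in free:
        level = "full"
    elif "gamma" in free:
        level = "minimal_two_state"
    elif "eps" in free:
        level = "emax"
    else:
        level = "clark"

    declared = spec.ladder_level
    if declared is not None:
        allowed = _LADDER_FREE[declared]
        stray = free - allowed
        if stray:
            raise ParameterError(
                f"ladder level {declared!r} is contradicted by free parameter(s) {sorted(stray)}"
            )
        for kind in PARAM_KINDS:
            rule = spec.rules[kind]
            if kind in _CANONICAL_FIXED and rule.status == "fixed":
                if kind not in allowed and rule.value != _CANONICAL_FIXED[kind]:
                    raise ParameterError(
                        f"ladder level {declared!r} requires {kind} fixed at "
                        f"{_CANONICAL_FIXED[kind]}, got {rule.value}"
                    )
    return ReducedModel(ladder_level=level, n_p=len(free))
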