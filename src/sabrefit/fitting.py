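"""Global nonlinear least-squares fitting of concentration–response data.

Fits any nested level of the SABRE ladder to one or many curves jointly.
Shared parameters arise from the grouping declared in the
:class:`~sabrefit.model.ModelSpec` — e.g. one gain γ per pathway, one
efficacy ε per compound per pathway, one Kd per compound — so a "global fit"
is simply a fit whose parameter table has fewer entries than curves.

Optimization runs on transformed scales (log10 Kd, log10 γ with lower bound
0 enforcing γ ≥ 1, ε box-bounded in [0, 1], log10 n) via trust-region
reflective least squares, with deterministic multi-start.  Standard errors
are asymptotic (Jacobian-based covariance at the optimum), delta-method
back-transformed to the natural scale.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    LADDER_LEVELS,
    LOG_GAMMA_BOUNDS,
    LOG_KD_BOUNDS,
    LOG_N_BOUNDS,
    PARAM_KINDS,
    ModelSpec,
    ParameterError,
    _response_core,
    reduce_model,
)

__all__ = [
    "Curve",
    "DoseResponseDataset",
    "FitResult",
    "FitError",
    "fit",
    "fit_response_vs_occupancy",
    "r_squared",
    "nested_compare",
    "NestedComparison",
    "identifiability_report",
    "IdentifiabilityReport",
]

logger = logging.getLogger("sabrefit")

#: adequate-fit guideline: data points per adjustable parameter
POINTS_PER_PARAM_MIN = 5.0

_LEASTSQ_KWS = dict(ftol=1e-13, xtol=1e-13, gtol=1e-13)


class FitError(RuntimeError):
    """Raised when no optimization start converges; carries best-so-far values."""

    def __init__(self, message: str, best_estimates: dict | None = None):
        super().__init__(message)
        self.best_estimates = best_estimates or {}


# ----------------------------------------------------------------------------
# dataset container
# ----------------------------------------------------------------------------


@dataclass
class Curve:
    """One concentration–response curve: a (compound, pathway) pair."""

    compound_id: str
    pathway_id: str
    conc: np.ndarray
    response: np.ndarray  # percent of system maximum, 0–100 convention

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape or self.conc.ndim != 1:
            raise ParameterError(
                f"curve ({self.compound_id}, {self.pathway_id}): conc and response "
                "must be 1-D arrays of equal length"
            )
        if np.any(self.conc <= 0) or not np.all(np.isfinite(self.conc)):
            raise ParameterError(
                f"curve ({self.compound_id}, {self.pathway_id}): concentrations must "
                "be positive and finite (log-scale data)"
            )
        if not np.all(np.isfinite(self.response)):
            raise ParameterError(
                f"curve ({self.compound_id}, {self.pathway_id}): responses must be finite"
            )
        order = np.argsort(self.conc)
        self.conc = self.conc[order]
        self.response = self.response[order]

    @property
    def n_points(self) -> int:
        return self.conc.size


@dataclass
class DoseResponseDataset:
    """A collection of curves plus an optional experimental-Kd table.

    ``fixed_log_kd`` maps compound id to a log10 M dissociation constant
    measured in an independent binding assay; a ModelSpec that fixes Kds
    with no explicit value draws them from this table.
    """

    curves: list[Curve]
    fixed_log_kd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.curves:
            key = (c.compound_id, c.pathway_id)
            if key in seen:
                raise ParameterError(f"duplicate curve for (compound, pathway) = {key}")
            seen.add(key)

    @property
    def n_points(self) -> int:
        return sum(c.n_points for c in self.curves)

    @property
    def compounds(self) -> list[str]:
        out: list[str] = []
        for c in self.curves:
            if c.compound_id not in out:
                out.append(c.compound_id)
        return out

    @property
    def pathways(self) -> list[str]:
        out: list[str] = []
        for c in self.curves:
            if c.pathway_id not in out:
                out.append(c.pathway_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            for conc, resp in zip(c.conc, c.response):
                row = {"compound": c.compound_id, "pathway": c.pathway_id,
                       "conc_M": conc, "response_pct": resp}
                if c.compound_id in self.fixed_log_kd:
                    row["log_kd_fixed"] = self.fixed_log_kd[c.compound_id]
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseDataset":
        curves = []
        fixed: dict[str, float] = {}
        for (cpd, pw), grp in df.groupby(["compound", "pathway"], sort=False):
            curves.append(Curve(str(cpd), str(pw),
                                grp["conc_M"].to_numpy(), grp["response_pct"].to_numpy()))
            if "log_kd_fixed" in grp and grp["log_kd_fixed"].notna().any():
                vals = grp.loc[grp["log_kd_fixed"].notna(), "log_kd_fixed"].unique()
                if len(vals) > 1:
                    raise ParameterError(
                        f"compound {cpd!r} has conflicting log_kd_fixed values {vals}"
                    )
                fixed[str(cpd)] = float(vals[0])
        return cls(curves=curves, fixed_log_kd=fixed)


# ----------------------------------------------------------------------------
# parameter bookkeeping
# ----------------------------------------------------------------------------

_SAN = re.compile(r"\W")


def _san(label: str) -> str:
    return _SAN.sub("_", str(label))


def _group_key(share: str, compound: str, pathway: str) -> tuple[str, ...]:
    if share == "compound":
        return (compound,)
    if share == "pathway":
        return (pathway,)
    if share in ("compound_pathway", "curve"):
        return (compound, pathway)
    return ("all",)


# internal (optimizer) scale per kind: name prefix, natural->internal,
# internal->natural, d(natural)/d(internal), bounds
_LN10 = np.log(10.0)
_SCALES = {
    "log_kd": ("log_kd", lambda v: v, lambda u: u, lambda u: 1.0, LOG_KD_BOUNDS),
    "eps": ("eps", lambda v: v, lambda u: u, lambda u: 1.0, (0.0, 1.0)),
    "eps_r0": ("eps_r0", lambda v: v, lambda u: u, lambda u: 1.0, (0.0, 1.0)),
    "gamma": ("log_gamma", np.log10, lambda u: 10.0 ** u,
              lambda u: _LN10 * 10.0 ** u, LOG_GAMMA_BOUNDS),
    "hill_n": ("log_n", np.log10, lambda u: 10.0 ** u,
               lambda u: _LN10 * 10.0 ** u, LOG_N_BOUNDS),
}


def _natural_name(kind: str, key: tuple[str, ...]) -> str:
    return kind + "[" + "|".join(key) + "]"


class _Problem:
    """Resolved fitting problem: lmfit parameter table plus per-curve bindings."""

    def __init__(self, dataset: DoseResponseDataset, spec: ModelSpec):
        self.dataset = dataset
        self.spec = spec
        self.param_index: dict[str, tuple[str, tuple[str, ...]]] = {}
        self.internal_of: dict[str, str] = {}  # natural name -> lmfit name
        self.fixed: dict[str, float] = {}      # natural name -> fixed value
        # per curve: kind -> ("param", internal_name) | ("fixed", value)
        self.bindings: list[dict[str, tuple[str, object]]] = []
        self._build()

    def _build(self) -> None:
        ds, spec = self.dataset, self.spec
        names_seen: dict[str, tuple] = {}
        for curve in ds.curves:
            binding: dict[str, tuple[str, object]] = {}
            for kind in PARAM_KINDS:
                rule = spec.rules[kind]
                key = _group_key(rule.share, curve.compound_id, curve.pathway_id)
                natural = _natural_name(kind, key)
                if rule.status == "fixed":
                    if kind == "log_kd" and rule.value is None:
                        if curve.compound_id not in ds.fixed_log_kd:
                            raise ParameterError(
                                f"spec fixes log_kd from the dataset table, but compound "
                                f"{curve.compound_id!r} has no fixed log_kd"
                            )
                        value = ds.fixed_log_kd[curve.compound_id]
                    else:
                        if rule.value is None:
                            raise ParameterError(f"fixed rule for {kind} needs a value")
                        value = float(rule.value)
                    self.fixed[natural] = value
                    binding[kind] = ("fixed", value)
                else:
                    prefix = _SCALES[kind][0]
                    internal = prefix + "__" + "__".join(_san(k) for k in key)
                    prev = names_seen.get(internal)
                    if prev is not None and prev != (kind, key):
                        raise ParameterError(
                            f"parameter-name collision after sanitization: {internal!r}"
                        )
                    names_seen[internal] = (kind, key)
                    self.param_index[natural] = (kind, key)
                    self.internal_of[natural] = internal
                    binding[kind] = ("param", internal)
            self.bindings.append(binding)

    @property
    def n_p(self) -> int:
        return len(set(self.internal_of.values()))

    def make_params(self, init: Mapping[str, float]) -> lmfit.Parameters:
        """Build an lmfit.Parameters table from natural-scale initial values."""
        params = lmfit.Parameters()
        done = set()
        for natural, internal in self.internal_of.items():
            if internal in done:
                continue
            done.add(internal)
            kind, _ = self.param_index[natural]
            _, to_int, _, _, bounds = _SCALES[kind]
            v = float(to_int(init[natural]))
            v = float(np.clip(v, bounds[0] + 1e-12, bounds[1] - 1e-12))
            params.add(internal, value=v, min=bounds[0], max=bounds[1])
        return params

    def residual(self, params: lmfit.Parameters) -> np.ndarray:
        vals = params.valuesdict()
        out = []
        for curve, binding in zip(self.dataset.curves, self.bindings):
            resolved = {}
            for kind in PARAM_KINDS:
                mode, ref = binding[kind]
                if mode == "fixed":
                    resolved[kind] = ref
                else:
                    resolved[kind] = _SCALES[kind][2](vals[ref])
            model = _response_core(
                curve.conc, 10.0 ** resolved["log_kd"], resolved["eps"],
                resolved["eps_r0"], resolved["gamma"], resolved["hill_n"],
            )
            out.append(curve.response - 100.0 * model)
        return np.concatenate(out)


# ----------------------------------------------------------------------------
# fit result
# ----------------------------------------------------------------------------


@dataclass
class FitResult:
    """Point estimates and uncertainty of a (global) SABRE fit.

    ``estimates``/``stderr`` are on the natural scale (log_kd in log10 M,
    eps and eps_r0 as fractions, gamma and hill_n as plain multipliers),
    keyed by names like ``"eps[cpd1|P1]"`` or ``"gamma[P1]"``.  ``covar`` is
    the asymptotic covariance on the internal optimizer scale over
    ``var_names``; :meth:`cov_natural` converts entries by the delta method.
    """

    estimates: dict[str, float]
    stderr: dict[str, float | None]
    covar: np.ndarray | None
    var_names: list[str]
    param_index: dict[str, tuple[str, tuple[str, ...]]]
    internal_of: dict[str, str]
    fixed: dict[str, float]
    residuals: np.ndarray
    r2: float
    ssr: float
    n_d: int
    n_p: int
    ladder_level: str | None
    success: bool
    message: str = ""

    @property
    def points_per_param(self) -> float:
        return self.n_d / self.n_p if self.n_p else float("inf")

    def value(self, kind: str, *key: str) -> float:
        """Look up one estimate (or fixed value) by kind and group labels."""
        name = _natural_name(kind, tuple(key))
        if name in self.estimates:
            return self.estimates[name]
        if name in self.fixed:
            return self.fixed[name]
        raise KeyError(name)

    def _dnat_dint(self, natural: str) -> float:
        kind, _ = self.param_index[natural]
        internal_val = _SCALES[kind][1](self.estimates[natural])
        return float(_SCALES[kind][3](internal_val))

    def cov_natural(self, name_a: str, name_b: str) -> float | None:
        """Covariance of two natural-scale estimates (delta method)."""
        if self.covar is None:
            return None
        try:
            ia = self.var_names.index(self.internal_of[name_a])
            ib = self.var_names.index(self.internal_of[name_b])
        except (KeyError, ValueError):
            return None
        return float(self.covar[ia, ib] * self._dnat_dint(name_a) * self._dnat_dint(name_b))

    def ci95(self, name: str) -> tuple[float, float] | None:
        """95 % normal-approximation confidence interval on the natural scale."""
        se = self.stderr.get(name)
        if se is None:
            return None
        v = self.estimates[name]
        return (v - 1.959963984540054 * se, v + 1.959963984540054 * se)

    def params_frame(self) -> pd.DataFrame:
        """Flat parameter report: name, kind, estimate, SE, 95 % CI."""
        rows = []
        for name, val in self.estimates.items():
            kind, key = self.param_index[name]
            se = self.stderr.get(name)
            ci = self.ci95(name)
            rows.append({
                "name": name, "kind": kind, "group": "|".join(key),
                "estimate": val, "stderr": se,
                "ci95_low": ci[0] if ci else None, "ci95_high": ci[1] if ci else None,
                "status": "free",
            })
        for name, val in self.fixed.items():
            kind = name.split("[", 1)[0]
            rows.append({"name": name, "kind": kind,
                         "group": name[name.index("[") + 1:-1],
                         "estimate": val, "stderr": None,
                         "ci95_low": None, "ci95_high": None, "status": "fixed"})
        return pd.DataFrame(rows)

    # -- serialization --------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "estimates": self.estimates,
            "stderr": self.stderr,
            "covar": None if self.covar is None else self.covar.tolist(),
            "var_names": self.var_names,
            "param_index": {k: [v[0], list(v[1])] for k, v in self.param_index.items()},
            "internal_of": self.internal_of,
            "fixed": self.fixed,
            "residuals": self.residuals.tolist(),
            "r2": self.r2, "ssr": self.ssr, "n_d": self.n_d, "n_p": self.n_p,
            "ladder_level": self.ladder_level,
            "success": self.success, "message": self.message,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            estimates=payload["estimates"],
            stderr=payload["stderr"],
            covar=None if payload["covar"] is None else np.asarray(payload["covar"]),
            var_names=payload["var_names"],
            param_index={k: (v[0], tuple(v[1])) for k, v in payload["param_index"].items()},
            internal_of=payload["internal_of"],
            fixed=payload["fixed"],
            residuals=np.asarray(payload["residuals"]),
            r2=payload["r2"], ssr=payload["ssr"],
            n_d=payload["n_d"], n_p=payload["n_p"],
            ladder_level=payload["ladder_level"],
            success=payload["success"], message=payload.get("message", ""),
        )


# ----------------------------------------------------------------------------
# statistics helpers
# ----------------------------------------------------------------------------


def r_squared(observed, fitted) -> float:
    """Pooled coefficient of determination 1 − SS_res/SS_tot.

    SS_tot is taken about the grand mean of all points entering the fit, so a
    global multi-curve fit reports one pooled r².  Zero variance in the
    observations makes r² undefined; that case returns NaN with a warning.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    fit_ = np.asarray(fitted, dtype=float).ravel()
    if obs.size < 2 or obs.size != fit_.size:
        raise ParameterError("r_squared needs >= 2 paired points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("observed values have zero variance; r^2 is undefined", stacklevel=2)
        return float("nan")
    ss_res = float(np.sum((obs - fit_) ** 2))
    return 1.0 - ss_res / ss_tot


# ----------------------------------------------------------------------------
# initialization heuristics
# ----------------------------------------------------------------------------


def _empirical_log_ec50(curve: Curve) -> float:
    """Crude half-maximum crossing on the measured grid (initialization only)."""
    top = float(np.max(curve.response))
    half = top / 2.0
    idx = int(np.argmin(np.abs(curve.response - half)))
    return float(np.log10(curve.conc[idx]))


def _heuristic_init(problem: _Problem) -> dict[str, float]:
    ds = problem.dataset
    emp_ec50 = {(c.compound_id, c.pathway_id): _empirical_log_ec50(c) for c in ds.curves}
    emp_top = {(c.compound_id, c.pathway_id): float(np.max(c.response)) for c in ds.curves}

    # Kd >= EC50 for any eps<=1, gamma>=1, so seed each compound's Kd at its
    # least-amplified (largest) empirical EC50, or its fixed value if present
    kd0: dict[str, float] = {}
    for cpd in ds.compounds:
        if cpd in ds.fixed_log_kd:
            kd0[cpd] = ds.fixed_log_kd[cpd]
        else:
            kd0[cpd] = max(v for (c, _), v in emp_ec50.items() if c == cpd)

    init: dict[str, float] = {}
    for natural, (kind, key) in problem.param_index.items():
        if kind == "log_kd":
            init[natural] = kd0[key[0]]
        elif kind == "eps":
            tops = [v for (c, p), v in emp_top.items()
                    if _group_key(problem.spec.rules["eps"].share, c, p) == key]
            init[natural] = float(np.clip(max(tops) / 100.0, 0.05, 1.0))
        elif kind == "eps_r0":
            init[natural] = 0.05
        elif kind == "gamma":
            shifts = [kd0[c] - v for (c, p), v in emp_ec50.items()
                      if _group_key(problem.spec.rules["gamma"].share, c, p) == key]
            init[natural] = float(np.clip(10.0 ** np.mean(shifts), 1.0, 1e6))
        elif kind == "hill_n":
            init[natural] = 1.0
    return init


def _perturb(init: Mapping[str, float], problem: _Problem,
             rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for natural, v in init.items():
        kind, _ = problem.param_index[natural]
        if kind == "log_kd":
            out[natural] = v + rng.normal(0.0, 0.5)
        elif kind in ("eps", "eps_r0"):
            out[natural] = float(np.clip(v * 10.0 ** rng.normal(0.0, 0.3), 1e-3, 1.0))
        elif kind == "gamma":
            out[natural] = float(np.clip(v * 10.0 ** rng.normal(0.0, 1.0), 1.0, 1e6))
        else:  # hill_n
            out[natural] = float(np.clip(v * 10.0 ** rng.normal(0.0, 0.15), 0.1, 10.0))
    return out


# ----------------------------------------------------------------------------
# gauge normalization
#
# With eps_r0 = 0 and n = 1, a global fit in which every Kd, eps and gamma is
# free carries an exact one-parameter degeneracy: for any c > 0,
#
#     eps  -> eps / (eps + c*(1 - eps))
#     gamma -> c * gamma
#     Kd   -> Kd * c / (eps + c*(1 - eps))
#
# reproduces every model curve identically (plateaus and EC50s are invariant),
# so only gamma ratios are determined by response data alone.  Fixing Kds at
# measured values breaks the degeneracy; without that, the gamma >= 1 bound
# makes the minimal-amplification representative (min_p gamma_p = 1) the
# canonical point of the flat ridge, and we report that representative.
# ----------------------------------------------------------------------------


def _gauge_transform_params(problem: "_Problem", params: lmfit.Parameters) -> bool:
    """Slide an optimum to its minimal-gain gauge representative (in place).

    Returns True when a transform was applied.  Exactly SSR-preserving; only
    valid (and only attempted) when eps_r0 is fixed at 0, hill_n at 1, and
    every log_kd, eps and gamma is free with eps resolvable per compound.
    """
    spec = problem.spec
    r = spec.rules
    if not (r["eps_r0"].status == "fixed" and r["eps_r0"].value == 0.0
            and r["hill_n"].status == "fixed" and r["hill_n"].value == 1.0
            and r["log_kd"].status == "free" and r["eps"].status == "free"
            and r["gamma"].status == "free"):
        return False
    # eps must be constant per compound: either shared per compound, or each
    # compound observed in a single pathway only
    if r["eps"].share not in ("compound", "compound_pathway", "curve"):
        return False
    eps_names: dict[str, list[str]] = {}
    kd_names: dict[str, str] = {}
    gamma_names: set[str] = set()
    for natural, (kind, key) in problem.param_index.items():
        if kind == "eps":
            eps_names.setdefault(key[0], []).append(natural)
        elif kind == "log_kd":
            kd_names[key[0]] = natural
        elif kind == "gamma":
            gamma_names.add(natural)
    if any(len(v) > 1 for v in eps_names.values()):
        return False  # per-pathway efficacies: gauge not exact
    if set(eps_names) != set(kd_names) or not gamma_names:
        return False

    vals = params.valuesdict()
    gammas = {nat: 10.0 ** vals[problem.internal_of[nat]] for nat in gamma_names}
    c = 1.0 / min(gammas.values())
    if c >= 1.0 - 1e-12:
        return False  # already at (or below) the minimal-gain representative
    for nat, g in gammas.items():
        params[problem.internal_of[nat]].value = np.log10(max(g * c, 1.0))
    for cpd, names in eps_names.items():
        nat_eps = names[0]
        int_eps = problem.internal_of[nat_eps]
        eps = vals[int_eps]
        denom = eps + c * (1.0 - eps)
        params[int_eps].value = min(eps / denom, 1.0)
        int_kd = problem.internal_of[kd_names[cpd]]
        params[int_kd].value = vals[int_kd] + np.log10(c / denom)
    return True


# ----------------------------------------------------------------------------
# fitting drivers
# ----------------------------------------------------------------------------


def _run_problem(problem: _Problem, *, multistart: int, seed: int,
                 min_points_margin: int) -> FitResult:
    n_d = problem.dataset.n_points
    n_p = problem.n_p
    if n_p == 0:
        raise ParameterError("spec has no free parameters; nothing to fit")
    if n_d < n_p + min_points_margin:
        raise ParameterError(
            f"refusing to fit: n_d = {n_d} data points for n_p = {n_p} free "
            f"parameters (need n_d {'>' if min_points_margin else '>='} n_p)"
        )

    init0 = _heuristic_init(problem)
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, multistart)):
        init = init0 if start == 0 else _perturb(init0, problem, rng)
        params = problem.make_params(init)
        try:
            with warnings.catch_warnings():
                # near-singular covariance on sloppy directions -> nan stderr,
                # reported as None and flagged by identifiability_report
                warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(problem.residual, params, method="least_squares",
                                     **_LEASTSQ_KWS)
        except Exception as exc:  # singular Jacobian etc. on a bad start
            logger.debug("start %d failed: %s", start, exc)
            continue
        logger.debug("start %d: chisqr = %.6g success = %s", start, res.chisqr, res.success)
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitError("no optimization start converged", best_estimates=dict(init0))

    # resolve the flat minimal-gain gauge direction (exactly SSR-preserving),
    # then repolish so the reported covariance belongs to the representative
    gauge_params = best.params.copy()
    if _gauge_transform_params(problem, gauge_params):
        logger.debug("applied minimal-gain gauge normalization")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            repolished = lmfit.minimize(problem.residual, gauge_params,
                                        method="least_squares", **_LEASTSQ_KWS)
        if repolished.success:
            best = repolished
        gauge_params = best.params.copy()
        if _gauge_transform_params(problem, gauge_params):
            for name in best.params:
                best.params[name].value = gauge_params[name].value

    estimates: dict[str, float] = {}
    stderr: dict[str, float | None] = {}
    for natural, internal in problem.internal_of.items():
        kind, _ = problem.param_index[natural]
        p = best.params[internal]
        nat = float(_SCALES[kind][2](p.value))
        estimates[natural] = nat
        if p.stderr is None or not np.isfinite(p.stderr):
            stderr[natural] = None
        else:
            stderr[natural] = float(p.stderr * _SCALES[kind][3](p.value))

    residuals = problem.residual(best.params)
    observed = np.concatenate([c.response for c in problem.dataset.curves])
    if observed.size >= 2 and np.ptp(observed) > 0:
        r2 = r_squared(observed, observed - residuals)
    else:
        r2 = float("nan")
    covar = getattr(best, "covar", None)
    var_names = list(getattr(best, "var_names", []))
    level = (problem.spec.ladder_level
             or reduce_model(problem.spec).ladder_level)
    result = FitResult(
        estimates=estimates, stderr=stderr,
        covar=None if covar is None else np.asarray(covar), var_names=var_names,
        param_index=dict(problem.param_index), internal_of=dict(problem.internal_of),
        fixed=dict(problem.fixed),
        residuals=residuals, r2=r2, ssr=float(np.sum(residuals ** 2)),
        n_d=n_d, n_p=n_p, ladder_level=level,
        success=bool(best.success), message=str(best.message),
    )
    logger.info("fit converged: ladder=%s n_d=%d n_p=%d r2=%.4f", level, n_d, n_p, r2)
    return result


def fit(dataset: DoseResponseDataset, spec: ModelSpec, *,
        multistart: int = 5, seed: int = 0) -> FitResult:
    """Fit a ModelSpec to all curves of a dataset by joint least squares.

    Minimizes the summed squared residuals (response %, unweighted) over all
    curves simultaneously; parameters shared across curves per the spec's
    grouping take a single value.  ``multistart`` deterministic restarts
    (seeded perturbations of a data-driven initialization) guard against
    local minima.  Refuses under-determined problems (n_d ≤ n_p).
    """
    problem = _Problem(dataset, spec)
    return _run_problem(problem, multistart=multistart, seed=seed, min_points_margin=1)


class _OccupancyProblem(_Problem):
    """Response-versus-occupancy fitting: Eq. f_resp = εγf/(ε(γ−1)f+1)."""

    def __init__(self, dataset: DoseResponseDataset, spec: ModelSpec):
        rules = dict(spec.rules)
        r0 = rules["eps_r0"]
        rn = rules["hill_n"]
        if r0.status != "fixed" or r0.value != 0.0 or rn.status != "fixed" or rn.value != 1.0:
            raise ParameterError(
                "fit_response_vs_occupancy requires eps_r0 fixed at 0 and hill_n fixed at 1"
            )
        # Kd does not enter the response-vs-occupancy equation; neutralize its rule
        from .model import ParamRule

        rules["log_kd"] = ParamRule.fixed(0.0, share="compound")
        spec = ModelSpec(rules=rules)
        super().__init__(dataset, spec)

    def residual(self, params: lmfit.Parameters) -> np.ndarray:
        vals = params.valuesdict()
        out = []
        for curve, binding in zip(self.dataset.curves, self.bindings):
            def res(kind):
                mode, ref = binding[kind]
                return ref if mode == "fixed" else _SCALES[kind][2](vals[ref])
            eps, gamma = res("eps"), res("gamma")
            f = curve.conc  # occupancy fractions are stored in the conc slot
            model = eps * gamma * f / (eps * (gamma - 1.0) * f + 1.0)
            out.append(curve.response - 100.0 * model)
        return np.concatenate(out)


def fit_response_vs_occupancy(pairs, spec: ModelSpec, *,
                              multistart: int = 5, seed: int = 0) -> FitResult:
    """Fit fractional response directly against fractional occupancy.

    ``pairs`` is either an (N, 2) array of (f_occup, f_resp) fractions for a
    single ligand, or a DataFrame with columns ``compound``, ``f_occup``,
    ``f_resp`` for several ligands sharing one pathway gain.  When the
    occupancies are computed from the same Kds used in concentration-space
    fitting, the estimates coincide with those of :func:`fit` — the two
    parametrizations trace the same residual surface.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
        if not {"compound", "f_occup", "f_resp"} <= set(df.columns):
            raise ParameterError("pairs DataFrame needs columns compound, f_occup, f_resp")
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.shape[1] != 2:
            raise ParameterError("pairs array must have shape (N, 2): (f_occup, f_resp)")
        df = pd.DataFrame({"compound": "cpd1", "f_occup": arr[:, 0], "f_resp": arr[:, 1]})
    f = df["f_occup"].to_numpy(dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ParameterError("f_occup must lie strictly in (0, 1)")
    r = df["f_resp"].to_numpy(dtype=float)
    if np.any(~np.isfinite(r)):
        raise ParameterError("f_resp must be finite")

    # occupancy plays the role of the abscissa; responses as % internally
    curves = [Curve(str(cpd), "P", grp["f_occup"].to_numpy(),
                    100.0 * grp["f_resp"].to_numpy())
              for cpd, grp in df.groupby("compound", sort=False)]
    dataset = DoseResponseDataset(curves=curves)
    problem = _OccupancyProblem(dataset, spec)
    return _run_problem(problem, multistart=multistart, seed=seed, min_points_margin=0)


# ----------------------------------------------------------------------------
# model comparison and identifiability
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class NestedComparison:
    """Extra-sum-of-squares F comparison of two nested fits."""

    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    alpha: float
    preferred: str  # ladder level (or 'simple'/'complex' when unnamed)
    simple_level: str | None
    complex_level: str | None


def nested_compare(result_simple: FitResult, result_complex: FitResult,
                   *, alpha: float = 0.05) -> NestedComparison:
    """Extra-sum-of-squares F test between two fits of the same data.

    The simpler model is retained unless the richer one reduces the residual
    sum of squares significantly at level ``alpha`` — the "always use the
    simplest adequate form" rule of the nested ladder made quantitative.
    """
    rs, rc = result_simple, result_complex
    if rs.n_d != rc.n_d:
        raise ParameterError("nested_compare requires fits of the same dataset "
                             f"(n_d {rs.n_d} vs {rc.n_d})")
    if rc.n_p <= rs.n_p:
        raise ParameterError("specs are not strictly nested: complex fit must free "
                             f"more parameters (n_p {rs.n_p} vs {rc.n_p})")
    ls, lc = rs.ladder_level, rc.ladder_level
    if ls in LADDER_LEVELS and lc in LADDER_LEVELS:
        if LADDER_LEVELS.index(ls) >= LADDER_LEVELS.index(lc):
            raise ParameterError(f"ladder levels not nested: {ls} !< {lc}")
    df_num = rc.n_p - rs.n_p
    df_den = rc.n_d - rc.n_p
    if df_den <= 0:
        raise ParameterError("complex fit has no residual degrees of freedom")
    f_stat = ((rs.ssr - rc.ssr) / df_num) / (rc.ssr / df_den)
    f_stat = max(f_stat, 0.0)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    take_complex = p_value < alpha
    preferred = (lc if take_complex else ls) or ("complex" if take_complex else "simple")
    return NestedComparison(f_stat=float(f_stat), p_value=p_value,
                            df_num=df_num, df_den=df_den, alpha=alpha,
                            preferred=preferred, simple_level=ls, complex_level=lc)


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Diagnostics for how well-determined a fit's parameters are."""

    n_d: int
    n_p: int
    points_per_param: float
    adequate: bool
    ill_defined: tuple[str, ...]
    notes: tuple[str, ...]


def identifiability_report(result: FitResult) -> IdentifiabilityReport:
    """Flag under-determined fits and ill-defined parameters.

    A fit is under-determined when it has fewer than five well-distributed
    data points per adjustable parameter; a parameter whose standard error
    exceeds its estimate (or could not be computed) is flagged ill-defined —
    the signature of an ambiguous fit.
    """
    ppp = result.points_per_param
    adequate = ppp >= POINTS_PER_PARAM_MIN
    notes = []
    if not adequate:
        notes.append(
            f"under-determined: {ppp:.1f} data points per adjustable parameter "
            f"(guideline: 5-10)"
        )
    ill = []
    for name, est in result.estimates.items():
        se = result.stderr.get(name)
        if se is None:
            ill.append(name)
            notes.append(f"{name}: standard error unavailable (ill-defined parameter)")
        elif abs(est) > 0 and se > abs(est):
            ill.append(name)
            notes.append(f"{name}: SE {se:.3g} exceeds estimate {est:.3g} "
                         "(ill-defined parameter)")
    return IdentifiabilityReport(
        n_d=result.n_d, n_p=result.n_p, points_per_param=ppp,
        adequate=adequate, ill_defined=tuple(ill), notes=tuple(notes),
    )
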