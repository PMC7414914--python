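"""Biased-agonism quantification.

Because the SABRE parametrization separates pathway-specific amplification
(γ) from ligand-specific efficacy (ε), bias can be read directly off the
per-pathway efficacies: a ligand whose efficacy ratio ε_P1/ε_P2 differs
significantly from 1 is biased, with no reference ligand required — provided
each pathway is anchored by a full (or near-full) agonist that sets the ε
scale.  Without such an anchor only the εγ products are comparable and the
ratios are scale-ambiguous.

The conventional comparators are also provided: the ΔΔlog(Emax/EC50)
logarithmic bias factor against a reference ligand, and Ehlert's intrinsic
relative activity RA_i = (Emax_L/EC50_L)/(Emax_ref/EC50_ref) per pathway.
For SABRE-generated data (n = 1, ε_R0 = 0) Emax/EC50 = εγ/Kd and
τ/K_D = ε(γ−1)/Kd, so ΔΔlog(Emax/EC50) and ΔΔlog(τ/K_D) both collapse to
the difference of log efficacy ratios — the γ and Kd terms cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitResult, _natural_name
from .model import ParameterError

__all__ = ["BiasReport", "efficacy_ratio_bias", "ddlog_emax_ec50"]

#: a pathway counts as anchored when its largest fitted efficacy reaches this
FULL_AGONIST_MIN_EPS = 0.9

_Z95 = 1.959963984540054


@dataclass
class BiasReport:
    """Flat per-ligand bias table: (ligand, metric, value, se, flag)."""

    table: pd.DataFrame
    p1: str
    p2: str
    reference: str | None = None

    def row(self, ligand: str, metric: str) -> pd.Series:
        sel = self.table[(self.table.ligand == ligand) & (self.table.metric == metric)]
        if sel.empty:
            raise KeyError((ligand, metric))
        return sel.iloc[0]


def _as_table(rows: list[dict]) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    for col in ("value", "se", "ci95_low", "ci95_high"):
        table[col] = table[col].astype(float)
    return table


def _eps_lookup(fit: FitResult, pathway: str) -> dict[str, tuple[str, float]]:
    """ligand -> (natural param name, estimate) for per-pathway efficacies."""
    out = {}
    for name, (kind, key) in fit.param_index.items():
        if kind == "eps" and len(key) == 2 and key[1] == pathway:
            out[key[0]] = (name, fit.estimates[name])
    return out


def efficacy_ratio_bias(fit: FitResult, p1: str, p2: str) -> BiasReport:
    """Per-ligand efficacy ratios ε_P1/ε_P2 with propagated uncertainty.

    Standard errors come from first-order propagation through the fit
    covariance (on the log-ratio scale for the confidence interval); a
    ligand is flagged ``unbiased`` when the 95 % CI of its ratio covers 1.
    If either pathway lacks a full-agonist anchor (max ε < 0.9), the εγ
    products are compared instead and every row is flagged
    ``scale_ambiguous``.  A missing covariance yields ratios without SEs,
    flagged ``no_covariance``.
    """
    eps1 = _eps_lookup(fit, p1)
    eps2 = _eps_lookup(fit, p2)
    ligands = [lig for lig in eps1 if lig in eps2]
    if not ligands:
        raise ParameterError(
            f"fit has no per-pathway efficacies for pathways {p1!r} and {p2!r} "
            "(eps must be shared per compound-pathway, not per compound)"
        )

    def gamma_of(pathway: str) -> float:
        name = _natural_name("gamma", (pathway,))
        if name in fit.estimates:
            return fit.estimates[name]
        if name in fit.fixed:
            return fit.fixed[name]
        raise ParameterError(f"fit provides no gamma for pathway {pathway!r}")

    def _anchored(eps_map: dict[str, tuple[str, float]]) -> bool:
        # a full (or close to full) agonist sets the eps scale; an estimate
        # whose 95 % upper bound reaches 1 is consistent with full agonism
        for name, est in eps_map.values():
            se = fit.stderr.get(name)
            if est >= FULL_AGONIST_MIN_EPS:
                return True
            if se is not None and est + _Z95 * se >= 1.0:
                return True
        return False

    anchored = _anchored(eps1) and _anchored(eps2)
    g1 = g2 = 1.0
    if not anchored:
        g1, g2 = gamma_of(p1), gamma_of(p2)

    rows = []
    for lig in ligands:
        name1, e1 = eps1[lig]
        name2, e2 = eps2[lig]
        metric = "eps_ratio" if anchored else "eps_gamma_ratio"
        v1, v2 = e1 * g1, e2 * g2
        flags = [] if anchored else ["scale_ambiguous"]
        if v2 <= 0 or v1 <= 0:
            rows.append({"ligand": lig, "metric": metric, "value": np.inf if v2 <= 0 else 0.0,
                         "se": None, "ci95_low": None, "ci95_high": None,
                         "flag": ";".join(flags + ["ill_defined"])})
            continue
        ratio = v1 / v2
        var1 = (fit.stderr.get(name1) or np.nan) ** 2
        var2 = (fit.stderr.get(name2) or np.nan) ** 2
        cov12 = fit.cov_natural(name1, name2)
        if not (math.isfinite(var1) and math.isfinite(var2)) or cov12 is None:
            rows.append({"ligand": lig, "metric": metric, "value": ratio,
                         "se": None, "ci95_low": None, "ci95_high": None,
                         "flag": ";".join(flags + ["no_covariance"])})
            continue
        # first-order propagation; gammas enter the eps-gamma products as
        # scale factors common to all ligands and drop out of the ratio's
        # relative variance
        rel_var = var1 / e1 ** 2 + var2 / e2 ** 2 - 2.0 * cov12 / (e1 * e2)
        rel_var = max(rel_var, 0.0)
        se = ratio * math.sqrt(rel_var)
        se_log = math.sqrt(rel_var)  # sd of ln(ratio)
        lo = ratio * math.exp(-_Z95 * se_log)
        hi = ratio * math.exp(_Z95 * se_log)
        if lo <= 1.0 <= hi:
            flags.append("unbiased")
        else:
            flags.append("biased")
        if se > ratio:
            flags.append("ill_defined")
        rows.append({"ligand": lig, "metric": metric, "value": ratio, "se": se,
                     "ci95_low": lo, "ci95_high": hi, "flag": ";".join(flags)})
    return BiasReport(table=_as_table(rows), p1=p1, p2=p2)


def ddlog_emax_ec50(curve_params: pd.DataFrame, reference_ligand: str,
                    p1: str | None = None, p2: str | None = None) -> BiasReport:
    """ΔΔlog(Emax/EC50) bias factors and per-pathway RA_i vs a reference.

    ``curve_params`` needs one row per (ligand, pathway) with columns
    ``ligand``, ``pathway``, ``emax``, ``ec50`` (Emax in any fixed unit,
    EC50 in molar).  The bias factor for ligand L between pathways P1, P2 is

        [log(Emax_P1,L/EC50_P1,L) − log(Emax_P2,L/EC50_P2,L)]
      − [log(Emax_P1,ref/EC50_P1,ref) − log(Emax_P2,ref/EC50_P2,ref)]

    and is identically 0 for the reference.  RA_i rows report
    (Emax_L/EC50_L)/(Emax_ref/EC50_ref) within each pathway.
    """
    need = {"ligand", "pathway", "emax", "ec50"}
    if not need <= set(curve_params.columns):
        raise ParameterError(f"curve_params needs columns {sorted(need)}")
    df = curve_params.copy()
    pathways = list(dict.fromkeys(df["pathway"]))
    if p1 is None or p2 is None:
        if len(pathways) != 2:
            raise ParameterError(
                f"found pathways {pathways}; pass p1 and p2 explicitly"
            )
        p1, p2 = pathways
    lookup = {(r.ligand, r.pathway): math.log10(r.emax / r.ec50)
              for r in df.itertuples()}
    for pw in (p1, p2):
        if (reference_ligand, pw) not in lookup:
            raise ParameterError(
                f"reference ligand {reference_ligand!r} has no entry for pathway {pw!r}"
            )
    ref_delta = lookup[(reference_ligand, p1)] - lookup[(reference_ligand, p2)]

    rows = []
    for lig in dict.fromkeys(df["ligand"]):
        if (lig, p1) in lookup and (lig, p2) in lookup:
            if lig == reference_ligand:
                dd = 0.0
            else:
                dd = (lookup[(lig, p1)] - lookup[(lig, p2)]) - ref_delta
            rows.append({"ligand": lig, "metric": "ddlog_emax_ec50", "value": dd,
                         "se": None, "ci95_low": None, "ci95_high": None,
                         "flag": "reference" if lig == reference_ligand else ""})
        for pw in (p1, p2):
            if (lig, pw) in lookup:
                rai = 10.0 ** (lookup[(lig, pw)] - lookup[(reference_ligand, pw)])
                rows.append({"ligand": lig, "metric": f"RA_i[{pw}]", "value": rai,
                             "se": None, "ci95_low": None, "ci95_high": None,
                             "flag": "reference" if lig == reference_ligand else ""})
    return BiasReport(table=_as_table(rows), p1=p1, p2=p2,
                      reference=reference_ligand)
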