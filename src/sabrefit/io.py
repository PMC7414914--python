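"""File formats and run configuration.

Datasets travel as plain CSV with header columns ``compound``, ``pathway``,
``conc_M`` (molar, scientific notation welcome), ``response_pct`` and an
optional per-compound ``log_kd_fixed`` column carrying independently
measured log10 Kd values.  Fit runs are configured by a single structured
YAML (or JSON) mapping; see :data:`CONFIG_KEYS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import DoseResponseDataset
from .model import LADDER_LEVELS, ModelSpec, ParameterError

__all__ = ["read_dataset", "write_dataset", "RunConfig", "read_config"]

logger = logging.getLogger("sabrefit")

REQUIRED_COLUMNS = ("compound", "pathway", "conc_M", "response_pct")

CONFIG_KEYS = {
    "ladder": f"one of {LADDER_LEVELS}",
    "fix_kd": "bool — fix each compound's log Kd at the dataset's log_kd_fixed value",
    "eps_share": "'compound_pathway' (default) or 'compound' (one eps across pathways)",
    "hill_share": "'pathway' (default, per assay) or 'curve' for a freed Hill n",
    "seed": "int — multi-start seed (default 0)",
    "multistart": "int — optimization restarts (default 5)",
}


def read_dataset(path) -> DoseResponseDataset:
    """Read and validate a concentration–response CSV.

    Errors name the offending rows (1-based, counting the header as row 1):
    missing columns, non-positive or non-finite concentrations, non-finite
    responses, duplicate (compound, pathway, conc) triples, or conflicting
    per-compound log_kd_fixed values.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing required column(s) {missing}; "
                             f"expected header {list(REQUIRED_COLUMNS)}")

    def rows(mask) -> list[int]:
        return [int(i) + 2 for i in df.index[mask]]  # +2: header + 1-based

    conc = pd.to_numeric(df["conc_M"], errors="coerce")
    bad = conc.isna() | ~np.isfinite(conc) | (conc <= 0)
    if bad.any():
        raise ParameterError(
            f"{path}: conc_M must be positive and finite; bad rows {rows(bad)}"
        )
    resp = pd.to_numeric(df["response_pct"], errors="coerce")
    bad = resp.isna() | ~np.isfinite(resp)
    if bad.any():
        raise ParameterError(
            f"{path}: response_pct must be finite numbers; bad rows {rows(bad)}"
        )
    df["conc_M"] = conc
    df["response_pct"] = resp
    dup = df.duplicated(subset=["compound", "pathway", "conc_M"], keep=False)
    if dup.any():
        raise ParameterError(
            f"{path}: duplicate (compound, pathway, conc_M) triples at rows {rows(dup)}"
        )
    dataset = DoseResponseDataset.from_frame(df)
    logger.info("read %d curves / %d points from %s",
                len(dataset.curves), dataset.n_points, path)
    return dataset


def write_dataset(dataset: DoseResponseDataset, path) -> None:
    """Write a dataset as CSV (12 significant digits; lossless round trip)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.12g")
    logger.info("wrote %d curves to %s", len(dataset.curves), path)


@dataclass(frozen=True)
class RunConfig:
    """Validated fit-run configuration (see CONFIG_KEYS for the schema)."""

    ladder: str
    fix_kd: bool = False
    eps_share: str = "compound_pathway"
    hill_share: str = "pathway"
    seed: int = 0
    multistart: int = 5

    def model_spec(self) -> ModelSpec:
        return ModelSpec.from_ladder(self.ladder, fix_kd=self.fix_kd,
                                     eps_share=self.eps_share,
                                     hill_share=self.hill_share)


def read_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: config must be a mapping; keys: "
                             + ", ".join(f"{k} ({v})" for k, v in CONFIG_KEYS.items()))
    unknown = set(raw) - set(CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"{path}: unknown config key(s) {sorted(unknown)}; "
                             f"valid keys are {sorted(CONFIG_KEYS)}")
    if "ladder" not in raw:
        raise ParameterError(f"{path}: config must declare 'ladder' "
                             f"(one of {LADDER_LEVELS})")
    if raw["ladder"] not in LADDER_LEVELS:
        raise ParameterError(f"{path}: unknown ladder {raw['ladder']!r}; "
                             f"choose from {LADDER_LEVELS}")
    for key, typ in (("fix_kd", bool), ("seed", int), ("multistart", int)):
        if key in raw and not isinstance(raw[key], typ):
            raise ParameterError(f"{path}: {key} must be {typ.__name__}, "
                                 f"got {raw[key]!r}")
    for key, choices in (("eps_share", ("compound_pathway", "compound")),
                         ("hill_share", ("pathway", "curve"))):
        if key in raw and raw[key] not in choices:
            raise ParameterError(f"{path}: {key} must be one of {choices}, "
                                 f"got {raw[key]!r}")
    return RunConfig(**raw)
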