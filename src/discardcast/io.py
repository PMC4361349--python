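"""File interfaces: input tables, configs, and result export.

All tabular formats are plain CSV (column conventions in
``docs/data_dictionary.md``); configs are YAML or JSON; posterior draws can
be exported through arviz's InferenceData (NetCDF-compatible).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .survey import LengthWeightParams

__all__ = [
    "read_length_weight_csv",
    "read_taxon_mapping_csv",
    "read_mls_csv",
    "read_haul_tables",
    "load_config",
    "observations_to_frame",
    "truth_to_json",
    "save_run",
    "to_inference_data",
]


def read_length_weight_csv(path) -> dict[str, LengthWeightParams]:
    """species, a, b  ->  allometric parameters per species."""
    df = pd.read_csv(path)
    return {row["species"]: LengthWeightParams(row["a"], row["b"])
            for _, row in df.iterrows()}


def read_taxon_mapping_csv(path) -> dict[str, str]:
    """taxon, group  ->  aggregation mapping."""
    df = pd.read_csv(path)
    return dict(zip(df["taxon"], df["group"]))


def read_mls_csv(path, prefer: str = "latest") -> dict[str, float]:
    """species, mls_cm, basis, effective_year  ->  one MLS per species.

    Where a species has several historical values, ``prefer='latest'``
    keeps the most recent (the value in force for the longest stretch of a
    modern analysis window); ``'earliest'`` keeps the oldest.
    """
    df = pd.read_csv(path)
    if "effective_year" in df.columns:
        df = df.sort_values("effective_year")
        keep = df.groupby("species").last() if prefer == "latest" \
            else df.groupby("species").first()
    else:
        keep = df.groupby("species").last()
    return keep["mls_cm"].to_dict()


def read_haul_tables(hauls_path, lengths_path):
    """The two-table survey dialect: hauls.csv + lengths.csv."""
    return pd.read_csv(hauls_path), pd.read_csv(lengths_path)


def load_config(path) -> dict:
    """YAML or JSON run configuration (priors, MCMC sizes, value classes)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yml", ".yaml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def observations_to_frame(obs) -> pd.DataFrame:
    """Tidy annual observation table for one species."""
    out = pd.DataFrame({"species": obs.species, "year": obs.years,
                        "index_kg_km2": obs.index,
                        "landings_tonnes": obs.landings})
    out["discards_tonnes"] = obs.discards if obs.discards is not None else np.nan
    return out


def truth_to_json(truth, path=None) -> str:
    """Serialise a synthetic TruthRecord (generating truth) to JSON."""
    payload = {
        "species": truth.species,
        "years": truth.years.tolist(),
        "Q": truth.q_ratio.tolist(),
        "u": truth.u.tolist(),
        "q": truth.q.tolist(),
        "capture": {"l50": truth.capture.l50, "interval": truth.capture.interval},
        "retention": {"l50": truth.retention.l50, "interval": truth.retention.interval},
        "sigma_index": truth.sigma_index,
        "sigma_landings": truth.sigma_landings,
        "sigma_discards": truth.sigma_discards,
        "mls": truth.mls,
        "landings_only": truth.landings_only,
        "catch": None if truth.catch is None else truth.catch.tolist(),
        "discards": None if truth.discards is None else truth.discards.tolist(),
        "landings": None if truth.landings is None else truth.landings.tolist(),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def to_inference_data(results, variables=("Q", "u", "q", "D", "C")):
    """Posterior draws as an arviz InferenceData (NetCDF-exportable)."""
    import arviz as az

    return az.from_dict(posterior={v: results.posterior[v] for v in variables})


def save_run(results, outdir, name: str = "fit") -> None:
    """Write tidy posterior summaries plus a JSON run log (seed, config,
    convergence flag) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if hasattr(results, "to_frame"):
        results.to_frame().to_csv(outdir / f"{name}_series.csv", index=False)
    results.summary().to_csv(outdir / f"{name}_params.csv")
    log = {"seed": results.seed, "config": results.config,
           "converged": results.converged, "max_rhat": results.max_rhat}
    (outdir / f"{name}_runlog.json").write_text(json.dumps(log, indent=2))
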