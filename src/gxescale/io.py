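"""Readers and writers for the package's delimited table formats.

All tables are plain tab-separated text with a header row; writers prepend
a comment line stamping the package version and, where applicable, the
generating seed, so an emitted file records its own provenance.
Columns follow common GWAS tooling conventions (SNP, CHR, BP, A1, A2,
BETA, SE, P, N for summary statistics; SNP, A1, WEIGHT for score files).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import Cohort, GenotypePanel, SimulationConfig

__all__ = [
    "write_cohort",
    "read_cohort_table",
    "write_genotype_panel",
    "read_genotype_panel",
    "write_gwas",
    "read_gwas",
    "write_prs_weights",
    "read_prs_weights",
    "write_config",
    "read_config",
]

_GWAS_OUT = {"snp": "SNP", "chr": "CHR", "bp": "BP", "a1": "A1", "a2": "A2",
             "beta": "BETA", "se": "SE", "p": "P", "n": "N"}


def _header(seed=None) -> str:
    line = f"# gxescale v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _write_tsv(df: pd.DataFrame, path, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cohort(cohort: Cohort, path, seed=None) -> None:
    """Cohort as a TSV: sample_id, y_observed, E, PGS_1..PGS_m [, covariates]."""
    n, m = cohort.G.shape
    df = pd.DataFrame({"sample_id": np.arange(1, n + 1)})
    df["y_observed"] = cohort.y_observed
    df["E"] = cohort.E
    for j in range(m):
        df[f"PGS_{j + 1}"] = cohort.G[:, j]
    if cohort.C is not None:
        for k in range(cohort.C.shape[1]):
            df[f"C_{k + 1}"] = cohort.C[:, k]
    if cohort.groups is not None:
        df["group"] = cohort.groups
    _write_tsv(df, path, seed=seed)


def read_cohort_table(path) -> pd.DataFrame:
    """A written cohort back as a DataFrame (phenotype, E, PGS columns)."""
    return _read_tsv(path)


def write_genotype_panel(panel: GenotypePanel, prefix, seed=None) -> None:
    """Panel as ``<prefix>.dosages.tsv`` and ``<prefix>.snps.tsv``."""
    prefix = Path(prefix)
    dosage_df = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    dosage_df.insert(0, "sample_id", np.arange(1, panel.n_samples + 1))
    _write_tsv(dosage_df, prefix.with_suffix(".dosages.tsv"), seed=seed)
    _write_tsv(panel.snp_map, prefix.with_suffix(".snps.tsv"), seed=seed)


def read_genotype_panel(prefix) -> GenotypePanel:
    prefix = Path(prefix)
    dosage_df = _read_tsv(prefix.with_suffix(".dosages.tsv"))
    snp_map = _read_tsv(prefix.with_suffix(".snps.tsv"))
    dosages = dosage_df[list(snp_map["snp"])].to_numpy(dtype=float)
    return GenotypePanel(dosages=dosages, snp_map=snp_map)


def write_gwas(gwas: pd.DataFrame, path, seed=None) -> None:
    out = gwas.rename(columns=_GWAS_OUT)
    _write_tsv(out, path, seed=seed)


def read_gwas(path) -> pd.DataFrame:
    df = _read_tsv(path)
    inverse = {v: k for k, v in _GWAS_OUT.items()}
    return df.rename(columns=inverse)


def write_prs_weights(weights: pd.DataFrame, path, seed=None) -> None:
    out = weights.rename(columns={"snp": "SNP", "a1": "A1", "weight": "WEIGHT"})
    _write_tsv(out, path, seed=seed)


def read_prs_weights(path) -> pd.DataFrame:
    df = _read_tsv(path)
    return df.rename(columns={"SNP": "snp", "A1": "a1", "WEIGHT": "weight"})


def write_config(config: SimulationConfig, path) -> None:
    """Simulation parameters as a YAML key-value file."""
    payload = {
        "package_version": __version__,
        "n_samples": config.n_samples,
        "n_pgs": config.n_pgs,
        "h2": config.h2,
        "env_var": config.env_var,
        "gamma": config.gamma,
        "observation_scale": config.observation_scale,
        "env_dist": config.env_dist,
        "env_frequency": config.env_frequency,
        "location_shift": config.location_shift,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload.pop("package_version", None)
    return SimulationConfig(**payload)
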