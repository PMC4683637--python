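"""Delimited-text I/O, packaged study fixtures, and the end-to-end workflow.

All on-disk formats are plain UTF-8 CSV with explicit headers:

* offspring tables  ``sire,bin,outcome``      (outcome 0/1)
* count tables      ``sire,bin,settled,swimming``
* genotype tables   ``sample,<locus>_a,<locus>_b,...`` with ``NA`` missing
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import model
from .parentage import GenotypeTable

logger = logging.getLogger("halfsib")


class StageError(RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# -- offspring / count tables -------------------------------------------------


def read_offspring_table(path) -> pd.DataFrame:
    """Read and validate an offspring table (``sire,bin,outcome``).

    Malformed outcomes are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    if list(df.columns[:3]) != ["sire", "bin", "outcome"]:
        raise ValueError(f"{path}: header must be 'sire,bin,outcome', got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    out = pd.to_numeric(df["outcome"], errors="coerce")
    bad = df.index[~out.isin([0, 1])]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: outcome must be 0 or 1; offending lines: {lines}")
    if df[["sire", "bin"]].isna().any().any():
        bad = df.index[df[["sire", "bin"]].isna().any(axis=1)]
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: missing sire/bin labels on lines: {lines}")
    df["outcome"] = out.astype(np.int64)
    return model.as_offspring_table(df)


def write_offspring_table(data, path) -> None:
    model.as_offspring_table(data).to_csv(path, index=False)


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a sire x bin count table."""
    df = pd.read_csv(path)
    return model.as_count_table(df)


def write_count_table(data, path) -> None:
    model.as_count_table(data).to_csv(path, index=False)


def aggregate_counts(data) -> pd.DataFrame:
    """Collapse an offspring table to sire x bin (settled, swimming) counts."""
    off = model.as_offspring_table(data)
    if len(off) == 0:
        return pd.DataFrame(columns=list(model.COUNT_COLUMNS))
    grouped = off.groupby(["sire", "bin"], sort=True)["outcome"]
    counts = grouped.agg(settled="sum", swimming=lambda y: (1 - y).sum()).reset_index()
    counts["settled"] = counts["settled"].astype(np.int64)
    counts["swimming"] = counts["swimming"].astype(np.int64)
    return model.as_count_table(counts)


def expand_counts(data) -> pd.DataFrame:
    """Expand a count table to one row per offspring (inverse of aggregation)."""
    counts = model.as_count_table(data)
    sires, bins, outcomes = [], [], []
    for row in counts.itertuples(index=False):
        k = row.settled + row.swimming
        sires.extend([row.sire] * k)
        bins.extend([row.bin] * k)
        outcomes.extend([1] * row.settled + [0] * row.swimming)
    return model.as_offspring_table(
        pd.DataFrame({"sire": sires, "bin": bins, "outcome": outcomes})
    )


# -- genotype tables and packaged fixtures ------------------------------------


def read_genotype_table(path) -> GenotypeTable:
    """Read a wide genotype table (``sample,<locus>_a,<locus>_b,...``, NA missing)."""
    df = pd.read_csv(path, na_values=["NA"])
    if "sample" not in df.columns:
        raise ValueError(f"{path}: first column must be 'sample'")
    return GenotypeTable.from_wide(df)


def _data_path(name: str):
    return resources.files("halfsib").joinpath("data", name)


def load_sire_genotypes() -> GenotypeTable:
    """The nine study sires' genotypes at the six paternity loci."""
    with resources.as_file(_data_path("sire_genotypes.csv")) as p:
        return read_genotype_table(p)


def load_marker_metadata() -> pd.DataFrame:
    """Per-locus marker metadata: observed size range, allele count, dye label."""
    with resources.as_file(_data_path("marker_metadata.csv")) as p:
        return pd.read_csv(p)


@dataclass
class StudyFixture:
    """Packaged study inputs: sire genotypes, marker metadata, design preset."""

    sire_genotypes: GenotypeTable
    marker_metadata: pd.DataFrame
    study_design: "object"


def load_study_fixture() -> StudyFixture:
    from .simulation import study_design

    return StudyFixture(load_sire_genotypes(), load_marker_metadata(), study_design())


# -- full workflow -------------------------------------------------------------


class WorkflowConfig(BaseModel):
    """Knobs of the fit -> heritability -> permutation pipeline."""

    n_quad: int = model.DEFAULT_N_QUAD
    n_perm: int = 500
    n_boot: int = 500
    scheme: str = "offspring"
    seed: int = 0
    bin_effect: bool = False
    alpha: float = 0.05


class WorkflowReport(BaseModel):
    """Schema of the structured report emitted by :func:`run_full_workflow`."""

    package: str
    version: str
    seed: int
    n_quad: int
    n_sires: int
    n_obs: int
    alpha_hat: float
    tau2_hat: float
    loglik_alt: float
    loglik_null: float
    lrt: float
    h2: float
    h2_clamped: float
    ci_lower: float
    ci_upper: float
    boot_sd: float
    boot_mean_tau2: float
    n_boot: int
    n_boot_dropped: int
    p_value: float
    n_perm: int
    significant: bool


def run_full_workflow(offspring, config: WorkflowConfig | dict | None = None) -> dict:
    """Fit, heritability bootstrap and permutation test in one call.

    ``offspring`` is a path to an offspring table or an in-memory table.
    Returns the report as a plain dict (validated against
    :class:`WorkflowReport`); deterministic given the config seed.
    """
    from . import __version__, heritability, permutation

    if config is None:
        config = WorkflowConfig()
    elif isinstance(config, dict):
        config = WorkflowConfig(**config)

    try:
        off = read_offspring_table(offspring) if isinstance(offspring, (str, bytes)) or hasattr(offspring, "__fspath__") else model.as_offspring_table(offspring)
    except (ValueError, OSError) as err:
        raise StageError("read", str(err)) from err

    try:
        counts = aggregate_counts(off)
        alt = model.fit_alternative(counts, n_quad=config.n_quad, bin_effect=config.bin_effect)
        null = model.fit_null(counts, bin_effect=config.bin_effect)
        lrt = model.lrt_statistic(alt, null)
    except ValueError as err:
        raise StageError("fit", str(err)) from err

    try:
        est = heritability.bootstrap_heritability(
            off, n_boot=config.n_boot, scheme=config.scheme,
            seed=config.seed, n_quad=config.n_quad,
        )
    except (ValueError, RuntimeError) as err:
        raise StageError("heritability", str(err)) from err

    try:
        perm = permutation.permutation_lrt_test(
            off, n_perm=config.n_perm, seed=config.seed, n_quad=config.n_quad
        )
    except ValueError as err:
        raise StageError("permutation", str(err)) from err

    report = WorkflowReport(
        package="halfsib",
        version=__version__,
        seed=config.seed,
        n_quad=config.n_quad,
        n_sires=alt.n_sires,
        n_obs=alt.n_obs,
        alpha_hat=alt.alpha,
        tau2_hat=alt.tau2,
        loglik_alt=alt.loglik,
        loglik_null=null.loglik,
        lrt=lrt,
        h2=est.h2,
        h2_clamped=est.h2_clamped,
        ci_lower=est.ci_lower,
        ci_upper=est.ci_upper,
        boot_sd=est.boot_sd,
        boot_mean_tau2=est.boot_mean_tau2,
        n_boot=est.n_boot,
        n_boot_dropped=est.n_dropped,
        p_value=perm.p_value,
        n_perm=perm.n_perm,
        significant=perm.p_value <= config.alpha,
    )
    logger.info(
        "workflow: tau2=%.4g h2=%.3g (95%% CI %.2f-%.2f) LRT=%.3g p=%.4g (n_perm=%d)",
        report.tau2_hat, report.h2, report.ci_lower, report.ci_upper,
        report.lrt, report.p_value, report.n_perm,
    )
    return report.model_dump()
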