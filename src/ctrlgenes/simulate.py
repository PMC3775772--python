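"""Synthetic multi-cohort RPKM studies with planted stable control genes.

Real multi-cohort patient expression data cannot ship with the package, so
every downstream stage is exercised on simulated studies that reproduce
the statistical shape of bulk RNA-seq RPKM matrices from cancer cohorts:
per-gene mean expression spanning roughly 4-4000 RPKM (log-uniform), and
per-gene between-sample variability in the 40-120% CV range for ordinary
genes, with a planted minority of highly consistent genes at ~10% CV —
the signal a control-gene screen is supposed to find.

Each gene's per-sample expression follows a log-normal law. For a target
coefficient of variation ``cv`` (as a fraction) the log-scale dispersion
is solved from the exact log-normal relation CV^2 = exp(sigma^2) - 1,
i.e. sigma = sqrt(ln(1 + cv^2)), and the log-mean is set so the
arithmetic mean equals the drawn per-gene mean. Datasets share the gene
universe (means, classes) but draw samples independently — no batch
structure beyond that.

qPCR Ct tables are derived from RPKM through an ideal log-linear
amplification model, Ct = intercept - slope * log2(RPKM) + N(0, noise_sd),
which is the standard-curve relation of real assays (intercept = Ct at
1 RPKM; slope = cycles per doubling, 1.0 for perfect efficiency).

Reproducibility: a single master seed spawns fixed, non-colliding
substreams — [seed, 0] for the gene universe, [seed, 1+d] for dataset d,
and a label-keyed stream for Ct tables — so adding datasets never
perturbs earlier ones.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .io import CtTable, ExpressionMatrix

try:  # YAML config files are accepted when pyyaml is present
    import yaml
except ImportError:  # pragma: no cover
    yaml = None


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a 10-cohort screen of 2000 genes x 100 samples with
    5% planted stable genes at 10% CV against a 40-120% CV background.
    """

    n_genes: int = 2000
    n_samples: int = 100
    n_datasets: int = 10
    frac_stable: float = 0.05
    mean_log2_range: tuple[float, float] = (2.0, 12.0)  # log2-RPKM mean bounds
    stable_cv_target: float = 10.0  # percent
    variable_cv_range: tuple[float, float] = (40.0, 120.0)  # percent
    ct_intercept: float = 30.0  # Ct at 1 RPKM
    ct_slope: float = 1.0  # cycles per log2-RPKM
    ct_noise_sd: float = 0.25  # cycles
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = [
            self.frac_stable,
            *self.mean_log2_range,
            self.stable_cv_target,
            *self.variable_cv_range,
            self.ct_intercept,
            self.ct_slope,
            self.ct_noise_sd,
        ]
        if not all(math.isfinite(float(v)) for v in scalars):
            raise ValueError("all config values must be finite")
        for name in ("n_genes", "n_samples", "n_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_stable <= 1.0:
            raise ValueError("frac_stable must lie in [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.stable_cv_target < 0:
            raise ValueError("stable_cv_target must be >= 0")
        lo, hi = self.variable_cv_range
        if not (0 < lo <= hi):
            raise ValueError("variable_cv_range must be positive and ordered")
        if not self.stable_cv_target < lo:
            raise ValueError(
                "stable_cv_target must be below the variable CV range "
                "(planted classes must be separable)"
            )
        if not self.mean_log2_range[0] <= self.mean_log2_range[1]:
            raise ValueError("mean_log2_range must be ordered")


def load_config(path) -> SyntheticConfig:
    """Read a SyntheticConfig from a JSON or YAML file."""
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        if yaml is None:  # pragma: no cover
            raise RuntimeError("pyyaml not installed; use a JSON config")
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    for key in ("mean_log2_range", "variable_cv_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)


def _sigma_ln(cv_percent: np.ndarray) -> np.ndarray:
    """Log-scale sd giving an exact log-normal CV: sigma = sqrt(ln(1+cv^2))."""
    cv = np.asarray(cv_percent, dtype=float) / 100.0
    return np.sqrt(np.log1p(cv**2))


def gene_universe(config: SyntheticConfig) -> pd.DataFrame:
    """The shared gene set: ids, hidden class labels, means, CV targets.

    This is the generator's sidecar ground truth — it is never written
    into the expression files themselves, so downstream selection cannot
    peek at the labels. Deterministic in ``config.seed`` alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    n_stable = int(round(config.frac_stable * n))
    classes = np.array(["variable"] * n, dtype=object)
    stable_idx = rng.choice(n, size=n_stable, replace=False)
    classes[stable_idx] = "stable"
    mean_rpkm = 2.0 ** rng.uniform(*config.mean_log2_range, size=n)
    cv_target = rng.uniform(*config.variable_cv_range, size=n)
    cv_target[stable_idx] = config.stable_cv_target
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "mean_rpkm": mean_rpkm,
            "cv_target": cv_target,
        }
    )


def generate_dataset(config: SyntheticConfig, dataset_index: int) -> ExpressionMatrix:
    """One cohort's RPKM matrix, strictly positive, reproducible.

    Per gene g with mean m and CV target c: values are log-normal with
    sigma = sqrt(ln(1 + c^2)) and mu = ln(m) - sigma^2/2, so the
    population mean is exactly m and the population CV exactly c. A CV
    target of zero degenerates to the constant m.
    """
    if dataset_index < 0 or dataset_index >= config.n_datasets:
        raise ValueError(
            f"dataset_index must lie in [0, {config.n_datasets}), got {dataset_index}"
        )
    universe = gene_universe(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 + dataset_index])
    )
    means = universe["mean_rpkm"].to_numpy()
    sigma = _sigma_ln(universe["cv_target"].to_numpy())
    mu = np.log(means) - sigma**2 / 2.0
    z = rng.standard_normal((config.n_genes, config.n_samples))
    values = np.exp(mu[:, None] + sigma[:, None] * z)
    label = f"synthetic{dataset_index}"
    df = pd.DataFrame(
        values,
        index=universe["gene_id"].tolist(),
        columns=[f"S{j:04d}" for j in range(config.n_samples)],
    )
    return ExpressionMatrix(df, label=label)


def generate_study(config: SyntheticConfig) -> list[ExpressionMatrix]:
    """All ``n_datasets`` cohorts; same gene universe, independent samples."""
    return [generate_dataset(config, d) for d in range(config.n_datasets)]


def generate_ct_table(
    matrix: ExpressionMatrix, config: SyntheticConfig, genes
) -> CtTable:
    """Ct values from RPKM via the log-linear amplification model.

    Ct(g, s) = ct_intercept - ct_slope * log2(RPKM(g, s)) + N(0, ct_noise_sd).
    The noise stream is keyed on (seed, matrix label) so repeated calls
    reproduce the identical table.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    sub = matrix.data.loc[genes]
    vals = sub.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("Ct model requires strictly positive RPKM (log2 undefined)")
    label_key = zlib.crc32(matrix.label.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 << 20, label_key])
    )
    ct = config.ct_intercept - config.ct_slope * np.log2(vals)
    if config.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, config.ct_noise_sd, size=ct.shape)
    return CtTable(pd.DataFrame(ct, index=sub.index, columns=sub.columns))


def write_labels(universe: pd.DataFrame, path) -> None:
    """Write the hidden-class sidecar as two-column TSV (gene_id, class)."""
    universe[["gene_id", "class"]].to_csv(path, sep="\t", index=False)
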