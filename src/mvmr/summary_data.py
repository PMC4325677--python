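"""Domain types and I/O for summarized genetic association data.

Multivariable Mendelian randomization can be run either from individual-level
records (genotype dosages, risk factors, outcome) or from GWAS-style
summarized data: per-variant beta coefficients and standard errors from
separate univariate regressions of each trait on each variant.  This module
defines both containers, the delimited-text readers/writers for them, and the
bridge ``summarize`` that collapses an individual-level dataset to its
summary-statistic representation.

Conventions
-----------
* All traits reported for one variant must refer to the same effect allele;
  allele harmonization is the caller's responsibility.
* Genotypes are per-allele dosages (0/1/2, real-valued for imputed data);
  the genetic model is additive.
* Missing values are rejected, never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "OUTCOME_SCALES",
    "SummaryAssociations",
    "TraitCorrelationModel",
    "VariantLDMatrix",
    "IndividualDataset",
    "read_summary_table",
    "write_summary_table",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "read_individual_data",
    "summarize",
    "estimate_trait_correlations",
]

#: Scales on which the per-variant outcome associations may be measured.
#: For a binary outcome analysed by logistic regression the betas are log
#: odds ratios and causal effects inherit that scale.
OUTCOME_SCALES = ("linear", "log_odds", "log_relative_risk")

_PSD_TOL = 1e-8


def _as_2d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D array, got shape {arr.shape}")
    return arr


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D array, got shape {arr.shape}")
    return arr


@dataclass
class SummaryAssociations:
    """Per-variant association estimates for K risk factors and an outcome.

    Parameters
    ----------
    variant_ids
        J unique variant identifiers (e.g. rsIDs), row order of all matrices.
    beta_exposures, se_exposures
        J x K matrices of estimated genetic associations with each risk
        factor and their standard errors (per effect allele, on each risk
        factor's own scale).
    beta_outcome, se_outcome
        Length-J association estimates with the outcome.  For a binary
        outcome these are log odds ratios or log relative risks, recorded in
        ``outcome_scale``.
    outcome_scale
        One of ``"linear"``, ``"log_odds"``, ``"log_relative_risk"``.
    exposure_names
        K risk-factor names, column order of the exposure matrices.
    """

    variant_ids: list[str]
    beta_exposures: np.ndarray
    se_exposures: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    outcome_scale: str = "linear"
    exposure_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exposures = _as_2d(self.beta_exposures, "beta_exposures")
        self.se_exposures = _as_2d(self.se_exposures, "se_exposures")
        self.beta_outcome = _as_1d(self.beta_outcome, "beta_outcome")
        self.se_outcome = _as_1d(self.se_outcome, "se_outcome")
        self.variant_ids = [str(v) for v in self.variant_ids]
        J, K = self.beta_exposures.shape
        if not self.exposure_names:
            self.exposure_names = [f"x{k + 1}" for k in range(K)]
        self.exposure_names = [str(e) for e in self.exposure_names]
        if len(self.variant_ids) != J:
            raise ValidationError(
                f"{len(self.variant_ids)} variant ids for {J} rows of beta_exposures"
            )
        if len(set(self.variant_ids)) != J:
            raise ValidationError("variant_ids must be unique")
        if self.se_exposures.shape != (J, K):
            raise ValidationError("se_exposures shape differs from beta_exposures")
        if self.beta_outcome.shape != (J,) or self.se_outcome.shape != (J,):
            raise ValidationError("outcome vectors must have length J")
        if len(self.exposure_names) != K:
            raise ValidationError(f"{len(self.exposure_names)} exposure names for K={K}")
        if self.outcome_scale not in OUTCOME_SCALES:
            raise ValidationError(
                f"outcome_scale must be one of {OUTCOME_SCALES}, got {self.outcome_scale!r}"
            )
        for mat, which in ((self.se_exposures, "exposure"), (self.se_outcome[:, None], "outcome")):
            bad = np.argwhere(~(mat > 0))
            if bad.size:
                j, k = bad[0]
                trait = self.exposure_names[k] if which == "exposure" else "outcome"
                raise ValidationError(
                    f"standard error for variant {self.variant_ids[j]!r}, trait {trait!r} "
                    f"is not strictly positive"
                )
        if not (np.isfinite(self.beta_exposures).all() and np.isfinite(self.beta_outcome).all()):
            raise ValidationError("beta coefficients must be finite")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_exposures.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-variant table (the on-disk layout)."""
        data: dict[str, object] = {"id": self.variant_ids}
        for k, name in enumerate(self.exposure_names):
            data[f"beta_{name}"] = self.beta_exposures[:, k]
            data[f"se_{name}"] = self.se_exposures[:, k]
        data["beta_outcome"] = self.beta_outcome
        data["se_outcome"] = self.se_outcome
        return pd.DataFrame(data)


def _check_correlation(corr: np.ndarray, name: str) -> np.ndarray:
    corr = _as_2d(corr, name)
    m = corr.shape[0]
    if corr.shape != (m, m):
        raise ValidationError(f"{name} must be square, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValidationError(f"{name} must have unit diagonal")
    if np.any(np.abs(corr) > 1 + 1e-10):
        raise ValidationError(f"{name} entries must lie in [-1, 1]")
    if np.linalg.eigvalsh(corr).min() < -_PSD_TOL:
        raise ValidationError(f"{name} must be positive semi-definite")
    return 0.5 * (corr + corr.T)


@dataclass
class TraitCorrelationModel:
    """Correlations between the per-variant beta coefficients across traits.

    When all associations are estimated in the same sample these are
    approximately the observational correlations between the K risk factors
    and the outcome (ordering: exposures first, outcome last).  For a
    two-sample analysis the exposure-outcome entries are zero.
    """

    corr: np.ndarray
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.corr = _check_correlation(self.corr, "trait correlation matrix")
        m = self.corr.shape[0]
        if not self.trait_names:
            self.trait_names = [f"x{k + 1}" for k in range(m - 1)] + ["outcome"]
        if len(self.trait_names) != m:
            raise ValidationError("trait_names length must match matrix dimension")

    @classmethod
    def identity(cls, n_exposures: int) -> "TraitCorrelationModel":
        return cls(np.eye(n_exposures + 1))


@dataclass
class VariantLDMatrix:
    """Pairwise linkage-disequilibrium correlations between the J variants.

    Under sample overlap the correlations between same-trait beta
    coefficients of two variants equal the genotype correlation of the
    variants, so this matrix drives the stacked-likelihood covariance.
    """

    corr: np.ndarray
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.corr = _check_correlation(self.corr, "LD matrix")
        m = self.corr.shape[0]
        if not self.variant_ids:
            self.variant_ids = [f"v{j + 1}" for j in range(m)]
        if len(self.variant_ids) != m:
            raise ValidationError("variant_ids length must match LD matrix dimension")


@dataclass
class IndividualDataset:
    """Individual-level genotype dosages, risk factors and outcome.

    Rows are subjects.  Genotype dosages are additive allele counts in
    {0, 1, 2} (real-valued entries allowed for imputed data).  Missing
    values are rejected.
    """

    genotypes: np.ndarray
    exposures: np.ndarray
    outcome: np.ndarray
    variant_ids: list[str] = field(default_factory=list)
    exposure_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = _as_2d(self.genotypes, "genotypes")
        self.exposures = _as_2d(self.exposures, "exposures")
        self.outcome = _as_1d(self.outcome, "outcome")
        n, J = self.genotypes.shape
        K = self.exposures.shape[1]
        if not self.variant_ids:
            self.variant_ids = [f"v{j + 1}" for j in range(J)]
        if not self.exposure_names:
            self.exposure_names = [f"x{k + 1}" for k in range(K)]
        if self.exposures.shape[0] != n or self.outcome.shape[0] != n:
            raise ValidationError("genotype, exposure and outcome row counts differ")
        if len(self.variant_ids) != J or len(self.exposure_names) != K:
            raise ValidationError("column name counts do not match data dimensions")
        for arr, name in ((self.genotypes, "genotypes"), (self.exposures, "exposures"),
                          (self.outcome, "outcome")):
            if not np.isfinite(arr).all():
                raise ValidationError(f"{name} contain missing or non-finite values")
        var = self.genotypes.var(axis=0)
        if np.any(var == 0):
            j = int(np.argmax(var == 0))
            raise ValidationError(
                f"genotype column {self.variant_ids[j]!r} has zero variance"
            )

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_exposures(self) -> int:
        return self.exposures.shape[1]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    """Read a headered TSV/CSV, sniffing the delimiter."""
    path = Path(path)
    with open(path) as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        sep = "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_summary_table(
    path,
    column_map: Mapping[str, object] | None = None,
    outcome_scale: str = "linear",
) -> SummaryAssociations:
    """Read a per-variant summary-association table from delimited text.

    The default layout has columns ``id``, ``beta_<exposure>``/
    ``se_<exposure>`` for each risk factor, and ``beta_outcome``/
    ``se_outcome``.  Arbitrary upstream headers are absorbed through
    ``column_map``::

        {"id": "rsid",
         "exposures": {"ldl": ("bx1", "se1"), "hdl": ("bx2", "se2")},
         "outcome": ("by", "sey")}
    """
    df = _read_delimited(path)

    if column_map is None:
        beta_cols = [c for c in df.columns
                     if c.startswith("beta_") and c != "beta_outcome"]
        exposures = {c[len("beta_"):]: (c, f"se_{c[len('beta_'):]}") for c in beta_cols}
        column_map = {"id": "id", "exposures": exposures,
                      "outcome": ("beta_outcome", "se_outcome")}

    id_col = column_map.get("id", "id")
    exposures = dict(column_map["exposures"])  # type: ignore[index]
    out_beta, out_se = column_map["outcome"]  # type: ignore[index,misc]

    needed = [id_col, out_beta, out_se]
    for bcol, scol in exposures.values():
        needed += [bcol, scol]
    for col in needed:
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} (available: {list(df.columns)})"
            )

    names = list(exposures)
    beta_x = df[[exposures[n][0] for n in names]].to_numpy(float)
    se_x = df[[exposures[n][1] for n in names]].to_numpy(float)
    return SummaryAssociations(
        variant_ids=df[id_col].astype(str).tolist(),
        beta_exposures=beta_x,
        se_exposures=se_x,
        beta_outcome=df[out_beta].to_numpy(float),
        se_outcome=df[out_se].to_numpy(float),
        outcome_scale=outcome_scale,
        exposure_names=names,
    )


def write_summary_table(assoc: SummaryAssociations, path, sep: str = "\t") -> None:
    """Write ``assoc`` in the default layout at full float precision."""
    assoc.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_correlation_matrix(path) -> np.ndarray:
    """Read a square labelled correlation matrix from delimited text."""
    path = Path(path)
    with open(path) as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        sep = "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    return df.to_numpy(float)


def write_correlation_matrix(corr: np.ndarray, labels: Sequence[str], path,
                             sep: str = "\t") -> None:
    pd.DataFrame(corr, index=list(labels), columns=list(labels)).to_csv(
        path, sep=sep, float_format="%.17g"
    )


def read_individual_data(genotypes_path, exposures_path, outcome_path) -> IndividualDataset:
    """Assemble an :class:`IndividualDataset` from three delimited files."""
    g = _read_delimited(genotypes_path)
    x = _read_delimited(exposures_path)
    y = _read_delimited(outcome_path)
    if y.shape[1] != 1:
        raise ConfigurationError("outcome file must contain exactly one column")
    return IndividualDataset(
        genotypes=g.to_numpy(float),
        exposures=x.to_numpy(float),
        outcome=y.iloc[:, 0].to_numpy(float),
        variant_ids=list(g.columns),
        exposure_names=list(x.columns),
    )


# ---------------------------------------------------------------------------
# individual-level -> summarized bridge
# ---------------------------------------------------------------------------

def _univariate_slopes(g: np.ndarray, traits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope and SE of each trait regressed on one genotype (with intercept).

    Vectorised over trait columns: slope = Sgy/Sgg, SE from the residual sum
    of squares on n-2 degrees of freedom.
    """
    n = g.shape[0]
    gc = g - g.mean()
    sgg = gc @ gc
    tc = traits - traits.mean(axis=0)
    slope = (gc @ tc) / sgg
    rss = (tc * tc).sum(axis=0) - slope**2 * sgg
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / (n - 2) / sgg)
    return slope, se


def summarize(data: IndividualDataset) -> SummaryAssociations:
    """Collapse individual-level data into per-variant univariate summaries.

    For every variant j and every trait (each risk factor and the outcome),
    the beta coefficient and its standard error come from a simple
    least-squares regression of the trait on that variant alone, with
    intercept — the layout in which GWAS consortia publish associations.
    SEs that are exactly zero (perfect fits) are floored at a tiny positive
    value so the result remains a valid :class:`SummaryAssociations`.
    """
    n, J = data.genotypes.shape
    if n <= 2:
        raise ValidationError("summarize requires more than 2 subjects")
    K = data.n_exposures
    traits = np.column_stack([data.exposures, data.outcome])
    betas = np.empty((J, K + 1))
    ses = np.empty((J, K + 1))
    for j in range(J):
        betas[j], ses[j] = _univariate_slopes(data.genotypes[:, j], traits)
    tiny = 1e-300
    ses = np.maximum(ses, tiny)
    return SummaryAssociations(
        variant_ids=list(data.variant_ids),
        beta_exposures=betas[:, :K],
        se_exposures=ses[:, :K],
        beta_outcome=betas[:, K],
        se_outcome=ses[:, K],
        outcome_scale="linear",
        exposure_names=list(data.exposure_names),
    )


def estimate_trait_correlations(data: IndividualDataset) -> TraitCorrelationModel:
    """Observational Pearson correlations of the K risk factors and outcome.

    These approximate the correlations between same-variant beta
    coefficients when all associations are estimated in one sample.
    """
    K = data.n_exposures
    if data.n_subjects <= K + 1:
        raise ValidationError("need n > K+1 subjects to estimate trait correlations")
    mat = np.column_stack([data.exposures, data.outcome])
    if np.any(mat.std(axis=0) == 0):
        k = int(np.argmax(mat.std(axis=0) == 0))
        names = list(data.exposure_names) + ["outcome"]
        raise ValidationError(f"trait {names[k]!r} is constant; correlation undefined")
    corr = np.corrcoef(mat, rowvar=False)
    return TraitCorrelationModel(corr, trait_names=list(data.exposure_names) + ["outcome"])
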