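"""Containers and file I/O for two-sample MR summary statistics.

Two-sample Mendelian randomisation consumes GWAS summary statistics only:
a p x K matrix of per-SNP per-exposure association estimates (gamma-hat)
with matching standard errors, and a length-p vector of SNP-outcome
estimates (Gamma-hat) with standard errors.  These containers hold the
aligned matrices that every downstream step (decomposition, retention,
IVW regression) operates on.

.. warning::
    No allele or strand harmonisation is performed.  Inputs are assumed to
    already be harmonised to a common effect allele per SNP, as is the case
    for curated summary-statistic releases.  Misaligned alleles will silently
    flip effect signs; harmonise upstream.

Missing values are rejected rather than imputed: every downstream formula
assumes complete matrices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpExposureMatrix",
    "OutcomeStats",
    "AnalysisConfig",
    "read_summary_tables",
    "write_matrix",
    "align",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))}")
    return ids


@dataclass
class SnpExposureMatrix:
    """p x K matrix of SNP-exposure association estimates with standard errors.

    Parameters
    ----------
    snp_ids : sequence of str, length p
        Variant identifiers; must be unique.
    exposure_ids : sequence of str, length K
        Exposure (trait) names; must be unique.
    gamma : ndarray of shape (p, K)
        Association estimates, standardized-trait units per effect allele.
    se : ndarray of shape (p, K)
        Standard errors of ``gamma``; strictly positive.
    """

    snp_ids: list[str]
    exposure_ids: list[str]
    gamma: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = _check_unique(self.snp_ids, "SNP")
        self.exposure_ids = _check_unique(self.exposure_ids, "exposure")
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.se = np.atleast_2d(np.asarray(self.se, dtype=float))
        p, k = self.gamma.shape
        if self.se.shape != (p, k):
            raise ValueError(
                f"gamma shape {self.gamma.shape} != se shape {self.se.shape}"
            )
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length does not match gamma rows")
        if len(self.exposure_ids) != k:
            raise ValueError("exposure_ids length does not match gamma columns")
        if p < 2:
            raise ValueError("need at least 2 SNPs")
        if k < 1:
            raise ValueError("need at least 1 exposure")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("gamma contains non-finite values")
        if not (np.all(np.isfinite(self.se)) and np.all(self.se > 0)):
            bad = np.argwhere(~(np.isfinite(self.se) & (self.se > 0)))
            j, k_ = bad[0]
            raise ValueError(
                f"non-positive or non-finite SE for SNP {self.snp_ids[j]!r}, "
                f"exposure {self.exposure_ids[k_]!r}"
            )

    @property
    def n_snps(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.gamma.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized copy of ``gamma`` (zero mean, unit variance)."""
        g = self.gamma
        sd = g.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant gamma column cannot be standardized")
        return (g - g.mean(axis=0)) / sd

    def unit_scaled(self) -> np.ndarray:
        """Copy of ``gamma`` with unit-norm (but uncentered) columns.

        The scale on which retention eigenvalues are computed: the
        cross-product of the scaled matrix has trace K, so a
        non-informative column contributes eigenvalue mass ~1 and the
        usual eigenvalue cutoffs keep their reference level.  No centering
        — the workflow's one-sample equivalence rests on the uncentered
        cross-product, and centering would fold the block-mean structure
        the components are meant to pick up into column contrasts.
        """
        g = self.gamma
        norms = np.linalg.norm(g, axis=0)
        if np.any(norms == 0):
            raise ValueError("all-zero gamma column cannot be scaled")
        return g / norms

    def to_frame(self) -> pd.DataFrame:
        """Wide-format view: SNP, beta_<exposure>, se_<exposure>, ..."""
        data: dict[str, object] = {"SNP": self.snp_ids}
        for k, name in enumerate(self.exposure_ids):
            data[f"beta_{name}"] = self.gamma[:, k]
            data[f"se_{name}"] = self.se[:, k]
        return pd.DataFrame(data)


@dataclass
class OutcomeStats:
    """Length-p vector of SNP-outcome association estimates and SEs.

    The outcome is never transformed by any decomposition step; it enters
    the second-step IVW regression on its original scale.
    """

    snp_ids: list[str]
    Gamma: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = _check_unique(self.snp_ids, "SNP")
        self.Gamma = np.asarray(self.Gamma, dtype=float).ravel()
        self.se = np.asarray(self.se, dtype=float).ravel()
        p = self.Gamma.shape[0]
        if self.se.shape[0] != p or len(self.snp_ids) != p:
            raise ValueError("snp_ids, Gamma and se must have equal length")
        if not np.all(np.isfinite(self.Gamma)):
            raise ValueError("Gamma contains non-finite values")
        if not (np.all(np.isfinite(self.se)) and np.all(self.se > 0)):
            bad = int(np.argmax(~(np.isfinite(self.se) & (self.se > 0))))
            raise ValueError(
                f"non-positive or non-finite SE for SNP {self.snp_ids[bad]!r}"
            )

    @property
    def n_snps(self) -> int:
        return self.Gamma.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snp_ids, "beta": self.Gamma, "se": self.se})


@dataclass
class AnalysisConfig:
    """Plumbing knobs shared by retention and second-step testing.

    alpha is the nominal two-sided significance level; component-level tests
    in the pipeline are run at alpha / B where B is the number of retained
    components.  ``covariance_mode`` controls whether cross-exposure,
    within-SNP covariances enter the Q-statistic variance terms ("zero"
    drops them; "user" expects per-SNP K x K matrices to be supplied).
    """

    alpha: float = 0.05
    n_permutations: int = 1000
    covariance_mode: str = "zero"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.covariance_mode not in ("zero", "user"):
            raise ValueError("covariance_mode must be 'zero' or 'user'")


# ---------------------------------------------------------------------------
# File I/O


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _read_table(path: Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _exposure_from_wide(df: pd.DataFrame, path: str) -> SnpExposureMatrix:
    cols = list(df.columns)
    if cols[0].lower() != "snp":
        raise ValueError(f"{path}: first column must be 'SNP', got {cols[0]!r}")
    beta_cols = [c for c in cols if c.startswith("beta_")]
    names = [c[len("beta_") :] for c in beta_cols]
    for name in names:
        if f"se_{name}" not in cols:
            raise ValueError(f"{path}: missing se_{name} column for beta_{name}")
    if not names:
        raise ValueError(f"{path}: no beta_<exposure>/se_<exposure> column pairs")
    gamma = df[[f"beta_{n}" for n in names]].to_numpy(dtype=float)
    se = df[[f"se_{n}" for n in names]].to_numpy(dtype=float)
    return SnpExposureMatrix(list(df["SNP"].astype(str)), names, gamma, se)


def _exposure_from_long(df: pd.DataFrame, path: str) -> SnpExposureMatrix:
    required = {"SNP", "exposure", "beta", "se"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long format needs columns {sorted(required)}")
    # keep first-appearance order for both axes
    snps = list(dict.fromkeys(df["SNP"].astype(str)))
    exposures = list(dict.fromkeys(df["exposure"].astype(str)))
    if df.duplicated(["SNP", "exposure"]).any():
        raise ValueError(f"{path}: duplicate (SNP, exposure) rows")
    wide_b = df.pivot(index="SNP", columns="exposure", values="beta")
    wide_s = df.pivot(index="SNP", columns="exposure", values="se")
    wide_b = wide_b.loc[snps, exposures]
    wide_s = wide_s.loc[snps, exposures]
    if wide_b.isna().any().any() or wide_s.isna().any().any():
        raise ValueError(f"{path}: incomplete SNP x exposure grid (missing cells)")
    return SnpExposureMatrix(
        snps, exposures, wide_b.to_numpy(float), wide_s.to_numpy(float)
    )


def read_summary_tables(
    exposure_path: str | Path,
    outcome_path: str | Path,
    dialect: str = "auto",
    delimiter: str | None = None,
) -> tuple[SnpExposureMatrix, OutcomeStats, dict]:
    """Read exposure and outcome summary tables and align them on SNP id.

    Parameters
    ----------
    exposure_path, outcome_path : path
        Delimited text files with a header row.  The exposure table is either
        wide (``SNP, beta_<name>, se_<name>, ...``) or long
        (``SNP, exposure, beta, se``); the outcome table has columns
        ``SNP, beta, se``.
    dialect : {"auto", "wide", "long"}
        Exposure-table layout; "auto" detects long format by the presence of
        an ``exposure`` column.
    delimiter : str, optional
        Field delimiter; sniffed from the file when omitted.

    Returns
    -------
    exposures : SnpExposureMatrix
    outcome : OutcomeStats
        Restricted to the intersection of SNP ids, in exposure-file order.
    report : dict
        Counts of SNPs dropped from each table during alignment.
    """
    exposure_path, outcome_path = Path(exposure_path), Path(outcome_path)
    edf = _read_table(exposure_path, delimiter)
    if dialect == "auto":
        dialect = "long" if "exposure" in edf.columns else "wide"
    if dialect == "wide":
        exposures = _exposure_from_wide(edf, str(exposure_path))
    elif dialect == "long":
        exposures = _exposure_from_long(edf, str(exposure_path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    odf = _read_table(outcome_path, delimiter)
    if not {"SNP", "beta", "se"}.issubset(odf.columns):
        raise ValueError(f"{outcome_path}: outcome table needs columns SNP, beta, se")
    outcome = OutcomeStats(
        list(odf["SNP"].astype(str)),
        odf["beta"].to_numpy(float),
        odf["se"].to_numpy(float),
    )
    return align(exposures, outcome)


def align(
    exposures: SnpExposureMatrix, outcome: OutcomeStats
) -> tuple[SnpExposureMatrix, OutcomeStats, dict]:
    """Restrict both tables to their common SNPs, in exposure order.

    Idempotent: aligning already-aligned inputs is a no-op apart from copies.
    """
    common = set(exposures.snp_ids) & set(outcome.snp_ids)
    if not common:
        raise ValueError("no SNPs in common between exposure and outcome tables")
    keep = [s for s in exposures.snp_ids if s in common]
    report = {
        "n_common": len(keep),
        "n_dropped_exposure": exposures.n_snps - len(keep),
        "n_dropped_outcome": outcome.n_snps - len(keep),
    }
    e_idx = [exposures.snp_ids.index(s) for s in keep]
    o_pos = {s: i for i, s in enumerate(outcome.snp_ids)}
    o_idx = [o_pos[s] for s in keep]
    exposures2 = SnpExposureMatrix(
        keep,
        list(exposures.exposure_ids),
        exposures.gamma[e_idx],
        exposures.se[e_idx],
    )
    outcome2 = OutcomeStats(keep, outcome.Gamma[o_idx], outcome.se[o_idx])
    return exposures2, outcome2, report


def write_matrix(obj, path: str | Path, delimiter: str = "\t") -> None:
    """Write any matrix-bearing object as delimited text with a header row.

    Floats carry 17 significant digits so that a read/write round trip is
    the identity well beyond 12 significant digits.  Accepts the containers
    from this module, a pandas DataFrame, or a bare ndarray.
    """
    path = Path(path)
    if hasattr(obj, "to_frame"):
        df = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        arr = np.atleast_2d(np.asarray(obj))
        df = pd.DataFrame(arr, columns=[f"c{i}" for i in range(arr.shape[1])])
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
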