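"""Phenotype preparation and per-variant linear association.

The trait pipeline mirrors a residual-GWAS design: measurements are
log-transformed and residualized on covariates once, and the residual is
then regressed on each variant's dosage separately.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ConfigurationError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_trait",
    "clean_repeated_measures",
    "run_gwas",
    "filter_assoc",
]


def preprocess_trait(raw_values, covariates) -> np.ndarray:
    """Residuals of log(raw) on the covariate matrix.

    ``covariates`` is a DataFrame or 2-D array; an intercept column is the
    caller's responsibility (pass a column of ones for plain centering).
    """
    y = np.asarray(raw_values, dtype=float)
    bad = np.flatnonzero(~(y > 0))
    if len(bad):
        raise DomainError(f"non-positive trait measurement at record {bad[0]}")
    X = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) != len(y):
        raise DomainError("covariates and measurements differ in length")
    if np.isnan(X).any():
        raise DomainError("covariates contain missing values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    ly = np.log(y)
    coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
    return ly - X @ coef


def clean_repeated_measures(observations) -> pd.DataFrame:
    """Two-stage outlier exclusion on per-individual medians.

    Stage 1 drops individuals whose median is more than 10 x IQR(medians)
    from the median of medians (skipped entirely when the IQR is 0, since a
    literal reading would discard every non-median individual).  Stage 2
    drops survivors beyond 4 standard deviations (n-1 denominator) of the
    survivors' mean.  Quartiles use linear interpolation between order
    statistics.
    """
    if isinstance(observations, dict):
        items = list(observations.items())
    else:
        items = list(enumerate(observations))
    if not items:
        raise DomainError("empty input: no individuals to clean")
    ids = [k for k, _ in items]
    meds = np.array([np.median(np.asarray(v, dtype=float)) for _, v in items])
    nobs = np.array([len(v) for _, v in items])
    if (nobs == 0).any():
        raise DomainError("every individual needs at least one observation")

    kept = np.ones(len(ids), dtype=bool)
    stage = np.array([""] * len(ids), dtype=object)

    center = np.median(meds)
    q1, q3 = np.percentile(meds, [25, 75])  # linear interpolation
    iqr = q3 - q1
    if iqr > 0:
        drop1 = np.abs(meds - center) > 10.0 * iqr
        kept[drop1] = False
        stage[drop1] = "stage1"

    surv = kept.copy()
    if surv.sum() >= 2:
        mu = meds[surv].mean()
        sd = meds[surv].std(ddof=1)
        if sd > 0:
            drop2 = surv & (np.abs(meds - mu) > 4.0 * sd)
            kept[drop2] = False
            stage[drop2] = "stage2"

    return pd.DataFrame({
        "individual": ids,
        "median": meds,
        "n_obs": nobs,
        "kept": kept,
        "stage": stage,
    })


def run_gwas(
    panel,
    phenotype,
    maf_min: float = 0.0,
    missing_max: float = 1.0,
    hwe_midp: float | None = None,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Simple linear regression of phenotype on each variant's dosage.

    Variants failing the empirical-MAF or missingness filters are absent
    from the output (counts logged).  Zero-variance dosages are skipped,
    not fatal.  ``hwe_midp`` is accepted for interface parity only:
    synthetic genotypes are in HWE by construction, so the flag is logged
    and otherwise ignored.
    """
    y = np.asarray(phenotype, dtype=float)
    if panel.n_variants == 0:
        raise DomainError("empty panel")
    if len(y) != panel.n_individuals:
        raise DomainError("phenotype not aligned to panel samples")
    if hwe_midp is not None:
        logger.info("hwe_midp=%g accepted as a pass-through flag (not applied)", hwe_midp)

    vm = panel.variant_map
    n = panel.n_individuals
    records = []
    n_maf = n_miss = n_mono = 0
    for a in range(0, panel.n_variants, chunk):
        b = min(a + chunk, panel.n_variants)
        X = np.asarray(panel.dosages[:, a:b], dtype=float)
        miss = np.isnan(X)
        n_i = n - miss.sum(axis=0)
        miss_frac = 1.0 - n_i / n
        Xz = np.where(miss, 0.0, X)
        sx = Xz.sum(axis=0)
        freq = sx / (2.0 * np.maximum(n_i, 1))
        maf_emp = np.minimum(freq, 1.0 - freq)

        yv = np.where(miss, 0.0, y[:, None])
        sy = yv.sum(axis=0)
        sxx = (Xz * Xz).sum(axis=0)
        sxy = (Xz * yv).sum(axis=0)
        syy = (yv * yv).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Sxx = sxx - sx * sx / n_i
            Sxy = sxy - sx * sy / n_i
            Syy = syy - sy * sy / n_i
            beta = Sxy / Sxx
            dfree = n_i - 2
            rss = Syy - beta * Sxy
            se = np.sqrt(np.maximum(rss, 0.0) / np.maximum(dfree, 1) / Sxx)

        for j in range(b - a):
            if miss_frac[j] > missing_max:
                n_miss += 1
                continue
            if maf_emp[j] < maf_min or maf_emp[j] <= 0:
                if maf_emp[j] <= 0 and Sxx[j] <= 1e-12:
                    n_mono += 1
                else:
                    n_maf += 1
                continue
            if Sxx[j] <= 1e-12 or se[j] <= 0 or not np.isfinite(se[j]):
                n_mono += 1
                continue
            t = beta[j] / se[j]
            p = 2.0 * stats.t.sf(abs(t), dfree[j])
            records.append((
                vm["variant_id"].iat[a + j], vm["chrom"].iat[a + j],
                int(vm["position_bp"].iat[a + j]), float(maf_emp[j]), 1.0,
                int(n_i[j]), float(beta[j]), float(se[j]), float(t),
                float(max(p, 5e-324)),
            ))
    if n_maf or n_miss or n_mono:
        logger.info(
            "run_gwas filtered variants: %d below MAF, %d above missingness, %d monomorphic/zero-variance",
            n_maf, n_miss, n_mono,
        )
    return pd.DataFrame.from_records(
        records,
        columns=["variant_id", "chrom", "pos_bp", "maf", "info",
                 "n_obs", "beta", "se", "t_stat", "p"],
    )


def filter_assoc(assoc: pd.DataFrame, maf_min: float = 0.0, info_min: float = 0.0) -> pd.DataFrame:
    """Keep rows with MAF strictly above ``maf_min`` and INFO strictly above
    ``info_min``; row order preserved."""
    if "maf" not in assoc.columns:
        raise ConfigurationError("association table lacks a maf column")
    keep = assoc["maf"] > maf_min
    if info_min > 0:
        if "info" not in assoc.columns:
            raise ConfigurationError("info_min > 0 but table has no INFO column")
        keep &= assoc["info"] > info_min
    return assoc.loc[keep].copy()
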