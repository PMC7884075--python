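"""Dominance, pairwise-epistasis and stratified paired-difference screens.

Each genotype test is a nested-model F comparison on residualized trait
values; genotype classes come from rounding dosage to the nearest of
{0, 1, 2} (ties at .5 round half-up).  Degrees of freedom are computed from
design-matrix ranks, so hard-called dosages (where the dosage column is
collinear with the class indicators) are handled without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, DomainError, HarmonizationError, MonomorphicError

__all__ = [
    "NonAddResult",
    "EpistasisResult",
    "dominance_test",
    "epistasis_test",
    "paired_difference_test",
]

LOW_COUNT = 5


@dataclass
class NonAddResult:
    variant_id: str
    f_stat: float
    df1: int
    df2: int
    p: float
    low_count: bool


@dataclass
class EpistasisResult:
    variant_a: str
    variant_b: str
    f_stat: float
    df1: int
    df2: int
    p: float
    low_count: bool


def round_genotype(dosage: np.ndarray) -> np.ndarray:
    """Round dosage to the nearest of {0, 1, 2}; .5 ties round half-up."""
    return np.clip(np.floor(np.asarray(dosage, dtype=float) + 0.5), 0, 2).astype(int)


def _rss_rank(X: np.ndarray, y: np.ndarray):
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    return rss, int(rank)


def _indicators(g: np.ndarray) -> np.ndarray:
    classes = np.unique(g)
    return np.column_stack([(g == c).astype(float) for c in classes])


def _nested_f(X_small: np.ndarray, X_big: np.ndarray, y: np.ndarray):
    rss0, rank0 = _rss_rank(X_small, y)
    rss1, rank1 = _rss_rank(X_big, y)
    df1 = rank1 - rank0
    df2 = len(y) - rank1
    if df1 == 0:
        return 0.0, 0, df2, 1.0
    if df2 <= 0:
        raise DomainError("not enough observations for the full model")
    f = max(rss0 - rss1, 0.0) / df1 / (rss1 / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, max(p, 5e-324)


def dominance_test(dosage, trait, variant_id: str = "") -> NonAddResult:
    """Dosage-only vs dosage + rounded-genotype-class indicators."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(trait, dtype=float)
    if d.shape != y.shape:
        raise DomainError("dosage and trait must align")
    g = round_genotype(d)
    classes, counts = np.unique(g, return_counts=True)
    if len(classes) < 2:
        raise MonomorphicError("fewer than 2 rounded genotype classes")
    ones = np.ones_like(d)
    X_small = np.column_stack([ones, d])
    X_big = np.column_stack([ones, d, _indicators(g)])
    f, df1, df2, p = _nested_f(X_small, X_big, y)
    return NonAddResult(variant_id, f, df1, df2, p, bool((counts < LOW_COUNT).any()))


def epistasis_test(dosage_a, dosage_b, trait, id_a: str = "", id_b: str = "") -> EpistasisResult:
    """Two-locus genotype-class main effects vs full interaction model."""
    da = np.asarray(dosage_a, dtype=float)
    db = np.asarray(dosage_b, dtype=float)
    y = np.asarray(trait, dtype=float)
    ga = round_genotype(da)
    gb = round_genotype(db)
    for g, lab in ((ga, "a"), (gb, "b")):
        if len(np.unique(g)) < 2:
            raise MonomorphicError(f"variant {lab} monomorphic after rounding")
    ones = np.ones(len(y))
    Ia = _indicators(ga)
    Ib = _indicators(gb)
    X_main = np.column_stack([ones, Ia, Ib])
    cell = ga * 3 + gb
    X_full = np.column_stack([ones, _indicators(cell)])
    f, df1, df2, p = _nested_f(X_main, X_full, y)
    if df1 == 0:
        raise CollinearityError("interaction adds no rank (collinear design)")
    _, cell_counts = np.unique(cell, return_counts=True)
    return EpistasisResult(id_a, id_b, f, df1, df2, p, bool((cell_counts < LOW_COUNT).any()))


def paired_difference_test(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame) -> pd.DataFrame:
    """Per-variant paired-difference Z between two disjoint strata.

    z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    Variants present in only one stratum are excluded (count in
    ``attrs['n_excluded']``).
    """
    cols = ["variant_id", "beta", "se"]
    extra = [c for c in ("ref", "alt") if c in assoc_a.columns and c in assoc_b.columns]
    merged = assoc_a[cols + extra].merge(
        assoc_b[cols + extra], on="variant_id", suffixes=("_a", "_b")
    )
    for c in extra:
        if not (merged[f"{c}_a"] == merged[f"{c}_b"]).all():
            raise HarmonizationError(f"allele mismatch between strata in column {c}")
    z = (merged["beta_a"] - merged["beta_b"]) / np.sqrt(
        merged["se_a"] ** 2 + merged["se_b"] ** 2
    )
    out = pd.DataFrame({
        "variant_id": merged["variant_id"],
        "beta_a": merged["beta_a"],
        "se_a": merged["se_a"],
        "beta_b": merged["beta_b"],
        "se_b": merged["se_b"],
        "z": z,
        "p": np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0),
    })
    out.attrs["n_excluded"] = int(len(assoc_a) + len(assoc_b) - 2 * len(merged))
    return out
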