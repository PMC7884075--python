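"""Causal architectures and phenotype simulation.

A fraction ``pi1`` of eligible variants carries a nonzero effect drawn from
a zero-mean normal (or scaled t) distribution on the standardized-genotype
scale; effects are globally rescaled so the theoretical genetic variance
matches the target heritability exactly.  Clumpy placement draws a causal
probability per megabase from Beta(alpha, alpha/rho) and then a Bernoulli
per variant inside that megabase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..errors import DegenerateSignalError, DomainError, EmptyEligibleError

__all__ = [
    "ArchitectureSpec",
    "SimulatedTrait",
    "draw_causal_effects",
    "simulate_phenotype",
]

MEGABASE = 1_000_000


@dataclass(frozen=True)
class ArchitectureSpec:
    """Description of a simulated genetic architecture.

    ``per_allele_effects`` switches raw effects to the per-allele scale
    (standardized effects proportional to sqrt(2*maf*(1-maf))), which makes
    low-MAF variants carry less variance and hence less association power.
    """

    pi1: float
    h2: float
    effect_family: str = "normal"  # "normal" | "t"
    df: float | None = None
    placement: str = "uniform"  # "uniform" | "clumpy"
    alpha: float | None = None
    rho: float | None = None
    maf_floor: float = 0.0
    inflation_lambda: float = 1.0
    per_allele_effects: bool = False

    def validate(self) -> None:
        if not (0 <= self.pi1 <= 1):
            raise DomainError("pi1 must lie in [0, 1]")
        if not (0 <= self.h2 <= 1):
            raise DomainError("h2 must lie in [0, 1]")
        if self.effect_family not in ("normal", "t"):
            raise DomainError("effect_family must be 'normal' or 't'")
        if self.effect_family == "t" and (self.df is None or self.df <= 2):
            raise DomainError("t effects require df > 2")
        if self.placement not in ("uniform", "clumpy"):
            raise DomainError("placement must be 'uniform' or 'clumpy'")
        if self.placement == "clumpy":
            if self.alpha is None or self.alpha <= 0:
                raise DomainError("clumpy placement requires alpha > 0")
            if self.rho is None or not (0 < self.rho < 1):
                raise DomainError("clumpy placement requires rho in (0, 1)")
        if self.inflation_lambda < 0:
            raise DomainError("inflation_lambda must be >= 0")

    def with_(self, **kw) -> "ArchitectureSpec":
        return replace(self, **kw)


@dataclass
class SimulatedTrait:
    """Causal mask, per-variant effects, and (once simulated) the phenotype.

    ``true_effects`` is on the dosage scale of the final standardized
    phenotype once :func:`simulate_phenotype` has run; before that it holds
    the raw standardized-scale draws.
    """

    causal_mask: np.ndarray
    true_effects: np.ndarray
    phenotype: np.ndarray | None = None
    realized_h2: float | None = None


def _variant_map(panel_or_map) -> pd.DataFrame:
    if isinstance(panel_or_map, pd.DataFrame):
        return panel_or_map
    return panel_or_map.variant_map


def draw_causal_mask(variant_map: pd.DataFrame, spec: ArchitectureSpec, rng) -> np.ndarray:
    """Bernoulli causal indicators under uniform or clumpy placement."""
    maf = variant_map["maf"].to_numpy()
    eligible = maf >= spec.maf_floor
    if not eligible.any():
        raise EmptyEligibleError("maf_floor excludes every variant")
    m = len(variant_map)
    mask = np.zeros(m, dtype=bool)
    if spec.pi1 == 0:
        return mask
    if spec.placement == "uniform":
        mask[eligible] = rng.random(int(eligible.sum())) < spec.pi1
        if spec.pi1 == 1:
            mask[eligible] = True
        return mask
    # clumpy: per-megabase probability P ~ Beta(alpha, alpha/rho), then
    # Bernoulli per variant; the Beta mean is rho/(1+rho), approximately rho.
    chrom = variant_map["chrom"].to_numpy()
    mb = variant_map["position_bp"].to_numpy() // MEGABASE
    keys = pd.Series(list(zip(chrom, mb)))
    for _, idx in keys.groupby(keys, sort=False).groups.items():
        p_mb = rng.beta(spec.alpha, spec.alpha / spec.rho)
        sub = np.asarray(idx)
        sub = sub[eligible[sub]]
        mask[sub] = rng.random(len(sub)) < p_mb
    return mask


def draw_raw_effects(
    variant_map: pd.DataFrame, mask: np.ndarray, spec: ArchitectureSpec, rng
) -> np.ndarray:
    """Zero-mean effect draws on the standardized-genotype scale (unscaled)."""
    m = len(variant_map)
    effects = np.zeros(m)
    k = int(mask.sum())
    if k == 0:
        return effects
    if spec.effect_family == "normal":
        draws = rng.standard_normal(k)
    else:
        draws = rng.standard_t(spec.df, size=k)
    if spec.per_allele_effects:
        maf = variant_map["maf"].to_numpy()[mask]
        draws = draws * np.sqrt(2.0 * maf * (1.0 - maf))
    effects[mask] = draws
    return effects


def draw_causal_effects(panel_or_map, spec: ArchitectureSpec, seed: int) -> SimulatedTrait:
    """Draw the causal mask and raw (unscaled) effect sizes."""
    spec.validate()
    vm = _variant_map(panel_or_map)
    if len(vm) == 0:
        raise DomainError("empty panel")
    rng = np.random.default_rng(seed)
    mask = draw_causal_mask(vm, spec, rng)
    effects = draw_raw_effects(vm, mask, spec, rng)
    return SimulatedTrait(causal_mask=mask, true_effects=effects)


def simulate_phenotype(panel, effects: SimulatedTrait, h2: float, seed: int) -> SimulatedTrait:
    """Phenotype = genetic value + Gaussian noise at target heritability.

    The returned phenotype is standardized to mean 0, variance 1 (ddof=0),
    and ``true_effects`` is rescaled to the dosage scale of that phenotype so
    that sum(2*maf*(1-maf)*beta^2) equals ``realized_h2`` exactly.
    """
    if not (0 <= h2 <= 1):
        raise DomainError("h2 must lie in [0, 1]")
    raw = np.asarray(effects.true_effects, dtype=float)
    if len(raw) != panel.n_variants:
        raise DomainError("effects not aligned to panel variants")
    mask = effects.causal_mask
    rng = np.random.default_rng(seed)
    n = panel.n_individuals

    if h2 > 0 and not np.any(raw != 0):
        raise DegenerateSignalError("all effects are zero but h2 > 0")

    maf = panel.variant_map["maf"].to_numpy()
    het = 2.0 * maf * (1.0 - maf)
    if h2 == 0 or not np.any(raw != 0):
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        return SimulatedTrait(mask, np.zeros_like(raw), phenotype=y, realized_h2=0.0)

    # scale standardized-genotype effects so theoretical genetic variance = h2
    beta_std = raw * np.sqrt(h2 / np.sum(raw**2))
    beta_dos = beta_std / np.sqrt(het)
    idx = np.flatnonzero(beta_dos != 0)
    g = np.asarray(panel.dosages[:, idx], dtype=float) @ beta_dos[idx]
    g = g - g.mean()
    if h2 == 1.0:
        y_raw = g
    else:
        y_raw = g + rng.standard_normal(n) * np.sqrt(1.0 - h2)
    y_raw = y_raw - y_raw.mean()
    s = y_raw.std()
    y = y_raw / s
    beta_final = beta_dos / s
    # clip guards the [0, 1] contract when empirical var(g) dips below h2
    realized = float(min(np.sum(het * beta_final**2), 1.0))
    return SimulatedTrait(mask, beta_final, phenotype=y, realized_h2=realized)
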