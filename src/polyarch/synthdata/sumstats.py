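"""Direct simulation of GWAS summary statistics from a block LD profile.

Marginal z-scores are drawn per LD block from the multivariate normal
implied by the joint causal effects and the block correlation matrix:

    z_block ~ MVN(sqrt(N) * R @ beta_block, R)

with AR(1) block correlation, after which chi-square statistics are
multiplied by the requested inflation factor.  This reproduces the
LD-score-regression expectation E[chi2_i] = lambda * (1 + N * h2 * l_i / M)
without simulating individuals, which makes genome-scale replicates cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ConfigurationError, LDProfileError
from .arch import ArchitectureSpec, SimulatedTrait, draw_causal_mask, draw_raw_effects

__all__ = ["LDProfile", "make_ld_profile", "simulate_summary_stats"]


@dataclass
class LDProfile:
    """Per-variant map plus per-block AR(1) latent correlation.

    ``variant_map`` columns: ``variant_id, chrom, position_bp, maf, block``;
    blocks partition the variants into contiguous runs.
    """

    variant_map: pd.DataFrame
    block_rho: np.ndarray

    def __post_init__(self):
        rho = np.asarray(self.block_rho, dtype=float)
        if np.any(np.abs(rho) >= 1.0):
            raise LDProfileError("block AR(1) correlation must satisfy |rho| < 1")
        blocks = self.variant_map["block"].to_numpy()
        if blocks.min() < 0 or blocks.max() >= len(rho):
            raise ConfigurationError("block indices out of range for block_rho")
        self.block_rho = rho

    @property
    def n_variants(self) -> int:
        return len(self.variant_map)

    def ldscores(self) -> np.ndarray:
        """Closed-form LD scores: l_k = sum_j rho^(2|k-j|) within the block."""
        out = np.empty(self.n_variants)
        blocks = self.variant_map["block"].to_numpy()
        for b, rho in enumerate(self.block_rho):
            idx = np.flatnonzero(blocks == b)
            m = len(idx)
            a = rho * rho
            k = np.arange(m)
            if a == 0:
                out[idx] = 1.0
            else:
                left = a * (1 - a**k) / (1 - a)
                right = a * (1 - a ** (m - 1 - k)) / (1 - a)
                out[idx] = 1.0 + left + right
        return out

    def ldscore_table(self) -> pd.DataFrame:
        vm = self.variant_map
        return pd.DataFrame({
            "variant_id": vm["variant_id"],
            "chrom": vm["chrom"],
            "pos_bp": vm["position_bp"],
            "ldscore": self.ldscores(),
            "maf": vm["maf"],
        })


def make_ld_profile(
    n_variants: int,
    block_size: int = 100,
    rho_range: tuple[float, float] = (0.0, 0.95),
    maf_sampler=None,
    bp_spacing: int = 1000,
    chrom: str = "chr1",
    seed: int = 0,
) -> LDProfile:
    """Random LD profile: fixed-size AR(1) blocks with uniform rho draws.

    Drawing rho per block spreads the LD-score distribution over roughly
    [1, 2/(1-rho_max^2)], mimicking the long right tail of real panels.
    """
    rng = np.random.default_rng(seed)
    n_blocks = (n_variants + block_size - 1) // block_size
    rho = rng.uniform(rho_range[0], rho_range[1], size=n_blocks)
    if maf_sampler is None:
        maf = rng.uniform(0.01, 0.5, size=n_variants)
    elif callable(maf_sampler):
        maf = np.asarray(maf_sampler(rng, n_variants), dtype=float)
    else:
        _, lo, hi = maf_sampler
        maf = rng.uniform(lo, hi, size=n_variants)
    bp = bp_spacing * np.arange(1, n_variants + 1)
    vm = pd.DataFrame({
        "variant_id": [f"{chrom}:{p}" for p in bp],
        "chrom": chrom,
        "position_bp": bp,
        "maf": maf,
        "block": np.arange(n_variants) // block_size,
    })
    return LDProfile(vm, rho)


def _block_slices(blocks: np.ndarray):
    """Contiguous (start, stop) per block id, in order of first appearance."""
    change = np.flatnonzero(np.diff(blocks) != 0) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(blocks)]))
    return [(blocks[a], a, b) for a, b in zip(starts, stops)]


def simulate_summary_stats(
    spec: ArchitectureSpec,
    ld_profile: LDProfile,
    n_individuals: int,
    n_variants: int,
    seed: int,
    return_truth: bool = False,
    effects: np.ndarray | None = None,
):
    """Simulate a per-variant association table on the fast path.

    Output columns follow the internal association dialect (variant_id,
    chrom, pos_bp, maf, info, n_obs, beta, se, t_stat, p).  With
    ``return_truth`` also returns the :class:`SimulatedTrait` holding the
    causal mask and standardized-scale effects.  ``effects`` overrides the
    random architecture with caller-supplied standardized-scale effects
    (used for planted architectures); they are used as given, without the
    h2 rescale.
    """
    spec.validate()
    if ld_profile.n_variants != n_variants:
        raise ConfigurationError(
            f"ld_profile has {ld_profile.n_variants} variants, expected {n_variants}"
        )
    rng = np.random.default_rng(seed)
    vm = ld_profile.variant_map
    if effects is not None:
        beta_std = np.asarray(effects, dtype=float)
        if len(beta_std) != n_variants:
            raise ConfigurationError("effects not aligned to variants")
        mask = beta_std != 0
    else:
        mask = draw_causal_mask(vm, spec, rng)
        raw = draw_raw_effects(vm, mask, spec, rng)
        beta_std = np.zeros(n_variants)
        if spec.h2 > 0 and np.any(raw != 0):
            beta_std = raw * np.sqrt(spec.h2 / np.sum(raw**2))

    blocks = vm["block"].to_numpy()
    rho_by_block = ld_profile.block_rho
    sqrt_n = np.sqrt(n_individuals)
    z = np.empty(n_variants)
    for b, a, stop in _block_slices(blocks):
        m = stop - a
        rho = rho_by_block[b]
        beta_b = beta_std[a:stop]
        # mean term sqrt(N) * R @ beta with R AR(1)
        if np.any(beta_b != 0):
            k = np.arange(m)
            R = rho ** np.abs(k[:, None] - k[None, :])
            mu = sqrt_n * (R @ beta_b)
        else:
            mu = 0.0
        # AR(1) noise by recursion
        e = rng.standard_normal(m)
        if rho != 0.0 and m > 1:
            s = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                e[j] = rho * e[j - 1] + s * e[j]
        z[a:stop] = mu + e

    if spec.inflation_lambda != 1.0:
        z = z * np.sqrt(spec.inflation_lambda)

    maf = vm["maf"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_individuals)
    assoc = pd.DataFrame({
        "variant_id": vm["variant_id"].to_numpy(),
        "chrom": vm["chrom"].to_numpy(),
        "pos_bp": vm["position_bp"].to_numpy(),
        "maf": maf,
        "info": 1.0,
        "n_obs": n_individuals,
        "beta": z * se,
        "se": se,
        "t_stat": z,
        "p": np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324),
    })
    if return_truth:
        return assoc, SimulatedTrait(causal_mask=mask, true_effects=beta_std)
    return assoc
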