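"""Genotype panel simulation.

Genotypes are generated from a latent Gaussian AR(1) process per chromosome:
each haplotype carries a standard-normal latent variable per variant whose
adjacent-variant correlation decays geometrically with genetic distance, and
the alternate allele is called where the latent value falls below the
MAF-quantile threshold.  This is the cheapest generator with a tunable
LD-score distribution; it makes no attempt at coalescent realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import DomainError, LayoutError

__all__ = ["GenotypePanel", "uniform_layout", "simulate_genotypes"]


@dataclass
class GenotypePanel:
    """Dosage matrix plus a per-variant map (bp, cM, MAF).

    ``dosages`` is (individuals x variants), alternate-allele counts in
    [0, 2].  ``variant_map`` columns: ``variant_id, chrom, position_bp,
    position_cm, allele_ref, allele_alt, maf``.
    """

    sample_ids: list
    variant_map: pd.DataFrame
    dosages: np.ndarray
    latent: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        vm = self.variant_map
        if not ((vm["maf"] > 0) & (vm["maf"] <= 0.5)).all():
            raise DomainError("maf must lie in (0, 0.5] for every retained variant")
        for _, grp in vm.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["position_bp"].to_numpy()) > 0):
                raise LayoutError("position_bp not strictly increasing within a chromosome")
            if not np.all(np.diff(grp["position_cm"].to_numpy()) > 0):
                raise LayoutError("position_cm not strictly increasing within a chromosome")
        d = self.dosages
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise DomainError("dosages must lie in [0, 2]")

    def standardized(self, dtype=np.float64) -> np.ndarray:
        """Column-standardized dosage matrix (mean 0, sd 1 per variant)."""
        X = np.asarray(self.dosages, dtype=dtype)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd


def save_panel(panel: GenotypePanel, directory) -> None:
    """Write a panel as plain text: samples.txt, variants.tsv, dosages.tsv."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "samples.txt").write_text("\n".join(panel.sample_ids) + "\n")
    panel.variant_map.to_csv(d / "variants.tsv", sep="\t", index=False)
    np.savetxt(d / "dosages.tsv", panel.dosages, fmt="%.4g", delimiter="\t")


def load_panel(directory) -> GenotypePanel:
    from pathlib import Path

    d = Path(directory)
    sample_ids = (d / "samples.txt").read_text().splitlines()
    variant_map = pd.read_csv(d / "variants.tsv", sep="\t")
    dosages = np.loadtxt(d / "dosages.tsv", delimiter="\t", dtype=np.float32, ndmin=2)
    panel = GenotypePanel(sample_ids, variant_map, dosages)
    panel.validate()
    return panel


def uniform_layout(
    n_variants: int,
    n_chromosomes: int = 1,
    bp_spacing: int = 1000,
    cm_per_mb: float = 1.0,
    chrom_prefix: str = "chr",
) -> pd.DataFrame:
    """Evenly spaced per-chromosome bp/cM grid (variants split evenly)."""
    per = [n_variants // n_chromosomes] * n_chromosomes
    for i in range(n_variants % n_chromosomes):
        per[i] += 1
    frames = []
    for c, m in enumerate(per, start=1):
        bp = bp_spacing * np.arange(1, m + 1)
        frames.append(pd.DataFrame({
            "chrom": f"{chrom_prefix}{c}",
            "position_bp": bp,
            "position_cm": bp * (cm_per_mb / 1e6),
        }))
    return pd.concat(frames, ignore_index=True)


def _resolve_maf_sampler(maf_sampler):
    if maf_sampler is None:
        return lambda rng, size: rng.uniform(0.01, 0.5, size=size)
    if callable(maf_sampler):
        return maf_sampler
    if isinstance(maf_sampler, tuple) and maf_sampler[0] == "uniform":
        _, lo, hi = maf_sampler
        return lambda rng, size: rng.uniform(lo, hi, size=size)
    raise DomainError(f"unsupported maf_sampler: {maf_sampler!r}")


def simulate_genotypes(
    n_individuals: int,
    variant_layout: pd.DataFrame,
    ld_decay: float,
    maf_sampler=None,
    seed: int = 0,
    keep_latent: bool = False,
) -> GenotypePanel:
    """Simulate a diploid dosage panel on the given variant layout.

    ``ld_decay`` is the latent correlation per centimorgan: two adjacent
    variants separated by ``d`` cM have latent haplotype correlation
    ``ld_decay ** d``.  Identical seed and arguments give bit-identical
    output.  With ``keep_latent`` the per-individual mean latent matrix is
    retained for diagnostics.
    """
    if n_individuals < 2:
        raise DomainError("need at least 2 individuals")
    if len(variant_layout) < 2:
        raise DomainError("need at least 2 variants")
    if not (0 <= ld_decay < 1):
        raise DomainError("ld_decay must lie in [0, 1)")

    layout = variant_layout.reset_index(drop=True)
    for _, grp in layout.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["position_bp"].to_numpy()) > 0):
            raise LayoutError("position_bp not strictly increasing within a chromosome")
        if not np.all(np.diff(grp["position_cm"].to_numpy()) > 0):
            raise LayoutError("position_cm not strictly increasing within a chromosome")

    rng = np.random.default_rng(seed)
    m = len(layout)
    sampler = _resolve_maf_sampler(maf_sampler)
    maf = np.asarray(sampler(rng, m), dtype=float)
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise DomainError("maf_sampler yielded values outside (0, 0.5]")

    thresh = stats.norm.ppf(maf)
    dosages = np.empty((n_individuals, m), dtype=np.float32)
    latent = np.empty((n_individuals, m), dtype=np.float32) if keep_latent else None

    # Adjacent latent correlation within a chromosome: ld_decay ** (delta cM);
    # first variant of each chromosome starts a fresh AR chain.
    chrom = layout["chrom"].to_numpy()
    cm = layout["position_cm"].to_numpy()
    r = np.zeros(m)
    same = np.empty(m, dtype=bool)
    same[0] = False
    same[1:] = chrom[1:] == chrom[:-1]
    if ld_decay > 0:
        r[1:] = np.where(same[1:], ld_decay ** np.abs(np.diff(cm)), 0.0)

    h1 = np.empty(n_individuals)
    h2 = np.empty(n_individuals)
    for j in range(m):
        e1 = rng.standard_normal(n_individuals)
        e2 = rng.standard_normal(n_individuals)
        if j == 0 or r[j] == 0.0:
            h1, h2 = e1, e2
        else:
            s = np.sqrt(1.0 - r[j] ** 2)
            h1 = r[j] * h1 + s * e1
            h2 = r[j] * h2 + s * e2
        dosages[:, j] = (h1 < thresh[j]).astype(np.float32) + (h2 < thresh[j])
        if keep_latent:
            latent[:, j] = (h1 + h2) / np.sqrt(2.0)

    variant_map = pd.DataFrame({
        "variant_id": [f"{c}:{p}" for c, p in zip(chrom, layout["position_bp"])],
        "chrom": chrom,
        "position_bp": layout["position_bp"].to_numpy(),
        "position_cm": cm,
        "allele_ref": "A",
        "allele_alt": "G",
        "maf": maf,
    })
    sample_ids = [f"I{i:07d}" for i in range(n_individuals)]
    panel = GenotypePanel(sample_ids, variant_map, dosages, latent=latent)
    panel.validate()
    return panel
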