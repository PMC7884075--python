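"""Synthetic gene annotations and gene-set collections.

Fixtures for the enrichment and pathway-heritability stages: non-overlapping
gene intervals packed into chromosomes, pathways as random gene subsets, and
a helper to plant causal variants inside designated pathway windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import DomainError, PackingError

__all__ = ["simulate_gene_landscape", "plant_causal_mask"]


def simulate_gene_landscape(
    n_genes: int,
    chromosome_lengths,
    pathway_spec=None,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (5_000, 50_000),
):
    """Generate non-overlapping gene intervals and random gene sets.

    ``chromosome_lengths`` maps chromosome name to bp length (a list is
    accepted and named chr1..chrN).  ``pathway_spec`` maps pathway name to
    member count.  Returns ``(genes, gene_sets)`` where ``genes`` is a BED-
    like frame (chrom, start, end, name) in 0-based half-open coordinates.
    """
    if n_genes < 1:
        raise DomainError("n_genes must be >= 1")
    if not isinstance(chromosome_lengths, dict):
        chromosome_lengths = {
            f"chr{i}": int(l) for i, l in enumerate(chromosome_lengths, start=1)
        }
    rng = np.random.default_rng(seed)
    chroms = list(chromosome_lengths)
    lens = np.array([chromosome_lengths[c] for c in chroms], dtype=float)

    # genes to chromosomes, proportional to length
    counts = rng.multinomial(n_genes, lens / lens.sum())
    lo, hi = gene_length_range
    rows = []
    g = 0
    for c, cnt in zip(chroms, counts):
        if cnt == 0:
            continue
        L = chromosome_lengths[c]
        glens = rng.integers(lo, hi + 1, size=cnt)
        span = int(glens.sum())
        if span > L:
            raise PackingError(f"requested gene span {span} exceeds {c} length {L}")
        # distribute the leftover length as random inter-gene gaps
        cuts = np.sort(rng.integers(0, L - span + 1, size=cnt))
        starts = cuts + np.concatenate(([0], np.cumsum(glens[:-1])))
        for s, gl in zip(starts, glens):
            rows.append({"chrom": c, "start": int(s), "end": int(s + gl),
                         "name": f"GENE{g:05d}"})
            g += 1
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    gene_sets: dict[str, list[str]] = {}
    if pathway_spec:
        names = genes["name"].to_numpy()
        for pname, size in pathway_spec.items():
            if size > len(names):
                raise DomainError(f"pathway {pname!r} larger than gene universe")
            members = rng.choice(names, size=size, replace=False)
            gene_sets[pname] = sorted(members)
    return genes, gene_sets


def plant_causal_mask(
    variant_map: pd.DataFrame,
    windows: pd.DataFrame,
    n_causal: int,
    seed: int = 0,
) -> np.ndarray:
    """Causal mask with all ``n_causal`` variants inside the given windows.

    Variant positions are 1-based points; windows are 0-based half-open.
    """
    rng = np.random.default_rng(seed)
    pos = variant_map["position_bp"].to_numpy()
    chrom = variant_map["chrom"].to_numpy()
    inside = np.zeros(len(variant_map), dtype=bool)
    for _, w in windows.iterrows():
        inside |= (chrom == w["chrom"]) & (w["start"] <= pos - 1) & (pos - 1 < w["end"])
    idx = np.flatnonzero(inside)
    if len(idx) < n_causal:
        raise DomainError("fewer eligible in-window variants than requested causals")
    mask = np.zeros(len(variant_map), dtype=bool)
    mask[rng.choice(idx, size=n_causal, replace=False)] = True
    return mask
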