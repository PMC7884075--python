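"""Lead-SNP definition and pathway enrichment.

Clumping follows the greedy plink convention: index variants processed in
ascending p, each absorbing nearby correlated variants.  The centimorgan
merge is anchor-greedy by default — the minimum-p lead absorbs everything
within the window and the procedure repeats on the remainder — with
chain-transitive merging available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnnotationError, DegenerateDesignError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "clump_assoc",
    "merge_leads_cm",
    "gene_windows",
    "genes_near_hits",
    "fisher_pathway_enrichment",
    "poisson_rate_enrichment",
    "matched_null_sets",
]


@dataclass
class EnrichmentResult:
    method: str
    counts: dict
    fold: float
    p: float


def _ld_getter(ld):
    if callable(ld):
        return ld
    missing_logged = [False]

    def get(a, b):
        for key in ((a, b), (b, a)):
            if key in ld:
                return ld[key]
        if not missing_logged[0]:
            logger.warning("missing LD for pair (%s, %s); treating r2 as 0", a, b)
            missing_logged[0] = True
        return 0.0

    return get


def clump_assoc(
    assoc: pd.DataFrame,
    ld,
    p1: float = 1e-4,
    p2: float = 1e-4,
    r2_min: float = 0.01,
    kb_window: float = 10_000,
) -> pd.DataFrame:
    """Greedy p-value clumping; returns the lead table with clump members.

    ``ld`` is either a dict keyed by (id_a, id_b) or a callable returning
    the pairwise r2; missing pairs count as r2 = 0 with a logged warning.
    Ties in p are broken by (chrom, bp).
    """
    get_r2 = _ld_getter(ld)
    df = assoc.sort_values(["p", "chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    cand = df.loc[df["p"] <= p1]
    members = df.loc[df["p"] <= p2]
    assigned: set[str] = set()
    leads = []
    bp_win = kb_window * 1000.0
    for _, row in cand.iterrows():
        vid = row["variant_id"]
        if vid in assigned:
            continue
        assigned.add(vid)
        clump = []
        near = members.loc[
            (members["chrom"] == row["chrom"])
            & (members["pos_bp"] - row["pos_bp"]).abs().le(bp_win)
        ]
        for _, other in near.iterrows():
            ovid = other["variant_id"]
            if ovid in assigned:
                continue
            if get_r2(vid, ovid) >= r2_min:
                assigned.add(ovid)
                clump.append(ovid)
        lead = {
            "variant_id": vid,
            "chrom": row["chrom"],
            "pos_bp": int(row["pos_bp"]),
            "p": float(row["p"]),
            "clump_members": ",".join(clump),
        }
        if "pos_cm" in row.index:
            lead["pos_cm"] = float(row["pos_cm"])
        leads.append(lead)
    return pd.DataFrame(leads)


def merge_leads_cm(leads: pd.DataFrame, window_cm: float = 0.1, chain: bool = False) -> pd.DataFrame:
    """Greedy merge of leads within ``window_cm``, keeping the minimum-p lead.

    Anchor mode (default): the best remaining lead absorbs all remaining
    leads within the window of *its own* position, then the procedure
    repeats.  ``chain=True`` instead grows each merged group transitively
    through successive within-window neighbours.
    """
    if len(leads) == 0:
        return leads.copy()
    if "pos_cm" not in leads.columns:
        raise DomainError("leads need a pos_cm column for centimorgan merging")
    df = leads.sort_values(["p", "chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    taken = np.zeros(len(df), dtype=bool)
    keep_rows = []
    for i in range(len(df)):
        if taken[i]:
            continue
        taken[i] = True
        anchor = df.iloc[i]
        group = {i}
        frontier = [i]
        while frontier:
            j = frontier.pop()
            ref = df.iloc[j]
            near = np.flatnonzero(
                (~taken)
                & (df["chrom"] == ref["chrom"]).to_numpy()
                & ((df["pos_cm"] - ref["pos_cm"]).abs() <= window_cm).to_numpy()
            )
            for k in near:
                taken[k] = True
                group.add(int(k))
                if chain:
                    frontier.append(int(k))
        keep_rows.append(anchor)
    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    return out


def gene_windows(genes: pd.DataFrame, flank_bp: int = 100_000, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Gene bodies extended by ``flank_bp``, clipped to chromosome bounds."""
    out = genes.copy()
    if chrom_sizes is not None:
        unknown = set(out["chrom"]) - set(chrom_sizes)
        if unknown:
            raise AnnotationError(f"genes on unknown chromosome(s): {sorted(unknown)}")
    out["start"] = np.maximum(out["start"] - flank_bp, 0)
    if chrom_sizes is not None:
        limit = out["chrom"].map(chrom_sizes).to_numpy()
        out["end"] = np.minimum(out["end"] + flank_bp, limit)
    else:
        out["end"] = out["end"] + flank_bp
    return out


def genes_near_hits(windows: pd.DataFrame, leads: pd.DataFrame, p_max: float = 5e-8) -> pd.Series:
    """Per-gene indicator: any lead with p < p_max inside the gene window.

    Lead positions are 1-based points; a lead at 1-based position ``pos``
    is inside the 0-based half-open window [start, end) iff
    start <= pos - 1 < end.
    """
    qual = leads.loc[leads["p"] < p_max]
    flags = pd.Series(False, index=windows["name"].to_numpy())
    for c, grp in qual.groupby("chrom", sort=False):
        w = windows.loc[windows["chrom"] == c]
        if not len(w):
            continue
        pos0 = grp["pos_bp"].to_numpy() - 1
        for name, s, e in zip(w["name"], w["start"], w["end"]):
            if np.any((pos0 >= s) & (pos0 < e)):
                flags[name] = True
    return flags


def fisher_pathway_enrichment(hit_indicator, pathway, universe) -> EnrichmentResult:
    """Two-sided Fisher 2x2 test of pathway membership vs hit status.

    Fold is the ratio of hit rates inside vs outside the pathway; the full
    2x2 counts are reported so alternative fold definitions can be
    recomputed.
    """
    universe = list(universe)
    pathway = set(pathway)
    if not universe:
        raise DomainError("empty universe")
    if not pathway:
        raise DomainError("empty pathway: fold undefined")
    if not pathway <= set(universe):
        raise DomainError("pathway is not a subset of the universe")
    hits = {g for g in universe if bool(hit_indicator[g])}
    k = len(pathway & hits)
    K = len(pathway)
    m = len(hits)
    N = len(universe)
    table = np.array([[k, K - k], [m - k, N - K - (m - k)]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    out_rate = (m - k) / (N - K) if N > K else np.nan
    in_rate = k / K
    if np.isnan(out_rate) or (out_rate == 0 and in_rate == 0):
        fold = 1.0
    elif out_rate == 0:
        fold = np.inf
    else:
        fold = in_rate / out_rate
    return EnrichmentResult(
        method="fisher",
        counts={"k": k, "K": K, "m": m, "N": N},
        fold=float(fold),
        p=float(min(p, 1.0)),
    )


def _total_mb(intervals: pd.DataFrame) -> float:
    from .heritability import _merge

    if len(intervals) == 0:
        return 0.0
    total = 0
    for _, g in intervals.groupby("chrom", sort=False):
        for s, e in _merge(zip(g["start"], g["end"])):
            total += e - s
    return total / 1e6


def _count_leads_in(intervals: pd.DataFrame, leads: pd.DataFrame) -> int:
    from .heritability import _merge

    n = 0
    for c, g in intervals.groupby("chrom", sort=False):
        merged = _merge(zip(g["start"], g["end"]))
        pos0 = leads.loc[leads["chrom"] == c, "pos_bp"].to_numpy() - 1
        for s, e in merged:
            n += int(np.sum((pos0 >= s) & (pos0 < e)))
    return n


def poisson_rate_enrichment(
    leads: pd.DataFrame,
    pathway_windows: pd.DataFrame,
    background_windows: pd.DataFrame,
) -> EnrichmentResult:
    """Exact conditional comparison of lead rates per megabase.

    Conditional on the total count, the in-pathway count is binomial with
    probability proportional to the in-pathway megabases, which gives the
    exact Poisson rate comparison.
    """
    mb_in = _total_mb(pathway_windows)
    mb_out = _total_mb(background_windows)
    if mb_in <= 0 or mb_out <= 0:
        raise DegenerateDesignError("zero megabases in one of the window classes")
    k_in = _count_leads_in(pathway_windows, leads)
    k_out = _count_leads_in(background_windows, leads)
    total = k_in + k_out
    if total == 0:
        return EnrichmentResult(
            "poisson",
            {"hits_in": 0, "hits_out": 0, "mb_in": mb_in, "mb_out": mb_out},
            fold=1.0,
            p=1.0,
        )
    rate_in = k_in / mb_in
    rate_out = k_out / mb_out
    fold = 1.0 if (rate_in == 0 and rate_out == 0) else (
        np.inf if rate_out == 0 else rate_in / rate_out
    )
    p = stats.binomtest(k_in, total, mb_in / (mb_in + mb_out)).pvalue
    return EnrichmentResult(
        "poisson",
        {"hits_in": k_in, "hits_out": k_out, "mb_in": mb_in, "mb_out": mb_out},
        fold=float(fold),
        p=float(p),
    )


def _decile(x: np.ndarray) -> np.ndarray:
    """Decile codes 0..9 by rank (stable under ties via average rank)."""
    order = stats.rankdata(x, method="average")
    return np.minimum((10 * (order - 0.5) / len(x)).astype(int), 9)


def matched_null_sets(
    leads: pd.DataFrame,
    variant_table: pd.DataFrame,
    n_sets: int,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Random variant sets matched to leads on MAF, LD score and gene distance.

    Matching cells are (MAF decile x LD-score decile x gene-distance decile)
    computed over the full variant table; leads are excluded from every
    matched set and sampling is without replacement within a set.  An empty
    cell falls back to the nearest cell in decile space (logged).
    """
    required = {"variant_id", "maf", "ldscore", "gene_distance"}
    if not required <= set(variant_table.columns):
        raise DomainError(f"variant_table needs columns {sorted(required)}")
    vt = variant_table.reset_index(drop=True)
    codes = np.column_stack([
        _decile(vt["maf"].to_numpy()),
        _decile(vt["ldscore"].to_numpy()),
        _decile(vt["gene_distance"].to_numpy()),
    ])
    lead_ids = set(leads["variant_id"])
    is_lead = vt["variant_id"].isin(lead_ids).to_numpy()
    id_arr = vt["variant_id"].to_numpy()

    cells: dict[tuple, np.ndarray] = {}
    for i in range(len(vt)):
        if not is_lead[i]:
            cells.setdefault(tuple(codes[i]), []).append(i)
    cells = {k: np.asarray(v) for k, v in cells.items()}
    lead_codes = {}
    by_id = {v: i for i, v in enumerate(id_arr)}
    for vid in leads["variant_id"]:
        if vid not in by_id:
            raise DomainError(f"lead {vid!r} missing from variant_table")
        lead_codes[vid] = tuple(codes[by_id[vid]])

    rng = np.random.default_rng(seed)
    out = []
    n_fallback = 0
    for s in range(n_sets):
        used: set[int] = set()
        rows = []
        for vid in leads["variant_id"]:
            code = lead_codes[vid]
            pool = [i for i in cells.get(code, []) if i not in used]
            fallback = False
            if not pool:
                fallback = True
                best = None
                for other, members in cells.items():
                    avail = [i for i in members if i not in used]
                    if not avail:
                        continue
                    d = max(abs(a - b) for a, b in zip(code, other))
                    if best is None or d < best[0]:
                        best = (d, avail)
                if best is None:
                    raise DomainError("variant table exhausted while matching")
                pool = best[1]
                n_fallback += 1
            pick = int(rng.choice(pool))
            used.add(pick)
            rows.append({
                "variant_id": id_arr[pick],
                "source_lead": vid,
                "maf": vt["maf"].iat[pick],
                "ldscore": vt["ldscore"].iat[pick],
                "gene_distance": vt["gene_distance"].iat[pick],
                "fallback": fallback,
            })
        out.append(pd.DataFrame(rows))
    if n_fallback:
        logger.warning("matched_null_sets: %d matches relaxed to nearest cell", n_fallback)
    return out
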