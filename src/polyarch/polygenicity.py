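"""Causal-fraction estimation from LD-binned summary statistics.

Pipeline: windowed LD scores; ntile binning of variants by LD score with a
per-bin empirical-Bayes null proportion and mean chi-square; univariate
LD-score regression for the inflation intercept; and two estimators of the
causal fraction pi1 — matching observed bin curves against a simulated
reference library over a (pi1, lambda) grid, and a parametric fit of the
non-null fraction as a function of LD score.

The parametric functional form 1 - (1 - pi1)^(c * l) is this package's
construction (the probability a marker tags no causal variant among an
effective c * l neighbours); it is recorded as such in fit metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import ashcore
from .errors import (
    AlignmentError,
    DegenerateDesignError,
    FitFailureError,
    InsufficientDataError,
    InsufficientSampleError,
)
from .synthdata import ArchitectureSpec, LDProfile, simulate_summary_stats

__all__ = [
    "compute_ld_scores",
    "bin_and_summarize",
    "ldsc_regression",
    "ReferenceLibrary",
    "build_reference_curves",
    "estimate_pi1_matching",
    "estimate_pi1_parametric",
    "PolygenicityFit",
]


# ---------------------------------------------------------------------------
# LD scores

def compute_ld_scores(panel, window_cm: float = 1.0, chunk: int = 512) -> pd.DataFrame:
    """Windowed LD scores with the small-sample bias adjustment.

    l_i = sum over j within ``window_cm`` of i (self included) of
    max(0, r2_ij - (1 - r2_ij)/(n - 2)).
    """
    n = panel.n_individuals
    if n < 3:
        raise InsufficientSampleError("need at least 3 individuals for adjusted r2")
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    vm = panel.variant_map
    ell = np.empty(panel.n_variants)
    for _, grp in vm.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = grp["position_cm"].to_numpy()
        X = np.asarray(panel.dosages[:, idx], dtype=np.float32)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        lo_all = np.searchsorted(cm, cm - window_cm, side="left")
        hi_all = np.searchsorted(cm, cm + window_cm, side="right")
        for a in range(0, len(idx), chunk):
            b = min(a + chunk, len(idx))
            lo, hi = lo_all[a:b].min(), hi_all[a:b].max()
            r = (X[:, a:b].T @ X[:, lo:hi]) / np.float32(n)
            r2 = r.astype(np.float64) ** 2
            adj = np.maximum(r2 - (1.0 - r2) / (n - 2), 0.0)
            cs = np.concatenate([np.zeros((b - a, 1)), np.cumsum(adj, axis=1)], axis=1)
            rows = np.arange(b - a)
            ell[idx[a:b]] = cs[rows, hi_all[a:b] - lo] - cs[rows, lo_all[a:b] - lo]
    return pd.DataFrame({
        "variant_id": vm["variant_id"],
        "chrom": vm["chrom"],
        "pos_bp": vm["position_bp"],
        "ldscore": ell,
        "maf": vm["maf"],
    })


# ---------------------------------------------------------------------------
# binning

def _ntile_sizes(n: int, n_bins: int) -> np.ndarray:
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    return sizes


def bin_and_summarize(
    assoc: pd.DataFrame,
    ldscores: pd.DataFrame,
    n_bins: int,
    maf_range: tuple[float, float] = (0.0, 0.5),
    penalty: float = 10.0,
    min_bin: int = 10,
    bootstrap_se: int = 0,
    seed: int = 0,
    ash_tol: float = 1e-6,
    ash_maxiter: int = 1000,
    tail_chisq: float = 9.0,
) -> pd.DataFrame:
    """Equal-count LD-score bins with per-bin mean chi-square and null weight.

    Variants are filtered to ``maf_range`` (strict inequalities on both
    ends, except an inclusive upper bound at 0.5), ranked by LD score with
    stable ties on input order, and split into ``n_bins`` ntile bins.  Bins
    with fewer than ``min_bin`` variants are flagged and get no prop_null.
    ``bootstrap_se > 0`` adds a prop_null_se column from that many within-
    bin multinomial resamples.

    Each bin also carries ``tail_frac``, the fraction of chi-square
    statistics above ``tail_chisq``: unlike the mixture-based null weight,
    the marginal chi-square distribution is exactly calibrated under the
    null even when test statistics are LD-correlated, which makes this the
    most robust of the matched curves at small variant counts.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    df = assoc.merge(ldscores[["variant_id", "ldscore"]], on="variant_id", how="inner")
    lo, hi = maf_range
    keep = df["maf"] > lo
    keep &= (df["maf"] <= 0.5) if hi >= 0.5 else (df["maf"] < hi)
    df = df.loc[keep].reset_index(drop=True)
    n = len(df)
    if n < n_bins:
        raise InsufficientDataError(f"{n} variants cannot fill {n_bins} bins")
    order = np.argsort(df["ldscore"].to_numpy(), kind="stable")
    sizes = _ntile_sizes(n, n_bins)
    bounds = np.concatenate(([0], np.cumsum(sizes)))

    chisq = df["t_stat"].to_numpy() ** 2
    rows = []
    for k in range(n_bins):
        sel = order[bounds[k]:bounds[k + 1]]
        nb = len(sel)
        ell = df["ldscore"].to_numpy()[sel]
        x2 = chisq[sel]
        beta = df["beta"].to_numpy()[sel]
        se = df["se"].to_numpy()[sel]
        row = {
            "bin_index": k,
            "mean_ld": ell.mean(),
            "se_ld": ell.std(ddof=1) / np.sqrt(nb) if nb > 1 else np.nan,
            "mean_chisq": np.nanmean(x2),
            "se_chisq": np.nanstd(x2, ddof=1) / np.sqrt(np.sum(~np.isnan(x2))) if nb > 1 else np.nan,
            "mean_maf": df["maf"].to_numpy()[sel].mean(),
            "n_variants": nb,
            "prop_null": np.nan,
            "tail_frac": float(np.nanmean(x2 > tail_chisq)),
            "tail_se": float(
                max(np.sqrt(np.nanmean(x2 > tail_chisq)
                            * (1 - np.nanmean(x2 > tail_chisq)) / nb), 1e-4)
            ),
            "flagged": nb < min_bin,
        }
        if nb >= max(min_bin, 10):  # mixture fit needs >= 10 observations
            model = ashcore.fit_ash(beta, se, penalty=penalty, tol=ash_tol, maxiter=ash_maxiter)
            row["prop_null"] = model.pi0
            if bootstrap_se > 0:
                boots = ashcore.bootstrap_pi0(
                    beta, se, n_boot=bootstrap_se, seed=seed * 100003 + k,
                    penalty=penalty,
                )
                row["prop_null_se"] = float(np.std(boots, ddof=1))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_bins"] = n_bins
    out.attrs["maf_range"] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# LD-score regression

def ldsc_regression(assoc: pd.DataFrame, ldscores: pd.DataFrame, n_individuals: int):
    """Weighted least squares of chi-square on LD score.

    Starts from the 1/max(1, l)^2 heteroscedasticity proxy and then
    iterates the weights as 1/(2 * E[chi2]^2) using the current fit (the
    variance of chi-square grows with its expectation, so signal-heavy
    variants must be down-weighted or the intercept becomes noisy).
    Returns (slope, intercept, se_slope, se_intercept, h2_implied).
    """
    df = assoc.merge(ldscores[["variant_id", "ldscore"]], on="variant_id", how="inner")
    if len(df) < 100:
        raise InsufficientDataError("need at least 100 variants")
    x = df["ldscore"].to_numpy()
    y = df["t_stat"].to_numpy() ** 2
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant LD score")

    X = np.column_stack([np.ones_like(x), x])
    w = 1.0 / np.maximum(1.0, x) ** 2
    for _ in range(3):
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        coef = np.linalg.solve(XtWX, Xw.T @ y)
        expected = np.maximum(X @ coef, 0.1)
        w = 1.0 / (2.0 * expected**2) / np.maximum(1.0, x)
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    coef = np.linalg.solve(XtWX, Xw.T @ y)
    resid = y - X @ coef
    dof = len(x) - 2
    s2 = np.sum(w * resid**2) / dof
    cov = s2 * np.linalg.inv(XtWX)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    M = len(df)
    h2 = slope * M / n_individuals
    return float(slope), float(intercept), float(se_slope), float(se_int), float(h2)


# ---------------------------------------------------------------------------
# reference library

@dataclass
class ReferenceLibrary:
    """Averaged bin curves per (pi1, lambda) grid point."""

    pi1_grid: list
    lambda_grid: list
    curves: dict  # (pi1, lambda) -> DataFrame of bin summaries
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "pi1_grid": list(self.pi1_grid),
            "lambda_grid": list(self.lambda_grid),
            "meta": self.meta,
            "curves": [
                {"pi1": p, "lambda": l, "bins": curve.to_dict(orient="list")}
                for (p, l), curve in sorted(self.curves.items())
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ReferenceLibrary":
        d = json.loads(s)
        curves = {
            (c["pi1"], c["lambda"]): pd.DataFrame(c["bins"]) for c in d["curves"]
        }
        return cls(d["pi1_grid"], d["lambda_grid"], curves, d["meta"])


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0])


def build_reference_curves(
    pi1_grid,
    lambda_grid,
    spec_template: ArchitectureSpec,
    ld_profile: LDProfile,
    n_individuals: int,
    n_variants: int,
    n_reps: int,
    seed: int,
    n_bins: int = 1000,
    maf_range: tuple[float, float] = (0.0, 0.5),
    penalty: float = 10.0,
    cache_dir=None,
) -> ReferenceLibrary:
    """Simulate and summarize reference curves over a (pi1, lambda) grid.

    Each replicate is simulated once at lambda = 1; inflation is applied to
    the simulated statistics (t and beta scaled by sqrt(lambda)) and the bin
    summaries, including prop_null, are recomputed on the inflated values.
    Results are cached to ``cache_dir`` keyed by a content hash of all
    parameters.
    """
    if not len(pi1_grid) or not len(lambda_grid):
        raise ValueError("grids must be nonempty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if ld_profile.n_variants != n_variants:
        raise AlignmentError("ld_profile does not match n_variants")

    key = {
        "pi1_grid": list(map(float, pi1_grid)),
        "lambda_grid": list(map(float, lambda_grid)),
        "spec": {k: (v if not isinstance(v, np.generic) else float(v))
                 for k, v in spec_template.__dict__.items()},
        "n_individuals": int(n_individuals),
        "n_variants": int(n_variants),
        "n_reps": int(n_reps),
        "seed": int(seed),
        "n_bins": int(n_bins),
        "maf_range": list(map(float, maf_range)),
        "penalty": float(penalty),
        "profile_rho_digest": hashlib.sha256(
            np.ascontiguousarray(ld_profile.block_rho).tobytes()
        ).hexdigest(),
    }
    digest = hashlib.sha256(json.dumps(key, sort_keys=True).encode()).hexdigest()[:16]
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"reflib_{digest}.json"
        if cache_path.exists():
            return ReferenceLibrary.from_json(cache_path.read_text())

    ldsc_table = ld_profile.ldscore_table()
    ldsc_table = ldsc_table.rename(columns={"pos_bp": "pos_bp"})
    acc: dict[tuple, list] = {}
    for i, pi1 in enumerate(pi1_grid):
        spec = spec_template.with_(pi1=float(pi1), inflation_lambda=1.0)
        for r in range(n_reps):
            assoc = simulate_summary_stats(
                spec, ld_profile, n_individuals, n_variants,
                seed=_child_seed(seed, i, r),
            )
            for lam in lambda_grid:
                inflated = assoc.copy()
                s = np.sqrt(float(lam))
                inflated["t_stat"] = assoc["t_stat"] * s
                inflated["beta"] = assoc["beta"] * s
                bins = bin_and_summarize(
                    inflated, ldsc_table, n_bins, maf_range, penalty=penalty,
                )
                acc.setdefault((float(pi1), float(lam)), []).append(bins)

    curves = {}
    for k, frames in acc.items():
        g = pd.concat(frames).groupby("bin_index")
        stacked = g.mean(numeric_only=True).reset_index()
        # between-replicate spread: realization noise of a single curve,
        # needed to weight the matching objective honestly
        if n_reps > 1:
            stacked["prop_null_rep_sd"] = g["prop_null"].std(ddof=1).to_numpy()
            stacked["chisq_rep_sd"] = g["mean_chisq"].std(ddof=1).to_numpy()
            stacked["tail_rep_sd"] = g["tail_frac"].std(ddof=1).to_numpy()
        else:
            stacked["prop_null_rep_sd"] = 0.0
            stacked["chisq_rep_sd"] = 0.0
            stacked["tail_rep_sd"] = 0.0
        stacked["n_reps"] = n_reps
        curves[k] = stacked
    meta = {
        "n_bins": n_bins, "maf_range": list(maf_range),
        "n_individuals": int(n_individuals), "n_variants": int(n_variants),
        "h2": float(spec_template.h2), "n_reps": int(n_reps), "seed": int(seed),
        "digest": digest,
    }
    lib = ReferenceLibrary(list(map(float, pi1_grid)), list(map(float, lambda_grid)), curves, meta)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(lib.to_json())
    return lib


def deflate_assoc(assoc: pd.DataFrame, lambda_assumed: float) -> pd.DataFrame:
    """Rescale test statistics by an assumed inflation before re-binning.

    Dividing chi-square by ``lambda_assumed`` (t and beta by its square
    root) lets downstream fits be rerun under different inflation
    assumptions.
    """
    if lambda_assumed <= 0:
        raise ValueError("lambda_assumed must be positive")
    out = assoc.copy()
    s = np.sqrt(lambda_assumed)
    out["t_stat"] = assoc["t_stat"] / s
    out["beta"] = assoc["beta"] / s
    return out


# ---------------------------------------------------------------------------
# estimators

@dataclass
class PolygenicityFit:
    pi1_hat: float
    method: str
    lambda_grid: list
    objective_by_lambda: dict
    best_lambda: float
    diagnostics: dict = field(default_factory=dict)


def _smoothed_sq(values: pd.Series, win: int) -> np.ndarray:
    # few-replicate sd estimates are chi-distributed noise; smooth across
    # neighbouring bins before squaring into a variance
    return values.rolling(win, center=True, min_periods=1).mean().to_numpy() ** 2


def _common_tail_variance(library: "ReferenceLibrary", lam: float):
    """Grid-shared per-bin tail-fraction variance at inflation ``lam``.

    The tail curve uses one variance profile for the whole pi1 grid (the
    median of the smoothed between-replicate variances) so that grid points
    with spiky reference curves cannot win the match purely by
    down-weighting their own residuals.
    """
    vt = []
    for p in library.pi1_grid:
        s = library.curves[(p, lam)]
        if "tail_rep_sd" not in s:
            return None
        win = max(5, len(s) // 20)
        vt.append(_smoothed_sq(s["tail_rep_sd"], win))
    n_reps = float(library.meta.get("n_reps", 1))
    infl = 1.0 + 1.0 / max(n_reps, 1.0)
    return infl * np.median(vt, axis=0)


def _objective(
    observed: pd.DataFrame,
    sim: pd.DataFrame,
    min_bin: int,
    tail_var_common: np.ndarray | None = None,
):
    """Weighted mismatch of observed vs simulated bin curves.

    Three matched curves: the empirical-Bayes null proportion and the mean
    chi-square (per-curve realization variance from library replicates),
    and the chi-square tail fraction (grid-shared variance).  The observed
    curve is a single draw while the library curve is an n_reps average,
    hence the (1 + 1/n_reps) inflation of the replicate variance.
    """
    o = observed.set_index("bin_index")
    s = sim.set_index("bin_index")
    common = o.index.intersection(s.index)
    o = o.loc[common]
    s = s.loc[common]
    boot_pn = (
        o["prop_null_se"].to_numpy() if "prop_null_se" in o else np.full(len(o), 0.02)
    )
    if "prop_null_rep_sd" in s:
        win = max(5, len(s) // 20)
        infl = 1.0 + 1.0 / max(float(s["n_reps"].iloc[0]) if "n_reps" in s else 1.0, 1.0)
        var_pn = boot_pn**2 + infl * _smoothed_sq(s["prop_null_rep_sd"], win)
        var_chi = o["se_chisq"].to_numpy() ** 2 + infl * _smoothed_sq(s["chisq_rep_sd"], win)
    else:
        var_pn = boot_pn**2
        var_chi = o["se_chisq"].to_numpy() ** 2
    usable = (
        o["prop_null"].notna() & s["prop_null"].notna()
        & (o["n_variants"] >= min_bin)
    ).to_numpy()
    se_pn = np.maximum(np.sqrt(var_pn), 1e-3)
    se_chi = np.maximum(np.sqrt(var_chi), 1e-6)
    r_pn = ((o["prop_null"].to_numpy() - s["prop_null"].to_numpy()) / se_pn)[usable]
    r_chi = ((o["mean_chisq"].to_numpy() - s["mean_chisq"].to_numpy()) / se_chi)[usable]
    obj = float(np.sum(r_pn**2) + np.sum(r_chi**2))
    if "tail_frac" in o and "tail_frac" in s:
        var_tail = o["tail_se"].to_numpy() ** 2 if "tail_se" in o else 0.0
        if tail_var_common is not None:
            var_tail = var_tail + np.asarray(tail_var_common)[common]
        elif "tail_rep_sd" in s:
            win = max(5, len(s) // 20)
            var_tail = var_tail + _smoothed_sq(s["tail_rep_sd"], win)
        se_tail = np.maximum(np.sqrt(var_tail), 1e-4)
        r_tail = ((o["tail_frac"].to_numpy() - s["tail_frac"].to_numpy()) / se_tail)[usable]
        obj += float(np.sum(r_tail**2))
    return obj, r_pn, r_chi


def estimate_pi1_matching(
    observed: pd.DataFrame,
    library: ReferenceLibrary,
    min_bin: int = 10,
    lambda_fixed: float | None = None,
) -> PolygenicityFit:
    """Grid match of observed bin curves against the reference library.

    Selects the (pi1, lambda) grid point minimizing the weighted curve
    mismatch, then refines pi1 by a quadratic fit of the objective in
    log10(pi1) between the bracketing grid points.

    ``lambda_fixed`` pins the inflation to the nearest grid value instead
    of fitting it — typically the observed LD-score-regression intercept.
    Left free, lambda can partially compensate a wrong pi1 (a deflated
    chi-square pairs with a higher causal fraction), so pinning it to the
    intercept gives the most calibrated estimates.
    """
    if observed.attrs.get("n_bins") is not None and library.meta.get("n_bins") is not None:
        if observed.attrs["n_bins"] != library.meta["n_bins"]:
            raise AlignmentError("observed and library built with different n_bins")
        if tuple(observed.attrs.get("maf_range", ())) != tuple(library.meta.get("maf_range", ())):
            raise AlignmentError("observed and library built with different maf_range")

    pi1s = sorted(library.pi1_grid)
    lams = sorted(library.lambda_grid)
    surface = {}
    for lam in lams:
        vt = _common_tail_variance(library, lam)
        vals = []
        for p in pi1s:
            obj, _, _ = _objective(observed, library.curves[(p, lam)], min_bin, vt)
            vals.append(obj)
        surface[lam] = vals

    if lambda_fixed is not None:
        best_lam = min(lams, key=lambda l: abs(l - lambda_fixed))
    else:
        best_lam = min(lams, key=lambda l: min(surface[l]))
    vals = surface[best_lam]
    j = int(np.argmin(vals))
    pi1_hat = pi1s[j]
    if 0 < j < len(pi1s) - 1 and vals[j] > 1e-9 and pi1s[j - 1] > 0:
        x = np.log10([pi1s[j - 1], pi1s[j], pi1s[j + 1]])
        y = np.array([vals[j - 1], vals[j], vals[j + 1]])
        denom = (x[1] - x[0]) * (y[1] - y[2]) - (x[1] - x[2]) * (y[1] - y[0])
        if denom != 0:
            vertex = x[1] - 0.5 * (
                (x[1] - x[0]) ** 2 * (y[1] - y[2]) - (x[1] - x[2]) ** 2 * (y[1] - y[0])
            ) / denom
            # trust region: at most half the narrower log-spacing, so a
            # shallow objective cannot drag the refinement off-grid
            half = 0.5 * min(x[1] - x[0], x[2] - x[1])
            vertex = float(np.clip(vertex, x[1] - half, x[1] + half))
            pi1_hat = 10.0 ** vertex

    _, r_pn, r_chi = _objective(observed, library.curves[(pi1s[j], best_lam)], min_bin)
    return PolygenicityFit(
        pi1_hat=float(pi1_hat),
        method="matching",
        lambda_grid=lams,
        objective_by_lambda=surface,
        best_lambda=float(best_lam),
        diagnostics={
            "pi1_grid": pi1s,
            "best_grid_pi1": pi1s[j],
            "residuals_prop_null": r_pn.tolist(),
            "residuals_chisq": r_chi.tolist(),
        },
    )


def _fit_offset_decay(ell: np.ndarray, y: np.ndarray, weights: np.ndarray | None):
    """Least-squares fit of y = a + (1 - a) * (1 - exp(-k * l))."""
    w = np.ones_like(ell) if weights is None else weights

    def resid(theta):
        a, k = theta
        return w * (a + (1.0 - a) * (1.0 - np.exp(-k * ell)) - y)

    best = None
    for x0 in ((0.0, 0.01), (0.01, 0.001), (0.05, 0.05), (0.0, 0.2)):
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=([0.0, 0.0], [0.5, 5.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("parametric fit failed from every start")
    return best


def calibrate_parametric_c(library: ReferenceLibrary, lam: float = 1.0) -> float:
    """Tagging exponent c from reference curves at known pi1.

    For each library pi1, fit the decay rate k of the non-null fraction and
    take c = k / (-log(1 - pi1)); the median over the grid is returned.  The
    exponent summarizes how many markers each causal variant lifts above
    the null, which is a property of the LD structure and sample size, not
    of pi1 itself.
    """
    cs = []
    for p in library.pi1_grid:
        if p <= 0:
            continue
        curve = library.curves[(p, lam)]
        u = curve.loc[curve["prop_null"].notna()]
        sol = _fit_offset_decay(
            u["mean_ld"].to_numpy(), 1.0 - u["prop_null"].to_numpy(), None
        )
        k = sol.x[1]
        if k > 1e-6:
            cs.append(k / (-np.log1p(-p)))
    if not cs:
        raise FitFailureError("no usable library curve for c calibration")
    return float(np.median(cs))


def estimate_pi1_from_assoc(
    assoc: pd.DataFrame,
    ldscores: pd.DataFrame,
    library: ReferenceLibrary,
    n_individuals: int,
    n_bins: int | None = None,
    maf_range: tuple[float, float] | None = None,
    lambda_grid=None,
    assume_lambda: float | None = None,
    n_boot: int = 30,
    seed: int = 0,
) -> PolygenicityFit:
    """Full matching pipeline from an association table.

    Estimates the inflation from the LD-score-regression intercept,
    deflates the statistics by it, and matches the deflated bin curves
    against the library's lambda = 1 column; ``best_lambda`` reports the
    grid value nearest the intercept.  With ``assume_lambda`` the intercept
    step is skipped and the statistics are taken as calibrated at that
    inflation (deflated by it before matching).
    """
    n_bins = n_bins if n_bins is not None else library.meta.get("n_bins", 1000)
    maf_range = tuple(maf_range if maf_range is not None else library.meta.get("maf_range", (0.0, 0.5)))
    lams = sorted(lambda_grid) if lambda_grid is not None else sorted(library.lambda_grid)
    if 1.0 not in library.lambda_grid:
        raise AlignmentError("library must contain lambda = 1 curves")
    if assume_lambda is not None:
        lam_hat = float(assume_lambda)
    else:
        _, intercept, _, _, _ = ldsc_regression(assoc, ldscores, n_individuals)
        lam_hat = float(intercept)
    deflated = deflate_assoc(assoc, max(lam_hat, 1e-6))
    bins = bin_and_summarize(
        deflated, ldscores, n_bins, maf_range, bootstrap_se=n_boot, seed=seed,
    )
    fit = estimate_pi1_matching(bins, library, lambda_fixed=1.0)
    fit.best_lambda = float(min(lams, key=lambda l: abs(l - lam_hat)))
    fit.lambda_grid = list(lams)
    fit.diagnostics["lambda_hat"] = lam_hat
    return fit


def estimate_pi1_parametric(
    observed: pd.DataFrame,
    lambda_assumed: float = 1.0,
    c_cal: float | None = None,
    min_bins: int = 20,
    min_bin: int = 10,
) -> PolygenicityFit:
    """Parametric fit of the non-null fraction as a function of LD score.

    The fitted model is 1 - prop_null(l) = a + (1 - a) * (1 - (1-pi1)^(c*l)),
    where the intercept ``a`` absorbs uniform test-statistic inflation —
    that offset is what makes this estimator robust to the assumed lambda.
    Only the product k = -c*log(1-pi1) is identified by the curve, so the
    exponent must be supplied: ``c_cal`` (typically from
    :func:`calibrate_parametric_c` on a reference library) or the raw
    tagged-fraction convention c = 1.  ``lambda_assumed`` is recorded in
    the metadata; sensitivity to it is checked by re-binning statistics
    deflated with :func:`deflate_assoc`.
    """
    usable = observed.loc[
        observed["prop_null"].notna() & (observed["n_variants"] >= min_bin)
    ]
    if len(usable) < min_bins:
        raise InsufficientDataError(f"need >= {min_bins} usable bins, have {len(usable)}")
    ell = usable["mean_ld"].to_numpy()
    y = 1.0 - usable["prop_null"].to_numpy()
    best = _fit_offset_decay(ell, y, None)
    a_hat, k_hat = best.x
    c = float(c_cal) if c_cal is not None else 1.0
    pi1_hat = 1.0 - np.exp(-k_hat / c)
    return PolygenicityFit(
        pi1_hat=float(pi1_hat),
        method="parametric",
        lambda_grid=[float(lambda_assumed)],
        objective_by_lambda={float(lambda_assumed): [float(2 * best.cost)]},
        best_lambda=float(lambda_assumed),
        diagnostics={
            "c": c,
            "k": float(k_hat),
            "offset": float(a_hat),
            "functional_form": (
                "1-prop_null = a + (1-a)*(1-(1-pi1)^(c*l)) "
                "[package construction; only c*(-log(1-pi1)) identified]"
            ),
            "n_bins_used": int(len(usable)),
        },
    )
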