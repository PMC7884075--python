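"""Experiment orchestration: config round-trips, the end-to-end synthetic
architecture report, and I/O round-trip validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import polygenicity
from .errors import PolyarchError
from .synthdata import ArchitectureSpec, make_ld_profile, simulate_summary_stats

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_architecture_report", "io_roundtrips"]


@dataclass
class ExperimentConfig:
    """Declarative description of a synthetic architecture experiment."""

    pi1_truth: list = field(default_factory=lambda: [0.003])
    pi1_grid: list = field(default_factory=lambda: [0.0001, 0.001, 0.003, 0.01, 0.03])
    lambda_grid: list = field(default_factory=lambda: [0.9, 1.0, 1.05, 1.1, 1.2])
    h2: float = 0.3
    effect_family: str = "normal"
    effect_df: float | None = None
    placement: str = "uniform"
    clumpy_alpha: float | None = None
    clumpy_rho: float | None = None
    n_individuals: int = 50_000
    n_variants: int = 100_000
    block_size: int = 100
    n_bins: int = 200
    maf_range: tuple = (0.0, 0.5)
    n_reps: int = 3
    n_boot: int = 50
    seed: int = 0
    out_dir: str = "scratch/report"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ExperimentConfig":
        d = json.loads(s)
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def spec_template(self) -> ArchitectureSpec:
        return ArchitectureSpec(
            pi1=0.0, h2=self.h2, effect_family=self.effect_family,
            df=self.effect_df, placement=self.placement,
            alpha=self.clumpy_alpha, rho=self.clumpy_rho,
        )


def run_architecture_report(config: ExperimentConfig, out_dir=None) -> dict:
    """Run synthdata -> binning -> ldsc -> pi1 estimation end to end.

    Emits ``report.json`` plus TSV tables in the output directory; every
    payload is stamped with the config hash and seed.  A stage failure is
    recorded in the report; earlier outputs are preserved.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
        "recovery": [],
    }
    try:
        profile = make_ld_profile(
            config.n_variants, block_size=config.block_size, seed=config.seed,
        )
        ldsc_table = profile.ldscore_table()
        report["stages"]["profile"] = "ok"
    except PolyarchError as exc:  # pragma: no cover - defensive
        report["stages"]["profile"] = f"failed: {exc}"
        _write_report(report, out)
        return report

    try:
        library = polygenicity.build_reference_curves(
            config.pi1_grid, config.lambda_grid, config.spec_template(),
            profile, config.n_individuals, config.n_variants,
            n_reps=config.n_reps, seed=config.seed + 1,
            n_bins=config.n_bins, maf_range=config.maf_range,
            cache_dir=out / "cache",
        )
        report["stages"]["library"] = "ok"
    except PolyarchError as exc:
        report["stages"]["library"] = f"failed: {exc}"
        _write_report(report, out)
        return report

    for t, pi1 in enumerate(config.pi1_truth):
        row = {"pi1_truth": float(pi1)}
        try:
            spec = config.spec_template().with_(pi1=float(pi1))
            assoc = simulate_summary_stats(
                spec, profile, config.n_individuals, config.n_variants,
                seed=config.seed + 1000 + t,
            )
            pio.write_assoc(assoc, out / f"assoc_truth{t}.glm.linear.tsv")
            slope, intercept, *_ , h2_imp = polygenicity.ldsc_regression(
                assoc, ldsc_table, config.n_individuals
            )
            row["ldsc_slope"] = slope
            row["ldsc_intercept"] = intercept
            row["ldsc_h2"] = h2_imp
            bins = polygenicity.bin_and_summarize(
                assoc, ldsc_table, config.n_bins, config.maf_range,
                bootstrap_se=config.n_boot, seed=config.seed + 2000 + t,
            )
            bins.to_csv(out / f"bins_truth{t}.tsv", sep="\t", index=False)
            fit = polygenicity.estimate_pi1_from_assoc(
                assoc, ldsc_table, library, config.n_individuals,
                n_bins=config.n_bins, maf_range=config.maf_range,
                lambda_grid=config.lambda_grid, n_boot=config.n_boot,
                seed=config.seed + 2000 + t,
            )
            row["pi1_hat"] = fit.pi1_hat
            row["best_lambda"] = fit.best_lambda
            par = polygenicity.estimate_pi1_parametric(bins, min_bins=min(20, config.n_bins))
            row["pi1_hat_parametric"] = par.pi1_hat
            report["stages"][f"trait{t}"] = "ok"
        except PolyarchError as exc:
            report["stages"][f"trait{t}"] = f"failed: {exc}"
        report["recovery"].append(row)

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if report["recovery"]:
        pd.DataFrame(report["recovery"]).to_csv(out / "recovery.tsv", sep="\t", index=False)


def io_roundtrips(paths: dict) -> dict:
    """read -> write -> read equality checks for the declared dialects.

    ``paths`` maps dialect name ('assoc', 'ldscore', 'bed', 'gmt') to a
    file path; returns a per-dialect {'ok': bool, 'detail': str} report.
    """
    import tempfile

    out = {}
    for kind, path in paths.items():
        try:
            if kind == "assoc":
                a = pio.read_assoc(path)
                with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
                    pio.write_assoc(a, fh.name)
                    b = pio.read_assoc(fh.name)
                ok = a.equals(b)
            elif kind == "ldscore":
                a = pio.read_ldscores(path)
                with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
                    pio.write_ldscores(a.rename(columns={"pos_bp": "pos_bp"}), fh.name)
                    b = pio.read_ldscores(fh.name)
                ok = np.allclose(a["ldscore"], b["ldscore"]) and (a["variant_id"] == b["variant_id"]).all()
            elif kind == "bed":
                a = pio.read_bed(path)
                with tempfile.NamedTemporaryFile("w", suffix=".bed", delete=False) as fh:
                    pio.write_bed(a, fh.name)
                    b = pio.read_bed(fh.name)
                ok = a.equals(b)
            elif kind == "gmt":
                a = pio.read_gmt(path)
                with tempfile.NamedTemporaryFile("w", suffix=".gmt", delete=False) as fh:
                    pio.write_gmt(a, fh.name)
                    b = pio.read_gmt(fh.name)
                ok = a == b
            else:
                out[kind] = {"ok": False, "detail": f"unknown dialect {kind!r}"}
                continue
            out[kind] = {"ok": bool(ok), "detail": "" if ok else "round-trip mismatch"}
        except Exception as exc:
            out[kind] = {"ok": False, "detail": str(exc)}
    return out
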