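"""Readers/writers for the plain-text dialects used across the package.

Dialects:

* association results — tab-separated with the plink2 ``.glm.linear``
  column set ``CHROM POS ID REF ALT A1_FREQ OBS_CT BETA SE T_STAT P``
  (an optional ``INFO`` column is carried through when present);
* LD scores — the ldsc ``.l2.ldscore`` column set ``CHR SNP BP L2``
  with an optional ``MAF`` column;
* genomic intervals — BED3(+name), 0-based half-open;
* gene sets — GMT (set name, description, member genes).
"""

from __future__ import annotations

import pandas as pd

from .errors import DialectError

ASSOC_COLUMNS = [
    "variant_id", "chrom", "pos_bp", "maf", "info",
    "n_obs", "beta", "se", "t_stat", "p",
]


def write_assoc(assoc: pd.DataFrame, path) -> None:
    """Write an association table in the plink2 ``.glm.linear`` dialect."""
    out = pd.DataFrame({
        "CHROM": assoc["chrom"],
        "POS": assoc["pos_bp"],
        "ID": assoc["variant_id"],
        "REF": assoc.get("ref", pd.Series(["A"] * len(assoc), index=assoc.index)),
        "ALT": assoc.get("alt", pd.Series(["G"] * len(assoc), index=assoc.index)),
        "A1_FREQ": assoc["maf"],
        "OBS_CT": assoc["n_obs"],
        "BETA": assoc["beta"],
        "SE": assoc["se"],
        "T_STAT": assoc["t_stat"],
        "P": assoc["p"],
    })
    if "info" in assoc.columns:
        out["INFO"] = assoc["info"]
    out.to_csv(path, sep="\t", index=False)


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"CHROM", "POS", "ID", "A1_FREQ", "OBS_CT", "BETA", "SE", "T_STAT", "P"}
    missing = required - set(df.columns)
    if missing:
        raise DialectError(f"association table missing columns: {sorted(missing)}")
    out = pd.DataFrame({
        "variant_id": df["ID"].astype(str),
        "chrom": df["CHROM"].astype(str),
        "pos_bp": df["POS"].astype(int),
        "maf": df["A1_FREQ"].astype(float).pipe(lambda s: s.where(s <= 0.5, 1.0 - s)),
        "n_obs": df["OBS_CT"].astype(int),
        "beta": df["BETA"].astype(float),
        "se": df["SE"].astype(float),
        "t_stat": df["T_STAT"].astype(float),
        "p": df["P"].astype(float),
    })
    if "INFO" in df.columns:
        out["info"] = df["INFO"].astype(float)
    if "REF" in df.columns:
        out["ref"] = df["REF"].astype(str)
        out["alt"] = df["ALT"].astype(str)
    return out


def write_ldscores(ldscores: pd.DataFrame, path) -> None:
    """Write LD scores in the ldsc ``.l2.ldscore`` column dialect."""
    out = pd.DataFrame({
        "CHR": ldscores.get("chrom", pd.Series(["1"] * len(ldscores), index=ldscores.index)),
        "SNP": ldscores["variant_id"],
        "BP": ldscores.get("pos_bp", pd.Series(range(1, len(ldscores) + 1), index=ldscores.index)),
        "L2": ldscores["ldscore"],
    })
    if "maf" in ldscores.columns:
        out["MAF"] = ldscores["maf"]
    out.to_csv(path, sep="\t", index=False)


def read_ldscores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"SNP", "L2"} - set(df.columns)
    if missing:
        raise DialectError(f"LD-score table missing columns: {sorted(missing)}")
    out = pd.DataFrame({
        "variant_id": df["SNP"].astype(str),
        "ldscore": df["L2"].astype(float),
    })
    if "CHR" in df.columns:
        out["chrom"] = df["CHR"].astype(str)
    if "BP" in df.columns:
        out["pos_bp"] = df["BP"].astype(int)
    if "MAF" in df.columns:
        out["maf"] = df["MAF"].astype(float)
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED3(+name); intervals are 0-based half-open."""
    cols = ["chrom", "start", "end"]
    if "name" in intervals.columns:
        cols.append("name")
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DialectError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise DialectError(
                    f"{path}:{lineno}: malformed interval start={start} >= end={end}"
                )
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                row["name"] = parts[3]
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]
                        if rows and "name" in rows[0] else ["chrom", "start", "end"])


def write_gmt(gene_sets: dict, path) -> None:
    """Write gene sets as GMT: name <tab> description <tab> genes..."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path) -> dict:
    """Read GMT.  Duplicate genes within a set are dropped (first kept)."""
    import warnings

    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DialectError(f"{path}:{lineno}: GMT line needs name and description")
            name, genes = parts[0], parts[2:]
            seen: dict[str, None] = {}
            dups = 0
            for g in genes:
                if g in seen:
                    dups += 1
                else:
                    seen[g] = None
            if dups:
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} had {dups} duplicate gene(s); deduplicated"
                )
            sets[name] = list(seen)
    return sets


def read_keyed_table(path, key: str = "IID") -> pd.DataFrame:
    """Read a headered TSV keyed by sample id (phenotypes / covariates)."""
    df = pd.read_csv(path, sep="\t")
    if key not in df.columns:
        raise DialectError(f"{path}: missing key column {key!r}")
    return df.set_index(key)
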