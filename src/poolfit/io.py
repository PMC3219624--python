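"""Tab-delimited I/O with schema validation.

All tables are TSV with a header row, UTF-8, "." decimal separator and "-"
for missing values. Leading lines starting with '#' are provenance stamps
(config hash and seed) and are skipped on read. Coordinates are 1-based
inclusive; gene_fraction is strand-aware (0 at the start codon).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    EXPERIMENT_COLUMNS,
    GENE_COLUMNS,
    INTENSITY_COLUMNS,
    STRAIN_COLUMNS,
    Genome,
    IntensityTable,
)
from .util import ValidationError

MISSING = "-"

_SCHEMAS = {
    "genes": GENE_COLUMNS,
    "strains": STRAIN_COLUMNS,
    "experiments": EXPERIMENT_COLUMNS,
    "intensities": INTENSITY_COLUMNS,
    "truth": ["gene_id", "condition_name", "true_fitness"],
}


def _stamp(path: Path, lines: list[str]) -> None:
    if lines:
        text = path.read_text()
        path.write_text("".join(f"# {ln}\n" for ln in lines) + text)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    float_format: str = "%.6g",
    index: bool = False,
    stamp: list[str] | None = None,
) -> Path:
    """Write a TSV with '-' for missing values and an optional '#' stamp."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=MISSING, float_format=float_format, index=index)
    _stamp(path, stamp or [])
    return path


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV written by this package; validates the header if a schema
    name is given.

    The '-' missing marker is converted to NaN only in numeric columns;
    in text columns (strand, gene_id of intergenic strains, subrole) it is
    a meaningful value and is kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                     comment="#")
    for col in df.columns:
        if df[col].dtype != object:
            continue
        s = df[col].mask(df[col] == MISSING)
        observed = s.dropna()
        num = pd.to_numeric(s, errors="coerce")
        if len(observed) and num.notna().equals(s.notna()):
            df[col] = num
        elif len(observed) and set(observed.unique()) <= {"True", "False"}:
            df[col] = s.map({"True": True, "False": False})
    if schema is not None:
        expected = _SCHEMAS[schema]
        got = list(df.columns)[: len(expected)]
        if got != expected:
            raise ValidationError(
                f"{path.name}: header mismatch; expected {expected}, got {got}")
    return df


def config_hash(items: dict) -> str:
    payload = ";".join(f"{k}={items[k]}" for k in sorted(items))
    return hashlib.md5(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# dataset-level validation
# ---------------------------------------------------------------------------

def _fail(table: str, row: int, message: str) -> None:
    raise ValidationError(f"{table}.tsv row {row}: {message}")


def validate_genes(genes: pd.DataFrame) -> None:
    for i, row in enumerate(genes.itertuples(index=False), start=2):
        if row.start > row.end:
            _fail("genes", i, f"start {row.start} > end {row.end}")
        if row.replicon not in ("chromosome", "megaplasmid"):
            _fail("genes", i, f"unknown replicon {row.replicon!r}")
        if row.strand not in ("+", "-"):
            _fail("genes", i, f"unknown strand {row.strand!r}")
    dup = genes["gene_id"][genes["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"genes.tsv: duplicate gene_id {dup.iloc[0]!r}")


def validate_strains(strains: pd.DataFrame, genes: pd.DataFrame) -> None:
    known = set(genes["gene_id"])
    frac = strains["gene_fraction"].to_numpy(dtype=float)
    for i, (gid, fr, pool) in enumerate(
            zip(strains["gene_id"], frac, strains["pool"]), start=2):
        if isinstance(gid, str) and gid != MISSING and gid not in known:
            _fail("strains", i, f"gene_id {gid!r} not in genes table")
        if np.isfinite(fr) and not 0 <= fr <= 1:
            _fail("strains", i, f"gene_fraction {fr} outside [0, 1]")
        if pool not in ("up", "dn"):
            _fail("strains", i, f"unknown pool {pool!r}")


def validate_experiments(experiments: pd.DataFrame) -> None:
    for i, cls in enumerate(experiments["class"], start=2):
        if cls not in ("start", "control", "condition"):
            _fail("experiments", i, f"unknown class {cls!r}")
    dup = experiments["experiment_id"][experiments["experiment_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"experiments.tsv: duplicate experiment_id {dup.iloc[0]!r}")


def validate_intensities(intensities: pd.DataFrame,
                         experiments: pd.DataFrame) -> None:
    known = set(experiments["experiment_id"])
    bad = intensities.loc[~intensities["experiment_id"].isin(known)]
    if len(bad):
        _fail("intensities", int(bad.index[0]) + 2,
              f"experiment_id {bad['experiment_id'].iloc[0]!r} not in experiments table")


def validate_dataset(
    genes: pd.DataFrame,
    strains: pd.DataFrame,
    experiments: pd.DataFrame,
    intensities: pd.DataFrame | None = None,
) -> None:
    """Referential-integrity and range checks across the input tables."""
    validate_genes(genes)
    validate_strains(strains, genes)
    validate_experiments(experiments)
    if intensities is not None:
        validate_intensities(intensities, experiments)


# ---------------------------------------------------------------------------
# typed readers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    genes = read_table(path, schema="genes")
    validate_genes(genes)
    genes["subrole"] = genes["subrole"].fillna(MISSING)
    genes["hypothetical"] = genes["hypothetical"].astype(bool)
    return Genome(genes)


def read_strains(path: str | Path, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    strains = read_table(path, schema="strains")
    strains["gene_id"] = strains["gene_id"].fillna(MISSING)
    if genes is not None:
        validate_strains(strains, genes)
    return strains


def read_experiments(path: str | Path) -> pd.DataFrame:
    exps = read_table(path, schema="experiments")
    validate_experiments(exps)
    exps["condition_name"] = exps["condition_name"].fillna(MISSING)
    return exps


def read_intensities(path: str | Path,
                     experiments: pd.DataFrame | None = None) -> pd.DataFrame:
    df = read_table(path, schema="intensities")
    if experiments is not None:
        validate_intensities(df, experiments)
    return df


def read_intensity_table(int_path: str | Path, exp_path: str | Path) -> IntensityTable:
    experiments = read_experiments(exp_path)
    intensities = read_intensities(int_path, experiments)
    return IntensityTable(intensities=intensities, experiments=experiments)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read truth.tsv back into a gene-by-condition matrix."""
    long = read_table(path, schema="truth")
    return long.pivot(index="gene_id", columns="condition_name",
                      values="true_fitness")


def read_matrix(path: str | Path, index_cols: list[str] | None = None) -> pd.DataFrame:
    """Read a wide matrix table (gene or strain rows x experiment columns)."""
    df = read_table(path)
    index_cols = index_cols or [df.columns[0]]
    return df.set_index(index_cols)


# ---------------------------------------------------------------------------
# typed writers
# ---------------------------------------------------------------------------

def write_genes(genome: Genome, path: str | Path, stamp: list[str] | None = None) -> Path:
    return write_table(genome.genes[GENE_COLUMNS], path, stamp=stamp)


def write_strains(strains: pd.DataFrame, path: str | Path,
                  stamp: list[str] | None = None) -> Path:
    return write_table(strains[STRAIN_COLUMNS], path, stamp=stamp)


def write_experiments(experiments: pd.DataFrame, path: str | Path,
                      stamp: list[str] | None = None) -> Path:
    return write_table(experiments[EXPERIMENT_COLUMNS], path, stamp=stamp)


def write_intensities(intensities: pd.DataFrame, path: str | Path,
                      stamp: list[str] | None = None) -> Path:
    return write_table(intensities[INTENSITY_COLUMNS], path,
                       float_format="%.4f", stamp=stamp)


def write_truth(truth_matrix: pd.DataFrame, path: str | Path,
                stamp: list[str] | None = None) -> Path:
    long = truth_matrix.stack().rename("true_fitness").reset_index()
    long.columns = ["gene_id", "condition_name", "true_fitness"]
    return write_table(long, path, stamp=stamp)


def write_matrix(matrix: pd.DataFrame, path: str | Path, float_format: str = "%.5f",
                 stamp: list[str] | None = None) -> Path:
    """Write a wide matrix with its (possibly multi-level) index as columns."""
    return write_table(matrix.reset_index(), path, float_format=float_format,
                       stamp=stamp)
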