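"""Tab-separated readers/writers for every pipeline artifact, plus packaged
reference tables (the published per-environment trait summaries and
significant-pair counts).

All files are UTF-8 TSV with a header row, ``.`` decimal separator and the
literal ``NA`` for missing.  Readers reject malformed input rather than
coercing it; every writer produces files its paired reader round-trips
exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .simdata import VALID_CODES, LinkageMap, PhenotypeSet, RILPopulation

__all__ = [
    "FormatError",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_results",
    "write_results",
    "canonical_pair",
    "load_table1_fixture",
    "load_table2_fixture",
]

SCAN_COLUMNS = ["env_id", "marker_a", "marker_b", "chi_square", "p_value", "cv_mean_chi_square"]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


def canonical_pair(a: str, b: str, index: dict[str, int] | None = None) -> tuple[str, str]:
    """Canonical storage order for an unordered marker pair.

    With a marker -> column-index mapping the pair is ordered by map
    position, otherwise lexicographically; either way the key of (a, b)
    equals the key of (b, a).
    """
    if a == b:
        raise ValueError("a pair must consist of two distinct markers")
    if index is not None:
        return (a, b) if index[a] < index[b] else (b, a)
    return (a, b) if a < b else (b, a)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# genetic map

def read_map(path: str | Path) -> LinkageMap:
    df = _read_tsv(path, dtype={"marker_id": str})
    required = {"marker_id", "linkage_group", "position_cm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: map file needs columns {sorted(required)}")
    return LinkageMap(
        tuple(df["marker_id"]),
        df["linkage_group"].to_numpy(dtype=np.int64),
        df["position_cm"].to_numpy(dtype=np.float64),
    )


def write_map(linkage_map: LinkageMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker_id": linkage_map.marker_ids,
            "linkage_group": linkage_map.groups,
            "position_cm": linkage_map.positions,
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path) -> RILPopulation:
    """Read a lines x markers genotype table (first column ``line_id``)."""
    df = _read_tsv(path, dtype={"line_id": str})
    if df.columns[0] != "line_id":
        raise FormatError(f"{path}: first column must be 'line_id'")
    if df["line_id"].duplicated().any():
        dup = df.loc[df["line_id"].duplicated(), "line_id"].iloc[0]
        raise FormatError(f"{path}: duplicate line id {dup!r}")
    markers = tuple(df.columns[1:])
    if not markers:
        raise FormatError(f"{path}: no marker columns")
    body = df.iloc[:, 1:]
    try:
        geno = body.to_numpy(dtype=np.int64)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: non-integer genotype code present") from None
    bad = ~np.isin(geno, VALID_CODES)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype code {geno[r, c]} at line "
            f"{df['line_id'].iloc[r]!r}, marker {markers[c]!r}"
        )
    return RILPopulation(tuple(df["line_id"]), markers, geno.astype(np.int8))


def write_genotypes(pop: RILPopulation, path: str | Path) -> None:
    df = pd.DataFrame(pop.genotypes, columns=list(pop.marker_ids))
    df.insert(0, "line_id", list(pop.line_ids))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path: str | Path, env_id: str | None = None) -> PhenotypeSet:
    """Read a per-environment ``line_id<TAB>value`` table.

    The environment id defaults to the file stem, stripped of a leading
    ``pheno_`` prefix (so ``pheno_2006HRB.tsv`` -> ``2006HRB``).
    """
    path = Path(path)
    if env_id is None:
        env_id = path.stem.removeprefix("pheno_")
    df = _read_tsv(path, dtype={"line_id": str})
    if list(df.columns[:2]) != ["line_id", "value"]:
        raise FormatError(f"{path}: phenotype file needs columns line_id, value")
    if df["line_id"].duplicated().any():
        dup = df.loc[df["line_id"].duplicated(), "line_id"].iloc[0]
        raise FormatError(f"{path}: duplicate line id {dup!r}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        row = df.loc[values.isna()].iloc[0]
        raise FormatError(
            f"{path}: non-numeric value {row['value']!r} for line {row['line_id']!r}"
        )
    return PhenotypeSet(env_id, dict(zip(df["line_id"], values.astype(float))))


def write_phenotypes(pheno: PhenotypeSet, path: str | Path) -> None:
    pd.DataFrame(
        {"line_id": list(pheno.values), "value": list(pheno.values.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scan results and reports

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV, rendering missing values as ``NA``."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, na_values=["NA"], keep_default_na=False)
    if {"env_id", "marker_a", "marker_b"}.issubset(df.columns):
        if df.duplicated(subset=["env_id", "marker_a", "marker_b"]).any():
            raise FormatError(f"{path}: duplicate (environment, pair) rows")
    return df


# ---------------------------------------------------------------------------
# packaged reference tables

def _fixture(name: str):
    return resources.files("episcan.data").joinpath(name)


def load_table1_fixture() -> pd.DataFrame:
    """Published per-environment oil-content summaries for the 147-line RIL
    population: parent means and population mean/min/max/SD/kurtosis/skewness
    for each of the 23 year x location environments."""
    with resources.as_file(_fixture("table1_environments.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"env_id": str})


def load_table2_fixture() -> dict[str, int | None]:
    """Published count of Bonferroni-significant interaction pairs per
    environment; ``None`` marks environments without any significant pair."""
    with resources.as_file(_fixture("table2_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"env_id": str}, na_values=["NA"], keep_default_na=False)
    return {
        row.env_id: (None if pd.isna(row.n_pairs) else int(row.n_pairs))
        for row in df.itertuples()
    }
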