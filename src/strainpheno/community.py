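"""Family-level abundance vs condition correlations for fecal fermentations.

Samples are donor x condition cultures; taxa are collapsed to bacterial
families and each family's relative abundance is correlated (Pearson)
against the numeric condition value (pH, or osmolality in mOsm/kg),
pooling all donors.  Families absent from a sample contribute genuine
zeros — sparsity across donors is part of the signal, not masked.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

META_COLUMNS = ["sample", "donor", "condition_type", "condition_value"]


@dataclass
class AbundanceTable:
    """Samples x taxa abundances with per-sample condition metadata.

    ``abundance`` is indexed by sample id with one column per taxon;
    ``meta`` carries donor, condition_type and numeric condition_value per
    sample, aligned on the same index.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.abundance.index)
            if self.meta.isna().any().any():
                raise ValueError("metadata missing for some samples")


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions: each row divided by its sum.

    Values must be non-negative and every sample must contain something;
    an all-zero sample is an error naming the sample.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance values must be non-negative")
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = list(counts.index[zero])
        raise ValueError(f"all-zero sample(s): {bad}")
    return counts.div(counts.sum(axis=1), axis=0)


_RANK_PREFIX = re.compile(r"^[a-z]__")


def parse_family(lineage: str) -> str:
    """Family from a lineage string; tolerant of 'f__Family' rank prefixes.

    Accepts either a bare family name or a semicolon-joined lineage with
    greengenes/SILVA-style rank prefixes; empty or absent family maps to
    "Unassigned".
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return "Unassigned"
    text = str(lineage).strip()
    if not text:
        return "Unassigned"
    if ";" in text or _RANK_PREFIX.match(text):
        for part in text.split(";"):
            part = part.strip()
            if part.startswith("f__"):
                name = part[3:].strip()
                return name if name else "Unassigned"
        return "Unassigned"
    return text


def aggregate_to_family(
    proportions: pd.DataFrame, lineage: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Sum member taxa into family columns per sample.

    ``lineage`` maps taxon -> family (or a rank-prefixed lineage string);
    taxa without a family pool under "Unassigned".  Aggregation conserves
    each sample's total.
    """
    if isinstance(lineage, pd.Series):
        lineage = lineage.to_dict()
    families = {
        taxon: parse_family(lineage.get(taxon)) for taxon in proportions.columns
    }
    out = proportions.T.groupby(
        proportions.columns.map(families)
    ).sum().T
    out = out[sorted(out.columns)]
    return out


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one family's abundance with one axis."""

    family: str
    axis: str
    r: float
    n: int
    defined: bool


def correlate_families(
    family_proportions: pd.DataFrame,
    condition_values: pd.Series | np.ndarray,
    axis: str = "",
) -> pd.DataFrame:
    """Per-family Pearson r against a numeric condition axis.

    Pools every provided sample (all donors); a family whose abundance has
    zero variance — or a constant axis — yields ``defined=False`` with
    NaN r instead of an exception.  Requires >= 3 samples.
    """
    cond = np.asarray(condition_values, dtype=float)
    n = len(family_proportions)
    if cond.size != n:
        raise ValueError("condition values must align with samples")
    if n < 3:
        raise ValueError("need at least 3 samples to correlate")
    cond_constant = np.ptp(cond) == 0
    rows = []
    for family in family_proportions.columns:
        y = family_proportions[family].to_numpy(dtype=float)
        if cond_constant or np.ptp(y) == 0:
            rows.append((family, axis, np.nan, n, False))
            continue
        r = float(pearsonr(cond, y).statistic)
        rows.append((family, axis, r, n, True))
    out = pd.DataFrame(rows, columns=["family", "axis", "r", "n", "defined"])
    return out.sort_values("r", na_position="last", kind="stable").reset_index(drop=True)


def correlate_families_by_donor(
    table: AbundanceTable, axis: str
) -> pd.DataFrame:
    """Diagnostic per-donor breakdown of the pooled correlations."""
    mask = table.meta["condition_type"] == axis
    rows = []
    for donor, idx in table.meta.loc[mask].groupby("donor").groups.items():
        sub = table.abundance.loc[idx]
        cond = table.meta.loc[idx, "condition_value"]
        if len(sub) < 3:
            continue
        res = correlate_families(sub, cond, axis=axis)
        res.insert(0, "donor", donor)
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=["donor", "family", "axis", "r", "n", "defined"])
    return pd.concat(rows, ignore_index=True)


def correlate_table(table: AbundanceTable, axis: str) -> pd.DataFrame:
    """Pooled family correlations for one condition axis of a table."""
    mask = table.meta["condition_type"] == axis
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 samples with condition_type={axis!r}")
    return correlate_families(
        table.abundance.loc[mask],
        table.meta.loc[mask, "condition_value"],
        axis=axis,
    )


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_abundance_tsv(abundance: pd.DataFrame, path: str | Path) -> None:
    out = abundance.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_sample_meta_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return df.set_index("sample")


def write_sample_meta_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_lineage_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    if not {"taxon", "lineage"}.issubset(df.columns):
        raise ValueError("lineage TSV needs columns taxon, lineage")
    return df.set_index("taxon")["lineage"]
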