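"""Genome featurization from PATRIC-style subsystem annotations.

PATRIC's subsystems export maps each genome name to many PATRIC IDs, each
annotated with a Superclass, Class, Subclass, Subsystem Name, and Role ID.
Featurization counts, per genome and per annotation column, how many rows
carry each observed value: a genome with exactly seven rows whose
Subsystem is "DNA repair, bacterial" gets value 7 in the feature column
"Subsystem Name = DNA repair, bacterial".  Taxonomy contributes binary
indicator features per observed value of Phylum ... Species.  Counts are
over table rows (a PATRIC ID contributing two role rows counts twice for
its subsystem); values are matched verbatim after trimming outer
whitespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# file column -> printed feature-name prefix
ANNOTATION_COLUMNS = {
    "superclass": "Superclass",
    "class": "Class",
    "subclass": "Subclass",
    "subsystem_name": "Subsystem Name",
    "role_id": "Role ID",
}

TAXONOMY_RANKS = {
    "phylum": "Phylum",
    "class": "Class",
    "order": "Order",
    "family": "Family",
    "genus": "Genus",
    "species": "Species",
}


def _clean(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip()


def featurize_annotations(records: pd.DataFrame) -> pd.DataFrame:
    """Count-featurize an annotation table into genomes x named features.

    For each of the five annotation columns, one feature per observed
    non-empty value, valued as the number of records for that genome
    carrying the value; genomes with no such record get 0.  Column order
    is sorted for determinism; the result is a pure function of the
    multiset of records.
    """
    if "genome_name" not in records.columns:
        raise ValueError("annotation table needs a genome_name column")
    names = _clean(records["genome_name"])
    if (names == "").any():
        raise ValueError("empty genome_name in annotation table")
    genomes = sorted(names.unique())
    frames = []
    for col, label in ANNOTATION_COLUMNS.items():
        if col not in records.columns:
            continue
        values = _clean(records[col])
        keep = values != ""
        if not keep.any():
            continue
        counts = (
            pd.DataFrame({"genome_name": names[keep], "value": values[keep]})
            .groupby(["genome_name", "value"])
            .size()
            .unstack(fill_value=0)
        )
        counts.columns = [f"{label} = {v}" for v in counts.columns]
        frames.append(counts)
    if frames:
        table = pd.concat(frames, axis=1).reindex(genomes).fillna(0).astype(int)
    else:
        table = pd.DataFrame(index=pd.Index(genomes))
    table = table[sorted(table.columns)]
    table.index.name = "genome_name"
    return table


def taxonomy_indicators(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Binary indicator features for each observed value of each rank.

    One record per genome; a missing rank value leaves all of that rank's
    indicators 0 for the genome, with a warning.
    """
    if "genome_name" not in taxonomy.columns:
        raise ValueError("taxonomy table needs a genome_name column")
    names = _clean(taxonomy["genome_name"])
    if names.duplicated().any():
        raise ValueError("taxonomy must have one record per genome")
    genomes = sorted(names)
    frames = []
    for col, label in TAXONOMY_RANKS.items():
        if col not in taxonomy.columns:
            continue
        values = _clean(taxonomy[col])
        missing = values == ""
        if missing.any():
            warnings.warn(
                f"{int(missing.sum())} genome(s) missing {label}; their "
                f"{label} indicators are all 0",
                stacklevel=2,
            )
        keep = ~missing
        if not keep.any():
            continue
        ind = pd.crosstab(names[keep], values[keep]).clip(upper=1)
        ind.columns = [f"{label} = {v}" for v in ind.columns]
        frames.append(ind)
    if frames:
        table = pd.concat(frames, axis=1).reindex(genomes).fillna(0).astype(int)
    else:
        table = pd.DataFrame(index=pd.Index(genomes))
    table = table[sorted(table.columns)]
    table.index.name = "genome_name"
    return table


def build_feature_table(
    annotations: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate count and indicator features over the union of genomes.

    Accepts raw record tables; genomes present in only one input are kept
    with zeros for the other block (annotation-only genomes warn, since
    their taxonomy indicators are all absent).
    """
    counts = featurize_annotations(annotations)
    indicators = taxonomy_indicators(taxonomy)
    overlap = set(counts.columns) & set(indicators.columns)
    if overlap:
        raise ValueError(f"feature name collision between blocks: {sorted(overlap)}")
    missing_tax = set(counts.index) - set(indicators.index)
    if missing_tax:
        warnings.warn(
            f"{len(missing_tax)} genome(s) have annotations but no taxonomy "
            "record; their indicators are all 0",
            stacklevel=2,
        )
    genomes = sorted(set(counts.index) | set(indicators.index))
    table = pd.concat(
        [counts.reindex(genomes), indicators.reindex(genomes)], axis=1
    ).fillna(0).astype(int)
    table = table[sorted(table.columns)]
    table.index.name = "genome_name"
    return table


@dataclass
class ModelDataset:
    """Feature table joined to one perturbation axis's phenotype outputs.

    ``outputs`` holds the four normalized max-OD values (one column per
    condition level of the axis) for every genome retained after listwise
    removal; ``excluded`` records dropped genomes with reasons.
    """

    features: pd.DataFrame
    outputs: pd.DataFrame
    axis: str = ""
    excluded: list[tuple[str, str]] = field(default_factory=list)


def join_phenotypes(
    features: pd.DataFrame, outputs: pd.DataFrame, axis: str = ""
) -> ModelDataset:
    """Listwise-join genomes to their phenotype outputs for one axis.

    Genomes missing from the outputs, or with any missing output value,
    are removed and listed with reasons; an empty result is a hard error.
    Outputs are normalized max ODs and must lie in [0, 1].
    """
    excluded: list[tuple[str, str]] = []
    kept = []
    for genome in features.index:
        if genome not in outputs.index:
            excluded.append((genome, "no phenotype record"))
            continue
        row = outputs.loc[genome]
        if row.isna().any():
            bad = ", ".join(str(c) for c in row.index[row.isna()])
            excluded.append((genome, f"missing output(s): {bad}"))
            continue
        kept.append(genome)
    if not kept:
        raise ValueError("no genome has a complete set of outputs")
    y = outputs.loc[kept].astype(float)
    if ((y.to_numpy() < -1e-9) | (y.to_numpy() > 1 + 1e-9)).any():
        raise ValueError("outputs must be normalized to [0, 1]")
    return ModelDataset(
        features=features.loc[kept],
        outputs=y.clip(0.0, 1.0),
        axis=axis,
        excluded=excluded,
    )


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    required = {"genome_name"} | set(ANNOTATION_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    return df


def write_annotations_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_filter=False)


def write_taxonomy_tsv(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t", index=False)


def read_feature_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_name")


def write_feature_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
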