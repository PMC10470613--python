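"""End-to-end synthetic study: simulate -> growth -> pH -> rank -> correlate.

One callable per stage, each writing plain-text tables into an output
directory, plus a driver that chains them.  The defaults reproduce the
study design at reduced scale: a characterization plate of strains in
quadruplicate across the eight pH/osmolality conditions, an annotated
genome collection with planted stress-tolerance features, and six-donor
fecal fermentations across the osmolality gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import features as feat
from . import growth as gr
from . import ph as phmod
from . import plates, stumps, synth

# reduced-scale defaults for the worked study
N_STRAINS = 6
RUN_HOURS = 24.0

# planted genotype-phenotype signal: osmotic-stress annotations raise the
# normalized max OD at the two highest osmolalities for carrier strains
PLANTED = (
    synth.PlantedFeature(
        "Osmotic stress cluster", 0.5, (0.0, 0.0, 0.15, 0.15)
    ),
    synth.PlantedFeature(
        "Choline uptake and conversion to betaine", 0.35, (0.0, 0.0, 0.0, 0.12)
    ),
)

# fermentation families: tolerant families rise along the osmolality
# gradient, sensitive ones fall (slopes in abundance units per mOsm/kg)
FERMENTATION_FAMILIES = (
    synth.FamilySpec("Enterococcaceae", 0.08, 1.5e-4),
    synth.FamilySpec("Enterobacteriaceae", 0.10, 0.8e-4),
    synth.FamilySpec("Lachnospiraceae", 0.35, -1.6e-4),
    synth.FamilySpec("Bacteroidaceae", 0.30, -1.2e-4),
    synth.FamilySpec("Bifidobacteriaceae", 0.12, -0.3e-4),
    synth.FamilySpec("Lactobacillaceae", 0.05, 0.4e-4),
)


def _strain_truth(seed: int, n_strains: int = N_STRAINS) -> pd.DataFrame:
    """Ground-truth growth parameters per strain x condition.

    Each strain gets a random baseline vigor and a tolerance profile:
    growth declines away from its preferred pH and above its osmolality
    ceiling, mirroring the spread of responses across families.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    rows = []
    conditions = [("pH", v) for v in synth.PH_CONDITIONS] + [
        ("osmolality", v) for v in synth.OSMOLALITY_CONDITIONS
    ]
    for s in range(n_strains):
        strain = f"S{s + 1:02d}"
        a_best = rng.uniform(0.5, 1.2)
        mu_best = rng.uniform(0.15, 0.6)
        ph_opt = rng.uniform(5.5, 7.5)
        ph_width = rng.uniform(1.0, 3.0)
        osm_ceiling = rng.uniform(500.0, 2000.0)
        for ctype, cval in conditions:
            if ctype == "pH":
                factor = float(np.exp(-((cval - ph_opt) / ph_width) ** 2))
            else:
                factor = float(1.0 / (1.0 + np.exp((cval - osm_ceiling) / 150.0)))
            a = a_best * factor
            grows = a >= 0.08
            rows.append(
                (strain, ctype, cval,
                 a if grows else 0.0,
                 mu_best * factor if grows else 0.0,
                 rng.uniform(1.0, 6.0))
            )
    return pd.DataFrame(
        rows, columns=["strain", "condition_type", "condition_value",
                       "A", "mu_max", "lag"]
    )


def simulate_study_plate(
    out_dir: str | Path,
    seed: int,
    n_strains: int = N_STRAINS,
    hours: float = RUN_HOURS,
    od_noise_sd: float = synth.DEFAULT_OD_NOISE_SD,
) -> dict[str, Path]:
    """Write plate.csv, layout.csv, calibration.csv and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = _strain_truth(seed, n_strains)
    t_grid = synth.default_time_grid(hours)
    wells: list[synth.WellSpec] = []
    for i, row in enumerate(truth.itertuples(index=False)):
        gspec = synth.GrowthSimSpec(
            y0=synth.BLANK_OD + 0.01,
            A=row.A if row.A > 0 else 0.0,
            mu_max=row.mu_max,
            lag=row.lag,
            noise_sd=od_noise_sd,
            t_grid=t_grid,
            seed=seed + i,
        )
        ph0 = row.condition_value if row.condition_type == "pH" else 6.9
        wells.extend(
            synth.quadruplicate_wells(
                row.strain, row.condition_type, row.condition_value, gspec,
                well_prefix=f"W{i:03d}R", ph_trajectory=float(ph0),
            )
        )
    for ci, (ctype, cval) in enumerate(
        [("pH", v) for v in synth.PH_CONDITIONS]
        + [("osmolality", v) for v in synth.OSMOLALITY_CONDITIONS]
    ):
        meta = plates.WellMeta(
            well=f"CTRL{ci}", strain="sterile", condition_type=ctype,
            condition_value=cval, replicate=1, sterile=True,
        )
        wells.append(synth.WellSpec(meta=meta))
    run = synth.simulate_plate_run(
        wells, t_grid=t_grid, calibration=synth.DEFAULT_CALIBRATION, seed=seed,
        od_noise_sd=od_noise_sd,
    )
    paths = {
        "plate": out / "plate.csv",
        "layout": out / "layout.csv",
        "calibration": out / "calibration.csv",
        "truth": out / "growth_truth.tsv",
    }
    plates.write_plate_csv(run, paths["plate"])
    plates.write_layout_csv(run.wells, paths["layout"])
    phmod.write_calibration_csv(synth.DEFAULT_CALIBRATION, paths["calibration"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def quantify_growth(plate: Path, layout: Path, out_dir: str | Path) -> dict[str, Path]:
    """Parse, QC, fit and normalize; write metrics + QC tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = plates.parse_plate_run(plate, layout)
    metrics, qc = gr.analyze_run(run)
    normalized = gr.normalize_metrics(metrics)
    paths = {
        "metrics": out / "growth_metrics.tsv",
        "normalized": out / "growth_metrics_normalized.tsv",
        "qc": out / "qc_report.tsv",
    }
    metrics.round(9).to_csv(paths["metrics"], sep="\t", index=False)
    normalized.round(9).to_csv(paths["normalized"], sep="\t", index=False)
    qc.to_csv(paths["qc"], sep="\t", index=False)
    return paths


def infer_ph(plate: Path, layout: Path, calibration: Path,
             out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = plates.parse_plate_run(plate, layout)
    curve = phmod.read_calibration_csv(calibration)
    trajectories = phmod.infer_plate_ph(run, curve)
    path = out / "ph_trajectories.tsv"
    trajectories.round(9).to_csv(path, sep="\t", index=False)
    return path


def rank_genotype_features(
    out_dir: str | Path,
    seed: int,
    n_genomes: int = 80,
    n_noise_features: int = 500,
    noise_sd: float = 0.05,
) -> dict[str, Path]:
    """Simulate genomes, featurize, rank by worst train/test stump rank."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synth.GenotypeSimSpec(
        n_genomes=n_genomes, n_noise_features=n_noise_features,
        planted_features=PLANTED, noise_sd=noise_sd, seed=seed,
    )
    ann, tax, phen = synth.simulate_genotype_phenotype(spec)
    table = feat.build_feature_table(ann, tax)
    dataset = feat.join_phenotypes(table, phen, axis="osmolality")
    ranking = stumps.rank_dataset(dataset.features, dataset.outputs, k=5, seed=seed)
    top = ranking.index[0]
    part = stumps.partition_strains(
        dataset.features, dataset.outputs, top,
        float(ranking.loc[top, "mean_threshold"]),
    )
    paths = {
        "annotations": out / "annotations.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "ranking": out / "feature_ranking.tsv",
        "partition": out / "top_feature_partition.tsv",
    }
    feat.write_annotations_tsv(ann, paths["annotations"])
    feat.write_taxonomy_tsv(tax, paths["taxonomy"])
    phen.round(9).to_csv(paths["phenotypes"], sep="\t")
    ranking.round(9).to_csv(paths["ranking"], sep="\t")
    part.summaries.round(9).to_csv(paths["partition"], sep="\t", index=False)
    return paths


def correlate_communities(
    out_dir: str | Path, seed: int, dispersion: float = 0.35
) -> dict[str, Path]:
    """Six-donor fermentations along the osmolality gradient -> family r."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synth.CommunitySimSpec(
        donors=synth.N_DONORS,
        condition_values=synth.FERMENTATION_OSMOLALITIES,
        condition_type="osmolality",
        families=FERMENTATION_FAMILIES,
        dispersion=dispersion,
        seed=seed,
    )
    table = synth.simulate_community_series(spec)
    pooled = comm.correlate_table(table, "osmolality")
    per_donor = comm.correlate_families_by_donor(table, "osmolality")
    paths = {
        "abundance": out / "abundance.tsv",
        "samples": out / "samples.tsv",
        "correlations": out / "family_correlations.tsv",
        "by_donor": out / "family_correlations_by_donor.tsv",
    }
    table.abundance.round(12).to_csv(paths["abundance"], sep="\t")
    comm.write_sample_meta_tsv(table.meta, paths["samples"])
    pooled.round(9).to_csv(paths["correlations"], sep="\t", index=False)
    per_donor.round(9).to_csv(paths["by_donor"], sep="\t", index=False)
    return paths


@dataclass
class StudyResult:
    """Paths of every table the end-to-end synthetic study wrote."""

    paths: dict[str, Path]


def run_study(out_dir: str | Path, seed: int = 1,
              n_strains: int = N_STRAINS) -> StudyResult:
    """The full chain on one seed; every byte written is seed-determined."""
    out = Path(out_dir)
    sim = simulate_study_plate(out / "sim", seed, n_strains=n_strains)
    growth_paths = quantify_growth(sim["plate"], sim["layout"], out / "growth")
    ph_path = infer_ph(sim["plate"], sim["layout"], sim["calibration"], out / "ph")
    rank_paths = rank_genotype_features(out / "rank", seed,
                                        n_genomes=40, n_noise_features=150)
    comm_paths = correlate_communities(out / "community", seed)
    paths = dict(sim)
    paths.update({f"growth_{k}": v for k, v in growth_paths.items()})
    paths["ph_trajectories"] = ph_path
    paths.update({f"rank_{k}": v for k, v in rank_paths.items()})
    paths.update({f"community_{k}": v for k, v in comm_paths.items()})
    return StudyResult(paths=paths)
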