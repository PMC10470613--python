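"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's three input kinds: (1) plate-reader
kinetic runs — Gompertz-shaped OD curves with additive noise, sterile and
optionally contaminated control wells, and BCECF fluorescence channels
consistent with a prescribed pH trajectory through a calibration curve;
(2) sparse PATRIC-style annotation tables with planted phenotype-
predictive features plus a taxonomy table; (3) donor x condition community
abundance tables whose family means are linear in the condition value
before logistic-normal noise and renormalization.

All randomness flows from one integer seed per spec through
``numpy.random.SeedSequence`` spawning; no global state is touched.
The default study conditions mirror the characterization design: OD and
fluorescence sampled every 13 min over 48 h, eight conditions (pH 4,
5.5, 6.9, 8 and ~440, 890, 1176, 1800 mOsm/kg), quadruplicate wells with
three BCECF replicates and one BCECF-free sister.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .ph import CalibrationCurve
from .plates import PlateReaderRun, WellMeta

# study-design defaults
SAMPLING_INTERVAL_H = 13.0 / 60.0
RUN_HOURS = 48.0
PH_CONDITIONS = (4.0, 5.5, 6.9, 8.0)
OSMOLALITY_CONDITIONS = (440.0, 890.0, 1176.0, 1800.0)
FERMENTATION_OSMOLALITIES = (472.0, 670.0, 862.0, 1047.0, 1247.0, 1437.0, 1637.0, 1824.0)
FERMENTATION_PH = (4.0, 5.5, 6.9, 7.6)
N_DONORS = 6

DEFAULT_OD_NOISE_SD = 0.005  # plate-reader OD noise (fixture choice)
BLANK_OD = 0.04
BG440, BG490 = 100.0, 120.0  # dye-free background fluorescence (au)
DYE_F440 = 500.0  # pH-independent BCECF signal in the 440 nm channel (au)

DEFAULT_CALIBRATION = CalibrationCurve(
    ph_knots=(4.0, 5.0, 6.0, 7.0, 8.0, 9.0),
    ratio_knots=(0.6, 1.1, 2.0, 3.2, 4.4, 5.2),
)


def default_time_grid(hours: float = RUN_HOURS) -> np.ndarray:
    return np.arange(0.0, hours + 1e-9, SAMPLING_INTERVAL_H)


@dataclass(frozen=True)
class GrowthSimSpec:
    """Ground-truth Gompertz parameters for one simulated OD curve."""

    y0: float
    A: float
    mu_max: float
    lag: float
    noise_sd: float = DEFAULT_OD_NOISE_SD
    t_grid: np.ndarray = field(default_factory=default_time_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A < 0 or self.mu_max < 0 or self.lag < 0 or self.noise_sd < 0:
            raise ValueError("A, mu_max, lag and noise_sd must be non-negative")
        if self.A == 0 and self.mu_max > 0:
            raise ValueError("inconsistent spec: A = 0 with mu_max > 0")
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        object.__setattr__(self, "t_grid", t)


def simulate_growth_curve(spec: GrowthSimSpec) -> np.ndarray:
    """OD600 series: Gompertz mean plus additive Gaussian noise."""
    from .growth import gompertz_model

    mean = gompertz_model(spec.t_grid, spec.y0, spec.A, spec.mu_max, spec.lag)
    if spec.noise_sd == 0:
        return mean
    rng = np.random.default_rng(spec.seed)
    return mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)


@dataclass(frozen=True)
class WellSpec:
    """Simulation recipe for one well: metadata plus ground truth."""

    meta: WellMeta
    growth: GrowthSimSpec | None = None  # None for sterile wells
    contamination_onset_h: float | None = None  # sterile wells only
    ph_trajectory: float | np.ndarray | None = None  # pH units on the grid


def _sterile_od(t: np.ndarray, onset: float | None, rng, noise_sd: float) -> np.ndarray:
    od = np.full_like(t, BLANK_OD)
    if onset is not None:
        # contamination blooms quickly: saturating rise with a 0.5 h scale
        late = t >= onset
        od[late] += 0.5 * (1.0 - np.exp(-(t[late] - onset) / 0.5))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return od


def simulate_plate_run(
    wells: Sequence[WellSpec],
    t_grid: np.ndarray | None = None,
    calibration: CalibrationCurve = DEFAULT_CALIBRATION,
    seed: int = 0,
    od_noise_sd: float | None = None,
    fluor_noise_sd: float = 0.0,
) -> PlateReaderRun:
    """Emit a full kinetic run: OD600 plus F440/F490 channels.

    BCECF wells get fluorescence such that background subtraction against
    their dye-free sister followed by the calibration inverse recovers the
    prescribed pH trajectory; dye-free wells carry background only;
    sterile wells stay at blank OD unless a contamination onset is
    injected.  pH trajectories outside the calibration knot range are
    refused so the simulation stays invertible.  ``od_noise_sd`` overrides
    every well's growth-spec noise when given.
    """
    if t_grid is None:
        t_grid = (
            wells[0].growth.t_grid
            if wells and wells[0].growth is not None
            else default_time_grid()
        )
    t_grid = np.asarray(t_grid, dtype=float)
    children = np.random.SeedSequence(seed).spawn(len(wells))
    od_cols, f440_cols, f490_cols = {}, {}, {}
    for ws, ss in zip(wells, children):
        rng = np.random.default_rng(ss)
        meta = ws.meta
        if meta.sterile or ws.growth is None:
            noise = od_noise_sd if od_noise_sd is not None else DEFAULT_OD_NOISE_SD
            if ws.growth is not None:
                noise = od_noise_sd if od_noise_sd is not None else ws.growth.noise_sd
            od = _sterile_od(t_grid, ws.contamination_onset_h, rng, noise)
        else:
            gspec = ws.growth
            noise = od_noise_sd if od_noise_sd is not None else gspec.noise_sd
            from .growth import gompertz_model

            od = gompertz_model(t_grid, gspec.y0, gspec.A, gspec.mu_max, gspec.lag)
            if noise > 0:
                od = od + rng.normal(0.0, noise, size=od.shape)
        od_cols[meta.well] = od

        if meta.bcecf:
            ph = ws.ph_trajectory
            if ph is None:
                ph = meta.condition_value if meta.condition_type == "pH" else 6.9
            ph = np.broadcast_to(np.asarray(ph, dtype=float), t_grid.shape)
            if not calibration.contains_ph(ph).all():
                lo, hi = calibration.ph_range
                raise ValueError(
                    f"well {meta.well}: pH trajectory leaves the calibration "
                    f"range [{lo}, {hi}]; simulation would not be invertible"
                )
            ratio = calibration.ph_to_ratio(ph)
            f440 = np.full_like(t_grid, BG440 + DYE_F440)
            f490 = BG490 + ratio * DYE_F440
        else:
            f440 = np.full_like(t_grid, BG440)
            f490 = np.full_like(t_grid, BG490)
        if fluor_noise_sd > 0:
            f440 = f440 + rng.normal(0.0, fluor_noise_sd, size=t_grid.shape)
            f490 = f490 + rng.normal(0.0, fluor_noise_sd, size=t_grid.shape)
        f440_cols[meta.well] = f440
        f490_cols[meta.well] = f490

    index = pd.Index(t_grid, name="time_h")
    return PlateReaderRun(
        times=t_grid,
        wells=[ws.meta for ws in wells],
        channels={
            "OD600": pd.DataFrame(od_cols, index=index),
            "F440": pd.DataFrame(f440_cols, index=index),
            "F490": pd.DataFrame(f490_cols, index=index),
        },
    )


def quadruplicate_wells(
    strain: str,
    condition_type: str,
    condition_value: float,
    growth: GrowthSimSpec,
    well_prefix: str,
    ph_trajectory=None,
) -> list[WellSpec]:
    """The study's replicate layout: three BCECF wells + one dye-free sister."""
    out = []
    for rep in range(1, 5):
        meta = WellMeta(
            well=f"{well_prefix}{rep}",
            strain=strain,
            condition_type=condition_type,
            condition_value=condition_value,
            replicate=rep,
            bcecf=rep <= 3,
            sterile=False,
        )
        out.append(WellSpec(meta=meta, growth=growth, ph_trajectory=ph_trajectory))
    return out


@dataclass(frozen=True)
class PlantedFeature:
    """One phenotype-predictive annotation value to hide in the table."""

    name: str
    carrier_fraction: float
    effects: tuple[float, ...]  # per-output shift, normalized-OD units
    column: str = "subsystem_name"

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier fraction must be in (0, 1)")


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Recipe for a genomes x annotations table with planted signal."""

    n_genomes: int = 80
    n_noise_features: int = 500
    planted_features: tuple[PlantedFeature, ...] = ()
    n_outputs: int = 4
    noise_sd: float = 0.05
    baseline: float = 0.4
    taxonomy_depth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        for pf in self.planted_features:
            if len(pf.effects) != self.n_outputs:
                raise ValueError(
                    f"planted feature {pf.name!r} needs {self.n_outputs} effects"
                )


_ANNOT_COLS = ["superclass", "class", "subclass", "subsystem_name", "role_id"]
_RANKS = ["phylum", "class", "order", "family", "genus", "species"]


def simulate_genotype_phenotype(
    spec: GenotypeSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (annotations, taxonomy, phenotypes) with known ground truth.

    Carriers of each planted feature get >= 1 record with that annotation
    value; noise-feature counts are independent of the phenotype.  Outputs
    are baseline + sum of carried effects + Gaussian noise, clipped to
    [0, 1] to match the normalized max-OD scale.
    """
    rng = np.random.default_rng(spec.seed)
    genomes = [f"G{i:03d}" for i in range(spec.n_genomes)]
    rows: list[tuple] = []
    pid = 0

    def add_record(genome: str, column: str, value: str) -> None:
        nonlocal pid
        rec = {c: "" for c in _ANNOT_COLS}
        rec[column] = value
        rows.append((genome, f"fig|sim.{pid}", *[rec[c] for c in _ANNOT_COLS]))
        pid += 1

    carried = np.zeros((spec.n_genomes, len(spec.planted_features)), dtype=bool)
    for j, pf in enumerate(spec.planted_features):
        n_carriers = max(1, round(pf.carrier_fraction * spec.n_genomes))
        carriers = rng.choice(spec.n_genomes, size=n_carriers, replace=False)
        carried[carriers, j] = True
        for g in carriers:
            for _ in range(int(rng.integers(1, 4))):
                add_record(genomes[g], pf.column, pf.name)

    for k in range(spec.n_noise_features):
        column = _ANNOT_COLS[int(rng.integers(len(_ANNOT_COLS)))]
        value = f"noise feature {k:04d}"
        frac = rng.uniform(0.1, 0.9)
        carriers = np.nonzero(rng.random(spec.n_genomes) < frac)[0]
        for g in carriers:
            for _ in range(int(rng.integers(1, 4))):
                add_record(genomes[g], column, value)

    annotations = pd.DataFrame(
        rows, columns=["genome_name", "patric_id", *_ANNOT_COLS]
    )

    # shallow random taxonomy: a few groups per rank, nested labels
    tax = {"genome_name": genomes}
    group = np.zeros(spec.n_genomes, dtype=int)
    for depth, rank in enumerate(_RANKS[: spec.taxonomy_depth]):
        splits = rng.integers(0, 2, size=spec.n_genomes)
        group = group * 2 + splits
        tax[rank] = [f"{rank.capitalize()}_{g:02d}" for g in group]
    taxonomy = pd.DataFrame(tax)

    outputs = np.full((spec.n_genomes, spec.n_outputs), spec.baseline)
    for j, pf in enumerate(spec.planted_features):
        outputs[carried[:, j]] += np.asarray(pf.effects)
    if spec.noise_sd > 0:
        outputs = outputs + rng.normal(0.0, spec.noise_sd, size=outputs.shape)
    outputs = np.clip(outputs, 0.0, 1.0)
    if np.ptp(outputs) == 0:
        warnings.warn(
            "all phenotype outputs identical; feature ranking is undefined",
            stacklevel=2,
        )
    phenotypes = pd.DataFrame(
        outputs,
        index=pd.Index(genomes, name="genome_name"),
        columns=[f"output_{i + 1}" for i in range(spec.n_outputs)],
    )
    return annotations, taxonomy, phenotypes


@dataclass(frozen=True)
class FamilySpec:
    """Linear condition response of one family before renormalization."""

    name: str
    baseline: float
    slope: float  # abundance units per condition unit

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline abundance must be positive")


@dataclass(frozen=True)
class CommunitySimSpec:
    """Recipe for a donors x conditions family-abundance table."""

    donors: int = N_DONORS
    condition_values: tuple[float, ...] = FERMENTATION_OSMOLALITIES
    condition_type: str = "osmolality"
    families: tuple[FamilySpec, ...] = ()
    dispersion: float = 0.0  # log-scale SD of the logistic-normal perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.donors < 1 or not self.condition_values:
            raise ValueError("need >= 1 donor and >= 1 condition value")
        if not self.families:
            raise ValueError("need at least one family")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def simulate_community_series(spec: CommunitySimSpec) -> AbundanceTable:
    """Generate per-sample family proportions with planted linear trends.

    Expected family abundance is baseline + slope * condition (floored at
    a tiny positive value) before a logistic-normal perturbation —
    multiplication by exp(N(0, dispersion)) — and renormalization of each
    sample to sum 1.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f.name for f in spec.families]
    records, meta_rows = [], []
    for d in range(1, spec.donors + 1):
        donor = f"TL{d}"
        for cond in spec.condition_values:
            mean = np.array(
                [max(f.baseline + f.slope * cond, 1e-9) for f in spec.families]
            )
            if spec.dispersion > 0:
                mean = mean * np.exp(rng.normal(0.0, spec.dispersion, size=mean.shape))
            if (mean == 0).all():
                warnings.warn("all-zero sample generated", stacklevel=2)
            sample = f"{donor}_{spec.condition_type}_{cond:g}"
            records.append(mean / mean.sum())
            meta_rows.append((sample, donor, spec.condition_type, float(cond)))
    index = pd.Index([m[0] for m in meta_rows], name="sample")
    abundance = pd.DataFrame(records, index=index, columns=names)
    zero_rows = (abundance.to_numpy() == 0).all(axis=0)
    if zero_rows.any():
        warnings.warn(
            f"family(ies) zero everywhere: {list(abundance.columns[zero_rows])}",
            stacklevel=2,
        )
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "donor", "condition_type", "condition_value"]
    ).set_index("sample")
    return AbundanceTable(abundance=abundance, meta=meta)
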