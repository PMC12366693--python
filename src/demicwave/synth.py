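"""Synthetic worlds, schemes and simulation campaigns.

Everything needed to exercise the full pipeline without external data: small
toy worlds (2-D strips or 1-D stepping-stone chains with a configurable zone
boundary), the packaged 23-sample study sampling scheme, pseudo-observed
datasets with known true parameters, and scaled-down simulation campaigns
(the full-scale analysis behind the published posteriors used hundreds of
thousands of simulations per scenario on a continental map; campaigns here
are sized to run on one CPU in minutes).

Toy-world defaults (a 10 x 6 strip, 200 generations, farmer onset at
generation 20) keep one forward+coalescent simulation in the low tens of
milliseconds.  On toy worlds the HG layer is seeded at carrying capacity in
every land cell, standing in for the pre-farming equilibrium that the
full-scale run reaches during the ~1250 generations before the farmer
expansion begins.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coalescent import LocusConfig, simulate_genomes
from .forward import (
    ForwardConfig,
    LayerParams,
    cohabitation_summary,
    demographic_filter,
    run_forward,
)
from .scenarios import (
    SCENARIOS,
    CohabCalibration,
    ParameterDraw,
    PriorSpec,
    ScenarioSpec,
    calibrate_cohabitation,
    draw_parameters,
    spatial_gamma_profile,
)
from .sumstats import grouping_from_scheme, panel_stat_vector, stat_names
from .world import (
    METERS_PER_DEGREE,
    ZONE_BOUNDARY_LATITUDE,
    SamplingScheme,
    SampleSpec,
    WorldGrid,
    load_sampling_scheme,
)


@dataclass
class ToyWorld:
    """A small world plus the origin demes and simulation clock defaults."""

    world: WorldGrid
    hg_origin: Optional[int]  # None: HG seeded at K in every land cell
    fa_origin: int
    T: int = 200
    fa_onset: int = 20
    #: ancestral panmictic pool size; stands in for the deep continental
    #: metapopulation so pairwise diversity reaches the 1e-4..1e-3 scale of
    #: the empirical pseudo-haploid data instead of drowning in the
    #: sequencing-error floor
    k_anc: int = 5000


def make_toy_world(
    n_cols: int = 10,
    n_rows: int = 6,
    boundary_row: int = 3,
    water: Optional[list[tuple[int, int]]] = None,
    cell_size: float = 100_000.0,
    T: int = 200,
    fa_onset: int = 20,
    fa_origin_rowcol: Optional[tuple[int, int]] = None,
    k_anc: int = 5000,
) -> ToyWorld:
    """Deterministic toy world; rows >= ``boundary_row`` lie in the north zone.

    The farmer origin sits in the south-east corner by default (standing in
    for Anatolia); hunter-gatherers start at carrying capacity everywhere.
    """
    if n_cols < 2 or n_rows < 1:
        raise ValueError("toy world needs at least 2 x 1 cells")
    origin_y = ZONE_BOUNDARY_LATITUDE * METERS_PER_DEGREE - boundary_row * cell_size
    land = np.ones((n_rows, n_cols), dtype=bool)
    if water:
        for r, c in water:
            land[r, c] = False
    world = WorldGrid(
        n_cols=n_cols,
        n_rows=n_rows,
        cell_size=cell_size,
        origin=(0.0, origin_y),
        land_mask=land,
    )
    if fa_origin_rowcol is None:
        fa_origin_rowcol = (0, n_cols - 1)
    fa_origin = world.index_of(*fa_origin_rowcol)
    if not world.land_flat[fa_origin]:
        raise ValueError("FA origin falls on water")
    return ToyWorld(
        world=world, hg_origin=None, fa_origin=fa_origin, T=T,
        fa_onset=fa_onset, k_anc=k_anc,
    )


def chain_world(n_cells: int = 15, T: int = 160, fa_onset: int = 20) -> ToyWorld:
    """1-D stepping-stone chain, all cells in the south zone, FA origin at 0."""
    toy = make_toy_world(
        n_cols=n_cells, n_rows=1, boundary_row=1, T=T, fa_onset=fa_onset,
        fa_origin_rowcol=(0, 0),
    )
    return toy


def _sample(label, layer, world, rowcol, n, gen, T):
    x, y = world.cell_center(world.index_of(*rowcol))
    return SampleSpec(
        label=label, layer=layer, x=x, y=y, n_individuals=n,
        mean_age=(T - gen) * 25.0, generation=gen,
    )


def toy_scheme(toy: ToyWorld) -> SamplingScheme:
    """Default sampling scheme for the 10 x 6 toy world.

    Hunter-gatherer samples early (before the farmer front crushes them) and
    farmer samples staggered along the expansion axis, with slack so the
    scheme stays realizable across the whole prior range.
    """
    w, T = toy.world, toy.T
    samples = [
        _sample("HG.far", "HG", w, (5, 0), 2, 45, T),
        _sample("HG.mid", "HG", w, (4, 2), 2, 40, T),
        _sample("HG.near", "HG", w, (2, 4), 2, 35, T),
        _sample("FA.origin", "FA", w, (0, 8), 3, 40, T),
        _sample("FA.near", "FA", w, (2, 6), 3, 80, T),
        _sample("FA.mid", "FA", w, (4, 3), 3, 120, T),
        _sample("FA.far", "FA", w, (5, 0), 3, 170, T),
    ]
    return SamplingScheme(samples, start_bp=T * 25.0, generations_total=T + 1)


def tight_scheme(toy: ToyWorld) -> SamplingScheme:
    """Schedule that demands an early farmer presence far from the origin.

    Used to probe the role of long-distance dispersal: without LDD the
    stepping-stone front barely reaches the far corner by the demanded
    generation, so the demographic filter passes far less often.
    """
    w, T = toy.world, toy.T
    samples = [
        _sample("HG.early", "HG", w, (5, 2), 2, 25, T),
        _sample("FA.origin", "FA", w, (0, 8), 2, 30, T),
        _sample("FA.leap", "FA", w, (5, 0), 1, 45, T),
    ]
    return SamplingScheme(samples, start_bp=T * 25.0, generations_total=T + 1)


def chain_scheme(toy: ToyWorld) -> SamplingScheme:
    """Sampling scheme for the 1-D chain world."""
    w, T = toy.world, toy.T
    samples = [
        _sample("HG.far", "HG", w, (0, 12), 3, 30, T),
        _sample("FA.near", "FA", w, (0, 2), 4, 50, T),
        _sample("FA.mid", "FA", w, (0, 8), 4, 90, T),
        _sample("FA.far", "FA", w, (0, 13), 4, 140, T),
    ]
    return SamplingScheme(samples, start_bp=T * 25.0, generations_total=T + 1)


def study_scheme(variant: str = "full") -> SamplingScheme:
    """The study's 23-sample scheme (or the Lepenski-Vir-free 18-sample variant).

    Transcribed population samples: deme coordinates in Plate Carree metres,
    population layer, sample size and mean age.  The table's sizes sum to 66
    genomes (its source text counts 67); the transcription is kept verbatim.
    """
    ref = importlib.resources.files("demicwave").joinpath("data/study_scheme.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if variant == "no-lepenski":
        df = df[~df.label.str.startswith("LepenskiVir")].reset_index(drop=True)
    elif variant != "full":
        raise ValueError(f"unknown scheme variant {variant!r}")
    return load_sampling_scheme(df)


def study_genome_metadata(spread: float = 60.0) -> pd.DataFrame:
    """Synthetic per-genome metadata matching the study's 23-sample grouping.

    The study's per-genome ages are not redistributed; this synthetic
    stand-in places each sample's genomes symmetrically around the sample's
    mean age (+- ``spread`` years), which reproduces the published grouping
    (23 samples from 66 genomes) under the 300-year rule.  Columns: genome,
    deme (x, y), layer, age.
    """
    rows = []
    for s in study_scheme().samples:
        if s.n_individuals == 1:
            ages = [s.mean_age]
        else:
            ages = list(s.mean_age + np.linspace(-spread, spread, s.n_individuals))
        for i, a in enumerate(ages):
            rows.append(
                {
                    "genome": f"{s.label}.g{i + 1}",
                    "deme": (s.x, s.y),
                    "layer": s.layer,
                    "age": float(a),
                }
            )
    return pd.DataFrame(rows)


# -- parameter draws -> forward configuration ------------------------------

def forward_config(
    toy: ToyWorld,
    draw: ParameterDraw,
    scenario: ScenarioSpec | str | None = None,
    priors: Optional[PriorSpec] = None,
) -> ForwardConfig:
    """Assemble a ForwardConfig from a parameter draw on a toy world."""
    if scenario is None:
        scenario = SCENARIOS[draw.scenario_id]
    elif isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    fixed = (priors or PriorSpec()).fixed
    hg = LayerParams(K=draw.K_HG, r=fixed["r_HG"], m=fixed["m_HG"])
    fa = LayerParams(
        K=draw.K_FA,
        r=fixed["r_FA"],
        m=draw.m_FA,
        p_ldd=draw.P_LDD,
        ldd_shape=fixed["ldd_shape"],
        ldd_rate=fixed["ldd_rate"],
    )
    gamma_profile = spatial_gamma_profile(
        scenario,
        toy.world,
        toy.fa_origin,
        gamma_max=draw.gamma,
        gamma_S=draw.gamma_S,
        gamma_N=draw.gamma_N,
    )
    temporal = "constant" if scenario.temporal_mode == "constant" else "ramp"
    return ForwardConfig(
        world=toy.world,
        hg=hg,
        fa=fa,
        alpha_N=draw.alpha_N,
        alpha_S=fixed["alpha_S"],
        gamma_profile=gamma_profile,
        temporal_mode=temporal,
        t_inc=draw.t_inc,
        T=toy.T,
        fa_origin=toy.fa_origin,
        fa_onset=toy.fa_onset,
        hg_origin=toy.hg_origin,
        k_anc=toy.k_anc,
    )


@dataclass
class PseudoObserved:
    """An end-to-end simulated dataset with known true parameters."""

    draw: ParameterDraw
    scenario_id: str
    stats: np.ndarray
    stat_names: list[str]
    seed: int
    n_retries: int


def generate_pseudo_observed(
    toy: ToyWorld,
    scenario: ScenarioSpec | str,
    draw: ParameterDraw,
    scheme: SamplingScheme,
    seed: int,
    locus_cfg: LocusConfig = LocusConfig(),
    max_retries: int = 100,
) -> PseudoObserved:
    """Run forward + coalescent + statistics for a fixed parameter draw.

    The forward run is retried with fresh seeds (same parameters) until the
    demographic filter passes, emulating the conditioning of retained
    simulations on the filter; the number of retries is reported.
    """
    scenario_id = scenario if isinstance(scenario, str) else scenario.id
    cfg = forward_config(toy, draw, scenario)
    grouping = grouping_from_scheme(scheme)
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        db = run_forward(cfg, rng)
        if demographic_filter(db, scheme).passed:
            panel = simulate_genomes(db, scheme, locus_cfg, draw.eps, rng)
            return PseudoObserved(
                draw=draw,
                scenario_id=scenario_id,
                stats=panel_stat_vector(panel, grouping),
                stat_names=stat_names(grouping),
                seed=seed,
                n_retries=attempt,
            )
    raise RuntimeError(
        f"demographic filter failed {max_retries} times for this parameter draw"
    )


_PARAM_COLUMNS = [
    "gamma", "gamma_S", "gamma_N", "t_inc", "gamma_inc",
    "K_HG", "K_FA", "m_FA", "P_LDD", "alpha_N", "eps",
]


def run_campaign(
    toy: ToyWorld,
    scenario: ScenarioSpec | str,
    priors: PriorSpec,
    n_sims: int,
    scheme: SamplingScheme,
    seed: int,
    calibration: Optional[CohabCalibration] = None,
    locus_cfg: LocusConfig = LocusConfig(),
    compute_stats: bool = True,
) -> pd.DataFrame:
    """Run a simulation campaign: draws, forward runs, filter, statistics.

    Returns one row per simulation with the parameter draw, the filter
    outcome and (for passing rows, when ``compute_stats``) the summary
    statistics as ``stat:<name>`` columns.  Simulation i uses the seed pair
    (seed, i), so campaigns are reproducible and embarrassingly parallel.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    grouping = grouping_from_scheme(scheme)
    names = stat_names(grouping)
    rows = []
    stats_rows = []
    for i in range(n_sims):
        rng = np.random.default_rng([seed, i])
        draw = draw_parameters(priors, scenario, rng, calibration)
        cfg = forward_config(toy, draw, scenario, priors)
        db = run_forward(cfg, rng)
        result = demographic_filter(db, scheme)
        cohab = cohabitation_summary(db)
        row = {c: getattr(draw, c) for c in _PARAM_COLUMNS}
        row.update(
            sim=i,
            scenario=scenario.id,
            passed=result.passed,
            hg_extinct=result.hg_extinct,
            cohabitation=np.nan if cohab is None else cohab,
        )
        rows.append(row)
        if result.passed and compute_stats:
            panel = simulate_genomes(db, scheme, locus_cfg, draw.eps, rng)
            stats_rows.append((i, panel_stat_vector(panel, grouping)))
    columns = _PARAM_COLUMNS + [
        "sim", "scenario", "passed", "hg_extinct", "cohabitation",
    ]
    df = pd.DataFrame(rows, columns=columns if not rows else None).set_index("sim")
    for name in names:
        df[f"stat:{name}"] = np.nan
    for i, vec in stats_rows:
        df.loc[i, [f"stat:{n}" for n in names]] = vec
    df.attrs["stat_names"] = names
    df.attrs["scenario"] = scenario.id
    df.attrs["seed"] = seed
    return df


def stat_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(passed-row statistic matrix, passed-row index) from a campaign table."""
    cols = [c for c in table.columns if c.startswith("stat:")]
    passed = table[table.passed & table[cols].notna().all(axis=1)]
    return passed[cols].to_numpy(dtype=float), passed.index.to_numpy()


def param_matrix(table: pd.DataFrame, names: list[str]) -> np.ndarray:
    passed = table[table.passed]
    return passed[names].to_numpy(dtype=float)


def preliminary_calibration(
    toy: ToyWorld,
    priors: PriorSpec,
    n_sims: int,
    scheme: SamplingScheme,
    seed: int,
) -> CohabCalibration:
    """AM1 forward-only campaign -> GAM of mean cohabitation time.

    Mirrors the two-stage design: ramp scenarios consult this calibration to
    set how fast the admixture rate may rise.
    """
    table = run_campaign(
        toy, "AM1", priors, n_sims, scheme, seed, compute_stats=False
    )
    ok = table.cohabitation.notna()
    return calibrate_cohabitation(
        table.K_HG[ok], table.K_FA[ok], table.alpha_N[ok], table.cohabitation[ok]
    )
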