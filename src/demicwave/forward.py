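"""Forward-in-time two-layer demography on the lattice.

Two population layers share each cell: Indigenous hunter-gatherers (HG,
layer 0) and incoming Neolithic farmers (FA, layer 1).  Per generation and
per cell the update is

1. logistic growth with Lotka-Volterra interspecific competition,
   ``N' = max(0, N + r N (1 - (N + alpha * N_other) / K))`` (half-up
   rounding), with the competition coefficient ``alpha`` symmetric between
   the layers and zone-dependent (``alpha_S`` south of latitude 43.2,
   ``alpha_N`` north of it);
2. unidirectional HG->FA admixture (assimilation): the expected number of
   transferred gene copies is ``gamma_t * N_HG * N_FA / (N_HG + N_FA)``,
   realized by stochastic rounding, where ``gamma_t`` may ramp up linearly
   with the local cohabitation clock;
3. emigration: each copy leaves with probability ``m``; emigrants move to one
   of the 4 orthogonal neighbours (stepping stone), except that for the FA
   layer a fraction ``P_LDD`` of emigration events are long-distance
   dispersals with a gamma-distributed displacement (shape 1.209, rate
   0.15046 per deme-width, i.e. a ~800 km mean).  Migrants drawn toward
   water or off-grid stay put (stepping stone) or redraw up to 10 times
   (LDD).

Every count the backward coalescent needs is recorded in a
:class:`DemographyDB`: post-step sizes, stepping-stone arrivals by source
direction, LDD events by source/target, and admixture transfers.  Gene
copies are integers throughout and are conserved by migration and transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .world import WorldGrid

HG, FA = 0, 1

#: source-offset convention for stepping-stone arrival records:
#: imm[..., d] counts copies that arrived from the neighbour at offset d
#: 0 = from north (row+1), 1 = from south (row-1),
#: 2 = from east (col+1), 3 = from west (col-1)
SOURCE_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))


class DemographyError(ValueError):
    pass


@dataclass(frozen=True)
class LayerParams:
    """Demographic parameters of one population layer.

    K is the effective haploid deme size in gene copies; m the per-copy
    emigration probability per generation; p_ldd the fraction of emigration
    events that are long-distance (used for the FA layer only).
    """

    K: int
    r: float
    m: float
    p_ldd: float = 0.0
    ldd_shape: float = 1.209
    ldd_rate: float = 0.15046

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise DemographyError("K must be positive")
        if not (0.0 <= self.m <= 1.0):
            raise DemographyError("m must be in [0, 1]")
        if not (0.0 <= self.p_ldd <= 1.0):
            raise DemographyError("p_ldd must be in [0, 1]")
        if self.ldd_shape <= 0 or self.ldd_rate <= 0:
            raise DemographyError("LDD kernel parameters must be positive")


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def logistic_competition_step(
    n_self: float, n_other: float, r: float, k_self: float, alpha: float
) -> int:
    """One Lotka-Volterra logistic update for one layer in one cell.

    Returns the half-up-rounded expected update; inside the simulator the
    same expectation is realized by stochastic rounding so that gene-copy
    counts stay integer without an absorbing floor at one copy.
    """
    if n_self < 0 or n_other < 0 or k_self <= 0:
        raise DemographyError("sizes must be non-negative and K positive")
    if not (0.0 <= alpha <= 1.0):
        raise DemographyError("alpha must be in [0, 1]")
    out = n_self + r * n_self * (1.0 - (n_self + alpha * n_other) / k_self)
    return int(max(0, _round_half_up(out)))


def emigrants(n: int, m: float, rng: np.random.Generator) -> int:
    """Binomial(n, m) draw of emigrating gene copies."""
    if not (0.0 <= m <= 1.0):
        raise DemographyError("m must be in [0, 1]")
    return int(rng.binomial(n, m))


def ldd_target(
    world: WorldGrid,
    source: int,
    beta: float,
    lam: float,
    rng: np.random.Generator,
    max_redraws: int = 10,
) -> Optional[int]:
    """Draw a long-distance dispersal target cell, or None if none found.

    The displacement length is Gamma(shape=beta, rate=lam) in deme-widths
    (mean beta/lam ~ 8 deme-widths ~ 800 km for the defaults) with a uniform
    direction; draws landing on water or off-grid are redrawn up to
    ``max_redraws`` times, after which the migrant stays (None).
    """
    x0, y0 = world.cell_center(source)
    for _ in range(max_redraws + 1):
        dist = rng.gamma(shape=beta, scale=1.0 / lam) * world.cell_size
        theta = rng.uniform(0.0, 2.0 * np.pi)
        x, y = x0 + dist * np.cos(theta), y0 + dist * np.sin(theta)
        try:
            deme = world.locate(x, y)
        except Exception:
            continue
        if deme.is_land and deme.index != source:
            return deme.index
    return None


def admixture_transfers(
    n_hg: int, n_fa: int, gamma_t: float, rng: np.random.Generator
) -> int:
    """Gene copies moving HG -> FA this generation (assimilation model).

    Expected transfers are ``gamma_t * N_HG * N_FA / (N_HG + N_FA)`` (the
    contact term is proportional to both layer densities), realized by
    stochastic rounding and capped at the available HG copies.
    """
    if n_hg < 0 or n_fa < 0:
        raise DemographyError("sizes must be non-negative")
    if n_hg == 0 or n_fa == 0 or gamma_t == 0.0:
        return 0
    expected = gamma_t * n_hg * n_fa / (n_hg + n_fa)
    base = int(np.floor(expected))
    transfer = base + int(rng.random() < expected - base)
    return min(transfer, n_hg)


def local_gamma(
    temporal_mode: str,
    gamma_max_local: float,
    g_since_colonization: int,
    t_inc: int,
) -> float:
    """Admixture rate in a deme given its local cohabitation clock.

    'constant': the deme's maximum rate throughout.  'ramp': linear increase
    from 0 over ``t_inc`` generations since FA colonization, then held at the
    maximum.
    """
    if t_inc < 1:
        raise DemographyError("t_inc must be >= 1")
    if g_since_colonization < 0:
        raise DemographyError("generations since colonization must be >= 0")
    if temporal_mode == "constant":
        return gamma_max_local
    return min(gamma_max_local, gamma_max_local * g_since_colonization / t_inc)


@dataclass
class ForwardConfig:
    """Everything one forward run needs besides the RNG."""

    world: WorldGrid
    hg: LayerParams
    fa: LayerParams
    alpha_N: float
    alpha_S: float = 1.0
    gamma_profile: np.ndarray | float = 0.0  # per-cell max admixture rate
    temporal_mode: str = "constant"  # 'constant' | 'ramp'
    t_inc: int = 1
    T: int = 200
    fa_origin: int = 0
    fa_onset: int = 20
    hg_origin: Optional[int] = None  # None => seed every land cell at K_HG
    k_anc: Optional[int] = None  # ancestral pool size; default K_HG

    def gamma_array(self) -> np.ndarray:
        g = np.asarray(self.gamma_profile, dtype=float)
        if g.ndim == 0:
            g = np.full(self.world.n_cells, float(g))
        if g.shape != (self.world.n_cells,):
            raise DemographyError("gamma_profile must be scalar or per-cell")
        return g


@dataclass
class DemographyDB:
    """Per-generation, per-layer, per-deme record of the forward run.

    Arrays are indexed [generation, layer, cell] with generation 0 the seeded
    initial state; layer 0 = HG, 1 = FA.  ``imm`` holds stepping-stone
    arrivals by source offset (see SOURCE_OFFSETS), ``ldd_events[g]`` rows are
    (layer, source, target, count), ``adm`` the within-cell HG->FA transfers.
    """

    config: ForwardConfig
    N: np.ndarray  # (T+1, 2, C) int32
    imm: np.ndarray  # (T+1, 2, C, 4) int32
    adm: np.ndarray  # (T+1, C) int32
    ldd_events: dict[int, np.ndarray] = field(default_factory=dict)
    colonized_at_fa: np.ndarray | None = None  # (C,) int32, -1 = never
    hg_extinction_generation: Optional[int] = None
    seed: Optional[int] = None

    @property
    def T(self) -> int:
        return self.N.shape[0] - 1

    def ldd_in(self) -> np.ndarray:
        """Aggregate LDD arrivals per (generation, layer, cell)."""
        out = np.zeros(self.N.shape, dtype=np.int64)
        for g, ev in self.ldd_events.items():
            np.add.at(out[g], (ev[:, 0], ev[:, 2]), ev[:, 3])
        return out

    def residents(self) -> np.ndarray:
        """Copies present at g that were already in the same (cell, layer) pool.

        N = residents + stepping-stone arrivals + LDD arrivals (+ admixture
        transfers for the FA layer); this is the backward tracer's first
        inflow category.
        """
        res = self.N.astype(np.int64) - self.imm.sum(axis=3) - self.ldd_in()
        res[:, FA, :] -= self.adm
        if res.min() < 0:
            raise DemographyError("inflow bookkeeping corrupted (negative residents)")
        return res

    def cohabitation_mask(self) -> np.ndarray:
        return (self.N[:, HG, :] > 0) & (self.N[:, FA, :] > 0)

    def save(self, path) -> None:
        """Compressed columnar dump of all per-generation records.

        Stores sizes, stepping-stone arrivals, admixture transfers and the
        flattened LDD event table; the ForwardConfig is supplied again on
        load (configs are small and fully reproducible from a run config).
        """
        if self.ldd_events:
            ev = np.vstack(
                [
                    np.column_stack([np.full(len(v), g), v])
                    for g, v in sorted(self.ldd_events.items())
                ]
            )
        else:
            ev = np.zeros((0, 5), dtype=np.int64)
        np.savez_compressed(
            path,
            N=self.N,
            imm=self.imm,
            adm=self.adm,
            ldd=ev,
            colonized=self.colonized_at_fa,
            hg_ext=np.array(
                [-1 if self.hg_extinction_generation is None
                 else self.hg_extinction_generation]
            ),
            seed=np.array([-1 if self.seed is None else self.seed]),
        )

    @classmethod
    def load(cls, path, config: "ForwardConfig") -> "DemographyDB":
        data = np.load(path)
        ldd_events: dict[int, np.ndarray] = {}
        for g in np.unique(data["ldd"][:, 0]):
            ldd_events[int(g)] = data["ldd"][data["ldd"][:, 0] == g, 1:]
        hg_ext = int(data["hg_ext"][0])
        seed = int(data["seed"][0])
        return cls(
            config=config,
            N=data["N"],
            imm=data["imm"],
            adm=data["adm"],
            ldd_events=ldd_events,
            colonized_at_fa=data["colonized"],
            hg_extinction_generation=None if hg_ext < 0 else hg_ext,
            seed=None if seed < 0 else seed,
        )


from numba import njit


@njit(cache=True)
def _forward_core(
    seed,
    T,
    n_rows,
    n_cols,
    land,
    alpha,
    gamma_max,
    ramp,
    t_inc,
    K0,
    r0,
    m0,
    K1,
    r1,
    m1,
    p_ldd_fa,
    ldd_shape,
    ldd_rate,
    fa_origin,
    fa_onset,
    hg_origin,
    origin_x,
    origin_y,
    cell_size,
):  # pragma: no cover - exercised through run_forward
    np.random.seed(seed)
    C = n_rows * n_cols
    N = np.zeros((T + 1, 2, C), np.int64)
    imm = np.zeros((T + 1, 2, C, 4), np.int64)
    adm = np.zeros((T + 1, C), np.int64)
    colonized = np.full(C, -1, np.int64)
    cap = 1024
    ldd_buf = np.zeros((cap, 4), np.int64)  # g, layer, src, dst (one per copy)
    n_ev = 0
    hg_ext = -1

    cur = np.zeros((2, C), np.int64)
    if hg_origin < 0:
        for c in range(C):
            if land[c]:
                cur[0, c] = K0
    else:
        cur[0, hg_origin] = K0
    N[0, 0] = cur[0]
    tot_hg0 = 0
    for c in range(C):
        tot_hg0 += cur[0, c]
    if tot_hg0 == 0:
        hg_ext = 0

    Ks = (float(K0), float(K1))
    rs = (r0, r1)
    ms = (m0, m1)
    grown = np.zeros((2, C), np.int64)
    new = np.zeros((2, C), np.int64)
    two_pi = 2.0 * np.pi

    for g in range(1, T + 1):
        if g == fa_onset and cur[1, fa_origin] < K1:
            cur[1, fa_origin] = K1

        # 1. growth + competition
        for ell in range(2):
            for c in range(C):
                n_self = cur[ell, c]
                if n_self > 0:
                    other = cur[1 - ell, c]
                    out = n_self + rs[ell] * n_self * (
                        1.0 - (n_self + alpha[c] * other) / Ks[ell]
                    )
                    if out < 0.0:
                        out = 0.0
                    # stochastic rounding: keeps sizes integer without an
                    # absorbing floor at 1 copy, so near-extinct demes can die
                    base = np.floor(out)
                    grown[ell, c] = np.int64(base) + (
                        1 if np.random.random() < out - base else 0
                    )
                else:
                    grown[ell, c] = 0

        # 2. admixture HG -> FA where the layers cohabit
        for c in range(C):
            a = 0
            if grown[0, c] > 0 and grown[1, c] > 0 and gamma_max[c] > 0.0:
                if ramp:
                    since = 0
                    if colonized[c] >= 0 and g > colonized[c]:
                        since = g - colonized[c]
                    gt = gamma_max[c] * since / t_inc
                    if gt > gamma_max[c]:
                        gt = gamma_max[c]
                else:
                    gt = gamma_max[c]
                expected = gt * grown[0, c] * grown[1, c] / (
                    grown[0, c] + grown[1, c]
                )
                a = int(np.floor(expected))
                if np.random.random() < expected - np.floor(expected):
                    a += 1
                if a > grown[0, c]:
                    a = grown[0, c]
                grown[0, c] -= a
            adm[g, c] = a

        # 3. emigration (stepping stone; LDD for the FA layer)
        for ell in range(2):
            for c in range(C):
                new[ell, c] = grown[ell, c]
        for ell in range(2):
            mm = ms[ell]
            if mm <= 0.0:
                continue
            for c in range(C):
                pool = grown[ell, c]
                if pool == 0:
                    continue
                E = np.random.binomial(pool, mm)
                if E == 0:
                    continue
                n_ldd = 0
                if ell == 1 and p_ldd_fa > 0.0:
                    n_ldd = np.random.binomial(E, p_ldd_fa)
                e_ss = E - n_ldd
                # exact 4-way multinomial split via conditional binomials
                d_n = np.random.binomial(e_ss, 0.25)
                rem = e_ss - d_n
                d_s = np.random.binomial(rem, 1.0 / 3.0)
                rem -= d_s
                d_e = np.random.binomial(rem, 0.5)
                d_w = rem - d_e
                row_c = c // n_cols
                col_c = c % n_cols
                # to north (arrives "from south" = 1)
                if d_n > 0 and row_c + 1 < n_rows and land[c + n_cols]:
                    new[ell, c] -= d_n
                    new[ell, c + n_cols] += d_n
                    imm[g, ell, c + n_cols, 1] += d_n
                # to south (arrives "from north" = 0)
                if d_s > 0 and row_c - 1 >= 0 and land[c - n_cols]:
                    new[ell, c] -= d_s
                    new[ell, c - n_cols] += d_s
                    imm[g, ell, c - n_cols, 0] += d_s
                # to east (arrives "from west" = 3)
                if d_e > 0 and col_c + 1 < n_cols and land[c + 1]:
                    new[ell, c] -= d_e
                    new[ell, c + 1] += d_e
                    imm[g, ell, c + 1, 3] += d_e
                # to west (arrives "from east" = 2)
                if d_w > 0 and col_c - 1 >= 0 and land[c - 1]:
                    new[ell, c] -= d_w
                    new[ell, c - 1] += d_w
                    imm[g, ell, c - 1, 2] += d_w
                # long-distance dispersal, one event per copy
                if n_ldd > 0:
                    x0 = origin_x + (col_c + 0.5) * cell_size
                    y0 = origin_y + (row_c + 0.5) * cell_size
                    for _e in range(n_ldd):
                        dst = -1
                        for _try in range(11):
                            dist = (
                                np.random.gamma(ldd_shape, 1.0 / ldd_rate)
                                * cell_size
                            )
                            th = np.random.random() * two_pi
                            cc = int(
                                np.floor(
                                    (x0 + dist * np.cos(th) - origin_x)
                                    / cell_size
                                )
                            )
                            rr = int(
                                np.floor(
                                    (y0 + dist * np.sin(th) - origin_y)
                                    / cell_size
                                )
                            )
                            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                                di = rr * n_cols + cc
                                if di != c and land[di]:
                                    dst = di
                                    break
                        if dst >= 0:
                            new[ell, c] -= 1
                            new[ell, dst] += 1
                            if n_ev >= cap:
                                bigger = np.zeros((cap * 2, 4), np.int64)
                                bigger[:cap] = ldd_buf
                                ldd_buf = bigger
                                cap *= 2
                            ldd_buf[n_ev, 0] = g
                            ldd_buf[n_ev, 1] = ell
                            ldd_buf[n_ev, 2] = c
                            ldd_buf[n_ev, 3] = dst
                            n_ev += 1

        # admixed copies join the FA deme they were assimilated into
        tot_hg = 0
        for c in range(C):
            new[1, c] += adm[g, c]
            if new[1, c] > 0 and colonized[c] < 0:
                colonized[c] = g
            tot_hg += new[0, c]
        N[g, 0] = new[0]
        N[g, 1] = new[1]
        tmp = cur
        cur = new
        new = tmp
        if hg_ext < 0 and tot_hg == 0:
            hg_ext = g

    return N, imm, adm, ldd_buf[:n_ev], colonized, hg_ext


def run_forward(
    config: ForwardConfig, rng: np.random.Generator | int
) -> DemographyDB:
    """Run the two-layer forward demography and record everything.

    Per generation: growth+competition, admixture where both layers cohabit,
    emigration (stepping stone + LDD for FA), then the post-step state is
    recorded.  Admixture transfers of a generation do not emigrate in that
    same generation, which keeps the inflow decomposition exact.  The inner
    loop is numba-compiled; the RNG stream is seeded from ``rng``.
    """
    if isinstance(rng, (int, np.integer)):
        seed = int(rng) % (2**31)
        rng = np.random.default_rng(seed)
    else:
        seed = None
    core_seed = int(rng.integers(2**31))
    world = config.world
    if config.T <= 0:
        raise DemographyError("T must be positive")
    if not world.land_flat[config.fa_origin]:
        raise DemographyError("FA origin must be a land cell")
    if config.hg_origin is not None and not world.land_flat[config.hg_origin]:
        raise DemographyError("HG origin must be a land cell")
    if config.temporal_mode not in ("constant", "ramp"):
        raise DemographyError(f"unknown temporal mode {config.temporal_mode!r}")
    if config.t_inc < 1:
        raise DemographyError("t_inc must be >= 1")

    north = world.north_mask_flat()
    alpha = np.where(north, config.alpha_N, config.alpha_S).astype(np.float64)
    if not ((alpha >= 0) & (alpha <= 1)).all():
        raise DemographyError("alpha must be in [0, 1]")
    gamma_max = config.gamma_array()

    N, imm, adm, ldd_rows, colonized, hg_ext = _forward_core(
        core_seed,
        int(config.T),
        world.n_rows,
        world.n_cols,
        world.land_flat,
        alpha,
        gamma_max,
        config.temporal_mode == "ramp",
        int(config.t_inc),
        int(config.hg.K),
        float(config.hg.r),
        float(config.hg.m),
        int(config.fa.K),
        float(config.fa.r),
        float(config.fa.m),
        float(config.fa.p_ldd),
        float(config.fa.ldd_shape),
        float(config.fa.ldd_rate),
        int(config.fa_origin),
        int(config.fa_onset),
        -1 if config.hg_origin is None else int(config.hg_origin),
        float(world.origin[0]),
        float(world.origin[1]),
        float(world.cell_size),
    )

    # aggregate per-copy LDD rows into (layer, src, dst, count) per generation
    ldd_events: dict[int, np.ndarray] = {}
    if len(ldd_rows):
        C = world.n_cells
        keys = ((ldd_rows[:, 0] * 2 + ldd_rows[:, 1]) * C + ldd_rows[:, 2]) * C + ldd_rows[:, 3]
        uniq, counts = np.unique(keys, return_counts=True)
        dst = uniq % C
        src = (uniq // C) % C
        ell = (uniq // (C * C)) % 2
        gg = uniq // (C * C * 2)
        for g in np.unique(gg):
            sel = gg == g
            ldd_events[int(g)] = np.column_stack(
                [ell[sel], src[sel], dst[sel], counts[sel]]
            ).astype(np.int64)

    return DemographyDB(
        config=config,
        N=N.astype(np.int32),
        imm=imm.astype(np.int32),
        adm=adm.astype(np.int32),
        ldd_events=ldd_events,
        colonized_at_fa=colonized.astype(np.int32),
        hg_extinction_generation=None if hg_ext < 0 else int(hg_ext),
        seed=seed,
    )


def cohabitation_summary(db: DemographyDB) -> Optional[float]:
    """Mean HG-FA co-occupancy span (generations) over ever-co-occupied demes.

    For each deme that ever held both layers, the span is
    (last co-occupied generation - first co-occupied generation + 1); returns
    None if the layers never met.
    """
    both = db.cohabitation_mask()
    ever = both.any(axis=0)
    if not ever.any():
        return None
    gens = np.arange(both.shape[0])[:, None]
    first = np.where(both, gens, np.iinfo(np.int64).max).min(axis=0)[ever]
    last = np.where(both, gens, -1).max(axis=0)[ever]
    return float(np.mean(last - first + 1))


@dataclass
class FilterResult:
    passed: bool
    hg_extinct: bool
    failing_samples: list[str]


def demographic_filter(db: DemographyDB, scheme) -> FilterResult:
    """First ABC stage: can this history realize every sample, with HGs gone?

    Pass iff (a) for every sample the recorded deme size at its generation,
    deme and layer holds at least as many gene copies as sampled individuals
    and (b) the HG layer went extinct over the whole map before the end of
    the simulation.
    """
    world = db.config.world
    failing = []
    layer_idx = {"HG": HG, "FA": FA}
    for s, deme in zip(scheme.samples, scheme.demes(world)):
        if s.generation > db.T or db.N[s.generation, layer_idx[s.layer], deme] < s.n_individuals:
            failing.append(s.label)
    hg_extinct = db.hg_extinction_generation is not None
    return FilterResult(
        passed=(not failing) and hg_extinct,
        hg_extinct=hg_extinct,
        failing_samples=failing,
    )
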