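"""Backward structured coalescent conditioned on a recorded demography.

One gene copy is traced per sampled individual (pseudo-haploid sampling:
the downstream statistic compares one majority-base call per individual and
site, so a single copy per genome is the minimal faithful representation).
Lineages activate at their sample's generation (serial sampling) and then,
going backward one generation at a time, pick their source deme/layer with
probability proportional to the forward-recorded inflows into their current
(deme, layer): residents, stepping-stone immigrants by direction, LDD
immigrants by source, and -- for the FA layer -- admixture transfers from the
cohabiting HG deme, which switch the lineage to the HG layer.  Lineages
co-located in a (deme, layer) then draw a parent copy uniformly among the
recorded deme size of the previous generation; collisions coalesce.  FA
lineages tracing past the farmer layer's founding reattach to the local HG
source population.  Lineages still uncoalesced at generation 0 enter a
panmictic ancestral pool of size ``k_anc`` (default K_HG) in which waiting
times to the next coalescence are drawn geometrically until the MRCA.

Mutations are dropped on each gene tree as Poisson(branch length x locus
length x mu) events at uniform positions, substituting a uniformly chosen
different base (finite-sites model); sequencing errors flip each base
independently with probability eps to one of the other three bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .forward import FA, HG, DemographyDB, DemographyError, SOURCE_OFFSETS
from .world import SamplingScheme

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LocusConfig:
    """Loci simulated per genome: count, length and mutation rate."""

    n_loci: int = 50
    locus_length: int = 1000
    mu: float = 2.15e-8

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.locus_length < 1 or self.mu <= 0:
            raise ValueError("invalid locus configuration")


@dataclass
class GeneTree:
    """Binary genealogy of one locus; times on the simulation-generation axis.

    Tips are nodes 0..n_tips-1 in genome order; ``parent[root] == -1``;
    branch length of v is ``time[v] - time[parent[v]]`` (children are more
    recent, i.e. at larger generation indices; ancestral-pool nodes may carry
    negative times).
    """

    n_tips: int
    parent: np.ndarray
    time: np.ndarray

    @property
    def root(self) -> int:
        roots = np.nonzero(self.parent == -1)[0]
        if len(roots) != 1:
            raise DemographyError(f"tree has {len(roots)} roots")
        return int(roots[0])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.parent))
        has = self.parent >= 0
        bl[has] = self.time[has] - self.time[self.parent[has]]
        if (bl < -1e-9).any():
            raise DemographyError("negative branch length")
        return np.maximum(bl, 0.0)

    def tmrca(self) -> float:
        return float(self.time[: self.n_tips].max() - self.time[self.root])


@dataclass
class SequencePanel:
    """Per-individual, per-locus pseudo-haploid sequences (0..3 base codes)."""

    labels: list[str]
    sample_of: np.ndarray  # sample index per genome
    loci: list[np.ndarray]  # each (n_genomes, locus_length) uint8
    eps_applied: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_genomes(self) -> int:
        return len(self.labels)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_sites(self) -> int:
        return sum(l.shape[1] for l in self.loci)

    def stacked(self) -> np.ndarray:
        return np.hstack(self.loci)

    def to_fasta(self, path, locus: int) -> None:
        """Write one locus as multi-FASTA with genome labels as IDs."""
        seqs = BASES[self.loci[locus]]
        with open(path, "w") as fh:
            for i, label in enumerate(self.labels):
                fh.write(f">{label}\n{seqs[i].tobytes().decode()}\n")


def _genome_index(scheme: SamplingScheme) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels, sample_of, gens = [], [], []
    for si, s in enumerate(scheme.samples):
        for i in range(s.n_individuals):
            labels.append(f"{s.label}.g{i + 1}")
            sample_of.append(si)
            gens.append(s.generation)
    return labels, np.array(sample_of), np.array(gens)


@njit(cache=True)
def _trace_core(
    seed,
    n_loci,
    C,
    tip_gen,
    tip_cell,
    tip_layer,
    inflow,  # (T+1, 2, C, 7) int64
    N,  # (T+1, 2, C) int64
    ldd_keys,  # sorted (g*2 + layer)*C + dst per aggregated LDD arrival row
    ldd_src,
    ldd_count,
    delta,  # (4,) source-offset cell deltas
    n_max,  # N.max() + 1
    k_anc,
):  # pragma: no cover - exercised through trace_loci
    np.random.seed(seed)
    n_tips = len(tip_gen)
    max_nodes = 2 * n_tips - 1
    parent = np.full((n_loci, max_nodes), -1, np.int64)
    time_arr = np.zeros((n_loci, max_nodes), np.float64)
    n_nodes = np.full(n_loci, n_tips, np.int64)
    for l in range(n_loci):
        for t in range(n_tips):
            time_arr[l, t] = tip_gen[t]
    root = np.full(n_loci, -1, np.int64)

    maxL = n_loci * n_tips
    lin_locus = np.empty(maxL, np.int64)
    lin_cell = np.empty(maxL, np.int64)
    lin_layer = np.empty(maxL, np.int64)
    lin_node = np.empty(maxL, np.int64)
    cnt_locus = np.zeros(n_loci, np.int64)
    L = 0

    order = np.argsort(-tip_gen)
    act = 0
    pending = n_tips
    g = int(tip_gen.max())
    keyarr = np.empty(maxL, np.int64)
    removed = np.zeros(maxL, np.uint8)

    while g >= 0:
        while act < n_tips and tip_gen[order[act]] == g:
            t = order[act]
            act += 1
            pending -= 1
            for l in range(n_loci):
                lin_locus[L] = l
                lin_cell[L] = tip_cell[t]
                lin_layer[L] = tip_layer[t]
                lin_node[L] = t
                cnt_locus[l] += 1
                L += 1
        if g == 0 or (L == 0 and pending == 0):
            break
        if L == 0:
            g -= 1
            continue

        # source pick proportional to recorded inflows at generation g
        for i in range(L):
            lay = lin_layer[i]
            c = lin_cell[i]
            tot = N[g, lay, c]
            if tot <= 0:
                return parent, time_arr, root, 1  # bookkeeping corruption
            u = np.random.random() * tot
            acc = 0.0
            cat = 6
            for k in range(7):
                acc += inflow[g, lay, c, k]
                if u < acc:
                    cat = k
                    break
            if cat == 0:
                pass
            elif cat <= 4:
                lin_cell[i] = c + delta[cat - 1]
            elif cat == 5:
                lin_layer[i] = 0  # admixture transfer: copy was HG
            else:
                key = (np.int64(g) * 2 + lay) * C + c
                lo = np.searchsorted(ldd_keys, key)
                hi = lo
                while hi < len(ldd_keys) and ldd_keys[hi] == key:
                    hi += 1
                if hi == lo:
                    return parent, time_arr, root, 2  # missing LDD record
                wsum = 0
                for j in range(lo, hi):
                    wsum += ldd_count[j]
                u2 = np.random.random() * wsum
                acc2 = 0.0
                src = ldd_src[lo]
                for j in range(lo, hi):
                    acc2 += ldd_count[j]
                    if u2 < acc2:
                        src = ldd_src[j]
                        break
                lin_cell[i] = src
            # FA founding: an empty FA pool reattaches to the local HG demes
            if N[g - 1, lin_layer[i], lin_cell[i]] == 0:
                if lin_layer[i] == 1:
                    lin_layer[i] = 0
                if N[g - 1, lin_layer[i], lin_cell[i]] == 0:
                    return parent, time_arr, root, 1

        # coalescence: uniform parent copy in the previous generation
        for i in range(L):
            npar = N[g - 1, lin_layer[i], lin_cell[i]]
            pidx = np.int64(np.random.random() * npar)
            keyarr[i] = (
                (lin_locus[i] * 2 + lin_layer[i]) * C + lin_cell[i]
            ) * n_max + pidx
        order2 = np.argsort(keyarr[:L])
        i0 = 0
        while i0 < L:
            i1 = i0 + 1
            while i1 < L and keyarr[order2[i1]] == keyarr[order2[i0]]:
                i1 += 1
            if i1 - i0 > 1:
                lead = order2[i0]
                l = lin_locus[lead]
                cur = lin_node[lead]
                for j in range(i0 + 1, i1):
                    oth = order2[j]
                    newn = n_nodes[l]
                    n_nodes[l] += 1
                    time_arr[l, newn] = g - 1
                    parent[l, cur] = newn
                    parent[l, lin_node[oth]] = newn
                    cur = newn
                    removed[oth] = 1
                    cnt_locus[l] -= 1
                lin_node[lead] = cur
            i0 = i1
        w = 0
        for i in range(L):
            if removed[i] == 0:
                lin_locus[w] = lin_locus[i]
                lin_cell[w] = lin_cell[i]
                lin_layer[w] = lin_layer[i]
                lin_node[w] = lin_node[i]
                w += 1
            else:
                removed[i] = 0
        L = w

        # a locus whose single remaining lineage is its MRCA is finished
        if pending == 0:
            w = 0
            for i in range(L):
                l = lin_locus[i]
                if cnt_locus[l] == 1:
                    root[l] = lin_node[i]
                else:
                    lin_locus[w] = lin_locus[i]
                    lin_cell[w] = lin_cell[i]
                    lin_layer[w] = lin_layer[i]
                    lin_node[w] = lin_node[i]
                    w += 1
            L = w
        g -= 1

    # ancestral panmictic pool below generation 0
    nodes = np.empty(n_tips, np.int64)
    for l in range(n_loci):
        k = 0
        for i in range(L):
            if lin_locus[i] == l:
                nodes[k] = lin_node[i]
                k += 1
        if k == 0:
            continue
        t = 0.0
        while k > 1:
            if k >= k_anc:
                p_event = 1.0
            else:
                p_no = 1.0
                for i in range(1, k):
                    p_no *= 1.0 - i / k_anc
                p_event = 1.0 - p_no
                if p_event < 1e-300:
                    p_event = 1e-300
            t -= np.random.geometric(p_event)
            a = np.int64(np.random.random() * k)
            b = np.int64(np.random.random() * (k - 1))
            if b >= a:
                b += 1
            newn = n_nodes[l]
            n_nodes[l] += 1
            time_arr[l, newn] = t
            parent[l, nodes[a]] = newn
            parent[l, nodes[b]] = newn
            lo_i = min(a, b)
            hi_i = max(a, b)
            nodes[lo_i] = newn
            nodes[hi_i] = nodes[k - 1]
            k -= 1
        root[l] = nodes[0]
    return parent, time_arr, root, 0


def trace_loci(
    db: DemographyDB,
    scheme: SamplingScheme,
    n_loci: int,
    rng: np.random.Generator,
    k_anc: Optional[int] = None,
) -> list[GeneTree]:
    """Trace ``n_loci`` independent gene trees through one recorded demography.

    All loci are traced simultaneously (they share the demography but are
    conditionally independent given it); free recombination between loci,
    none within.  The generation-by-generation tracing runs in a
    numba-compiled kernel seeded from ``rng``.
    """
    world = db.config.world
    C = world.n_cells
    if k_anc is None:
        k_anc = db.config.k_anc or db.config.hg.K
    if k_anc < 1:
        raise DemographyError("k_anc must be >= 1")
    labels, sample_of, tip_gen = _genome_index(scheme)
    n_tips = len(labels)
    if n_tips < 1:
        raise DemographyError("scheme contains no genomes")
    sample_demes = np.array(scheme.demes(world))
    tip_cell = sample_demes[sample_of]
    tip_layer = np.array(
        [HG if scheme.samples[si].layer == "HG" else FA for si in sample_of],
        dtype=np.int64,
    )
    if tip_gen.max() > db.T:
        raise DemographyError("scheme demands generations beyond the demography")

    # combined inflow table: categories 0=resident, 1-4=stepping-stone by
    # source direction, 5=admixture transfer (FA only), 6=LDD arrivals
    res = db.residents()  # (T+1, 2, C)
    ldd_in = db.ldd_in()
    N = db.N.astype(np.int64)
    inflow = np.empty(res.shape + (7,), dtype=np.int64)
    inflow[..., 0] = res
    inflow[..., 1:5] = db.imm
    inflow[..., 5] = 0
    inflow[:, FA, :, 5] = db.adm
    inflow[..., 6] = ldd_in

    # flattened, sorted LDD arrival records for in-kernel source sampling
    if db.ldd_events:
        ks, ss, cs = [], [], []
        for g, ev in db.ldd_events.items():
            ks.append((np.int64(g) * 2 + ev[:, 0]) * C + ev[:, 2])
            ss.append(ev[:, 1])
            cs.append(ev[:, 3])
        ldd_keys = np.concatenate(ks)
        ldd_src = np.concatenate(ss)
        ldd_count = np.concatenate(cs)
        o = np.argsort(ldd_keys, kind="stable")
        ldd_keys, ldd_src, ldd_count = ldd_keys[o], ldd_src[o], ldd_count[o]
    else:
        ldd_keys = np.empty(0, dtype=np.int64)
        ldd_src = np.empty(0, dtype=np.int64)
        ldd_count = np.empty(0, dtype=np.int64)

    delta = np.array(
        [dr * world.n_cols + dc for dr, dc in SOURCE_OFFSETS], dtype=np.int64
    )
    parent, time_arr, root, err = _trace_core(
        int(rng.integers(2**31)),
        int(n_loci),
        C,
        tip_gen.astype(np.int64),
        tip_cell.astype(np.int64),
        tip_layer,
        inflow,
        N,
        ldd_keys,
        ldd_src,
        ldd_count,
        delta,
        int(N.max()) + 1,
        int(k_anc),
    )
    if err:
        raise DemographyError(
            "lineage traced into an empty deme (bookkeeping corruption)"
            if err == 1
            else "LDD arrival without a matching event record"
        )
    trees = []
    for locus in range(n_loci):
        tree = GeneTree(
            n_tips=n_tips, parent=parent[locus], time=time_arr[locus]
        )
        if root[locus] < 0 or tree.parent[root[locus]] != -1:
            raise DemographyError("locus tracing did not terminate at a root")
        trees.append(tree)
    return trees



def trace_locus(
    db: DemographyDB,
    scheme: SamplingScheme,
    rng: np.random.Generator,
    k_anc: Optional[int] = None,
) -> GeneTree:
    """Trace a single locus (see :func:`trace_loci`)."""
    return trace_loci(db, scheme, 1, rng, k_anc)[0]


def drop_mutations(
    tree: GeneTree, cfg: LocusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mutate a uniform-random root sequence down the tree.

    Mutation counts per branch are Poisson(branch length x locus length x mu);
    each mutation hits a uniform site and substitutes a uniformly chosen
    different base.  Returns tip sequences (n_tips, locus_length) uint8 codes.
    """
    out = _mutate_core(
        int(rng.integers(2**31)),
        tree.parent[None, :],
        tree.branch_lengths()[None, :],
        tree.n_tips,
        cfg.locus_length,
        cfg.mu,
    )
    return out[0]


@njit(cache=True)
def _mutate_core(
    seed, parents, bls, n_tips, L, mu
):  # pragma: no cover - exercised through drop_mutations
    np.random.seed(seed)
    n_loci, n_nodes = parents.shape
    out = np.empty((n_loci, n_tips, L), np.uint8)
    seqs = np.empty((n_nodes, L), np.uint8)
    for l in range(n_loci):
        root = -1
        for v in range(n_nodes):
            if parents[l, v] < 0:
                root = v
        for j in range(L):
            seqs[root, j] = np.uint8(np.random.randint(0, 4))
        # internal nodes are created after their children, so parent index >
        # child index everywhere and reverse index order is parent-first
        for v in range(n_nodes - 1, -1, -1):
            p = parents[l, v]
            if p < 0:
                continue
            seqs[v] = seqs[p]
            n_mut = np.random.poisson(bls[l, v] * L * mu)
            for _k in range(n_mut):
                pos = np.random.randint(0, L)
                seqs[v, pos] = (
                    seqs[v, pos] + np.uint8(np.random.randint(1, 4))
                ) % 4
        out[l] = seqs[:n_tips]
    return out


def apply_sequencing_error(
    seqs: np.ndarray, eps: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each base independently with probability eps to another base."""
    if not (0.0 <= eps <= 1.0):
        raise ValueError("eps must be in [0, 1]")
    if eps == 0.0:
        return seqs
    size = seqs.size
    k = int(rng.binomial(size, eps))
    out = seqs.copy()
    if k:
        flat = out.reshape(-1)
        pos = rng.choice(size, size=k, replace=False)  # exact Bernoulli field
        flat[pos] = (flat[pos] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    return out


def error_pair_mismatch(eps: float) -> float:
    """Mismatch probability added by sequencing error alone for one site pair.

    Exactly 2 eps (1 - eps) + (2/3) eps^2: one of the two reads in error, or
    both in error landing on different bases.
    """
    return 2.0 * eps * (1.0 - eps) + (2.0 / 3.0) * eps * eps


def simulate_genomes(
    db: DemographyDB,
    scheme: SamplingScheme,
    cfg: LocusConfig,
    eps: float,
    rng: np.random.Generator,
    k_anc: Optional[int] = None,
) -> SequencePanel:
    """Full genetic simulation: trees -> mutations -> sequencing error."""
    labels, sample_of, _ = _genome_index(scheme)
    trees = trace_loci(db, scheme, cfg.n_loci, rng, k_anc)
    stacked = _mutate_core(
        int(rng.integers(2**31)),
        np.stack([t.parent for t in trees]),
        np.stack([t.branch_lengths() for t in trees]),
        trees[0].n_tips,
        cfg.locus_length,
        cfg.mu,
    )
    loci = [stacked[i] for i in range(cfg.n_loci)]
    if eps > 0:
        loci = [apply_sequencing_error(s, eps, rng) for s in loci]
    return SequencePanel(
        labels=labels,
        sample_of=sample_of,
        loci=loci,
        eps_applied=eps,
        meta={"n_loci": cfg.n_loci, "mu": cfg.mu},
    )
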