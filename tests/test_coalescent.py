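import numpy as np
import pytest

from demicwave import synth
from demicwave.coalescent import (
    GeneTree,
    LocusConfig,
    SequencePanel,
    apply_sequencing_error,
    drop_mutations,
    error_pair_mismatch,
    simulate_genomes,
    trace_loci,
    trace_locus,
)
from demicwave.forward import ForwardConfig, LayerParams, run_forward
from demicwave.world import SamplingScheme, SampleSpec


def _island_db(n_demes=1, N=400, T=3, k_anc=None):
    """Isolated constant-size demes with no migration."""
    toy = synth.make_toy_world(
        n_cols=max(2, n_demes), n_rows=1, boundary_row=1, T=T, fa_onset=T + 10
    )
    cfg = ForwardConfig(
        world=toy.world,
        hg=LayerParams(K=N, r=0.5, m=0.0),
        fa=LayerParams(K=N, r=0.5, m=0.0),
        alpha_N=0.0, alpha_S=0.0, T=T,
        fa_origin=toy.world.n_cells - 1, fa_onset=T + 10,
        k_anc=k_anc or N,
    )
    return toy, run_forward(cfg, 0)


def _scheme(toy, specs, T):
    samples = [
        SampleSpec(
            label=f"s{i}", layer=layer,
            x=toy.world.cell_center(cell)[0], y=toy.world.cell_center(cell)[1],
            n_individuals=n, mean_age=(T - gen) * 25.0, generation=gen,
        )
        for i, (layer, cell, n, gen) in enumerate(specs)
    ]
    return SamplingScheme(samples, start_bp=T * 25.0, generations_total=T + 1)


def _pair_mrca(tree: GeneTree, a: int, b: int) -> float:
    anc_a = set()
    v = a
    while v != -1:
        anc_a.add(v)
        v = int(tree.parent[v])
    v = b
    while v not in anc_a:
        v = int(tree.parent[v])
    return float(tree.time[v])


class TestTracing:
    def test_pair_tmrca_matches_closed_form(self, rng):
        # two copies in one constant deme of N coalesce after ~N generations
        N = 50
        toy, db = _island_db(N=N)
        scheme = _scheme(toy, [("HG", 0, 2, 3)], 3)
        trees = trace_loci(db, scheme, 4000, rng, k_anc=N)
        tm = np.array([t.tmrca() for t in trees])
        se = N / np.sqrt(len(tm))
        assert tm.mean() == pytest.approx(N, abs=3 * se)

    def test_tips_count_and_single_root(self, db_default, toy_scheme, rng):
        trees = trace_loci(db_default, toy_scheme, 5, rng)
        n_expected = sum(s.n_individuals for s in toy_scheme.samples)
        for t in trees:
            assert t.n_tips == n_expected
            assert (t.parent == -1).sum() == 1
            assert len(t.parent) == 2 * n_expected - 1
            assert (t.branch_lengths() >= 0).all()

    def test_serial_samples_enter_at_their_generation(self, rng):
        toy, db = _island_db(N=200, T=40)
        scheme = _scheme(toy, [("HG", 0, 1, 40), ("HG", 0, 1, 10)], 40)
        tree = trace_locus(db, scheme, rng)
        assert tree.time[0] == 40.0
        assert tree.time[1] == 10.0
        # the younger lineage cannot have coalesced before the older existed
        assert _pair_mrca(tree, 0, 1) <= 10.0

    def test_isolated_populations_only_meet_in_ancestral_pool(self, rng):
        # two never-connected demes: cross-deme pairs must coalesce before
        # the simulation start (negative time axis)
        toy, db = _island_db(n_demes=2, N=100, T=10)
        scheme = _scheme(toy, [("HG", 0, 2, 10), ("HG", 1, 2, 10)], 10)
        for tree in trace_loci(db, scheme, 30, rng, k_anc=100):
            assert _pair_mrca(tree, 0, 2) < 0
            assert _pair_mrca(tree, 1, 3) < 0

    def test_determinism(self, db_default, toy_scheme):
        p1 = simulate_genomes(
            db_default, toy_scheme, LocusConfig(n_loci=5), 5e-5,
            np.random.default_rng(3),
        )
        p2 = simulate_genomes(
            db_default, toy_scheme, LocusConfig(n_loci=5), 5e-5,
            np.random.default_rng(3),
        )
        for a, b in zip(p1.loci, p2.loci):
            assert np.array_equal(a, b)

    def test_loci_are_exchangeable(self, rng):
        from scipy.stats import ks_2samp

        toy, db = _island_db(N=80)
        scheme = _scheme(toy, [("HG", 0, 2, 3)], 3)
        panel = simulate_genomes(db, scheme, LocusConfig(n_loci=400), 0.0, rng)
        div = np.array([(l[0] != l[1]).mean() for l in panel.loci])
        assert ks_2samp(div[:200], div[200:]).pvalue > 0.01


class TestMutations:
    def test_zero_length_tree_gives_identical_sequences(self, rng):
        tree = GeneTree(
            n_tips=2,
            parent=np.array([2, 2, -1]),
            time=np.array([10.0, 10.0, 10.0]),
        )
        seqs = drop_mutations(tree, LocusConfig(), rng)
        assert np.array_equal(seqs[0], seqs[1])

    def test_pair_mismatch_tracks_2_t_mu(self, rng):
        T_div = 40_000.0
        tree = GeneTree(
            n_tips=2,
            parent=np.array([2, 2, -1]),
            time=np.array([T_div, T_div, 0.0]),
        )
        cfg = LocusConfig(n_loci=1, locus_length=1000)
        mism = np.array(
            [
                (lambda s: (s[0] != s[1]).mean())(drop_mutations(tree, cfg, rng))
                for _ in range(3000)
            ]
        )
        expected = 2 * T_div * cfg.mu  # 1.72e-3, small enough to be linear
        assert mism.mean() == pytest.approx(
            expected, abs=3 * mism.std() / np.sqrt(len(mism))
        )


class TestSequencingError:
    def test_eps_zero_is_identity(self, rng):
        seqs = rng.integers(0, 4, (3, 100), dtype=np.uint8)
        assert apply_sequencing_error(seqs, 0.0, rng) is seqs

    def test_alteration_fraction(self, rng):
        seqs = np.zeros((1, 1_000_000), dtype=np.uint8)
        out = apply_sequencing_error(seqs, 1e-3, rng)
        frac = (out != seqs).mean()
        se = np.sqrt(1e-3 / 1e6)
        assert frac == pytest.approx(1e-3, abs=4 * se)

    def test_error_only_pair_mismatch_formula(self, rng):
        eps = 0.01
        base = np.zeros((1, 400_000), dtype=np.uint8)
        a = apply_sequencing_error(base, eps, rng)
        b = apply_sequencing_error(base, eps, rng)
        expected = error_pair_mismatch(eps)  # 2e(1-e) + (2/3)e^2
        se = np.sqrt(expected / base.size)
        assert (a != b).mean() == pytest.approx(expected, abs=4 * se)

    def test_formula_value(self):
        assert error_pair_mismatch(5.7e-5) == pytest.approx(
            2 * 5.7e-5 * (1 - 5.7e-5) + 2 / 3 * 5.7e-5**2
        )


class TestAgainstMsprime:
    def test_single_deme_diversity_matches_msprime(self, rng):
        # independent oracle: a panmictic haploid population of size N in
        # msprime should give the same mean pairwise diversity
        msprime = pytest.importorskip("msprime")
        N, mu, n_loci = 120, 2.15e-8, 1500
        toy, db = _island_db(N=N)
        scheme = _scheme(toy, [("HG", 0, 2, 3)], 3)
        panel = simulate_genomes(db, scheme, LocusConfig(n_loci=n_loci), 0.0, rng)
        ours = np.array([(l[0] != l[1]).mean() for l in panel.loci])

        other = []
        ts_reps = msprime.sim_ancestry(
            samples=2, population_size=N, ploidy=1, sequence_length=1000,
            num_replicates=n_loci, random_seed=42,
        )
        for ts in ts_reps:
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=7)
            other.append(mts.diversity(span_normalise=True))
        other = np.array(other)
        se = np.sqrt(ours.var() / len(ours) + other.var() / len(other))
        assert ours.mean() == pytest.approx(other.mean(), abs=3.5 * se)


class TestIsolationByDistance:
    def test_between_deme_diversity_grows_with_separation(self):
        # 1-D stepping stone, HG layer only, low Nm and a window long enough
        # for mid-range pairs to coalesce before the ancestral pool
        toy = synth.make_toy_world(
            n_cols=9, n_rows=1, boundary_row=1, T=600, fa_onset=700
        )
        cfg = ForwardConfig(
            world=toy.world,
            hg=LayerParams(K=50, r=0.3, m=0.1),
            fa=LayerParams(K=50, r=0.3, m=0.0),
            alpha_N=0.0, alpha_S=0.0, T=600,
            fa_origin=8, fa_onset=700, k_anc=50,
        )
        scheme = _scheme(
            toy, [("HG", 0, 2, 600), ("HG", 2, 2, 600), ("HG", 8, 2, 600)], 600
        )
        within, near, far = [], [], []
        for seed in range(8):
            db = run_forward(cfg, seed)
            panel = simulate_genomes(
                db, scheme, LocusConfig(n_loci=150), 0.0,
                np.random.default_rng(seed),
            )
            X = panel.stacked()
            within.append((X[0] != X[1]).mean())  # same deme
            near.append((X[0] != X[2]).mean())  # demes 0 and 2
            far.append((X[0] != X[4]).mean())  # demes 0 and 8
        assert np.mean(within) <= np.mean(near) <= np.mean(far)
        assert np.mean(far) > np.mean(within)


class TestPanel:
    def test_fasta_roundtrip(self, panel_default, tmp_path):
        path = tmp_path / "locus0.fa"
        panel_default.to_fasta(path, 0)
        text = path.read_text().splitlines()
        assert text[0] == f">{panel_default.labels[0]}"
        assert set(text[1]) <= set("ACGT")
        assert len(text) == 2 * panel_default.n_genomes

    def test_panel_shape(self, panel_default, toy_scheme):
        assert panel_default.n_loci == 50
        assert panel_default.n_sites == 50_000
        assert panel_default.n_genomes == sum(
            s.n_individuals for s in toy_scheme.samples
        )
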