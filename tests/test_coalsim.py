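import numpy as np
import pytest

from coalboot.coalsim import GeneTree, RandomSource, simulate_gene_tree, simulate_replicate
from coalboot.demography import ScaledDemography, ScaledMigration, ScaledSplit

PANMICTIC = ScaledDemography(
    model_id="panmictic",
    relative_sizes={"a": 1.0},
    splits=[],
    migrations=[],
    reference_size=2.5e6,
    generations_per_year=2.0,
)

TWO_DEME_SPLIT = ScaledDemography(
    model_id="two-deme",
    relative_sizes={"a": 1.0, "b": 1.0, "anc": 1.0},
    splits=[ScaledSplit(0.3, "a", "anc"), ScaledSplit(0.3, "b", "anc")],
    migrations=[],
    reference_size=2.5e6,
    generations_per_year=2.0,
)


def assert_valid_tree(tree: GeneTree, expected_tips: int):
    assert tree.n_tips == expected_tips
    parent = tree.parent_array()
    n_internal = 0
    for i, kids in enumerate(tree.children):
        if kids:
            n_internal += 1
            assert len(kids) == 2, "coalescent trees are binary"
            for c in kids:
                assert tree.times[i] > tree.times[c] >= 0.0
        else:
            assert tree.times[i] == 0.0, "tips are contemporary (ultrametric)"
    assert n_internal == expected_tips - 1
    assert parent[tree.root] == -1


class TestSimulateGeneTree:
    def test_tree_shape_and_tip_conservation(self, scaled_r2, sampling):
        counts = sampling["EF1a"]
        tree = simulate_gene_tree(scaled_r2, counts, 123)
        assert_valid_tree(tree, 96)
        from collections import Counter

        by_deme = Counter(d for d in tree.tip_demes if d is not None)
        assert by_deme == {d: n for d, n in counts.items() if n > 0}

    def test_zero_count_demes_absent(self, scaled_r2, sampling):
        tree = simulate_gene_tree(scaled_r2, sampling["Anon15"], 5)
        assert "lorquini" not in set(tree.tip_demes)

    def test_determinism_and_seed_sensitivity(self, scaled_r2, sampling):
        nwk = lambda seed: simulate_gene_tree(
            scaled_r2, sampling["wg"], RandomSource(seed).generator()
        ).to_newick()
        assert nwk(7) == nwk(7)
        assert nwk(7) != nwk(8)

    def test_root_older_than_split_without_migration(self):
        for seed in range(50):
            tree = simulate_gene_tree(TWO_DEME_SPLIT, {"a": 1, "b": 1}, seed)
            assert tree.times[tree.root] > 0.3

    def test_pairwise_coalescence_mean(self):
        # E[T2] = 2N generations = 0.5 scaled units in a panmictic deme
        gen = RandomSource(11).generator()
        times = [
            simulate_gene_tree(PANMICTIC, {"a": 2}, gen).times[-1] for _ in range(20_000)
        ]
        assert np.mean(times) == pytest.approx(0.5, rel=0.03)

    def test_requires_two_samples(self, scaled_r2):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_gene_tree(scaled_r2, {"arthemis": 1}, 0)

    def test_unknown_deme_rejected(self, scaled_r2):
        with pytest.raises(ValueError, match="unknown deme"):
            simulate_gene_tree(scaled_r2, {"nope": 2}, 0)

    def test_disconnected_demes_error(self):
        disconnected = ScaledDemography(
            model_id="disconnected",
            relative_sizes={"a": 1.0, "b": 1.0},
            splits=[],
            migrations=[],
            reference_size=2.5e6,
            generations_per_year=2.0,
        )
        with pytest.raises(ValueError, match="unreachable"):
            simulate_gene_tree(disconnected, {"a": 1, "b": 1}, 0)


class TestSimulateReplicate:
    def test_one_tree_per_locus_with_table_counts(self, scaled_r2, sampling):
        trees = simulate_replicate(scaled_r2, sampling, RandomSource(3))
        assert len(trees) == 8
        by_locus = dict(zip(sampling, trees))
        assert by_locus["EF1a"].n_tips == 96
        assert "lorquini" not in set(by_locus["Anon15"].tip_demes)
        assert "archippus" not in set(by_locus["Anon17"].tip_demes)

    def test_replicate_determinism(self, scaled_r2, sampling):
        a = [t.to_newick() for t in simulate_replicate(scaled_r2, sampling, 42)]
        b = [t.to_newick() for t in simulate_replicate(scaled_r2, sampling, 42)]
        assert a == b

    def test_loci_are_independent_substreams(self, scaled_r2, sampling):
        trees = simulate_replicate(scaled_r2, sampling, 42)
        newicks = {t.to_newick() for t in trees}
        assert len(newicks) == 8


class TestMigrationEffect:
    """Higher migration between arthemis and astyanax makes recent
    cross-deme coalescences (younger than the first split) more common."""

    @staticmethod
    def _recent_cross_deme_events(tree: GeneTree, before: float) -> int:
        # count coalescences younger than `before` that join subtrees
        # containing tips of both focal demes
        focal = {"arthemis", "astyanax"}
        reach: dict[int, set] = {}
        count = 0
        for i, kids in enumerate(tree.children):
            if not kids:
                reach[i] = {tree.tip_demes[i]} & focal
            else:
                sets = [reach[c] for c in kids]
                reach[i] = set().union(*sets)
                if tree.times[i] < before and all(s for s in sets) and len(reach[i]) > 1:
                    count += 1
        return count

    def test_high_migration_increases_recent_mixing(self, scaled_mm1, models_by_id):
        from coalboot.demography import to_coalescent_scale

        scaled_mm7 = to_coalescent_scale(models_by_id["MM7"])
        t1 = scaled_mm1.splits[0].time
        counts = {"arthemis": 6, "astyanax": 6}
        means = {}
        for name, scaled in [("MM1", scaled_mm1), ("MM7", scaled_mm7)]:
            gen = RandomSource(17).generator()
            means[name] = np.mean(
                [
                    self._recent_cross_deme_events(
                        simulate_gene_tree(scaled, counts, gen), t1
                    )
                    for _ in range(1500)
                ]
            )
        assert means["MM7"] > means["MM1"]


class TestAgainstIndependentSimulator:
    """Mean TMRCA cross-checked against msprime on matching demographies."""

    N_REPS = 2000

    @staticmethod
    def _msprime_mean_tmrca(demography, samples, nreps, seed):
        # note: built with ploidy=1, so population sizes are haploid (2N)
        import msprime

        total = 0.0
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            ploidy=1,
            num_replicates=nreps,
            random_seed=seed,
        )
        for ts in reps:
            total += ts.max_root_time
        return total / nreps

    @staticmethod
    def _our_mean_tmrca(scaled, counts, nreps, seed):
        gen = RandomSource(seed).generator()
        return float(
            np.mean(
                [
                    simulate_gene_tree(scaled, counts, gen).times[-1]
                    for _ in range(nreps)
                ]
            )
        )

    def _check(self, scaled, msp_demography, counts, msp_samples, rel_tol):
        ours = self._our_mean_tmrca(scaled, counts, self.N_REPS, 5)
        # msprime times are in generations; one scaled unit is 4*N_ref
        theirs = self._msprime_mean_tmrca(
            msp_demography, msp_samples, self.N_REPS, 5
        ) / (4.0 * scaled.reference_size)
        assert ours == pytest.approx(theirs, rel=rel_tol)

    def test_panmictic(self):
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=2 * 2.5e6)
        self._check(PANMICTIC, dem, {"a": 5}, {"a": 5}, rel_tol=0.06)

    def test_two_demes_with_split(self):
        import msprime

        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=2 * 2.5e6)
        dem.add_population(name="b", initial_size=2 * 2.5e6)
        dem.add_population(name="anc", initial_size=2 * 2.5e6)
        dem.add_population_split(time=0.3 * 4 * 2.5e6, derived=["a", "b"], ancestral="anc")
        self._check(TWO_DEME_SPLIT, dem, {"a": 3, "b": 3}, {"a": 3, "b": 3}, rel_tol=0.06)

    def test_two_demes_with_migration_phase(self):
        import msprime

        scaled = ScaledDemography(
            model_id="mig",
            relative_sizes={"a": 1.0, "b": 0.5, "anc": 1.0},
            splits=[ScaledSplit(0.5, "a", "anc"), ScaledSplit(0.5, "b", "anc")],
            migrations=[ScaledMigration(0.0, 0.2, source="a", dest="b", rate=4.0)],
            reference_size=2.5e6,
            generations_per_year=2.0,
        )
        n_ref = 2.5e6
        dem = msprime.Demography()
        dem.add_population(name="a", initial_size=2 * n_ref)
        dem.add_population(name="b", initial_size=2 * 0.5 * n_ref)
        dem.add_population(name="anc", initial_size=2 * n_ref)
        # backward rate for lineages in b toward a: 4.0 per 4*N_ref generations
        dem.set_migration_rate(source="b", dest="a", rate=4.0 / (4 * n_ref))
        dem.add_migration_rate_change(time=0.2 * 4 * n_ref, source="b", dest="a", rate=0.0)
        dem.add_population_split(time=0.5 * 4 * n_ref, derived=["a", "b"], ancestral="anc")
        self._check(scaled, dem, {"a": 4, "b": 4}, {"a": 4, "b": 4}, rel_tol=0.06)
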