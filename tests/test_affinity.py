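"""Relative-affinity estimation and cross-condition comparison."""

import numpy as np
import pytest

import selexkit as sk
from selexkit import seq
from selexkit.background import MarkovModel


def toy_background():
    """Order-1 model over single bases: P(A)=0.25, P(C)=0.5, P(G)=P(T)=0.125."""
    initial = np.array([0.25, 0.5, 0.125, 0.125])
    return MarkovModel(order=1, initial=initial,
                       transitions=np.tile(initial, (4, 1)),
                       alpha=1.0, strand_mode="single")


def toy_table(counts, total=None):
    counts = np.asarray(counts, dtype=np.int64)
    return sk.KmerTable(k=1, strand_mode="single", counts=counts,
                        total_windows=int(total or counts.sum()),
                        n_reads=10, round_index=2, condition_label="toy")


class TestRelativeAffinity:
    def test_toy_ratio_arithmetic(self):
        # f = {A: 0.5, C: 0.5}; background {A: 0.25, C: 0.5}
        # raw ratios {A: 2, C: 1} -> rel {A: 1, C: 0.5}
        atab = sk.relative_affinity(toy_table([500, 500, 0, 0]),
                                    toy_background(), min_count=1)
        assert atab.ratio("A") == pytest.approx(2.0)
        assert atab.ratio("C") == pytest.approx(1.0)
        assert atab.affinity("A") == 1.0
        assert atab.affinity("C") == pytest.approx(0.5)
        assert atab.normalization_word == "A"

    def test_words_below_min_count_flagged_zero(self):
        atab = sk.relative_affinity(toy_table([500, 499, 1, 0]),
                                    toy_background(), min_count=2)
        assert atab.affinity("G") == 0.0
        assert atab.n_below_min_count == 1

    def test_scale_invariance(self):
        a1 = sk.relative_affinity(toy_table([500, 400, 100, 0]),
                                  toy_background(), min_count=1)
        a2 = sk.relative_affinity(toy_table([5000, 4000, 1000, 0]),
                                  toy_background(), min_count=1)
        assert np.allclose(a1.rel_affinity, a2.rel_affinity)

    def test_monotone_in_final_frequency(self):
        atab = sk.relative_affinity(toy_table([100, 200, 300, 400]),
                                    toy_background(), min_count=1)
        # G and T share a background prob; higher count => higher ratio
        assert atab.ratio("T") > atab.ratio("G")

    def test_per_round_root_same_ranking(self, recovery_experiment):
        table, model = recovery_experiment["table"], recovery_experiment["model"]
        flat = sk.relative_affinity(table, model, min_count=2, exponent_mode="ratio")
        rooted = sk.relative_affinity(table, model, min_count=2,
                                      exponent_mode="per_round_root")
        obs = flat.observed_indices()
        assert np.array_equal(np.argsort(flat.raw_ratio[obs], kind="stable"),
                              np.argsort(rooted.raw_ratio[obs], kind="stable"))
        # R-th root relation on the raw values
        assert np.allclose(rooted.raw_ratio[obs],
                           flat.raw_ratio[obs] ** 0.25)

    def test_strand_coherence_exact(self, recovery_experiment):
        atab = recovery_experiment["affinities"]
        rng = np.random.default_rng(0)
        for idx in rng.integers(0, 4 ** 10, 500):
            w = seq.index_to_word(int(idx), 10)
            assert atab.affinity(w) == atab.affinity(seq.revcomp(w))

    def test_requires_round_index(self):
        table = toy_table([10, 10, 10, 10])
        table.round_index = None
        with pytest.raises(ValueError):
            sk.relative_affinity(table, toy_background())

    def test_rejects_negative_min_count(self):
        with pytest.raises(ValueError):
            sk.relative_affinity(toy_table([10, 0, 0, 0]), toy_background(),
                                 min_count=-1)

    def test_tsv_export_contains_top_word(self, tmp_path):
        atab = sk.relative_affinity(toy_table([500, 500, 0, 0]),
                                    toy_background(), min_count=1)
        atab.to_tsv(tmp_path / "a.tsv")
        lines = (tmp_path / "a.tsv").read_text().splitlines()
        header = [l for l in lines if not l.startswith("#")]
        assert header[0] == "word\tcount\traw_ratio\trel_affinity"
        assert header[1].startswith("A\t500\t2\t1")


class TestRecoveryCharacterization:
    """What the ratio estimator genuinely recovers from a simulated
    selection: the top of the landscape, with rank fidelity degrading for
    words whose own binding weight is below the population mean (their
    counts are dominated by co-occurrence with strong sites)."""

    def test_perfect_words_rank_highest(self, recovery_experiment):
        atab = recovery_experiment["affinities"]
        land = recovery_experiment["landscape"]
        perfect = np.flatnonzero(land.values == 1.0)
        perfect = np.unique(seq.canonical_index(perfect, 10))
        obs = atab.observed_indices()
        order = obs[np.argsort(-atab.rel_affinity[obs])]
        top100 = set(order[:100].tolist())
        assert sum(int(i) in top100 for i in perfect) >= 30  # of 36

    def test_class_medians_ordered(self, recovery_experiment):
        atab = recovery_experiment["affinities"]
        land = recovery_experiment["landscape"]
        counts = atab.counts
        med = {}
        for target, label in [(1.0, 0), (0.3 ** 2, 2), (0.3 ** 4, 4)]:
            sel = np.isclose(land.values, target) & (counts >= 10)
            med[label] = float(np.median(atab.rel_affinity[sel]))
        assert med[0] > med[2] > med[4]

    def test_rank_correlation_positive(self, recovery_experiment):
        from scipy import stats

        atab = recovery_experiment["affinities"]
        land = recovery_experiment["landscape"]
        idx = np.flatnonzero(atab.counts >= 10)
        rho = stats.spearmanr(atab.rel_affinity[idx], land.values[idx]).statistic
        assert rho > 0.3


class TestCompare:
    def test_self_comparison_perfect_correlation(self, recovery_experiment):
        atab = recovery_experiment["affinities"]
        comp = sk.compare_affinities(atab, atab)
        assert comp.pearson_r == pytest.approx(1.0)
        assert comp.spearman_rho == pytest.approx(1.0)
        assert comp.log_discordance.max() == 0.0

    def test_replicate_simulations_concordant(self, carg_landscape):
        # two replicates of the same experiment differing only in the
        # sampling seed; at 50k reads/round the well-measured words agree
        tables = []
        for seed in (301, 302):
            config = sk.SimConfig(n_reads_per_round=50_000, n_rounds=2,
                                  stringency=2.0, seed=seed)
            rounds = sk.run_selex(config, carg_landscape)
            model = sk.fit_markov(rounds[0], 6, 1.0, "collapsed")
            table = sk.count_kmers(rounds[-1], 10, "collapsed")
            tables.append(sk.relative_affinity(table, model, min_count=10))
        comp = sk.compare_affinities(tables[0], tables[1])
        assert comp.spearman_rho > 0.8

    def test_mismatched_k_rejected(self, recovery_experiment):
        atab = recovery_experiment["affinities"]
        other = sk.relative_affinity(toy_table([10, 10, 0, 0]),
                                     toy_background(), min_count=1)
        with pytest.raises(ValueError):
            sk.compare_affinities(atab, other)

    def test_disjoint_word_sets_rejected(self):
        a = sk.relative_affinity(toy_table([10, 0, 0, 0]), toy_background(),
                                 min_count=1)
        b = sk.relative_affinity(toy_table([0, 0, 10, 0]), toy_background(),
                                 min_count=1)
        with pytest.raises(ValueError):
            sk.compare_affinities(a, b)

    def test_tsv_and_dotplot_written(self, recovery_experiment, tmp_path):
        atab = recovery_experiment["affinities"]
        comp = sk.compare_affinities(atab, atab)
        comp.to_tsv(tmp_path / "cmp.tsv")
        comp.plot_dotplot(tmp_path / "cmp.png")
        assert (tmp_path / "cmp.tsv").stat().st_size > 0
        assert (tmp_path / "cmp.png").stat().st_size > 0
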