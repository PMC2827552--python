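"""Structure/diversity/prediction matrices against brute-force oracles."""

import copy

import numpy as np
import pytest

from kleevec import datagen, indicator, matrices, seqspace
from kleevec.estimators import SequenceEncoder
from kleevec.indicator import IndicatorVector


def unit_iv(group, values):
    v = np.asarray(values, dtype=float)
    v = v / np.linalg.norm(v)
    return IndicatorVector(group, v, None, 1.0, 1.0)


class TestStructureMatrix:
    def test_diagonal_is_exactly_one(self, small_training_set):
        ivs = indicator.compute_indicators(small_training_set)
        sm = matrices.structure_matrix(
            [ivs[g] for g in small_training_set.group_order])
        np.testing.assert_allclose(np.diag(sm.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(sm.values, sm.values.T, atol=1e-12)
        assert np.all(np.abs(sm.values) <= 1 + 1e-12)

    def test_identical_and_orthogonal_indicators(self):
        a = unit_iv("a", [1, 0, 0, 0])
        b = unit_iv("b", [1, 0, 0, 0])
        c = unit_iv("c", [0, 1, 0, 0])
        sm = matrices.structure_matrix([a, b, c])
        assert sm.values[0, 1] == pytest.approx(1.0)
        assert sm.values[0, 2] == pytest.approx(0.0)

    def test_conjugation_invariance(self, small_training_set):
        ivs = indicator.compute_indicators(small_training_set)
        order = list(small_training_set.group_order)
        sm = matrices.structure_matrix([ivs[g] for g in order])
        perm = order[::-1]
        direct = matrices.structure_matrix([ivs[g] for g in perm])
        np.testing.assert_allclose(sm.permute(perm).values, direct.values,
                                   atol=1e-15)


class TestDiversityMatrix:
    def test_matches_brute_force_double_loop(self, small_training_set):
        ts = small_training_set
        dm = matrices.diversity_matrix(ts)
        G = ts.n_groups
        brute = np.zeros((G, G))
        for i, gk in enumerate(ts.group_order):
            for j, gm in enumerate(ts.group_order):
                acc = [float(u @ v) for u in ts.train_vectors[gk]
                       for v in ts.train_vectors[gm]]
                brute[i, j] = np.mean(acc)
        np.testing.assert_allclose(dm.values, brute, atol=1e-12)

    def test_exclusive_variant_matches_brute_force(self, small_training_set):
        ts = small_training_set
        dm = matrices.diversity_matrix(ts, includes_self_pairs=False)
        g0 = ts.group_order[0]
        U = ts.train_vectors[g0]
        acc = [float(U[i] @ U[j]) for i in range(len(U))
               for j in range(len(U)) if i != j]
        assert dm.values[0, 0] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_identical_members_give_unit_diagonal(self, small_training_set):
        ts = copy.deepcopy(small_training_set)
        g0 = ts.group_order[0]
        ts.train_vectors[g0] = np.tile(ts.train_vectors[g0][:1], (5, 1))
        dm = matrices.diversity_matrix(ts)
        assert dm.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_matches_star_model_expectation(self):
        """Two members of one group differ per site with probability
        p = 2 mu (1-mu) + (2/3) mu^2; diagonal with self-pairs is
        1/N + (1 - 1/N)(1 - p) in expectation."""
        mu, N, n_sites, reps = 0.05, 20, 400, 15
        vals = []
        for seed in range(reps):
            spec = datagen.SimSpec(n_groups=2, seqs_per_group=N,
                                   n_sites=n_sites, within_divergence=mu,
                                   rng_seed=seed)
            aln, manifest, _ = datagen.simulate(spec)
            ts = indicator.split_train_test(
                aln, manifest, indicator.TrainingConfig(N, 0),
                mask=seqspace.SiteMask.from_dropped([], n_sites))
            vals.append(matrices.diversity_matrix(ts).values[0, 0])
        p = 2 * mu * (1 - mu) + (2 / 3) * mu ** 2
        expected = 1 / N + (1 - 1 / N) * (1 - p)
        sem = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - expected) < 3 * max(sem, 1e-4)


class TestPredict:
    def test_indicator_itself_is_assigned_to_its_group(
            self, small_training_set):
        ivs = indicator.compute_indicators(small_training_set)
        ordered = [ivs[g] for g in small_training_set.group_order]
        probe = np.array([ordered[2].unit_form])
        pm = matrices.predict(probe, ordered)
        assert pm.assigned_group == [small_training_set.group_order[2]]

    def test_well_separated_groups_fully_correct(self, small_training_set):
        ts = small_training_set
        ivs = indicator.compute_indicators(ts)
        ordered = [ivs[g] for g in ts.group_order]
        pm = matrices.predict(ts.test_vectors, ordered, ts.test_ids,
                              ts.test_groups)
        rep = matrices.accuracy_report(pm)
        assert rep["overall_accuracy"] == 1.0
        # agreement with a nearest-centroid oracle on the same data
        centroids = np.array([ts.train_vectors[g].mean(axis=0)
                              for g in ts.group_order])
        nearest = np.argmin(
            ((ts.test_vectors[:, None, :] - centroids[None]) ** 2).sum(-1),
            axis=1)
        oracle = [ts.group_order[i] for i in nearest]
        assert oracle == pm.assigned_group

    def test_foreign_sequence_assigned_to_most_correlated(self):
        """A sequence from a group absent from training still lands on its
        most-correlated available indicator, with low max correlation."""
        spec = datagen.SimSpec(n_groups=4, seqs_per_group=6, n_sites=150,
                               rng_seed=9)
        aln, manifest, _ = datagen.simulate(spec)
        held_out = manifest.groups[-1]
        keep = [sid for sid in aln.ids
                if manifest.assignments[sid] != held_out]
        sub = aln.subset(keep)
        mf = type(manifest)({s: manifest.assignments[s] for s in keep})
        mask = seqspace.SiteMask.from_dropped([], aln.n_sites)
        ts = indicator.split_train_test(
            sub, mf, indicator.TrainingConfig(6, 0), mask=mask)
        ivs = indicator.compute_indicators(ts)
        ordered = [ivs[g] for g in ts.group_order]
        foreign = seqspace.encode_matrix(
            [aln.row(s) for s in aln.ids
             if manifest.assignments[s] == held_out])
        pm = matrices.predict(foreign, ordered)
        assert set(pm.assigned_group) <= set(ts.group_order)
        own_max = matrices.predict(ts.train_vectors[ts.group_order[0]],
                                   ordered).values.max(axis=1).mean()
        assert pm.values.max(axis=1).mean() < own_max

    def test_base_order_permutation_invariance(self, small_dataset):
        aln, manifest, _ = small_dataset
        results = []
        for order in [("A", "C", "G", "T"), ("T", "A", "C", "G")]:
            conv = seqspace.EncodingConvention(order)
            ts = indicator.split_train_test(
                aln, manifest, indicator.TrainingConfig(5, 3), conv=conv)
            ivs = indicator.compute_indicators(ts)
            pm = matrices.predict(ts.test_vectors,
                                  [ivs[g] for g in ts.group_order],
                                  ts.test_ids, ts.test_groups)
            results.append((pm.assigned_group, pm.values))
        assert results[0][0] == results[1][0]
        np.testing.assert_allclose(results[0][1], results[1][1], atol=1e-10)


class TestAccuracyReport:
    def test_arithmetic(self):
        ivs = [unit_iv("a", [1, 0]), unit_iv("b", [0, 1])]
        vectors = np.array([[1, 0], [0, 1], [1, 0]], dtype=float)
        pm = matrices.predict(vectors, ivs, ["x", "y", "z"], ["a", "b", "b"])
        rep = matrices.accuracy_report(pm)
        assert rep["overall_accuracy"] == pytest.approx(2 / 3)
        assert rep["errors"][0]["id"] == "z"
        assert rep["errors"][0]["correlation_gap"] == pytest.approx(1.0)
        assert rep["per_group_accuracy"] == {"a": 1.0, "b": 0.5}

    def test_indistinguishable_groups_confine_misassignments(self):
        """Two groups carrying identical sequences yield identical
        indicator vectors; their test members tie (flagged ambiguous) and
        every misassignment stays within that pair."""
        spec = datagen.SimSpec(n_groups=4, seqs_per_group=8, n_sites=150,
                               within_divergence=0.0, rng_seed=13)
        aln, manifest, _ = datagen.simulate(spec)
        shared = aln.rows[aln.ids.index("grp01_s0001")]
        rows = [shared if manifest.assignments[sid] == "grp02" else row
                for sid, row in zip(aln.ids, aln.rows)]
        aln = type(aln)(list(aln.ids), rows)
        ts = indicator.split_train_test(
            aln, manifest, indicator.TrainingConfig(4, 0))
        ivs = indicator.compute_indicators(ts)
        np.testing.assert_array_equal(ivs["grp01"].unit_form,
                                      ivs["grp02"].unit_form)
        ordered = [ivs[g] for g in ts.group_order]
        pm = matrices.predict(ts.test_vectors, ordered, ts.test_ids,
                              ts.test_groups)
        rep = matrices.accuracy_report(pm)
        assert rep["errors"], "the duplicated pair should produce errors"
        for err in rep["errors"]:
            assert {err["true"], err["assigned"]} <= {"grp01", "grp02"}
            assert err["ambiguous"]


class TestOrderByCorrelation:
    def test_most_connected_group_first(self):
        vals = np.array([
            [1.0, 0.9, 0.8],
            [0.9, 1.0, 0.1],
            [0.8, 0.1, 1.0],
        ])
        sm = matrices.StructureMatrix(vals, ["a", "b", "c"])
        assert matrices.order_by_correlation(sm) == ["a", "b", "c"]

    def test_matches_row_sum_sort_oracle(self, rng):
        for _ in range(10):
            G = 6
            A = rng.uniform(-1, 1, size=(G, G))
            vals = (A + A.T) / 2
            np.fill_diagonal(vals, 1.0)
            labels = [f"g{i}" for i in range(G)]
            sm = matrices.StructureMatrix(vals, labels)
            got = matrices.order_by_correlation(sm)
            sums = vals.sum(axis=1) - np.diag(vals)
            oracle = [labels[i] for i in np.argsort(-sums, kind="stable")]
            assert got == oracle

    def test_blocks_preserved(self):
        vals = np.eye(4)
        sm = matrices.StructureMatrix(vals, list("abcd"))
        out = matrices.order_by_correlation(sm, blocks=[["b", "a"], ["d", "c"]])
        assert set(out[:2]) == {"a", "b"} and set(out[2:]) == {"c", "d"}

    def test_singleton_block_unchanged(self):
        sm = matrices.StructureMatrix(np.array([[1.0]]), ["a"])
        assert matrices.order_by_correlation(sm) == ["a"]

    def test_invalid_partition(self):
        sm = matrices.StructureMatrix(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            matrices.order_by_correlation(sm, blocks=[["a"]])
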