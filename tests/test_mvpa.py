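"""Pattern preparation, SVM-RFE decoding, permutations, searchlight."""

import numpy as np
import pytest

from stereosim import mvpa, synthfmri
from stereosim.mvpa import (PatternDataset, permutation_baseline,
                            permute_block_labels, prepare_patterns,
                            reduced_decode, rfe_decode, searchlight)


class TestPreparePatterns:
    def test_within_run_zscoring(self, planted_dataset):
        _, data = planted_dataset
        pat = prepare_patterns(data, ("upright", "random"))
        # re-derive the z-scored run and check the selected samples' source
        run0 = data.runs[0]
        z0 = (run0 - run0.mean(0)) / run0.std(0)
        assert np.allclose(z0.mean(0), 0, atol=1e-8)
        assert np.allclose(z0.std(0), 1, atol=1e-8)
        sel = pat.run_id == 0
        assert pat.samples[sel].shape[1] == run0.shape[1]
        # every selected sample must be a row of the z-scored run
        assert all(np.any(np.all(np.isclose(z0, s), axis=1))
                   for s in pat.samples[sel][:5])

    def test_labels_pooled_and_balanced(self, planted_dataset):
        _, data = planted_dataset
        pat = prepare_patterns(data, ("upright", "inverted"))
        labels, counts = np.unique(pat.labels, return_counts=True)
        assert set(labels) == {"upright", "inverted"}
        assert counts[0] == counts[1]

    def test_shift_moves_labels_by_two_volumes(self, planted_dataset):
        _, data = planted_dataset
        pat = prepare_patterns(data, ("upright", "random"))
        design = data.designs[0]
        raw = design.volume_labels()
        first_upright = next(i for i, l in enumerate(raw) if l.startswith("upright"))
        # the volume attributed to that block starts 2 TRs later
        z = (data.runs[0] - data.runs[0].mean(0)) / data.runs[0].std(0)
        shifted_sample = z[first_upright + 2]
        sel = (pat.run_id == 0) & (pat.labels == "upright")
        assert np.any(np.all(np.isclose(pat.samples[sel], shifted_sample), axis=1))

    def test_zero_variance_voxel_dropped_with_warning(self, planted_dataset):
        _, data = planted_dataset
        bad = [r.copy() for r in data.runs]
        for r in bad:
            r[:, 5] = 1.0
        ds = synthfmri.SyntheticDataset(
            runs=bad, designs=data.designs, motion=data.motion,
            voxel_coords=data.voxel_coords, model=data.model,
            noise_sigma=data.noise_sigma, ar1_rho=data.ar1_rho, seed=None)
        with pytest.warns(UserWarning, match="zero-variance"):
            pat = prepare_patterns(ds, ("upright", "random"))
        assert pat.n_voxels == data.runs[0].shape[1] - 1
        assert 5 not in pat.voxel_ids
        with pytest.raises(ValueError):
            prepare_patterns(ds, ("upright", "random"), zero_variance="error")


def _toy_patterns(n_runs=2, n_per_class=20, n_voxels=30, n_informative=5,
                  effect=2.0, seed=0):
    """Directly constructed PatternDataset with a planted contrast."""
    rng = np.random.default_rng(seed)
    samples, labels, run_id, block_id = [], [], [], []
    block = 0
    for r in range(n_runs):
        for cls, sign in (("a", 1.0), ("b", -1.0)):
            x = rng.standard_normal((n_per_class, n_voxels))
            x[:, :n_informative] += sign * effect
            samples.append(x)
            labels += [cls] * n_per_class
            run_id += [r] * n_per_class
            block_id += [block] * (n_per_class // 2) + [block + 1] * (n_per_class - n_per_class // 2)
            block += 2
    coords = np.argwhere(np.ones((4, 4, 2))).astype(float) * 2.0
    return PatternDataset(samples=np.vstack(samples),
                          labels=np.array(labels, dtype=object),
                          run_id=np.array(run_id), block_id=np.array(block_id),
                          voxel_ids=np.arange(n_voxels),
                          voxel_coords=coords[:n_voxels])


class TestRfeDecode:
    def test_voxel_counts_form_arithmetic_sequence(self):
        pat = _toy_patterns(n_voxels=60, seed=1)
        res, steps = rfe_decode(pat, stop_size=20, seed=2, n_resamples=5)
        counts = [s.voxel_count for s in steps if s.fold == 0]
        assert counts == list(range(55, 15, -5))
        assert counts[-1] == 20
        elim = [set(s.eliminated_voxel_ids) for s in steps if s.fold == 0]
        assert all(len(a & b) == 0 for i, a in enumerate(elim)
                   for b in elim[i + 1:])
        assert res.final_pattern_size == 20

    def test_truncated_final_elimination_hits_stop_size_exactly(self):
        pat = _toy_patterns(n_voxels=33, seed=1)
        res, steps = rfe_decode(pat, stop_size=20, seed=2, n_resamples=3)
        counts = [s.voxel_count for s in steps if s.fold == 0]
        assert counts == [28, 23, 20]  # last step eliminates only 3

    def test_identical_seeds_give_identical_traces(self):
        pat = _toy_patterns(seed=3)
        res1, steps1 = rfe_decode(pat, stop_size=10, seed=7, n_resamples=5)
        res2, steps2 = rfe_decode(pat, stop_size=10, seed=7, n_resamples=5)
        assert res1.final_accuracy == res2.final_accuracy
        assert [s.eliminated_voxel_ids for s in steps1] == \
               [s.eliminated_voxel_ids for s in steps2]

    def test_planted_voxels_survive_with_high_accuracy(self):
        pat = _toy_patterns(n_voxels=40, n_informative=5, effect=2.5, seed=4)
        res, steps = rfe_decode(pat, stop_size=10, seed=5, n_resamples=5)
        for fold in np.unique([s.fold for s in steps]):
            eliminated = {v for s in steps if s.fold == fold
                          for v in s.eliminated_voxel_ids}
            assert set(range(5)) & eliminated == set()  # recall 1.0
        assert res.final_accuracy > 0.95

    def test_null_labels_decode_at_chance(self):
        accs = []
        for seed in range(15):
            pat = _toy_patterns(n_voxels=25, effect=0.0, seed=seed)
            res, _ = rfe_decode(pat, stop_size=10, seed=seed + 100, n_resamples=3)
            accs.append(res.final_accuracy)
        mean = np.mean(accs)
        # chance level with a generous Monte-Carlo margin
        assert abs(mean - 0.5) < 0.1

    def test_fold_containment_training_unaffected_by_test_data(self):
        pat = _toy_patterns(seed=6)
        _, steps_clean = rfe_decode(pat, stop_size=10, seed=8, n_resamples=5)
        poisoned = PatternDataset(
            samples=pat.samples.copy(), labels=pat.labels, run_id=pat.run_id,
            block_id=pat.block_id, voxel_ids=pat.voxel_ids,
            voxel_coords=pat.voxel_coords)
        poisoned.samples[pat.run_id == 1] = 1e3  # garbage in the held-out run
        _, steps_poisoned = rfe_decode(poisoned, stop_size=10, seed=8,
                                       n_resamples=5)
        clean0 = [s.eliminated_voxel_ids for s in steps_clean if s.fold == 1]
        pois0 = [s.eliminated_voxel_ids for s in steps_poisoned if s.fold == 1]
        assert clean0 == pois0  # elimination driven by training runs only

    def test_stop_size_too_large_rejected(self):
        pat = _toy_patterns(n_voxels=20)
        with pytest.raises(ValueError):
            rfe_decode(pat, stop_size=20, seed=0)

    def test_accuracy_nondecreasing_in_effect_size(self):
        means = []
        for effect in (0.0, 0.5, 1.5):
            accs = [reduced_decode(_toy_patterns(effect=effect, seed=s),
                                   stop_size=None).final_accuracy
                    for s in range(10)]
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.05 <= means[2] + 0.10
        assert means[2] > means[0]


class TestPermutation:
    def test_block_permutation_preserves_class_balance(self):
        pat = _toy_patterns(seed=9)
        rng = np.random.default_rng(0)
        for _ in range(10):
            new = permute_block_labels(pat, rng)
            for r in pat.runs:
                orig = np.sort(pat.labels[pat.run_id == r])
                perm = np.sort(new[pat.run_id == r])
                assert np.array_equal(orig, perm)

    def test_blocks_keep_uniform_labels(self):
        pat = _toy_patterns(seed=10)
        new = permute_block_labels(pat, np.random.default_rng(1))
        for b in np.unique(pat.block_id):
            assert len(set(new[pat.block_id == b])) == 1

    def test_identity_labels_reproduce_observed_accuracy(self):
        pat = _toy_patterns(seed=11, effect=2.0)
        observed = reduced_decode(pat, stop_size=10).final_accuracy
        same = reduced_decode(pat.with_labels(pat.labels.copy()),
                              stop_size=10).final_accuracy
        assert observed == same

    def test_null_mean_near_half_and_baseline_above(self):
        pat = _toy_patterns(seed=12, effect=0.0)
        null = permutation_baseline(pat, n=100, seed=13, stop_size=10)
        assert abs(null.null_accuracies.mean() - 0.5) < 0.08
        assert null.baseline >= 0.5 - 0.05
        assert null.n_permutations == 100

    def test_small_n_warns(self):
        pat = _toy_patterns(seed=14)
        with pytest.warns(UserWarning, match="small"):
            permutation_baseline(pat, n=10, seed=0, stop_size=10)


class TestSearchlight:
    def test_sphere_voxel_count_matches_lattice_enumeration(self):
        # brute-force: lattice points with 2-mm pitch inside a 6-mm ball
        count = sum(1 for i in range(-3, 4) for j in range(-3, 4)
                    for k in range(-3, 4)
                    if (2 * i) ** 2 + (2 * j) ** 2 + (2 * k) ** 2 <= 36)
        assert count == 123

        rng = np.random.default_rng(0)
        coords = np.argwhere(np.ones((7, 7, 7))).astype(float) * 2.0
        n_vox = coords.shape[0]
        n = 8
        pat = PatternDataset(
            samples=rng.standard_normal((4 * n, n_vox)),
            labels=np.array(["a", "b"] * (2 * n), dtype=object),
            run_id=np.repeat([0, 1], 2 * n),
            block_id=np.repeat(np.arange(8), n // 2),
            voxel_ids=np.arange(n_vox), voxel_coords=coords)
        sl = searchlight(pat, radius_mm=6.0)
        center_idx = int(np.flatnonzero(np.all(coords == 6.0, axis=1))[0])
        assert sl.n_voxels_per_sphere[center_idx] == 123
        assert sl.accuracies.shape == (n_vox,)
        assert np.all((sl.accuracies >= 0) & (sl.accuracies <= 1))

    def test_planted_signal_peaks_at_its_sphere(self):
        rng = np.random.default_rng(1)
        coords = np.argwhere(np.ones((6, 6, 2))).astype(float) * 2.0
        n_vox = coords.shape[0]
        target = int(np.flatnonzero(np.all(coords == [2.0, 2.0, 0.0], axis=1))[0])
        far = int(np.flatnonzero(np.all(coords == [10.0, 10.0, 2.0], axis=1))[0])
        n = 16
        x = rng.standard_normal((4 * n, n_vox))
        labels = np.array(["a", "b"] * (2 * n), dtype=object)
        x[labels == "a", target] += 8.0
        pat = PatternDataset(
            samples=x, labels=labels, run_id=np.repeat([0, 1], 2 * n),
            block_id=np.repeat(np.arange(8), n // 2),
            voxel_ids=np.arange(n_vox), voxel_coords=coords)
        sl = searchlight(pat, radius_mm=3.0)
        assert sl.accuracies[target] > 0.9
        assert sl.accuracies[target] > sl.accuracies[far]

    def test_missing_coordinates_rejected(self):
        pat = _toy_patterns()
        pat.voxel_coords = None
        with pytest.raises(ValueError):
            searchlight(pat)


def test_null_effect_dataset_decodes_at_chance(null_dataset):
    pat = prepare_patterns(null_dataset, ("upright", "random"))
    res = reduced_decode(pat, stop_size=None)
    assert 0.3 < res.final_accuracy < 0.7
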