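"""Multivoxel pattern analysis: z-scoring and hemodynamic label shifting,
leave-one-run-out linear SVM decoding with recursive feature elimination
(RFE), block-level permutation baselines, and searchlight mapping.

The RFE loop follows the ROI decoding recipe: within each cross-validation
fold, the classifier is trained on 20 resamples of 80% of the training
samples (drawn without regard to block boundaries), each voxel's weight is
averaged over the resamples, the five lowest-ranked voxels are eliminated,
and the surviving pattern is scored on the held-out run; elimination stops
when exactly ``stop_size`` voxels (250 by default) remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.svm import SVC

from .synthfmri import SyntheticDataset

__all__ = [
    "PatternDataset",
    "RfeStep",
    "CvResult",
    "PermutationNull",
    "SearchlightMap",
    "prepare_patterns",
    "rfe_decode",
    "reduced_decode",
    "permutation_baseline",
    "searchlight",
]

HRF_SHIFT_TRS = 2


def _make_svm(c: float = 1.0) -> SVC:
    # libsvm linear machine, soft margin fixed at C = 1 (no per-fold tuning)
    return SVC(kernel="linear", C=c)


@dataclass
class PatternDataset:
    """Labeled multivoxel samples with run/block structure.

    Samples are individual (hemodynamically shifted) volumes within
    stimulus blocks; every voxel is z-scored within run over the full run
    time course.
    """

    samples: np.ndarray  # (n_samples, n_voxels)
    labels: np.ndarray  # condition per sample
    run_id: np.ndarray
    block_id: np.ndarray
    voxel_ids: np.ndarray
    voxel_coords: np.ndarray | None = None
    shift_applied_trs: int = HRF_SHIFT_TRS

    def __post_init__(self) -> None:
        n = self.samples.shape[0]
        if not (len(self.labels) == len(self.run_id) == len(self.block_id) == n):
            raise ValueError("sample metadata lengths differ")

    @property
    def n_voxels(self) -> int:
        return self.samples.shape[1]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_id)

    def subset_voxels(self, idx: np.ndarray) -> "PatternDataset":
        return PatternDataset(
            samples=self.samples[:, idx], labels=self.labels,
            run_id=self.run_id, block_id=self.block_id,
            voxel_ids=self.voxel_ids[idx],
            voxel_coords=None if self.voxel_coords is None else self.voxel_coords[idx],
            shift_applied_trs=self.shift_applied_trs)

    def with_labels(self, labels: np.ndarray) -> "PatternDataset":
        return PatternDataset(
            samples=self.samples, labels=np.asarray(labels),
            run_id=self.run_id, block_id=self.block_id,
            voxel_ids=self.voxel_ids, voxel_coords=self.voxel_coords,
            shift_applied_trs=self.shift_applied_trs)


def prepare_patterns(dataset: SyntheticDataset, pair: tuple[str, str],
                     shift_trs: int = HRF_SHIFT_TRS,
                     zero_variance: str = "drop") -> PatternDataset:
    """Z-score, shift, and select volumes of the two target conditions.

    Each voxel's time course is converted to z scores within run; labels
    are shifted by 2 TRs (4 s) to absorb the hemodynamic delay, i.e. the
    volume acquired 2 TRs after a block's onset is the first attributed to
    it; volumes whose shifted label falls in one of the two target
    conditions (stimulus genders pooled) are retained as samples.

    ``zero_variance``: 'drop' removes constant voxels with a warning,
    'error' raises.
    """
    if dataset.n_runs < 2:
        raise ValueError("need >= 2 runs")
    sample_rows, labels, run_ids, block_ids = [], [], [], []
    zero_var_voxels: set[int] = set()
    z_runs = []
    for r, sig in enumerate(dataset.runs):
        mean = sig.mean(axis=0)
        sd = sig.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd == 0)
        zero_var_voxels.update(zero.tolist())
        sd_safe = np.where(sd == 0, 1.0, sd)
        z_runs.append((sig - mean) / sd_safe)
    if zero_var_voxels:
        if zero_variance == "error":
            raise ValueError(f"zero-variance voxels: {sorted(zero_var_voxels)}")
        warnings.warn(f"dropping {len(zero_var_voxels)} zero-variance voxel(s)")
    keep = np.setdiff1d(np.arange(dataset.runs[0].shape[1]),
                        np.array(sorted(zero_var_voxels), dtype=int))

    for r, z in enumerate(z_runs):
        design = dataset.designs[r]
        cond = np.array([b if b == "fixation" else b.rsplit("_", 1)[0]
                         for b in design.volume_labels()], dtype=object)
        blocks = design.volume_block_ids()
        shifted_cond = np.concatenate([np.full(shift_trs, "fixation", dtype=object),
                                       cond[:len(cond) - shift_trs]])
        shifted_block = np.concatenate([np.full(shift_trs, -1, dtype=int),
                                        blocks[:len(blocks) - shift_trs]])
        sel = np.isin(shifted_cond, pair)
        if not np.isin(shifted_cond[sel], pair[0]).any() or \
           not np.isin(shifted_cond[sel], pair[1]).any():
            raise ValueError(f"run {r} lacks one of the conditions {pair}")
        sample_rows.append(z[sel][:, keep])
        labels.append(shifted_cond[sel])
        run_ids.append(np.full(sel.sum(), r))
        block_ids.append(shifted_block[sel])
    return PatternDataset(
        samples=np.vstack(sample_rows),
        labels=np.concatenate(labels).astype(object),
        run_id=np.concatenate(run_ids),
        block_id=np.concatenate(block_ids),
        voxel_ids=keep,
        voxel_coords=None if dataset.voxel_coords is None else dataset.voxel_coords[keep],
        shift_applied_trs=shift_trs)


@dataclass(frozen=True)
class RfeStep:
    fold: int
    step_index: int
    voxel_count: int
    eliminated_voxel_ids: tuple[int, ...]
    test_accuracy: float


@dataclass
class CvResult:
    fold_accuracies: list[float]
    final_accuracy: float
    final_pattern_size: int
    pair: tuple[str, str]


def _accuracy(clf: SVC, x: np.ndarray, y: np.ndarray) -> float:
    return float((clf.predict(x) == y).mean())


def rfe_decode(patterns: PatternDataset, stop_size: int = 250,
               seed: int | np.random.Generator | None = None,
               n_resamples: int = 20, resample_fraction: float = 0.8,
               eliminate_per_step: int = 5, c: float = 1.0,
               ranking: str = "abs_mean") -> tuple[CvResult, list[RfeStep]]:
    """Leave-one-run-out decoding with recursive feature elimination.

    Per fold: repeatedly (a) draw ``n_resamples`` resamples of 80% of the
    training samples ignoring block boundaries, (b) train a linear SVM on
    each, (c) average each surviving voxel's weight across resamples,
    (d) eliminate the 5 voxels with the lowest-ranked weights (ties broken
    toward the lower voxel id), and (e) score the surviving pattern on the
    held-out run — until exactly ``stop_size`` voxels remain (the last
    elimination is truncated if needed).  The final accuracy is the mean
    across folds at ``stop_size``.

    ``ranking``: 'abs_mean' ranks by |mean signed weight| (default);
    'mean_abs' by the mean of absolute weights.
    """
    if stop_size >= patterns.n_voxels:
        raise ValueError("stop_size must be smaller than the initial voxel count")
    if ranking not in ("abs_mean", "mean_abs"):
        raise ValueError("ranking must be 'abs_mean' or 'mean_abs'")
    rng = np.random.default_rng(seed)
    classes = np.unique(patterns.labels)
    if classes.size != 2:
        raise ValueError(f"expected a 2-class problem, got {classes}")
    fold_acc, steps = [], []
    for fold, test_run in enumerate(patterns.runs):
        train = patterns.run_id != test_run
        xtr_full, ytr = patterns.samples[train], patterns.labels[train]
        xte, yte = patterns.samples[~train], patterns.labels[~train]
        n_train = xtr_full.shape[0]
        n_sub = max(2, int(round(resample_fraction * n_train)))
        active = np.arange(patterns.n_voxels)
        step_index = 0
        last_acc = np.nan
        while active.size > stop_size:
            weights = np.zeros((n_resamples, active.size))
            for s in range(n_resamples):
                idx = rng.choice(n_train, size=n_sub, replace=False)
                while np.unique(ytr[idx]).size < 2:  # resample must contain both classes
                    idx = rng.choice(n_train, size=n_sub, replace=False)
                clf = _make_svm(c).fit(xtr_full[idx][:, active], ytr[idx])
                weights[s] = clf.coef_.ravel()
            if ranking == "abs_mean":
                score = np.abs(weights.mean(axis=0))
            else:
                score = np.abs(weights).mean(axis=0)
            n_elim = min(eliminate_per_step, active.size - stop_size)
            order = np.lexsort((patterns.voxel_ids[active], score))
            eliminated = active[order[:n_elim]]
            active = np.setdiff1d(active, eliminated)
            clf = _make_svm(c).fit(xtr_full[:, active], ytr)
            last_acc = _accuracy(clf, xte[:, active], yte)
            steps.append(RfeStep(
                fold=fold, step_index=step_index, voxel_count=active.size,
                eliminated_voxel_ids=tuple(patterns.voxel_ids[eliminated]),
                test_accuracy=last_acc))
            step_index += 1
        fold_acc.append(last_acc)
    result = CvResult(fold_accuracies=fold_acc,
                      final_accuracy=float(np.mean(fold_acc)),
                      final_pattern_size=stop_size,
                      pair=tuple(classes))
    return result, steps


def reduced_decode(patterns: PatternDataset, stop_size: int | None = 250,
                   c: float = 1.0) -> CvResult:
    """Single-pass decoding: one ranking step to ``stop_size``, then score.

    Per leave-one-run-out fold the SVM is trained once on the full
    training set, the ``stop_size`` voxels with the largest |weights| are
    kept, and the refit classifier is scored on the held-out run.  With
    ``stop_size`` None (or >= the voxel count) this is plain leave-one-
    run-out decoding.  Used as the tractable decoder inside permutation
    baselines.
    """
    classes = np.unique(patterns.labels)
    fold_acc = []
    for test_run in patterns.runs:
        train = patterns.run_id != test_run
        xtr, ytr = patterns.samples[train], patterns.labels[train]
        xte, yte = patterns.samples[~train], patterns.labels[~train]
        active = np.arange(patterns.n_voxels)
        if stop_size is not None and stop_size < active.size:
            clf = _make_svm(c).fit(xtr, ytr)
            score = np.abs(clf.coef_.ravel())
            order = np.lexsort((patterns.voxel_ids, -score))
            active = np.sort(order[:stop_size])
        clf = _make_svm(c).fit(xtr[:, active], ytr)
        fold_acc.append(_accuracy(clf, xte[:, active], yte))
    size = patterns.n_voxels if stop_size is None else min(stop_size, patterns.n_voxels)
    return CvResult(fold_accuracies=fold_acc, final_accuracy=float(np.mean(fold_acc)),
                    final_pattern_size=size, pair=tuple(classes))


def permute_block_labels(patterns: PatternDataset,
                         rng: np.random.Generator) -> np.ndarray:
    """Permute condition labels at the block level within each run.

    Every sample of a block keeps a common label; the multiset of block
    labels within each run is preserved, so class balance is too.
    """
    new_labels = np.array(patterns.labels, dtype=object)
    for run in patterns.runs:
        in_run = patterns.run_id == run
        blocks = np.unique(patterns.block_id[in_run])
        block_label = {b: patterns.labels[in_run & (patterns.block_id == b)][0]
                       for b in blocks}
        permuted = rng.permutation([block_label[b] for b in blocks])
        for b, lab in zip(blocks, permuted):
            new_labels[in_run & (patterns.block_id == b)] = lab
    return new_labels


@dataclass
class PermutationNull:
    n_permutations: int
    null_accuracies: np.ndarray
    baseline: float  # 95th percentile of the null by default
    seed: int | None


def permutation_baseline(patterns: PatternDataset, n: int = 1000,
                         seed: int | np.random.Generator | None = None,
                         decoder: str = "reduced", stop_size: int | None = 250,
                         rfe_kwargs: dict | None = None,
                         summary_percentile: float = 95.0) -> PermutationNull:
    """Null accuracy distribution from decoding with shuffled labels.

    Labels are permuted at block level within run and the decoding
    pipeline re-run per permutation.  ``decoder`` selects the reduced
    single-pass pipeline (default, tractable at n = 1000) or the exact
    RFE pipeline ('rfe').  The baseline summary is the 95th percentile of
    the null accuracies.
    """
    if n < 100:
        warnings.warn(f"n = {n} permutations is small; baseline will be noisy")
    rng = np.random.default_rng(seed)
    stop = None if stop_size is None or stop_size >= patterns.n_voxels else stop_size
    null = np.empty(n)
    for i in range(n):
        shuffled = patterns.with_labels(permute_block_labels(patterns, rng))
        if decoder == "reduced":
            null[i] = reduced_decode(shuffled, stop).final_accuracy
        elif decoder == "rfe":
            res, _ = rfe_decode(shuffled, stop_size=stop or patterns.n_voxels - 5,
                                seed=rng, **(rfe_kwargs or {}))
            null[i] = res.final_accuracy
        else:
            raise ValueError("decoder must be 'reduced' or 'rfe'")
    return PermutationNull(
        n_permutations=n, null_accuracies=null,
        baseline=float(np.percentile(null, summary_percentile)),
        seed=None if isinstance(seed, np.random.Generator) else seed)


@dataclass
class SearchlightMap:
    accuracies: np.ndarray  # per center voxel
    centers: np.ndarray  # (n_voxels, 3) mm
    radius_mm: float
    n_voxels_per_sphere: np.ndarray


def searchlight(patterns: PatternDataset, radius_mm: float = 6.0,
                c: float = 1.0, min_sphere_voxels: int = 2) -> SearchlightMap:
    """Leave-one-run-out decoding in a sphere around every voxel.

    For each center, the voxels within Euclidean distance ``radius_mm``
    form the feature set (no RFE); the fold-mean accuracy is written at
    the center.  On a 2-mm grid a 6-mm sphere holds 123 voxels at
    interior centers.
    """
    if patterns.voxel_coords is None:
        raise ValueError("patterns carry no voxel coordinates")
    tree = cKDTree(patterns.voxel_coords)
    n = patterns.n_voxels
    acc = np.empty(n)
    counts = np.empty(n, dtype=int)
    for v in range(n):
        sphere = np.array(sorted(tree.query_ball_point(patterns.voxel_coords[v],
                                                       radius_mm)))
        counts[v] = sphere.size
        if sphere.size < min_sphere_voxels:
            raise ValueError(f"sphere at voxel {v} holds {sphere.size} voxel(s)")
        acc[v] = reduced_decode(patterns.subset_voxels(sphere),
                                stop_size=None, c=c).final_accuracy
    return SearchlightMap(accuracies=acc, centers=patterns.voxel_coords.copy(),
                          radius_mm=radius_mm, n_voxels_per_sphere=counts)
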