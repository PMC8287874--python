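"""Synthetic data generation: face-like depth maps, block-design run
schedules, and condition-structured multivoxel BOLD time series.

The generator emulates the acquisition side of a block-design scanning
session: each run holds 12 stimulus blocks (6 block types = 3 stimulus
conditions x 2 genders, each repeated twice, order randomized) strictly
interleaved with 13 fixation blocks, every block lasting 16 s.  A stimulus
block contains 8 trials (500 ms stimulus + 1500 ms response) balanced
between near and far depth positions, so a run has 96 trials, lasts
400 s, and yields 200 retained volumes at TR = 2 s (205 acquired, first 5
discarded as start-up transients — recorded as metadata, not simulated).

Voxel time series are built from known ground truth: per condition, a
spatial amplitude pattern (% signal change) is multiplied into the HRF-
convolved condition boxcar and summed, then Gaussian (optionally AR(1))
noise, an optional linear drift, and smooth random-walk motion nuisance
series are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .glm import HrfParams, two_gamma_hrf
from .stimgen import DepthMap, make_oval_mask

__all__ = [
    "Block",
    "RunDesign",
    "VoxelPatternModel",
    "SyntheticDataset",
    "make_face_like_depth_map",
    "make_run_design",
    "simulate_timeseries",
    "BLOCK_TYPES",
    "CONDITIONS",
]

CONDITIONS = ("upright", "inverted", "random")
GENDERS = ("female", "male")
BLOCK_TYPES = tuple(f"{c}_{g}" for c in CONDITIONS for g in GENDERS)
BLOCK_S = 16.0
TR_S = 2.0
TRIALS_PER_BLOCK = 8
DUMMY_VOLUMES = 5


def make_face_like_depth_map(seed: int | np.random.Generator | None = None,
                             grid_size: tuple[int, int] = (96, 68),
                             pixels_per_degree: float = 14.9,
                             smoothness: float | None = None,
                             n_features: int = 4) -> DepthMap:
    """Smooth, oval-masked random surface standing in for a face depth map.

    A heavily low-pass-filtered noise field (power concentrated well below
    a quarter of the Nyquist frequency) is combined with a few localized
    Gaussian protrusions/indentations placed in a loosely face-like
    arrangement (central protrusion, paired upper indentations).  The oval
    mask is applied and the amplitude normalized so max |depth| = 1.
    Distinct seeds give distinct maps.
    """
    rows, cols = grid_size
    if rows < 64 or cols < 64:
        raise ValueError("grid must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    sigma = smoothness if smoothness is not None else min(rows, cols) / 8.0
    base = gaussian_filter(rng.standard_normal((rows, cols)), sigma, mode="wrap")

    r = (np.arange(rows)[:, None] + 0.5) / rows  # 0 = top
    c = (np.arange(cols)[None, :] + 0.5) / cols
    features = np.zeros((rows, cols))
    # central protrusion (nose-like) and two upper indentations (orbit-like)
    centers = [(0.55, 0.5, +1.0, 0.10), (0.35, 0.33, -0.6, 0.09),
               (0.35, 0.67, -0.6, 0.09)]
    for k in range(max(0, n_features - 3)):
        centers.append((float(rng.uniform(0.25, 0.8)), float(rng.uniform(0.25, 0.75)),
                        float(rng.uniform(-0.5, 0.5)), float(rng.uniform(0.06, 0.12))))
    for (cr, cc, amp, width) in centers[:n_features]:
        features += amp * np.exp(-(((r - cr) ** 2 + (c - cc) ** 2) / (2 * width ** 2)))

    base = base / np.abs(base).max() if np.abs(base).max() > 0 else base
    surface = base + features
    mask = make_oval_mask((rows, cols))
    surface = np.where(mask, surface, 0.0)
    surface = surface / np.abs(surface).max()
    return DepthMap(values=surface, mask=mask, pixels_per_degree=pixels_per_degree)


@dataclass(frozen=True)
class Block:
    block_type: str  # one of BLOCK_TYPES or "fixation"
    onset_s: float
    duration_s: float = BLOCK_S

    @property
    def condition(self) -> str:
        return "fixation" if self.block_type == "fixation" else self.block_type.rsplit("_", 1)[0]


@dataclass
class RunDesign:
    """One run: 12 stimulus + 13 fixation blocks, fixation-bookended."""

    blocks: list[Block]
    trials: pd.DataFrame  # block_index, trial_index, onset_s, depth_position
    tr_s: float = TR_S
    dummy_volumes: int = DUMMY_VOLUMES

    @property
    def duration_s(self) -> float:
        last = self.blocks[-1]
        return last.onset_s + last.duration_s

    @property
    def n_volumes(self) -> int:
        """Volumes retained for analysis (dummies already discarded)."""
        return int(round(self.duration_s / self.tr_s))

    @property
    def n_volumes_acquired(self) -> int:
        return self.n_volumes + self.dummy_volumes

    def volume_labels(self) -> np.ndarray:
        """Block type of each retained volume."""
        labels = np.empty(self.n_volumes, dtype=object)
        t = np.arange(self.n_volumes) * self.tr_s
        for b in self.blocks:
            labels[(t >= b.onset_s) & (t < b.onset_s + b.duration_s)] = b.block_type
        return labels

    def volume_block_ids(self) -> np.ndarray:
        ids = np.empty(self.n_volumes, dtype=int)
        t = np.arange(self.n_volumes) * self.tr_s
        for i, b in enumerate(self.blocks):
            ids[(t >= b.onset_s) & (t < b.onset_s + b.duration_s)] = i
        return ids

    def condition_onsets(self, pool_genders: bool = True) -> dict[str, list[float]]:
        onsets: dict[str, list[float]] = {}
        for b in self.blocks:
            if b.block_type == "fixation":
                continue
            key = b.condition if pool_genders else b.block_type
            onsets.setdefault(key, []).append(b.onset_s)
        return onsets

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset": [b.onset_s for b in self.blocks],
            "duration": [b.duration_s for b in self.blocks],
            "block_type": [b.block_type for b in self.blocks],
        })


def make_run_design(seed: int | np.random.Generator | None = None) -> RunDesign:
    """Randomized block schedule for one run.

    Each of the 6 stimulus block types appears exactly twice in random
    order; fixation blocks interleave and bookend, giving 25 blocks of
    16 s (400 s, 200 retained volumes) and 96 trials with 4 near + 4 far
    per stimulus block.
    """
    rng = np.random.default_rng(seed)
    stim_order = list(BLOCK_TYPES) * 2
    rng.shuffle(stim_order)
    blocks: list[Block] = []
    t = 0.0
    for bt in stim_order:
        blocks.append(Block("fixation", t)); t += BLOCK_S
        blocks.append(Block(bt, t)); t += BLOCK_S
    blocks.append(Block("fixation", t))

    trial_rows = []
    trial_dur = 2.0  # 500 ms stimulus + 1500 ms response
    for bi, b in enumerate(blocks):
        if b.block_type == "fixation":
            continue
        positions = ["near"] * (TRIALS_PER_BLOCK // 2) + ["far"] * (TRIALS_PER_BLOCK // 2)
        rng.shuffle(positions)
        for k, pos in enumerate(positions):
            trial_rows.append({"block_index": bi, "trial_index": k,
                               "onset_s": b.onset_s + k * trial_dur,
                               "block_type": b.block_type,
                               "depth_position": pos})
    return RunDesign(blocks=blocks, trials=pd.DataFrame(trial_rows))


@dataclass
class VoxelPatternModel:
    """Ground-truth spatial activation patterns for the synthetic ROI.

    ``mean_pattern`` maps each condition to a voxel amplitude vector in %
    signal change; ``informative_set`` indexes the voxels whose amplitudes
    differ between conditions; ``voxel_coords`` are 3D mm positions used
    by the searchlight.
    """

    n_voxels: int
    mean_pattern: dict[str, np.ndarray]
    informative_set: np.ndarray
    effect_size: float
    voxel_coords: np.ndarray  # (n_voxels, 3) in mm

    @classmethod
    def planted(cls, n_voxels: int = 200, n_informative: int = 20,
                effect_size: float = 1.0,
                conditions: tuple[str, ...] = CONDITIONS,
                informative_pairs: tuple[tuple[str, str], ...] | None = None,
                seed: int | np.random.Generator | None = None,
                grid_shape: tuple[int, int, int] = (10, 10, 10),
                voxel_pitch_mm: float = 2.0) -> "VoxelPatternModel":
        """Random baseline pattern with a planted condition contrast.

        All voxels share a common baseline response to any stimulus block;
        ``n_informative`` voxels additionally separate the conditions with
        amplitudes +/- effect_size/2 in opposite directions per condition.
        Coordinates are the first ``n_voxels`` points of a 2-mm grid.
        """
        rng = np.random.default_rng(seed)
        coords_full = np.argwhere(np.ones(grid_shape)) * voxel_pitch_mm
        if n_voxels > coords_full.shape[0]:
            raise ValueError("grid too small for requested voxel count")
        coords = coords_full[:n_voxels].astype(float)
        baseline = rng.normal(0.5, 0.1, n_voxels)
        informative = rng.choice(n_voxels, size=n_informative, replace=False)
        pattern = {}
        for ci, cond in enumerate(conditions):
            amp = baseline.copy()
            # spread conditions on a signed ladder centred on zero
            offset = (ci - (len(conditions) - 1) / 2.0) * effect_size
            signs = np.where(np.arange(n_informative) % 2 == 0, 1.0, -1.0)
            amp[informative] += offset * signs
            pattern[cond] = amp
        return cls(n_voxels=n_voxels, mean_pattern=pattern,
                   informative_set=np.sort(informative),
                   effect_size=effect_size, voxel_coords=coords)


@dataclass
class SyntheticDataset:
    """Multi-run synthetic BOLD dataset with ground truth attached."""

    runs: list[np.ndarray]  # each (n_volumes, n_voxels)
    designs: list[RunDesign]
    motion: list[np.ndarray]  # each (n_volumes, 6)
    voxel_coords: np.ndarray
    model: VoxelPatternModel | None
    noise_sigma: float
    ar1_rho: float
    seed: int | None

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def labels(self, run: int) -> np.ndarray:
        return self.designs[run].volume_labels()


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               sigma: float, rho: float) -> np.ndarray:
    white = rng.standard_normal(shape) * sigma
    if rho == 0.0:
        return white
    out = np.empty_like(white)
    out[0] = white[0] / np.sqrt(1 - rho ** 2)
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + white[t]
    return out


def _smooth_random_walk(rng: np.random.Generator, n: int, scale: float = 0.02) -> np.ndarray:
    return gaussian_filter(np.cumsum(rng.normal(0, scale, n)), 4.0, mode="nearest")


def simulate_timeseries(model: VoxelPatternModel,
                        n_runs: int = 8,
                        noise_sigma: float = 1.0,
                        ar1_rho: float = 0.0,
                        baseline_offset: float = 100.0,
                        drift_amplitude: float = 0.0,
                        hrf: HrfParams = HrfParams(),
                        seed: int | np.random.Generator | None = None,
                        designs: list[RunDesign] | None = None) -> SyntheticDataset:
    """Simulate condition-structured voxel time series for several runs.

    Per voxel, signal = baseline + sum over conditions of (boxcar ⊛
    two-gamma HRF) x pattern amplitude, plus Gaussian noise (white, or
    AR(1) when ``ar1_rho`` > 0) and an optional linear drift, with smooth
    random-walk motion nuisance series generated alongside.  The default
    baseline of 100 makes raw pattern amplitudes read directly as percent
    signal change after constant-term normalization.  Requires >= 2 runs
    so that leave-one-run-out analyses are possible downstream.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out analyses")
    rng = np.random.default_rng(seed)
    kernel = two_gamma_hrf(hrf, TR_S)
    runs, run_designs, motions = [], [], []
    for r in range(n_runs):
        design = designs[r] if designs is not None else make_run_design(rng)
        nv = design.n_volumes
        onsets = design.condition_onsets(pool_genders=True)
        signal = np.full((nv, model.n_voxels), float(baseline_offset))
        t = np.arange(nv) * design.tr_s
        for cond, amp in model.mean_pattern.items():
            box = np.zeros(nv)
            for onset in onsets.get(cond, []):
                box[(t >= onset) & (t < onset + BLOCK_S)] = 1.0
            reg = np.convolve(box, kernel)[:nv]
            signal += np.outer(reg, amp)
        if noise_sigma > 0:
            signal += _ar1_noise(rng, signal.shape, noise_sigma, ar1_rho)
        if drift_amplitude != 0.0:
            signal += drift_amplitude * np.linspace(0, 1, nv)[:, None]
        motion = np.column_stack([_smooth_random_walk(rng, nv) for _ in range(6)])
        runs.append(signal)
        run_designs.append(design)
        motions.append(motion)
    return SyntheticDataset(runs=runs, designs=run_designs, motion=motions,
                            voxel_coords=model.voxel_coords, model=model,
                            noise_sigma=noise_sigma, ar1_rho=ar1_rho,
                            seed=None if isinstance(seed, np.random.Generator) else seed)
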