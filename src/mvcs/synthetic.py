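"""Synthetic study generator with known ground truth.

Real data for this kind of experiment (theta-burst stimulation of the
DLPFC crossed with sequential vs. random motor practice, imaged with
pre-task rest, task, and post-task rest fMRI runs) cannot be shared, so
every downstream stage of the package is exercised on synthetic studies
whose pattern persistence is known by construction.

Each ROI run is a low-rank factor model: voxel ``v`` follows

    y_v(t) = sum_k W[v, k] * s_k(t) + drift_v(t) + gamma_v . nuisance(t) + eps_v(t)

with smooth unit-variance factor time courses ``s_k``, low-frequency
drift, nuisance signals shared with the WM/CSF pools, and white noise.
The noiseless voxel-by-voxel correlation structure is determined by the
loading matrix ``W`` alone, so *pattern persistence* between two runs is
implemented by loading mixing:

    W_B = sqrt(rho) * W_A + sqrt(1 - rho) * W_new   (columns renormalized)

``rho = 0`` gives independent structure, ``rho = 1`` identical structure.
Condition effects on persistence are additive shifts of ``rho`` on a
product-coded scale (task +1/2 for SEQ, stimulation +1/2 for cTBS).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import BlockSpan, MotionParams, RoiTimeSeries
from .exceptions import ConfigError

__all__ = [
    "SiEffects",
    "BehaviorParams",
    "GeneratorConfig",
    "RunBundle",
    "ConditionData",
    "GroundTruth",
    "SyntheticStudy",
    "PAIRINGS",
    "CONDITIONS",
    "condition_codes",
    "mix_loadings",
    "random_loadings",
    "generate_roi_run",
    "generate_motion",
    "generate_behavior",
    "generate_experiment",
    "task_schedule",
]

#: The three run pairings an SI is computed for.
PAIRINGS = ("early_late", "rs_pre_post", "task_rs_post")

#: The 2x2 within-subject crossing of stimulation {cTBS, iTBS} and task
#: {SEQ, RND}.
CONDITIONS = ("cSEQ", "cRND", "iSEQ", "iRND")

_COND_FACTORS = {
    "cSEQ": ("cTBS", "SEQ"),
    "cRND": ("cTBS", "RND"),
    "iSEQ": ("iTBS", "SEQ"),
    "iRND": ("iTBS", "RND"),
}


def condition_codes(condition: str) -> tuple[float, float]:
    """Product codes (x_stim, x_task): +1/2 for cTBS / SEQ, -1/2 otherwise."""
    stim, task = _COND_FACTORS[condition]
    return (0.5 if stim == "cTBS" else -0.5, 0.5 if task == "SEQ" else -0.5)


@dataclass(frozen=True)
class SiEffects:
    """Additive condition effects on pattern persistence (rho scale).

    With product coding (+1/2 SEQ, +1/2 cTBS), a task effect ``t`` shifts
    each cell's rho by ``t * x_task``, a stimulation effect likewise, and
    an interaction ``i`` by ``i * x_task * x_stim`` (cells +/- i/4).
    """

    task: float = 0.0
    stimulation: float = 0.0
    interaction: float = 0.0

    def shift(self, condition: str) -> float:
        x_stim, x_task = condition_codes(condition)
        return (
            self.task * x_task
            + self.stimulation * x_stim
            + self.interaction * x_task * x_stim
        )


@dataclass(frozen=True)
class BehaviorParams:
    """Key-press model: lognormal RTs around an exponential learning curve.

    SEQ block means follow ``A + B * exp(-lambda * (block - 1))``; RND
    block means stay flat at ``A + B``.  Units: ms.
    """

    rt_baseline_ms: float = 350.0  # A, asymptotic RT
    rt_learning_ms: float = 150.0  # B, amplitude of the learning curve
    learning_rate: float = 0.35  # lambda, per block
    rt_sigma: float = 0.20  # lognormal shape of single presses
    accuracy: float = 0.95  # per-press probability of a correct key
    sequence: tuple[int, ...] = (4, 7, 3, 8, 6, 2, 5, 1)


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic study.

    Defaults emulate the study design: 19 subjects, four within-subject
    conditions (cTBS/iTBS x SEQ/RND) in counterbalanced visit order, two
    300-volume resting runs at TR 1 s flanking a 16-block task run at
    TR 2 s, and ROIs of a few hundred voxels.
    """

    n_subjects: int = 19
    rois: Mapping[str, int] = field(
        default_factory=lambda: {
            "dlpfc": 250,
            "hippocampus": 300,
            "putamen_assoc": 180,
            "putamen_sens": 140,
        }
    )
    # run geometry
    rest_volumes: int = 300
    rest_tr: float = 1.0
    task_tr: float = 2.0
    n_blocks: int = 16
    presses_per_block: int = 48
    rest_block_s: float = 15.0
    press_interval_s: float = 0.55
    # pattern model
    n_factors: int = 5
    factor_smooth_s: float = 6.0
    persistence_rho: Mapping[str, float] = field(
        default_factory=lambda: {
            "early_late": 0.5,
            "rs_pre_post": 0.35,
            "task_rs_post": 0.25,
        }
    )
    si_effects: SiEffects = field(default_factory=SiEffects)
    # nuisance model
    drift_amplitude: float = 2.0
    noise_sd: float = 1.5
    n_nuisance_latent: int = 3
    nuisance_pool_size: int = 20
    nuisance_gamma_sd: float = 0.5
    pool_noise_sd: float = 0.3
    gm_low_fraction: float = 0.08
    # motion model
    spike_prob: float = 0.02
    spike_mag: float = 1.0
    walk_sd_mm: float = 0.01
    walk_sd_rad: float = 2e-4
    # behavior
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    seed: int = 0

    def validate(self) -> None:
        def _count(name: str, value: int) -> None:
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value}")

        _count("n_subjects", self.n_subjects)
        _count("rest_volumes", self.rest_volumes)
        _count("n_blocks", self.n_blocks)
        _count("presses_per_block", self.presses_per_block)
        _count("n_factors", self.n_factors)
        if not self.rois:
            raise ConfigError("rois must name at least one ROI")
        for roi, n_vox in self.rois.items():
            _count(f"rois[{roi!r}]", n_vox)
        for name, tr in (("rest_tr", self.rest_tr), ("task_tr", self.task_tr)):
            if not tr > 0:
                raise ConfigError(f"{name} must be positive, got {tr}")
        for pairing in PAIRINGS:
            if pairing not in self.persistence_rho:
                raise ConfigError(f"persistence_rho missing pairing {pairing!r}")
            rho = self.persistence_rho[pairing]
            if not 0.0 <= rho <= 1.0:
                raise ConfigError(
                    f"persistence_rho[{pairing!r}] must be in [0, 1], got {rho}"
                )
        for name, p in (
            ("spike_prob", self.spike_prob),
            ("behavior.accuracy", self.behavior.accuracy),
            ("gm_low_fraction", self.gm_low_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name, v in (
            ("noise_sd", self.noise_sd),
            ("drift_amplitude", self.drift_amplitude),
            ("spike_mag", self.spike_mag),
            ("walk_sd_mm", self.walk_sd_mm),
            ("walk_sd_rad", self.walk_sd_rad),
            ("nuisance_gamma_sd", self.nuisance_gamma_sd),
            ("pool_noise_sd", self.pool_noise_sd),
            ("press_interval_s", self.press_interval_s),
            ("rest_block_s", self.rest_block_s),
        ):
            if v < 0:
                raise ConfigError(f"{name} must be non-negative, got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rois"] = dict(self.rois)
        d["persistence_rho"] = dict(self.persistence_rho)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "si_effects" in d and isinstance(d["si_effects"], Mapping):
            d["si_effects"] = SiEffects(**d["si_effects"])
        if "behavior" in d and isinstance(d["behavior"], Mapping):
            b = dict(d["behavior"])
            if "sequence" in b:
                b["sequence"] = tuple(b["sequence"])
            d["behavior"] = BehaviorParams(**b)
        return cls(**d)


@dataclass
class RunBundle:
    """One run's data: per-ROI time series, motion, and tissue pools."""

    roi_ts: dict[str, RoiTimeSeries]
    motion: MotionParams
    wm_pool: np.ndarray
    csf_pool: np.ndarray


@dataclass
class ConditionData:
    """All runs and behavior of one subject x condition session."""

    pre: RunBundle | None
    task: RunBundle | None
    post: RunBundle | None
    keypresses: pd.DataFrame | None


@dataclass
class GroundTruth:
    """Hidden generator parameters, for recovery tests.

    ``table`` has one row per subject x condition x roi x pairing with
    the persistence actually used (after condition effects and clipping).
    """

    table: pd.DataFrame
    si_effects: SiEffects


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    design: pd.DataFrame  # subject, visit, stimulation, task, condition
    data: dict[tuple[str, str], ConditionData]
    gm_prob: dict[tuple[str, str], np.ndarray]  # (subject, roi) -> per voxel
    ground_truth: GroundTruth

    @property
    def subjects(self) -> list[str]:
        return sorted(self.design["subject"].unique().tolist())


# ---------------------------------------------------------------------------
# building blocks


def _normalize_columns(w: np.ndarray) -> np.ndarray:
    """Scale each column to norm sqrt(n_voxels) (entries ~ unit scale)."""
    norms = np.linalg.norm(w, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return w / norms * np.sqrt(w.shape[0])


def random_loadings(
    n_voxels: int, n_factors: int, rng: np.random.Generator
) -> np.ndarray:
    return _normalize_columns(rng.standard_normal((n_voxels, n_factors)))


def mix_loadings(
    w_shared: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """sqrt(rho)*W_shared + sqrt(1-rho)*W_new, columns renormalized."""
    if not 0.0 <= rho <= 1.0:
        raise ConfigError(f"persistence rho must be in [0, 1], got {rho}")
    w_new = random_loadings(w_shared.shape[0], w_shared.shape[1], rng)
    return _normalize_columns(
        np.sqrt(rho) * w_shared + np.sqrt(1.0 - rho) * w_new
    )


def _smooth_signals(
    n_volumes: int, n_signals: int, tr: float, smooth_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Moving-average-smoothed white noise, standardized per column."""
    window = max(1, int(round(smooth_s / tr)))
    x = rng.standard_normal((n_volumes + window - 1, n_signals))
    if window > 1:
        csum = np.cumsum(x, axis=0)
        x = np.empty((n_volumes, n_signals))
        x[0] = csum[window - 1] / window
        x[1:] = (csum[window:] - csum[:-window]) / window
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return x / sd


def generate_roi_run(
    n_voxels: int,
    n_volumes: int,
    tr: float,
    loadings: np.ndarray,
    *,
    drift_amplitude: float = 2.0,
    noise_sd: float = 1.5,
    factor_smooth_s: float = 6.0,
    nuisance_signals: np.ndarray | None = None,
    nuisance_gamma_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    voxel_ids: np.ndarray | None = None,
    block_annotations: tuple[BlockSpan, ...] | None = None,
) -> RoiTimeSeries:
    """One ROI run from the factor model (see module docstring).

    ``nuisance_signals`` (volumes x signals), if given, are added with
    per-voxel random weights so that nuisance regression has shared
    structure to remove.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_volumes < 2:
        raise ConfigError(f"a run needs at least 2 volumes, got {n_volumes}")
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[0] != n_voxels:
        raise ConfigError(
            f"loadings rows ({loadings.shape[0]}) != n_voxels ({n_voxels})"
        )
    n_factors = loadings.shape[1]
    factors = _smooth_signals(n_volumes, n_factors, tr, factor_smooth_s, rng)
    data = factors @ loadings.T
    if drift_amplitude > 0:
        t = np.arange(n_volumes) * tr
        span = max(t[-1], 1.0)
        period = rng.uniform(160.0, 360.0)  # below the 1/128 Hz cutoff
        phase = rng.uniform(0, 2 * np.pi)
        shapes = np.column_stack(
            [t / span - 0.5, np.cos(2 * np.pi * t / period + phase)]
        )
        coeffs = rng.normal(0.0, drift_amplitude, size=(2, n_voxels))
        data = data + shapes @ coeffs
    if nuisance_signals is not None and nuisance_gamma_sd > 0:
        nuisance_signals = np.asarray(nuisance_signals, dtype=float)
        if nuisance_signals.shape[0] != n_volumes:
            raise ConfigError("nuisance_signals rows must equal n_volumes")
        gamma = rng.normal(
            0.0, nuisance_gamma_sd, size=(nuisance_signals.shape[1], n_voxels)
        )
        data = data + nuisance_signals @ gamma
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return RoiTimeSeries(
        data,
        tr=tr,
        voxel_ids=voxel_ids,
        block_annotations=block_annotations,
    )


def generate_motion(
    n_volumes: int,
    spike_prob: float = 0.02,
    spike_mag: float = 1.0,
    *,
    walk_sd_mm: float = 0.01,
    walk_sd_rad: float = 2e-4,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> MotionParams:
    """Slow random-walk trajectories plus occasional sustained step spikes.

    Each spike is a sustained offset of ``spike_mag`` mm on one random
    translation axis, so it produces exactly one framewise-displacement
    exceedance; the expected exceedance fraction is therefore close to
    ``spike_prob``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not 0.0 <= spike_prob <= 1.0:
        raise ConfigError(f"spike_prob must be in [0, 1], got {spike_prob}")
    steps = np.hstack(
        [
            rng.normal(0.0, walk_sd_mm, size=(n_volumes, 3)),
            rng.normal(0.0, walk_sd_rad, size=(n_volumes, 3)),
        ]
    )
    steps[0] = 0.0
    values = np.cumsum(steps, axis=0)
    spikes = rng.random(n_volumes) < spike_prob
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        values[t:, axis] += sign * spike_mag
    return MotionParams(values)


def task_schedule(
    n_blocks: int,
    presses_per_block: int,
    press_interval_s: float,
    rest_block_s: float,
    tr: float,
) -> tuple[tuple[BlockSpan, ...], int]:
    """Practice/rest spans of a task run and its volume count.

    Each block is ``presses_per_block * press_interval_s`` seconds of
    practice followed by a rest block; the run has one volume every TR
    within the total span.
    """
    spans: list[BlockSpan] = []
    t = 0.0
    practice_s = presses_per_block * press_interval_s
    for b in range(1, n_blocks + 1):
        spans.append(BlockSpan("practice", b, t, t + practice_s))
        t += practice_s
        spans.append(BlockSpan("rest", b, t, t + rest_block_s))
        t += rest_block_s
    n_volumes = int(np.ceil(t / tr))
    return tuple(spans), n_volumes


def generate_behavior(
    task: str,
    n_blocks: int = 16,
    presses_per_block: int = 48,
    params: BehaviorParams | None = None,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Key-press log for one session: block, press, keys, correctness, RT."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if params is None:
        params = BehaviorParams()
    if task not in ("SEQ", "RND"):
        raise ConfigError(f"task must be 'SEQ' or 'RND', got {task!r}")
    if n_blocks < 1 or presses_per_block < 1:
        raise ConfigError("n_blocks and presses_per_block must be >= 1")
    a, b, lam = (
        params.rt_baseline_ms,
        params.rt_learning_ms,
        params.learning_rate,
    )
    rows: list[tuple] = []
    seq = np.asarray(params.sequence, dtype=int)
    keys = np.arange(1, 9)
    for block in range(1, n_blocks + 1):
        if task == "SEQ":
            block_mean = a + b * np.exp(-lam * (block - 1))
            reps = int(np.ceil(presses_per_block / seq.size))
            targets = np.tile(seq, reps)[:presses_per_block]
        else:
            block_mean = a + b
            n_windows = int(np.ceil(presses_per_block / 8))
            targets = np.concatenate(
                [rng.permutation(keys) for _ in range(n_windows)]
            )[:presses_per_block]
        z = rng.standard_normal(presses_per_block)
        rt = block_mean * np.exp(
            params.rt_sigma * z - params.rt_sigma**2 / 2.0
        )
        correct = rng.random(presses_per_block) < params.accuracy
        pressed = targets.copy()
        for i in np.flatnonzero(~correct):
            wrong = keys[keys != targets[i]]
            pressed[i] = wrong[rng.integers(0, wrong.size)]
        for i in range(presses_per_block):
            rows.append(
                (block, i + 1, int(targets[i]), int(pressed[i]),
                 bool(correct[i]), float(rt[i]))
            )
    return pd.DataFrame(
        rows,
        columns=["block", "press", "target_key", "pressed_key", "correct",
                 "rt_ms"],
    )


# ---------------------------------------------------------------------------
# full experiment


def _latin_square_design(n_subjects: int) -> pd.DataFrame:
    """Counterbalanced visit order: cyclic Latin square over 4 conditions."""
    rows = []
    for s in range(n_subjects):
        subject = f"sub-{s + 1:02d}"
        for visit in range(1, 5):
            cond = CONDITIONS[(s + visit - 1) % 4]
            stim, task = _COND_FACTORS[cond]
            rows.append((subject, visit, stim, task, cond))
    return pd.DataFrame(
        rows, columns=["subject", "visit", "stimulation", "task", "condition"]
    )


def _clip_rho(rho: float) -> float:
    return float(min(1.0, max(0.0, rho)))


def _condition_rhos(
    config: GeneratorConfig, condition: str
) -> dict[str, float]:
    shift = config.si_effects.shift(condition)
    rhos = {
        p: _clip_rho(config.persistence_rho[p] + shift) for p in PAIRINGS
    }
    # The post-rest run shares structure with both the task run and the
    # pre-rest run; the two shared fractions cannot exceed 1 together.
    total = rhos["rs_pre_post"] + rhos["task_rs_post"]
    if total > 1.0:
        scale = 1.0 / total
        rhos["rs_pre_post"] *= scale
        rhos["task_rs_post"] *= scale
    return rhos


def _nuisance_set(
    config: GeneratorConfig, n_volumes: int, tr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent nuisance signals and the WM/CSF pools that expose them."""
    latent = _smooth_signals(
        n_volumes, config.n_nuisance_latent, tr, 10.0, rng
    )
    pools = []
    for _ in range(2):
        mix = rng.standard_normal(
            (config.n_nuisance_latent, config.nuisance_pool_size)
        )
        noise = rng.normal(
            0.0, config.pool_noise_sd,
            size=(n_volumes, config.nuisance_pool_size),
        )
        pools.append(latent @ mix + noise)
    return latent, pools[0], pools[1]


def _make_rest_bundle(
    config: GeneratorConfig,
    loadings: Mapping[str, np.ndarray],
    voxel_ids: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> RunBundle:
    n = config.rest_volumes
    latent, wm, csf = _nuisance_set(config, n, config.rest_tr, rng)
    roi_ts = {
        roi: generate_roi_run(
            config.rois[roi], n, config.rest_tr, loadings[roi],
            drift_amplitude=config.drift_amplitude,
            noise_sd=config.noise_sd,
            factor_smooth_s=config.factor_smooth_s,
            nuisance_signals=latent,
            nuisance_gamma_sd=config.nuisance_gamma_sd,
            rng=rng,
            voxel_ids=voxel_ids[roi],
        )
        for roi in config.rois
    }
    motion = generate_motion(
        n, config.spike_prob, config.spike_mag,
        walk_sd_mm=config.walk_sd_mm, walk_sd_rad=config.walk_sd_rad, rng=rng,
    )
    return RunBundle(roi_ts, motion, wm, csf)


def _make_task_bundle(
    config: GeneratorConfig,
    loadings_early: Mapping[str, np.ndarray],
    loadings_late: Mapping[str, np.ndarray],
    voxel_ids: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> RunBundle:
    spans, n = task_schedule(
        config.n_blocks, config.presses_per_block, config.press_interval_s,
        config.rest_block_s, config.task_tr,
    )
    half_block = config.n_blocks // 2
    boundary_s = max(s.end_s for s in spans if s.block <= half_block)
    times = np.arange(n) * config.task_tr
    n_early = int(np.sum(times < boundary_s))
    n_late = n - n_early
    latent, wm, csf = _nuisance_set(config, n, config.task_tr, rng)
    roi_ts = {}
    for roi in config.rois:
        early = generate_roi_run(
            config.rois[roi], n_early, config.task_tr, loadings_early[roi],
            drift_amplitude=config.drift_amplitude,
            noise_sd=config.noise_sd,
            factor_smooth_s=config.factor_smooth_s,
            nuisance_signals=latent[:n_early],
            nuisance_gamma_sd=config.nuisance_gamma_sd,
            rng=rng,
            voxel_ids=voxel_ids[roi],
        )
        late = generate_roi_run(
            config.rois[roi], n_late, config.task_tr, loadings_late[roi],
            drift_amplitude=config.drift_amplitude,
            noise_sd=config.noise_sd,
            factor_smooth_s=config.factor_smooth_s,
            nuisance_signals=latent[n_early:],
            nuisance_gamma_sd=config.nuisance_gamma_sd,
            rng=rng,
            voxel_ids=voxel_ids[roi],
        )
        roi_ts[roi] = RoiTimeSeries(
            np.vstack([early.data, late.data]),
            tr=config.task_tr,
            voxel_ids=voxel_ids[roi],
            block_annotations=spans,
        )
    motion = generate_motion(
        n, config.spike_prob, config.spike_mag,
        walk_sd_mm=config.walk_sd_mm, walk_sd_rad=config.walk_sd_rad, rng=rng,
    )
    return RunBundle(roi_ts, motion, wm, csf)


def generate_experiment(
    config: GeneratorConfig,
    *,
    runs: tuple[str, ...] = ("pre", "task", "post"),
    include_behavior: bool = True,
) -> SyntheticStudy:
    """Generate a complete synthetic study.

    The loading matrices of the five pattern states (pre rest, early
    task, late task, whole-task average, post rest) are tied together by
    the configured persistence values: late practice shares
    ``rho[early_late]`` of its structure with early practice, and the
    post-rest run mixes the whole-task structure (``rho[task_rs_post]``)
    with the pre-rest structure (``rho[rs_pre_post]``).

    ``runs`` can restrict generation to a subset of the three runs (the
    pattern states are drawn identically either way, so a restricted
    study is a projection of the full one).
    """
    config.validate()
    design = _latin_square_design(config.n_subjects)
    ss = np.random.SeedSequence(config.seed)
    gm_seed, *cond_seeds = ss.spawn(1 + config.n_subjects * len(CONDITIONS))
    gm_rng = np.random.default_rng(gm_seed)

    voxel_ids = {
        roi: np.array([f"{roi}_v{i:04d}" for i in range(n_vox)])
        for roi, n_vox in config.rois.items()
    }
    gm_prob: dict[tuple[str, str], np.ndarray] = {}
    subjects = [f"sub-{s + 1:02d}" for s in range(config.n_subjects)]
    for subject in subjects:
        for roi, n_vox in config.rois.items():
            p = gm_rng.beta(8.0, 1.5, size=n_vox)
            low = gm_rng.random(n_vox) < config.gm_low_fraction
            p[low] = gm_rng.uniform(0.0, 0.1, size=int(low.sum()))
            gm_prob[(subject, roi)] = p

    data: dict[tuple[str, str], ConditionData] = {}
    gt_rows = []
    k = 0
    for subject in subjects:
        for condition in CONDITIONS:
            rng = np.random.default_rng(cond_seeds[k])
            k += 1
            rhos = _condition_rhos(config, condition)
            w_pre, w_early, w_late, w_post = {}, {}, {}, {}
            for roi, n_vox in config.rois.items():
                w_pre[roi] = random_loadings(n_vox, config.n_factors, rng)
                w_early[roi] = random_loadings(n_vox, config.n_factors, rng)
                w_late[roi] = mix_loadings(
                    w_early[roi], rhos["early_late"], rng
                )
                w_task_mid = _normalize_columns(w_early[roi] + w_late[roi])
                rho_tp = rhos["task_rs_post"]
                rho_pp = rhos["rs_pre_post"]
                w_new = random_loadings(n_vox, config.n_factors, rng)
                w_post[roi] = _normalize_columns(
                    np.sqrt(rho_tp) * w_task_mid
                    + np.sqrt(rho_pp) * w_pre[roi]
                    + np.sqrt(max(0.0, 1.0 - rho_tp - rho_pp)) * w_new
                )
                for pairing in PAIRINGS:
                    gt_rows.append(
                        (subject, condition, roi, pairing, rhos[pairing])
                    )
            pre = (
                _make_rest_bundle(config, w_pre, voxel_ids, rng)
                if "pre" in runs else None
            )
            task_bundle = (
                _make_task_bundle(config, w_early, w_late, voxel_ids, rng)
                if "task" in runs else None
            )
            post = (
                _make_rest_bundle(config, w_post, voxel_ids, rng)
                if "post" in runs else None
            )
            _, task_name = _COND_FACTORS[condition]
            keypresses = (
                generate_behavior(
                    task_name, config.n_blocks, config.presses_per_block,
                    config.behavior, rng=rng,
                )
                if include_behavior else None
            )
            data[(subject, condition)] = ConditionData(
                pre, task_bundle, post, keypresses
            )

    ground_truth = GroundTruth(
        pd.DataFrame(
            gt_rows,
            columns=["subject", "condition", "roi", "pairing", "rho"],
        ),
        config.si_effects,
    )
    return SyntheticStudy(config, design, data, gm_prob, ground_truth)
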