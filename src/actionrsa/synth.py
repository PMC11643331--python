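"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analyses assume: a
stimulus set of categories x exemplars, a named set of model geometries,
and per-subject, per-session response-pattern tables whose noiseless
split-data RDM is a known weighted mixture of the model RDMs.

Model geometries are *correlation* geometries: each model is a latent
feature configuration (category structure plus exemplar noise) that is
balanced -- column-centered, whitened, and row-standardized to a fixed
point -- and its RDM is the correlation distance ``1 - F F'`` of the
balanced configuration.  Because split-data neural RDMs are themselves
correlation distances of (z-scored) patterns, composing subject patterns by
concatenating sqrt-weight-scaled model blocks makes the noiseless neural
similarity exactly the weighted sum of model similarities, and unit
z-scoring is a no-op in distribution.  See docs/methods.md for why the more
obvious route (metric-scaling a mixture RDM) distorts the recovered
geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Stimulus, StimulusSet, SubsetPlan
from .rdm import RDM, ArrangementTrial, GazeTrajectory

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "make_stimulus_set",
    "make_latent_configuration",
    "make_model_geometries",
    "simulate_subject_patterns",
    "simulate_arrangements",
    "simulate_gaze",
    "simulate_annotations",
    "make_grid_neighborhoods",
    "make_bundle",
]


@dataclass
class GroundTruth:
    """The generating conditions for a synthetic study."""

    latent_configurations: dict[str, np.ndarray]  # model -> balanced (m, fdim)
    mixture_weights: dict[str, float]
    noise_sd: float
    n_subjects: int
    n_sessions: int
    n_units: int
    seed: int
    stimulus_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for name, w in self.mixture_weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight for {name!r} must be finite and >= 0")
        if self.stimulus_ids is None:
            m = next(iter(self.latent_configurations.values())).shape[0]
            self.stimulus_ids = [f"stim{i:03d}" for i in range(m)]

    @property
    def latent_model_rdms(self) -> dict[str, "RDM"]:
        return {
            name: _corr_rdm_of(F, self.stimulus_ids, name)
            for name, F in self.latent_configurations.items()
        }


@dataclass
class SyntheticBundle:
    stimulus_set: StimulusSet
    patterns: dict[tuple[int, int], pd.DataFrame]  # (subject, session) -> table
    model_rdms: dict[str, RDM]
    ground_truth: GroundTruth
    arrangements: dict[str, list[ArrangementTrial]] = field(default_factory=dict)
    gaze: list[GazeTrajectory] = field(default_factory=list)
    annotations: dict | None = None
    embeddings: pd.DataFrame | None = None
    neighborhoods: dict[int, list[int]] | None = None


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def make_stimulus_set(
    n_categories: int = 18,
    n_exemplars: int = 5,
    social_fraction: float = 0.5,
) -> StimulusSet:
    """Build a categories x exemplars stimulus set (90 stimuli by default)."""
    if n_categories < 1 or n_exemplars < 1:
        raise ValueError("n_categories and n_exemplars must be >= 1")
    n_social = int(round(social_fraction * n_categories))
    stimuli = []
    for c in range(n_categories):
        cat = f"cat{c:02d}"
        for e in range(1, n_exemplars + 1):
            stimuli.append(
                Stimulus(
                    stimulus_id=f"{cat}_ex{e}",
                    category=cat,
                    exemplar_index=e,
                    is_social=c < n_social,
                )
            )
    return StimulusSet(stimuli=stimuli)


# ---------------------------------------------------------------------------
# model geometries
# ---------------------------------------------------------------------------

def _row_standardize(F: np.ndarray) -> np.ndarray:
    F = F - F.mean(axis=1, keepdims=True)
    return F / np.linalg.norm(F, axis=1, keepdims=True)


def _balance(F: np.ndarray, n_iter: int = 30, eig_floor: float = 1e-3) -> np.ndarray:
    """Iterate column-center / whiten / row-standardize to a fixed point.

    The balanced configuration has (approximately) zero column means,
    isotropic column covariance, and unit row norms, so unit z-scoring of
    patterns built from it changes nothing but scale.
    """
    F = _row_standardize(np.asarray(F, dtype=float))
    m = F.shape[0]
    for _ in range(n_iter):
        F = F - F.mean(axis=0)
        S = F.T @ F / m
        lam, V = np.linalg.eigh(S)
        lam = np.maximum(lam, lam.max() * eig_floor)
        F = F @ (V * lam**-0.5) @ V.T
        F = _row_standardize(F)
    return F


def _corr_rdm_of(F: np.ndarray, ids: list[str], name: str) -> RDM:
    mat = 1.0 - F @ F.T
    np.fill_diagonal(mat, 0.0)
    mat = np.clip(mat, 0.0, None)
    return RDM(ids, mat, {"source": "model", "model": name})


def make_latent_configuration(
    stimulus_set: StimulusSet,
    rng: np.random.Generator,
    feature_dim: int = 8,
    exemplar_scale: float = 0.6,
    shared: np.ndarray | None = None,
    shared_mix: float = 0.0,
) -> np.ndarray:
    """Balanced latent features: category means plus exemplar noise.

    With ``shared_mix = a`` the raw features are ``sqrt(a) * shared +
    sqrt(1-a) * own``, which induces a controllable correlation between the
    resulting model RDMs.
    """
    cats = stimulus_set.categories
    cat_idx = {c: i for i, c in enumerate(cats)}
    centers = rng.normal(size=(len(cats), feature_dim))
    U = np.stack(
        [
            centers[cat_idx[s.category]]
            + rng.normal(size=feature_dim) * exemplar_scale
            for s in stimulus_set.stimuli
        ]
    )
    if shared is not None and shared_mix > 0:
        U = np.sqrt(shared_mix) * shared + np.sqrt(1.0 - shared_mix) * U
    return _balance(U)


def make_model_geometries(
    stimulus_set: StimulusSet,
    inter_model_correlation: float = 0.0,
    rng_seed: int = 0,
    model_names: tuple[str, ...] = ("sociality", "transitivity", "object", "nuisance"),
    feature_dim: int = 8,
    exemplar_scale: float = 0.6,
) -> tuple[dict[str, RDM], dict[str, np.ndarray]]:
    """Named model RDMs with controlled pairwise Spearman correlation.

    Each model is a balanced latent configuration; the mean pairwise Spearman
    correlation between model-RDM vectors is steered to
    ``inter_model_correlation`` (within about 0.1) by bisecting on the
    shared-component mixing weight.  Returns (RDMs, latent configurations).
    """
    if not 0 <= inter_model_correlation < 1:
        raise ValueError("inter_model_correlation must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    ids = stimulus_set.stimulus_ids
    # category-structured shared component
    cats = stimulus_set.categories
    cat_idx = {c: i for i, c in enumerate(cats)}
    shared_centers = rng.normal(size=(len(cats), feature_dim))
    shared_raw = np.stack(
        [
            shared_centers[cat_idx[s.category]] + rng.normal(size=feature_dim) * exemplar_scale
            for s in stimulus_set.stimuli
        ]
    )
    child_seeds = rng.integers(0, 2**31 - 1, size=len(model_names))

    def build(mix: float) -> dict[str, np.ndarray]:
        return {
            name: make_latent_configuration(
                stimulus_set,
                np.random.default_rng(int(s)),
                feature_dim=feature_dim,
                exemplar_scale=exemplar_scale,
                shared=shared_raw,
                shared_mix=mix,
            )
            for name, s in zip(model_names, child_seeds)
        }

    def mean_pairwise_rho(configs: dict[str, np.ndarray]) -> float:
        from scipy.stats import spearmanr

        vecs = [_corr_rdm_of(F, ids, n).vector for n, F in configs.items()]
        if len(vecs) < 2:
            return 0.0
        rhos = [
            spearmanr(vecs[i], vecs[j]).statistic
            for i in range(len(vecs))
            for j in range(i + 1, len(vecs))
        ]
        return float(np.mean(rhos))

    if len(model_names) < 2 or inter_model_correlation == 0.0:
        configs = build(0.0)
    else:
        lo, hi = 0.0, 0.999
        configs = build(0.0)
        for _ in range(12):
            mid = (lo + hi) / 2
            configs = build(mid)
            rho = mean_pairwise_rho(configs)
            if abs(rho - inter_model_correlation) < 0.02:
                break
            if rho < inter_model_correlation:
                lo = mid
            else:
                hi = mid
    rdms = {name: _corr_rdm_of(F, ids, name) for name, F in configs.items()}
    return rdms, configs


# ---------------------------------------------------------------------------
# subject patterns
# ---------------------------------------------------------------------------

def simulate_subject_patterns(
    ground_truth: GroundTruth,
    stimulus_set: StimulusSet | None = None,
) -> dict[tuple[int, int], pd.DataFrame]:
    """Per-subject, per-session condition x unit pattern tables.

    The composite signal concatenates each model's balanced configuration
    scaled by the square root of its normalized weight, maps it to unit
    space through a shared orthonormal map, and adds independent Gaussian
    noise per subject x session x unit at ``noise_sd``.  Each unit's profile
    is z-scored across conditions (population SD).
    """
    gt = ground_truth
    names = list(gt.latent_configurations)
    w = np.array([gt.mixture_weights[n] for n in names], dtype=float)
    if w.sum() <= 0:
        raise ValueError("at least one mixture weight must be positive")
    w = w / w.sum()
    F = np.concatenate(
        [np.sqrt(wm) * gt.latent_configurations[n] for wm, n in zip(w, names)],
        axis=1,
    )
    m, k = F.shape
    if k > gt.n_units:
        raise ValueError(f"latent dimension {k} exceeds n_units {gt.n_units}")
    rng = np.random.default_rng(gt.seed)
    Q, _ = np.linalg.qr(rng.normal(size=(gt.n_units, k)))
    # scale so each unit carries signal variance ~ 1/k (SNR is then
    # 1/(k * noise_sd^2) per unit); orthogonality keeps the latent
    # geometry exact under the map
    signal = F @ (Q.T * np.sqrt(gt.n_units / k))  # (m, n_units)
    if stimulus_set is not None:
        ids = stimulus_set.stimulus_ids
    else:
        ids = [f"stim{i:03d}" for i in range(m)]
    cols = [f"unit{u:04d}" for u in range(gt.n_units)]
    out: dict[tuple[int, int], pd.DataFrame] = {}
    for s in range(gt.n_subjects):
        for sess in range(gt.n_sessions):
            pat = signal + rng.normal(size=signal.shape) * gt.noise_sd
            mu = pat.mean(axis=0)
            sd = pat.std(axis=0)
            const = sd == 0
            if const.any():  # pragma: no cover - needs exact ties
                warnings.warn("constant unit profile(s) zeroed", stacklevel=2)
            pat = (pat - mu) / np.where(const, 1.0, sd)
            pat[:, const] = 0.0
            out[(s, sess)] = pd.DataFrame(pat, index=ids, columns=cols)
    return out


# ---------------------------------------------------------------------------
# arrangements
# ---------------------------------------------------------------------------

def simulate_arrangements(
    behavior_rdm: RDM,
    subset_plan: SubsetPlan,
    placement_noise_sd: float = 0.0,
    arena_radius: float = 400.0,
    rng_seed: int = 0,
    task: str = "task",
    participant: str = "p0",
) -> list[ArrangementTrial]:
    """Arrangement trials: 2D metric scaling of each sub-RDM plus jitter.

    Each subset is laid out by classical metric scaling of its sub-RDM,
    randomly rotated/reflected, scaled so the farthest stimulus sits at the
    arena edge, and jittered with isotropic Gaussian noise.
    """
    rng = np.random.default_rng(rng_seed)
    trials = []
    for t_idx, subset in enumerate(subset_plan.subsets):
        sub = behavior_rdm.subset(subset)
        coords = _cmdscale_2d(sub.matrix)
        # random rotation and (possibly) reflection
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        if rng.random() < 0.5:
            rot = rot @ np.diag([1.0, -1.0])
        coords = coords @ rot.T
        r = np.linalg.norm(coords, axis=1).max()
        if r > 0:
            coords *= arena_radius / r
        coords = coords + rng.normal(size=coords.shape) * placement_noise_sd
        trials.append(
            ArrangementTrial(
                task=task,
                subset=list(subset),
                coords=coords,
                participant=participant,
                trial_index=t_idx,
            )
        )
    return trials


def _cmdscale_2d(D: np.ndarray) -> np.ndarray:
    m = D.shape[0]
    J = np.eye(m) - 1.0 / m
    B = -0.5 * J @ (D**2) @ J
    lam, V = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1][:2]
    lam2 = np.clip(lam[order], 0.0, None)
    return V[:, order] * np.sqrt(lam2)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def simulate_gaze(
    stimulus_set: StimulusSet,
    n_participants: int = 4,
    n_blocks: int = 4,
    duration_s: float = 2.5,
    rate_hz: float = 1000.0,
    blink_prob: float = 0.05,
    noise_sd_px: float = 15.0,
    rng_seed: int = 0,
    screen_px: tuple[float, float] = (1280.0, 720.0),
) -> list[GazeTrajectory]:
    """Gaze trajectories: smooth per-stimulus prototypes plus noisy copies.

    Each stimulus gets a low-pass random-walk prototype path; each
    participant x block trial is the prototype plus Gaussian jitter with
    censored blink spans covering about ``blink_prob`` of the samples
    (``blink_prob = 1`` censors entire trials).
    """
    n = int(round(duration_s * rate_hz))
    if abs(duration_s * rate_hz - n) > 1e-9:
        raise ValueError("duration_s x rate_hz must be integral")
    rng = np.random.default_rng(rng_seed)
    t_ms = np.arange(n) * 1000.0 / rate_hz + 1.0
    center = np.array(screen_px) / 2.0
    prototypes = {}
    kernel = np.ones(101) / 101.0
    for s in stimulus_set.stimuli:
        steps = rng.normal(size=(n + 200, 2)) * 3.0
        walk = np.cumsum(steps, axis=0)
        for d in range(2):
            walk[:, d] = np.convolve(walk[:, d], kernel, mode="same")
        prototypes[s.stimulus_id] = center + walk[100 : 100 + n]
    out = []
    for p in range(n_participants):
        pid = f"gz{p:02d}"
        for b in range(n_blocks):
            for s in stimulus_set.stimuli:
                xy = prototypes[s.stimulus_id] + rng.normal(size=(n, 2)) * noise_sd_px
                valid = np.ones(n, dtype=bool)
                if blink_prob >= 1.0:
                    valid[:] = False
                elif blink_prob > 0:
                    target = int(round(blink_prob * n))
                    censored = 0
                    while censored < target:
                        length = int(rng.integers(50, 301))
                        start = int(rng.integers(0, n))
                        stop = min(n, start + length)
                        censored += int(valid[start:stop].sum())
                        valid[start:stop] = False
                out.append(
                    GazeTrajectory(
                        t_ms=t_ms, x=xy[:, 0], y=xy[:, 1], valid=valid,
                        stimulus_id=s.stimulus_id, participant_id=pid, block=b,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    stimulus_set: StimulusSet,
    embedding_dim: int = 300,
    verb_range: tuple[int, int] = (2, 5),
    nonverb_range: tuple[int, int] = (3, 6),
    cluster_scale: float = 1.0,
    token_noise: float = 0.3,
    rng_seed: int = 0,
) -> tuple[dict[str, dict[str, list[str]]], pd.DataFrame]:
    """Synthetic verb/nonverb annotations plus a token embedding table.

    Token embeddings cluster by category (cluster separation
    ``cluster_scale`` vs within-cluster ``token_noise``); each stimulus gets
    2-5 verb and 3-6 nonverb tokens from its category vocabulary at the
    defaults.  Returns ``(annotations, table)`` where annotations maps
    stimulus id -> {"verb": [...], "nonverb": [...]}.
    """
    rng = np.random.default_rng(rng_seed)
    cats = stimulus_set.categories
    vocab_rows = {}
    per_cat_tokens: dict[str, dict[str, list[str]]] = {}
    for c in cats:
        center_v = rng.normal(size=embedding_dim) * cluster_scale
        center_n = rng.normal(size=embedding_dim) * cluster_scale
        verbs = [f"{c}_verb{i}" for i in range(6)]
        nonverbs = [f"{c}_noun{i}" for i in range(8)]
        for t in verbs:
            vocab_rows[t] = center_v + rng.normal(size=embedding_dim) * token_noise
        for t in nonverbs:
            vocab_rows[t] = center_n + rng.normal(size=embedding_dim) * token_noise
        per_cat_tokens[c] = {"verb": verbs, "nonverb": nonverbs}
    table = pd.DataFrame.from_dict(vocab_rows, orient="index")
    table.columns = [f"v{i}" for i in range(embedding_dim)]
    annotations: dict[str, dict[str, list[str]]] = {}
    for s in stimulus_set.stimuli:
        nv = int(rng.integers(verb_range[0], verb_range[1] + 1))
        nn = int(rng.integers(nonverb_range[0], nonverb_range[1] + 1))
        vpool = per_cat_tokens[s.category]["verb"]
        npool = per_cat_tokens[s.category]["nonverb"]
        annotations[s.stimulus_id] = {
            "verb": [vpool[i] for i in rng.choice(len(vpool), nv, replace=False)],
            "nonverb": [npool[i] for i in rng.choice(len(npool), nn, replace=False)],
        }
    return annotations, table


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------

def make_grid_neighborhoods(
    width: int, height: int, radius: float
) -> dict[int, list[int]]:
    """Unit neighborhoods on a rectangular grid (Euclidean radius)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    out = {}
    for c in range(len(pts)):
        d = np.linalg.norm(pts - pts[c], axis=1)
        out[c] = np.flatnonzero(d <= radius + 1e-12).tolist()
    return out


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def make_bundle(
    n_subjects: int = 20,
    n_sessions: int = 2,
    n_units: int = 500,
    noise_sd: float = 1.0,
    mixture_weights: dict[str, float] | None = None,
    inter_model_correlation: float = 0.2,
    n_categories: int = 18,
    n_exemplars: int = 5,
    seed: int = 0,
    with_behavior: bool = False,
    with_gaze: bool = False,
    with_annotations: bool = False,
) -> SyntheticBundle:
    """One-call synthetic study: stimuli, model RDMs, and subject patterns.

    Defaults mirror the study conditions the analyses target: 90 stimuli
    (18 x 5), two sessions, ~20 subjects, 500 units, moderate pattern noise.
    """
    stimulus_set = make_stimulus_set(n_categories, n_exemplars)
    if mixture_weights is None:
        mixture_weights = {
            "sociality": 1.0, "transitivity": 0.7, "object": 0.4, "nuisance": 0.2
        }
    rdms, configs = make_model_geometries(
        stimulus_set,
        inter_model_correlation=inter_model_correlation,
        rng_seed=seed,
        model_names=tuple(mixture_weights),
    )
    gt = GroundTruth(
        latent_configurations=configs,
        mixture_weights=dict(mixture_weights),
        noise_sd=noise_sd,
        n_subjects=n_subjects,
        n_sessions=n_sessions,
        n_units=n_units,
        seed=seed,
        stimulus_ids=stimulus_set.stimulus_ids,
    )
    patterns = simulate_subject_patterns(gt, stimulus_set)
    bundle = SyntheticBundle(
        stimulus_set=stimulus_set,
        patterns=patterns,
        model_rdms=rdms,
        ground_truth=gt,
    )
    rng = np.random.default_rng(seed + 1)
    if with_behavior:
        from .design import plan_arrangement_subsets

        plan = plan_arrangement_subsets(
            n_stimuli=len(stimulus_set),
            n_candidates=20,
            rng_seed=int(rng.integers(2**31 - 1)),
            stimulus_ids=stimulus_set.stimulus_ids,
        )
        for name, rdm in rdms.items():
            bundle.arrangements[name] = simulate_arrangements(
                rdm, plan, placement_noise_sd=20.0,
                rng_seed=int(rng.integers(2**31 - 1)), task=name,
            )
    if with_gaze:
        bundle.gaze = simulate_gaze(
            stimulus_set, rng_seed=int(rng.integers(2**31 - 1))
        )
    if with_annotations:
        bundle.annotations, bundle.embeddings = simulate_annotations(
            stimulus_set, rng_seed=int(rng.integers(2**31 - 1))
        )
    return bundle
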