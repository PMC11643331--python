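"""Group-level resampling inference.

Sign-flip permutation tests on Fisher-transformed subject correlations,
re-centered bootstrap tests for positively-biased R2 statistics, BH-FDR
step-up control, condition-label permutation nulls, and percentile
bootstrap confidence intervals over subjects or over subjects and stimuli
jointly.

p-value convention: one-sided (greater), tie-inclusive, with the add-one
correction p = (1 + #{permuted >= observed}) / (1 + N) so p is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "InferenceResult",
    "fisher_z",
    "fisher_z_inverse",
    "fisher_mean",
    "signflip_permutation_test",
    "recentered_bootstrap_test",
    "bh_fdr",
    "condition_label_permutation_null",
    "bootstrap_ci",
]


@dataclass
class InferenceConfig:
    n_permutations: int = 10_000
    n_bootstrap: int = 10_000
    fdr_q: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1 or self.n_bootstrap < 1:
            raise ValueError("resampling counts must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass
class InferenceResult:
    observed: float
    p_value: float
    method: str
    seed: int
    ci_low: float | None = None
    ci_high: float | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def fisher_z(r: float) -> float:
    """Fisher z-transform atanh(r); |r| must be < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1 for the Fisher transform (got {r})")
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    return float(np.tanh(z))


def fisher_mean(rs) -> float:
    """Mean of correlations on the Fisher-z scale, back-transformed.

    Tolerates r = +/-1 (maps through +/-inf and back to +/-1), which arises
    for noiseless data where the strict transform is undefined.
    """
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.asarray(rs, dtype=float))
    return float(np.tanh(z.mean()))


def _p_from_null(null: np.ndarray, observed: float) -> float:
    return float((1 + int(np.sum(null >= observed))) / (1 + len(null)))


def signflip_permutation_test(
    subject_correlations, cfg: InferenceConfig, exhaustive: bool = False
) -> InferenceResult:
    """Sign-flip permutation test on Fisher-transformed subject correlations.

    The observed statistic is the mean Fisher-z value; each permutation
    flips every subject's sign independently before z-averaging, and
    p = (1 + #{permuted >= observed}) / (1 + N).  With ``exhaustive=True``
    all 2^n flip patterns are enumerated instead of sampled.
    """
    r = np.asarray(subject_correlations, dtype=float)
    if len(r) < 2:
        raise ValueError("need >= 2 subjects")
    z = np.array([fisher_z(v) for v in r])
    observed = float(z.mean())
    rng = np.random.default_rng(cfg.seed)
    if exhaustive:
        n = len(z)
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        flips = np.where(bits, -1.0, 1.0)
    else:
        flips = rng.choice([-1.0, 1.0], size=(cfg.n_permutations, len(z)))
    null = (flips * z).mean(axis=1)
    return InferenceResult(
        observed=observed,
        p_value=_p_from_null(null, observed),
        method="signflip_permutation",
        seed=cfg.seed,
        null_distribution=null,
    )


def recentered_bootstrap_test(
    subject_r2s, cfg: InferenceConfig, exhaustive: bool = False
) -> InferenceResult:
    """Re-centered bootstrap test for the mean of subject-level R2 values.

    Bootstrap means are computed by resampling subjects with replacement;
    the distribution is re-centered by subtracting the observed mean and
    p = (1 + #{(b_k - observed) >= observed}) / (1 + N), one-sided.  With
    ``exhaustive=True`` all n^n ordered resamples are enumerated (tiny n
    only).
    """
    v = np.asarray(subject_r2s, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 subjects")
    observed = float(v.mean())
    rng = np.random.default_rng(cfg.seed)
    if exhaustive:
        n = len(v)
        grids = np.meshgrid(*([np.arange(n)] * n), indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
    else:
        idx = rng.integers(0, len(v), size=(cfg.n_bootstrap, len(v)))
    boots = v[idx].mean(axis=1)
    recentered = boots - observed
    return InferenceResult(
        observed=observed,
        p_value=_p_from_null(recentered, observed),
        method="recentered_bootstrap",
        seed=cfg.seed,
        null_distribution=recentered,
    )


def bh_fdr(p_values, q: float) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (effective p threshold, rejection mask).  The threshold is the
    largest p_(k) with p_(k) <= k q / m (0 if none); all hypotheses at or
    below it are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p)
    sorted_p = p[order]
    ks = np.arange(1, m + 1)
    ok = sorted_p <= ks * q / m
    if not ok.any():
        return 0.0, np.zeros(m, dtype=bool)
    threshold = float(sorted_p[np.flatnonzero(ok)[-1]])
    return threshold, p <= threshold


def condition_label_permutation_null(
    neural,
    model,
    cfg: InferenceConfig,
    statistic=None,
    exhaustive: bool = False,
) -> InferenceResult:
    """Permutation null from shuffling the model RDM's condition labels.

    Each permutation applies one random stimulus permutation jointly to the
    model RDM's rows and columns and recomputes the statistic (Spearman rho
    by default, or any ``statistic(neural, permuted_model) -> float``).
    With ``exhaustive=True`` all m! stimulus permutations are enumerated
    (tiny m only).
    """
    from itertools import permutations as iter_permutations

    from .rdm import RDM
    from .rsa import spearman_rsa

    if statistic is None:
        statistic = spearman_rsa
    if neural.stimulus_ids != model.stimulus_ids:
        raise ValueError("RDMs must share stimulus order")
    observed = float(statistic(neural, model))
    rng = np.random.default_rng(cfg.seed)
    m = neural.n_stimuli
    mat = model.matrix
    if exhaustive:
        perms = [np.array(p) for p in iter_permutations(range(m))]
    else:
        perms = [rng.permutation(m) for _ in range(cfg.n_permutations)]
    null = np.empty(len(perms))
    for k, perm in enumerate(perms):
        shuffled = RDM(model.stimulus_ids, mat[np.ix_(perm, perm)])
        null[k] = statistic(neural, shuffled)
    return InferenceResult(
        observed=observed,
        p_value=_p_from_null(null, observed),
        method="condition_label_permutation",
        seed=cfg.seed,
        null_distribution=null,
    )


def _resample_rdm_vector(matrix: np.ndarray, stim_idx: np.ndarray) -> np.ndarray:
    """Vectorize a stimulus-resampled RDM, dropping duplicate-stimulus cells.

    Cells pairing a stimulus with its own duplicate are zero-distance
    artifacts and are excluded from the vectorization.
    """
    sub = matrix[np.ix_(stim_idx, stim_idx)]
    iu = np.triu_indices(len(stim_idx), 1)
    keep = stim_idx[iu[0]] != stim_idx[iu[1]]
    return sub[iu][keep]


def bootstrap_ci(
    per_subject_inputs,
    statistic,
    cfg: InferenceConfig,
    resample: str = "subjects",
    max_discard_fraction: float = 0.1,
) -> tuple[float, float]:
    """95% percentile bootstrap CI for a group statistic.

    ``resample="subjects"`` resamples subject indices with replacement and
    recomputes ``statistic(list_of_inputs)``.  ``resample="subjects_and_stimuli"``
    additionally resamples stimulus indices: inputs must then be RDMs, and
    each resampled RDM is rebuilt from the sampled rows/columns with
    duplicate-stimulus cells excluded; ``statistic`` receives the list of
    resampled RDM *vectors*.  Draws on which the statistic is undefined are
    discarded and logged; more than ``max_discard_fraction`` discards is an
    error.
    """
    inputs = list(per_subject_inputs)
    if len(inputs) < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(cfg.seed)
    n = len(inputs)
    vals = []
    discarded = 0
    for _ in range(cfg.n_bootstrap):
        subj_idx = rng.integers(0, n, size=n)
        if resample == "subjects":
            sample = [inputs[i] for i in subj_idx]
        elif resample == "subjects_and_stimuli":
            m = inputs[0].n_stimuli
            stim_idx = rng.integers(0, m, size=m)
            sample = [
                _resample_rdm_vector(inputs[i].matrix, stim_idx) for i in subj_idx
            ]
        else:
            raise ValueError(f"unknown resample mode {resample!r}")
        try:
            vals.append(float(statistic(sample)))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            discarded += 1
    if discarded:
        logger.info("bootstrap_ci: discarded %d undefined draw(s)", discarded)
    if discarded > max_discard_fraction * cfg.n_bootstrap:
        raise ValueError(
            f"statistic undefined on {discarded}/{cfg.n_bootstrap} bootstrap draws"
        )
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)
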