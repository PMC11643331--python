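"""Representational dissimilarity matrices and their construction.

An :class:`RDM` is a labeled, symmetric, zero-diagonal (for distance-based
sources) matrix of pairwise dissimilarities between stimuli; its vectorized
upper triangle is the unit of comparison throughout the analyses.  This
module builds every RDM family used in the pipeline: split-data neural RDMs
from two-session response patterns, behavioral RDMs from multiple-
arrangement logs, gaze RDMs with inter-block reliability filtering, semantic
RDMs from averaged word embeddings, and generic feature RDMs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "RDM",
    "ArrangementTrial",
    "GazeTrajectory",
    "zscore_profiles",
    "split_data_rdm",
    "arrangement_distances",
    "aggregate_arrangements",
    "preprocess_gaze",
    "gaze_trial_distance",
    "build_gaze_rdm",
    "semantic_rdm",
    "annotator_agreement",
    "feature_rdm",
]

_SYM_TOL = 1e-9


@dataclass
class RDM:
    """Labeled square dissimilarity matrix over stimuli.

    The matrix is symmetrized on construction (asymmetries beyond 1e-9 are an
    error) and the vectorized form is the upper triangle excluding the
    diagonal, in row-major pair order.
    """

    stimulus_ids: list[str]
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stimulus_ids = list(self.stimulus_ids)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if m.shape[0] != len(self.stimulus_ids):
            raise ValueError("label/matrix size mismatch")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if np.abs(m - m.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("RDM is not symmetric within 1e-9")
        self.matrix = (m + m.T) / 2.0

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def vector(self) -> np.ndarray:
        """Upper triangle excluding the diagonal, row-major pair order."""
        iu = np.triu_indices(self.n_stimuli, 1)
        return self.matrix[iu]

    @classmethod
    def from_vector(cls, stimulus_ids, vector, meta=None) -> "RDM":
        m = len(stimulus_ids)
        vec = np.asarray(vector, dtype=float)
        if vec.size != m * (m - 1) // 2:
            raise ValueError("vector length does not match label count")
        mat = squareform(vec)
        return cls(stimulus_ids=list(stimulus_ids), matrix=mat, meta=meta or {})

    def reorder(self, stimulus_ids) -> "RDM":
        """Return a copy with rows/columns in the requested stimulus order."""
        pos = {s: i for i, s in enumerate(self.stimulus_ids)}
        idx = np.array([pos[s] for s in stimulus_ids])
        return RDM(list(stimulus_ids), self.matrix[np.ix_(idx, idx)], dict(self.meta))

    def subset(self, stimulus_ids) -> "RDM":
        return self.reorder(stimulus_ids)


@dataclass
class ArrangementTrial:
    """One behavioral arrangement: stimulus subset plus final 2D coordinates."""

    task: str
    subset: list[str]
    coords: np.ndarray  # (len(subset), 2) screen px
    participant: str = "p0"
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.subset)) != len(self.subset):
            raise ValueError("duplicate stimuli in arrangement subset")
        if self.coords.shape != (len(self.subset), 2):
            raise ValueError("coords must be (n_subset, 2)")


@dataclass
class GazeTrajectory:
    """Time-stamped 2D gaze samples with validity flags for one presentation."""

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    stimulus_id: str = ""
    participant_id: str = ""
    block: int = 0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# neural patterns
# ---------------------------------------------------------------------------

def zscore_profiles(pattern_table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each unit's response profile across conditions (population SD).

    Constant columns are set to zero with a warning.
    """
    if len(pattern_table) < 2:
        raise ValueError("need >= 2 conditions to z-score profiles")
    vals = pattern_table.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant unit profile(s) set to zero", stacklevel=2)
    out = (vals - mu) / np.where(const, 1.0, sd)
    out[:, const] = 0.0
    return pd.DataFrame(out, index=pattern_table.index, columns=pattern_table.columns)


def split_data_rdm(patterns_session1: pd.DataFrame, patterns_session2: pd.DataFrame) -> RDM:
    """Cross-session correlation-distance RDM.

    ``c_ij`` is the Pearson correlation between stimulus *i*'s session-1
    pattern and stimulus *j*'s session-2 pattern; the dissimilarity is
    ``1 - (c_ij + c_ji)/2``, symmetric by construction.  The diagonal stores
    ``1 - c_ii`` (the split-half reliability complement) but is excluded from
    vectorization.
    """
    if list(patterns_session1.index) != list(patterns_session2.index):
        raise ValueError("sessions must share stimulus order")
    if patterns_session1.shape[1] != patterns_session2.shape[1]:
        raise ValueError("sessions must share unit count")
    if patterns_session1.shape[1] < 2:
        raise ValueError("need >= 2 units")
    a = patterns_session1.to_numpy(dtype=float)
    b = patterns_session2.to_numpy(dtype=float)
    for name, arr in (("session1", a), ("session2", b)):
        sd = arr.std(axis=1)
        if np.any(sd == 0):
            bad = patterns_session1.index[int(np.argmax(sd == 0))]
            raise ValueError(f"zero-variance pattern for stimulus {bad!r} in {name}")
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    c = a @ b.T
    d = 1.0 - (c + c.T) / 2.0
    return RDM(list(patterns_session1.index), d, {"source": "split_data"})


# ---------------------------------------------------------------------------
# behavioral arrangements
# ---------------------------------------------------------------------------

def arrangement_distances(trial: ArrangementTrial) -> dict[tuple[str, str], float]:
    """Euclidean screen distances for every unordered pair in the subset."""
    if len(trial.subset) < 2:
        raise ValueError("arrangement trial needs >= 2 stimuli")
    d = pdist(trial.coords)
    out: dict[tuple[str, str], float] = {}
    k = 0
    n = len(trial.subset)
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((trial.subset[i], trial.subset[j])))
            out[key] = float(d[k])
            k += 1
    return out


def aggregate_arrangements(
    trials: list[ArrangementTrial],
    stimulus_ids: list[str],
    normalize_trials: bool = False,
) -> RDM:
    """Average sparse per-trial pair distances into a full RDM.

    Each cell is the arithmetic mean of that pair's distances over all trials
    measuring it; a pair never measured is an error.  ``normalize_trials``
    optionally divides each trial's distances by their RMS before averaging
    (off by default: raw screen pixels are averaged).

    Per-participant aggregation followed by cross-participant averaging is
    the caller's concern (see :func:`actionrsa.pipeline` usage); this
    function averages whatever trials it is given.
    """
    pos = {s: i for i, s in enumerate(stimulus_ids)}
    m = len(stimulus_ids)
    total = np.zeros((m, m))
    count = np.zeros((m, m))
    for trial in trials:
        dists = arrangement_distances(trial)
        if normalize_trials:
            rms = np.sqrt(np.mean([v**2 for v in dists.values()]))
            if rms > 0:
                dists = {k: v / rms for k, v in dists.items()}
        for (s1, s2), v in dists.items():
            i, j = pos[s1], pos[s2]
            total[i, j] += v
            total[j, i] += v
            count[i, j] += 1
            count[j, i] += 1
    iu = np.triu_indices(m, 1)
    missing = count[iu] == 0
    if missing.any():
        pairs = [
            (stimulus_ids[i], stimulus_ids[j])
            for i, j, miss in zip(*iu, missing)
            if miss
        ]
        raise ValueError(f"{len(pairs)} pair(s) never measured, e.g. {pairs[:3]}")
    with np.errstate(invalid="ignore"):
        mat = np.where(count > 0, total / np.where(count == 0, 1, count), 0.0)
    np.fill_diagonal(mat, 0.0)
    return RDM(list(stimulus_ids), mat, {"source": "arrangement"})


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def preprocess_gaze(
    traj: GazeTrajectory,
    window_ms: float = 84.0,
    out_rate_hz: float = 24.0,
    duration_s: float = 2.5,
) -> np.ndarray | None:
    """Censor, median-filter, and decimate one gaze trajectory.

    Invalid spans are linearly interpolated from flanking valid samples, a
    rolling median with the nearest odd sample count to ``window_ms`` is
    applied (window shrinking at the edges), and the output is the per-bin
    mean over ``duration_s * out_rate_hz`` equal sample bins (60 frames at
    the defaults).  Returns an (n_out, 2) array, or None if the trajectory
    is entirely invalid (trial excluded).
    """
    n = len(traj.t_ms)
    if not traj.valid.any():
        return None
    rate_hz = 1000.0 * (n - 1) / (traj.t_ms[-1] - traj.t_ms[0]) if n > 1 else 1000.0
    win = int(round(window_ms * rate_hz / 1000.0))
    if win % 2 == 0:
        win += 1
    idx = np.arange(n)
    good = traj.valid
    xy = np.column_stack([traj.x, traj.y]).astype(float)
    for d in range(2):
        xy[:, d] = np.interp(idx, idx[good], xy[good, d])
    filt = (
        pd.DataFrame(xy)
        .rolling(window=win, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    n_out = int(round(duration_s * out_rate_hz))
    bins = (idx * n_out) // n
    out = np.empty((n_out, 2))
    for b in range(n_out):
        out[b] = filt[bins == b].mean(axis=0)
    return out


def gaze_trial_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Sum over samples of the Euclidean distance between two trajectories."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectory length mismatch")
    return float(np.linalg.norm(a - b, axis=1).sum())


def _block_rdm(block_trajs: dict[str, np.ndarray], stimulus_ids: list[str]) -> np.ndarray:
    """Pairwise summed gaze distance for one block; NaN for missing stimuli."""
    m = len(stimulus_ids)
    mat = np.full((m, m), np.nan)
    np.fill_diagonal(mat, 0.0)
    present = [s for s in stimulus_ids if s in block_trajs]
    if len(present) >= 2:
        arr = np.stack([block_trajs[s] for s in present])  # (p, t, 2)
        diff = arr[:, None] - arr[None, :]
        dmat = np.linalg.norm(diff, axis=-1).sum(axis=-1)
        pos = [stimulus_ids.index(s) for s in present]
        mat[np.ix_(pos, pos)] = dmat
    return mat


def build_gaze_rdm(
    trajectories: list[GazeTrajectory],
    min_interblock_r: float = 0.1,
    window_ms: float = 84.0,
    out_rate_hz: float = 24.0,
    duration_s: float = 2.5,
) -> tuple[RDM, pd.DataFrame]:
    """Per-block gaze RDMs, reliability filtering, and the group-average RDM.

    For each participant and block an RDM of summed pairwise gaze distances
    is built from the preprocessed trajectories.  A participant is retained
    iff the mean pairwise Pearson correlation between their block RDM
    vectors is at least ``min_interblock_r``; retained participants' RDMs
    are averaged over blocks, then over participants.  The report lists each
    participant's inter-block r and exclusion status (fully-censored trials
    are excluded before RDM construction).
    """
    stimulus_ids = sorted({t.stimulus_id for t in trajectories})
    by_participant: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    for traj in trajectories:
        proc = preprocess_gaze(traj, window_ms, out_rate_hz, duration_s)
        if proc is None:
            logger.info(
                "excluding fully-censored trial: participant=%s block=%d stimulus=%s",
                traj.participant_id, traj.block, traj.stimulus_id,
            )
            continue
        by_participant.setdefault(traj.participant_id, {}).setdefault(traj.block, {})[
            traj.stimulus_id
        ] = proc

    iu = np.triu_indices(len(stimulus_ids), 1)
    report_rows = []
    retained_rdms = []
    for pid in sorted(by_participant):
        blocks = by_participant[pid]
        mats = {b: _block_rdm(blocks[b], stimulus_ids) for b in sorted(blocks)}
        vecs = {b: m[iu] for b, m in mats.items()}
        rs = []
        for b1, b2 in zip(*np.triu_indices(len(vecs), 1)):
            keys = sorted(vecs)
            v1, v2 = vecs[keys[b1]], vecs[keys[b2]]
            ok = np.isfinite(v1) & np.isfinite(v2)
            if ok.sum() >= 3:
                rs.append(float(np.corrcoef(v1[ok], v2[ok])[0, 1]))
        mean_r = float(np.mean(rs)) if rs else np.nan
        retained = bool(len(rs) > 0 and mean_r >= min_interblock_r)
        report_rows.append(
            {"participant": pid, "n_blocks": len(blocks),
             "mean_interblock_r": mean_r, "retained": retained}
        )
        if retained:
            stack = np.stack(list(mats.values()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                retained_rdms.append(np.nanmean(stack, axis=0))
    report = pd.DataFrame(report_rows)
    if not retained_rdms:
        raise ValueError("no participants retained by the gaze reliability filter")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(np.stack(retained_rdms), axis=0)
    if not np.all(np.isfinite(avg)):
        raise ValueError("gaze RDM has unmeasured pairs after exclusion")
    rdm = RDM(stimulus_ids, avg, {"source": "gaze", "min_interblock_r": min_interblock_r})
    return rdm, report


# ---------------------------------------------------------------------------
# semantics
# ---------------------------------------------------------------------------

def _stimulus_vectors(
    annotations: dict[str, list[str]], table: pd.DataFrame
) -> pd.DataFrame:
    """Mean embedding vector per stimulus; unknown tokens dropped with a warning."""
    rows = {}
    for stim, tokens in annotations.items():
        known = [t for t in tokens if t in table.index]
        dropped = set(tokens) - set(known)
        if dropped:
            logger.warning("stimulus %s: dropping unknown token(s) %s", stim, sorted(dropped))
        if not known:
            raise ValueError(f"stimulus {stim!r} has no resolvable tokens")
        rows[stim] = table.loc[known].to_numpy(dtype=float).mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def semantic_rdm(
    annotations: dict[str, list[str]],
    table: pd.DataFrame,
    token_class: str = "verb",
) -> RDM:
    """Cosine-distance RDM over mean word-embedding vectors per stimulus.

    ``annotations`` maps stimulus id -> token list (already restricted to the
    desired class); ``table`` is the token -> vector embedding table.
    """
    vecs = _stimulus_vectors(annotations, table)
    arr = vecs.to_numpy(dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    if np.any(norms == 0):
        bad = vecs.index[int(np.argmax(norms == 0))]
        raise ValueError(f"zero-norm embedding vector for stimulus {bad!r}")
    unit = arr / norms[:, None]
    mat = 1.0 - unit @ unit.T
    np.fill_diagonal(mat, 0.0)
    mat = np.clip(mat, 0.0, None)
    return RDM(list(vecs.index), mat, {"source": f"semantic_{token_class}"})


def annotator_agreement(
    ann_a: dict[str, list[str]],
    ann_b: dict[str, list[str]],
    table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-stimulus Pearson correlation between two annotators' mean vectors.

    Stimuli whose mean vector is constant are reported with NaN.
    """
    if set(ann_a) != set(ann_b):
        raise ValueError("annotators must cover the same stimuli")
    va = _stimulus_vectors(ann_a, table)
    vb = _stimulus_vectors(ann_b, table)
    rows = []
    for stim in va.index:
        x, y = va.loc[stim].to_numpy(), vb.loc[stim].to_numpy()
        if x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"stimulus_id": stim, "r": r})
    return pd.DataFrame(rows).set_index("stimulus_id")


# ---------------------------------------------------------------------------
# generic features
# ---------------------------------------------------------------------------

def feature_rdm(feature_table: pd.DataFrame, metric: str = "correlation") -> RDM:
    """Pairwise dissimilarity over a condition x feature table.

    ``metric`` is one of ``correlation`` (1 - Pearson, the default),
    ``euclidean``, or ``cosine``.
    """
    if feature_table.shape[1] < 2:
        raise ValueError("need >= 2 features")
    arr = feature_table.to_numpy(dtype=float)
    if metric == "correlation":
        sd = arr.std(axis=1)
        if np.any(sd == 0):
            bad = feature_table.index[int(np.argmax(sd == 0))]
            raise ValueError(f"zero-variance feature row for {bad!r}")
        mat = squareform(pdist(arr, metric="correlation"))
    elif metric == "euclidean":
        mat = squareform(pdist(arr, metric="euclidean"))
    elif metric == "cosine":
        mat = squareform(pdist(arr, metric="cosine"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return RDM(list(feature_table.index), mat, {"source": "feature", "metric": metric})
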