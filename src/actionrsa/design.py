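"""Generators for the condition-rich rapid event-related design.

The experiment presents 90 naturalistic action clips (18 categories x 5
exemplars) in a first-order counterbalanced trial order.  At the category
level the trial alphabet has ``n = n_categories + 2`` types (the categories
plus a null-fixation type and a probe type) and the session is a *serially
balanced sequence of type 1, index 1*: reading the n^2-trial sequence
circularly, every ordered pair of trial types -- self-pairs included --
occurs exactly once as an adjacency.  For even alphabets the sequence
additionally decomposes into n consecutive blocks, each containing every
type exactly once, which is what guarantees one probe and one null trial
per block (five of each per 100-trial run at the default n = 20).

The remaining machinery mirrors the rest of the session construction:
seeded exemplar assignment (each exemplar once per run), repair of probe
trials that trail a null/probe trial, truncated-exponential ISI jitter with
an exact run-total constraint, Dale-style estimation efficiency for
selecting among candidate onset timings, partitioning a session into runs
with prepended context trials, and planning of the multiple-arrangement
stimulus subsets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "Stimulus",
    "StimulusSet",
    "Trial",
    "DesignSequence",
    "TimingConfig",
    "SubsetPlan",
    "ConfigurationError",
    "build_serially_balanced_sequence",
    "assign_categories_and_exemplars",
    "fix_probe_collisions",
    "sample_jittered_isis",
    "double_gamma_hrf",
    "design_efficiency",
    "select_best_design",
    "add_timing",
    "partition_runs",
    "plan_arrangement_subsets",
]

NULL_ROLE = "null"
PROBE_ROLE = "probe"
CATEGORY_ROLE = "category"


class ConfigurationError(ValueError):
    """Raised when a design request is internally inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stimulus:
    stimulus_id: str
    category: str
    exemplar_index: int  # 1-based within category
    is_social: bool


@dataclass
class StimulusSet:
    """An ordered collection of stimuli grouped into categories."""

    stimuli: list[Stimulus]

    def __post_init__(self) -> None:
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("stimulus_ids must be unique")

    @property
    def stimulus_ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stimuli:
            seen.setdefault(s.category, None)
        return list(seen)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def exemplars(self, category: str) -> list[Stimulus]:
        return [s for s in self.stimuli if s.category == category]

    def __len__(self) -> int:
        return len(self.stimuli)


@dataclass
class Trial:
    type_code: int
    role: str  # "category" | "null" | "probe"
    category: str | None = None
    exemplar_id: str | None = None
    onset_s: float | None = None
    duration_s: float | None = None
    isi_s: float | None = None


@dataclass
class DesignSequence:
    trials: list[Trial]
    session_index: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class TimingConfig:
    stim_duration_s: float = 2.5
    mean_isi_s: float = 2.5
    min_isi_s: float = 2.0
    lead_in_s: float = 5.0
    tail_s: float = 15.0
    n_candidates: int = 1000
    isi_truncation_factor: float = 3.0  # ISIs capped at this multiple of the mean

    def __post_init__(self) -> None:
        if self.mean_isi_s < self.min_isi_s:
            raise ConfigurationError(
                f"mean_isi_s ({self.mean_isi_s}) must be >= min_isi_s ({self.min_isi_s})"
            )
        if self.n_candidates < 1:
            raise ConfigurationError("n_candidates must be >= 1")


@dataclass
class SubsetPlan:
    subsets: list[list[str]]
    unique_pair_count: int


# ---------------------------------------------------------------------------
# serially balanced sequences
# ---------------------------------------------------------------------------

def _eulerian_circuit(n: int, rng: np.random.Generator) -> list[int]:
    """Randomized Hierholzer circuit on the complete digraph with self-loops.

    Each of the n^2 arcs (a, b) -- including the n loops -- is traversed once;
    the vertex sequence (dropping the final repeat of the start) is a circular
    sequence in which every ordered pair occurs exactly once as an adjacency.
    """
    succ = {u: list(rng.permutation(n)) for u in range(n)}
    start = int(rng.integers(n))
    stack, circuit = [start], []
    while stack:
        u = stack[-1]
        if succ[u]:
            stack.append(int(succ[u].pop()))
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == n * n + 1 and circuit[0] == circuit[-1]
    return circuit[:-1]


def _hamiltonian_path(
    avail: np.ndarray, start: int, end: int, rng: np.random.Generator
):
    """Yield random Hamiltonian paths start -> end over the available arcs.

    Candidates are ordered by fewest remaining onward options (random
    tie-break), which keeps the search shallow on the dense graphs that arise
    block by block.
    """
    n = avail.shape[0]
    path = [start]
    visited = np.zeros(n, dtype=bool)
    visited[start] = True

    def rec():
        u = path[-1]
        if len(path) == n - 1:
            if avail[u, end] and not visited[end]:
                yield path + [end]
            return
        cands = np.flatnonzero(avail[u] & ~visited)
        cands = cands[cands != end]
        if cands.size == 0:
            return
        onward = (avail[cands] & ~visited).sum(axis=1)
        for c in cands[np.lexsort((rng.random(cands.size), onward))]:
            visited[c] = True
            path.append(int(c))
            yield from rec()
            path.pop()
            visited[c] = False

    if n == 1:
        yield [start]
    else:
        yield from rec()


def _blocked_balanced_sequence(n: int, rng: np.random.Generator) -> list[int] | None:
    """Circular type-1-index-1 sequence decomposing into n permutation blocks.

    Self-pairs can only occur at block junctions, so the sequence is a closed
    chain of n arc-disjoint Hamiltonian paths over the loopless complete
    digraph, consecutive paths linked end -> start.  The chain is found by
    backtracking over blocks with randomized Hamiltonian-path generators.
    """
    starts = [int(s) for s in rng.permutation(n)]
    avail = np.ones((n, n), dtype=bool)
    np.fill_diagonal(avail, False)
    blocks: list[list[int]] = []

    def rec(b: int) -> bool:
        if b == n:
            return True
        s, e = starts[b], starts[(b + 1) % n]
        for p in _hamiltonian_path(avail, s, e, rng):
            arcs = list(zip(p, p[1:]))
            for u, v in arcs:
                avail[u, v] = False
            blocks.append(p)
            if rec(b + 1):
                return True
            blocks.pop()
            for u, v in arcs:
                avail[u, v] = True
        return False

    if rec(0):
        return [x for p in blocks for x in p]
    return None


def _verify_balanced(seq: list[int], n: int) -> None:
    pairs = set()
    for i, a in enumerate(seq):
        p = (a, seq[(i + 1) % len(seq)])
        if p in pairs:  # pragma: no cover - construction guarantee
            raise RuntimeError(f"duplicate circular pair {p}")
        pairs.add(p)
    if len(pairs) != n * n:  # pragma: no cover
        raise RuntimeError("incomplete pair coverage")


def build_serially_balanced_sequence(n_types: int, rng_seed: int) -> list[int]:
    """Build a circular type 1 index 1 serially balanced sequence.

    Returns a list of ``n_types**2`` type codes in which every ordered pair of
    codes (self-pairs included) occurs exactly once among circular
    adjacencies.  For even ``n_types`` (other than 4, where no such blocked
    sequence exists) the sequence additionally decomposes into ``n_types``
    consecutive blocks that each contain every code exactly once.

    The construction is randomized and seeded; the returned sequence is also
    given a uniformly random rotation (by whole blocks when the block
    structure is present).
    """
    if n_types < 1:
        raise ConfigurationError("n_types must be >= 1")
    if n_types == 1:
        return [0]
    rng = np.random.default_rng(rng_seed)
    n = n_types
    if n % 2 == 0 and n != 4:
        seq = None
        for _ in range(200):
            seq = _blocked_balanced_sequence(n, rng)
            if seq is not None:
                break
        if seq is None:  # pragma: no cover - never observed for even n <= 24
            raise RuntimeError(f"blocked sequence construction failed for n={n}")
        shift = int(rng.integers(n)) * n  # rotate by whole blocks
    else:
        # Odd alphabets (and n=4, for which the blocked form provably does
        # not exist) use an unconstrained Eulerian circuit.
        seq = _eulerian_circuit(n, rng)
        shift = int(rng.integers(len(seq)))
    seq = seq[shift:] + seq[:shift]
    _verify_balanced(seq, n)
    return seq


# ---------------------------------------------------------------------------
# category / exemplar assignment and probe repair
# ---------------------------------------------------------------------------

def assign_categories_and_exemplars(
    type_sequence: list[int],
    stimulus_set: StimulusSet,
    run_length: int,
    rng_seed: int,
) -> DesignSequence:
    """Map type codes onto categories and draw exemplars once per run.

    A seeded random bijection maps the ``n_categories + 2`` codes onto the
    category labels plus the null and probe roles.  Within each run of
    ``run_length`` trials, the occurrences of a category are assigned its
    exemplars by sampling without replacement, so each exemplar appears
    exactly once per run.
    """
    rng = np.random.default_rng(rng_seed)
    n_types = stimulus_set.n_categories + 2
    if len(type_sequence) % run_length != 0:
        raise ConfigurationError(
            f"run_length {run_length} does not divide sequence length {len(type_sequence)}"
        )
    labels = list(stimulus_set.categories) + [NULL_ROLE, PROBE_ROLE]
    codes = rng.permutation(n_types)
    code_to_label = {int(c): lab for c, lab in zip(codes, labels)}

    trials: list[Trial] = []
    n_runs = len(type_sequence) // run_length
    for r in range(n_runs):
        chunk = type_sequence[r * run_length : (r + 1) * run_length]
        # exemplar pools per category for this run
        pools: dict[str, list[str]] = {}
        for cat in stimulus_set.categories:
            ex = [s.stimulus_id for s in stimulus_set.exemplars(cat)]
            occ = sum(1 for c in chunk if code_to_label[c] == cat)
            if occ % len(ex) != 0:
                raise ConfigurationError(
                    f"category {cat!r} occurs {occ}x in run {r}, not a "
                    f"multiple of its {len(ex)} exemplars"
                )
            # one without-replacement pass per cycle of occurrences
            pool: list[str] = []
            for _ in range(occ // len(ex)):
                pool.extend(ex[i] for i in rng.permutation(len(ex)))
            pools[cat] = pool
        for code in chunk:
            label = code_to_label[code]
            if label in (NULL_ROLE, PROBE_ROLE):
                trials.append(Trial(type_code=code, role=label))
            else:
                trials.append(
                    Trial(
                        type_code=code,
                        role=CATEGORY_ROLE,
                        category=label,
                        exemplar_id=pools[label].pop(),
                    )
                )
    return DesignSequence(trials=trials, meta={"run_length": run_length, "seed": rng_seed})


def fix_probe_collisions(sequence: DesignSequence) -> DesignSequence:
    """Convert probe trials that trail a null or probe trial into null trials.

    The scan is a single left-to-right pass in session order, so a probe whose
    predecessor was itself just converted to null is still repaired.
    """
    fixed: list[Trial] = []
    for trial in sequence.trials:
        if (
            trial.role == PROBE_ROLE
            and fixed
            and fixed[-1].role in (NULL_ROLE, PROBE_ROLE)
        ):
            fixed.append(replace(trial, role=NULL_ROLE))
        else:
            fixed.append(replace(trial))
    return DesignSequence(trials=fixed, session_index=sequence.session_index, meta=dict(sequence.meta))


# ---------------------------------------------------------------------------
# ISI jitter
# ---------------------------------------------------------------------------

def sample_jittered_isis(n_trials: int, cfg: TimingConfig, rng_seed: int) -> list[float]:
    """Draw jittered ISIs: min offset + truncated exponential, exact total.

    Each ISI is ``min_isi_s`` plus an exponential draw (mean
    ``mean_isi_s - min_isi_s``) truncated at ``isi_truncation_factor x
    mean_isi_s``.  Draws are iteratively rescaled so the ISI sum equals
    ``n_trials x mean_isi_s`` exactly, then quantized to 0.1 s with the
    residual repaired in 0.1 s steps, preserving the minimum and the cap.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    cap = cfg.isi_truncation_factor * cfg.mean_isi_s
    lo, hi = cfg.min_isi_s, cap
    target = n_trials * cfg.mean_isi_s
    scale = cfg.mean_isi_s - cfg.min_isi_s
    if scale == 0:
        return [cfg.min_isi_s] * n_trials

    rng = np.random.default_rng(rng_seed)
    extra = rng.exponential(scale, size=n_trials)
    extra = np.minimum(extra, hi - lo)
    extra_target = target - n_trials * lo
    for _ in range(200):
        s = extra.sum()
        if s == 0:
            extra = np.full(n_trials, extra_target / n_trials)
            continue
        extra *= extra_target / s
        over = extra > (hi - lo)
        if not over.any():
            break
        extra = np.minimum(extra, hi - lo)

    # quantize to 0.1 s and repair the residual in tenth-second steps
    tenths = np.round((lo + extra) * 10).astype(int)
    target_tenths = int(round(target * 10))
    lo_t, hi_t = int(round(lo * 10)), int(round(hi * 10))
    diff = target_tenths - int(tenths.sum())
    step = 1 if diff > 0 else -1
    order = np.argsort(tenths if step > 0 else -tenths)
    i = 0
    while diff != 0:
        j = order[i % n_trials]
        if lo_t <= tenths[j] + step <= hi_t:
            tenths[j] += step
            diff -= step
        i += 1
        if i > 100 * n_trials:  # pragma: no cover - safety valve
            raise RuntimeError("ISI quantization failed to converge")
    isis = (tenths / 10.0).tolist()
    assert abs(sum(isis) - target) < 1e-9
    return isis


# ---------------------------------------------------------------------------
# design efficiency
# ---------------------------------------------------------------------------

def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s)."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


def _design_matrix(
    onsets: np.ndarray,
    durations: np.ndarray,
    condition_idx: np.ndarray,
    n_conditions: int,
    tr: float,
    dt: float,
    total_s: float | None = None,
) -> np.ndarray:
    """Boxcar-convolved design matrix at dt resolution, sampled at the TR."""
    if total_s is None:
        total_s = float(onsets.max() + durations.max()) + 32.0
    n_hi = int(np.ceil(total_s / dt)) + 1
    box = np.zeros((n_hi, n_conditions))
    for onset, dur, c in zip(onsets, durations, condition_idx):
        i0 = int(round(onset / dt))
        i1 = min(n_hi, i0 + max(1, int(round(dur / dt))))
        box[i0:i1, c] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 32.0 + dt, dt))
    from scipy.signal import fftconvolve

    conv = fftconvolve(box, hrf[:, None], axes=0)[:n_hi]
    stride = int(round(tr / dt))
    X = conv[::stride]
    return np.column_stack([X, np.ones(X.shape[0])])  # intercept last


def design_efficiency(
    onsets,
    durations,
    contrast_spec=None,
    condition_idx=None,
    n_conditions: int | None = None,
    tr: float = 1.0,
    dt: float = 0.1,
) -> float:
    """Dale-style estimation efficiency 1 / trace(C (X'X)^-1 C').

    The design matrix is built by convolving per-condition boxcars with the
    canonical double-gamma response at ``dt`` (0.1 s) resolution and sampling
    at ``tr`` (1 s).  ``contrast_spec`` rows address the condition columns
    (identity by default; the intercept is handled internally).  A singular
    X'X yields efficiency 0 with a warning.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    if np.any(np.diff(onsets) <= 0):
        raise ConfigurationError("onsets must be strictly increasing")
    if condition_idx is None:
        condition_idx = np.zeros(len(onsets), dtype=int)
    condition_idx = np.asarray(condition_idx, dtype=int)
    if n_conditions is None:
        n_conditions = int(condition_idx.max()) + 1
    X = _design_matrix(onsets, durations, condition_idx, n_conditions, tr, dt)
    if contrast_spec is None:
        C = np.eye(n_conditions)
    else:
        C = np.atleast_2d(np.asarray(contrast_spec, dtype=float))
    C = np.column_stack([C, np.zeros(C.shape[0])])  # ignore intercept
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        warnings.warn("singular design: efficiency set to 0", stacklevel=2)
        return 0.0
    cov = C @ np.linalg.solve(xtx, C.T)
    denom = float(np.trace(cov))
    if denom <= 0 or not np.isfinite(denom):  # pragma: no cover
        warnings.warn("degenerate contrast covariance: efficiency set to 0", stacklevel=2)
        return 0.0
    return 1.0 / denom


def select_best_design(
    candidates,
    n_candidates: int | None = None,
    contrast_spec=None,
    score=None,
):
    """Return the most efficient candidate design (ties -> lowest index).

    ``candidates`` is an iterable of objects accepted by ``score`` (by default
    timed :class:`DesignSequence` objects scored with
    :func:`session_efficiency`).  Raises if every candidate scores 0.
    """
    if score is None:
        score = lambda d: session_efficiency(d, contrast_spec=contrast_spec)  # noqa: E731
    if n_candidates is not None:
        candidates = itertools.islice(candidates, n_candidates)
    best, best_eff, n_seen = None, 0.0, 0
    for cand in candidates:
        n_seen += 1
        eff = score(cand)
        if eff > best_eff:
            best, best_eff = cand, eff
    if n_seen == 0:
        raise ConfigurationError("no candidate designs supplied")
    if best is None:
        raise ConfigurationError("all candidate designs have zero efficiency")
    return best


def session_efficiency(session: DesignSequence, contrast_spec=None) -> float:
    """Efficiency of a timed session: category trials as conditions."""
    onsets, durs, cond = [], [], []
    cats: dict[str, int] = {}
    for t in session.trials:
        if t.onset_s is None:
            raise ConfigurationError("session must be timed before scoring")
        if t.role != CATEGORY_ROLE:
            continue
        onsets.append(t.onset_s)
        durs.append(t.duration_s)
        cond.append(cats.setdefault(t.category, len(cats)))
    return design_efficiency(
        onsets, durs, contrast_spec=contrast_spec,
        condition_idx=cond, n_conditions=len(cats),
    )


# ---------------------------------------------------------------------------
# timing and run partitioning
# ---------------------------------------------------------------------------

def add_timing(
    session: DesignSequence,
    cfg: TimingConfig,
    rng_seed: int,
    run_length: int | None = None,
) -> DesignSequence:
    """Attach jittered ISIs (sampled per run) and durations to a session.

    Onsets are not set here; they are laid out per run by
    :func:`partition_runs`, which owns lead-in and context timing.
    """
    run_length = run_length or session.meta.get("run_length", len(session))
    timed: list[Trial] = []
    n_runs = len(session) // run_length
    for r in range(n_runs):
        isis = sample_jittered_isis(run_length, cfg, rng_seed + r)
        for t, isi in zip(session.trials[r * run_length : (r + 1) * run_length], isis):
            timed.append(replace(t, duration_s=cfg.stim_duration_s, isi_s=isi))
    return DesignSequence(trials=timed, session_index=session.session_index, meta=dict(session.meta))


@dataclass
class Run:
    run_index: int
    context_trials: list[Trial]
    trials: list[Trial]
    duration_s: float


def partition_runs(
    session: DesignSequence,
    n_runs: int,
    prep_stimulus_pool: dict[str, str],
    cfg: TimingConfig,
) -> list[Run]:
    """Split a timed session into runs with context trials and fixation.

    Each run is: ``lead_in_s`` fixation, three context trials replicating the
    categories of the previous run's final three trials but drawn from the
    separate preparatory exemplar pool (the first run replicates the
    session's own final three trials), the run's trial block, and ``tail_s``
    fixation.  Context trials use the mean ISI.  At the defaults
    (100 trials/run, 2.5 s stimuli, 2.5 s mean ISI) each run lasts
    5 + 15 + 500 + 15 = 535 s.
    """
    if len(session) % n_runs != 0:
        raise ConfigurationError(
            f"n_runs {n_runs} does not divide trial count {len(session)}"
        )
    run_len = len(session) // n_runs
    chunks = [session.trials[i * run_len : (i + 1) * run_len] for i in range(n_runs)]
    runs: list[Run] = []
    for r, chunk in enumerate(chunks):
        prev = chunks[(r - 1) % n_runs]
        ctx_src = prev[-3:]
        ctx: list[Trial] = []
        for t in ctx_src:
            if t.role == CATEGORY_ROLE:
                if t.category not in prep_stimulus_pool:
                    raise ConfigurationError(
                        f"preparatory pool lacks category {t.category!r}"
                    )
                ex = prep_stimulus_pool[t.category]
            else:
                ex = None
            ctx.append(
                Trial(
                    type_code=t.type_code,
                    role=t.role,
                    category=t.category,
                    exemplar_id=ex,
                    duration_s=cfg.stim_duration_s,
                    isi_s=cfg.mean_isi_s,
                )
            )
        # lay out onsets
        t_cursor = cfg.lead_in_s
        for t in ctx:
            t.onset_s = round(t_cursor, 6)
            t_cursor += t.duration_s + t.isi_s
        timed_chunk: list[Trial] = []
        for t in chunk:
            if t.isi_s is None or t.duration_s is None:
                raise ConfigurationError("session must be timed (see add_timing)")
            nt = replace(t, onset_s=round(t_cursor, 6))
            t_cursor += nt.duration_s + nt.isi_s
            timed_chunk.append(nt)
        duration = t_cursor + cfg.tail_s
        runs.append(Run(run_index=r, context_trials=ctx, trials=timed_chunk,
                        duration_s=round(duration, 6)))
    return runs


# ---------------------------------------------------------------------------
# arrangement subset planning
# ---------------------------------------------------------------------------

def plan_arrangement_subsets(
    n_stimuli: int = 90,
    n_subsets: int = 12,
    subset_size: int = 30,
    n_candidates: int = 1000,
    rng_seed: int = 0,
    stimulus_ids: list[str] | None = None,
) -> SubsetPlan:
    """Plan the multiple-arrangement stimulus subsets.

    Each candidate consists of ``n_subsets`` subsets obtained by permuting the
    stimulus list and taking the first ``subset_size`` entries; candidates are
    scored by the number of distinct unordered pairs co-occurring in at least
    one subset, and the best candidate (ties -> lowest index) is returned,
    prepended with the full-set subset.
    """
    if subset_size > n_stimuli:
        raise ConfigurationError("subset_size must be <= n_stimuli")
    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:03d}" for i in range(n_stimuli)]
    rng = np.random.default_rng(rng_seed)
    iu = np.triu_indices(n_stimuli, 1)
    best_score, best_subsets = -1, None
    for _ in range(n_candidates):
        cover = np.zeros((n_stimuli, n_stimuli), dtype=bool)
        subsets = []
        for _ in range(n_subsets):
            idx = rng.permutation(n_stimuli)[:subset_size]
            cover[np.ix_(idx, idx)] = True
            subsets.append(idx)
        score = int(cover[iu].sum())
        if score > best_score:
            best_score, best_subsets = score, subsets
    planned = [list(stimulus_ids)] + [
        [stimulus_ids[i] for i in idx] for idx in best_subsets
    ]
    return SubsetPlan(subsets=planned, unique_pair_count=best_score)
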