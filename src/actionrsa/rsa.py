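"""Relating model RDMs to neural RDMs.

Spearman RSA per model, leave-one-out intersubject noise ceilings, joint
rank-regression R2 over multiple models, hierarchical variance partitioning
(unique R2 = full R2 - nested R2), and a generic neighborhood (searchlight)
mapper that applies any of these analyses to local unit subsets.

Conventions: model RDM vectors are rank-transformed (average ranks) and
standardized before ordinary least squares; the response vector is
rank-standardized as well by default, so the single-model fit reduces
exactly to Spearman rho squared and R2 maps are comparable to the Spearman
RSA maps.  Per-subject statistics are computed first and averaged after --
on the Fisher-z scale for correlations, arithmetically for R2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .rdm import RDM, split_data_rdm
from .stats import fisher_mean, fisher_z, fisher_z_inverse

__all__ = [
    "RSAResult",
    "JointFit",
    "VariancePartition",
    "vectorize_rdm",
    "devectorize_rdm",
    "spearman_rsa",
    "isc_noise_ceiling",
    "joint_regression_r2",
    "variance_partition",
    "neighborhood_map",
]


@dataclass
class RSAResult:
    model: str
    per_subject_rho: list[float]
    region: str = ""

    @property
    def group_mean(self) -> float:
        """Fisher-z mean of the per-subject correlations, back-transformed."""
        return fisher_mean(self.per_subject_rho)


@dataclass
class JointFit:
    model_names: list[str]
    per_subject_coefs: np.ndarray  # (n_subjects, n_models)
    per_subject_r2: list[float]
    meta: dict = field(default_factory=dict)

    @property
    def group_mean_r2(self) -> float:
        return float(np.mean(self.per_subject_r2))

    @property
    def group_mean_coefs(self) -> np.ndarray:
        return self.per_subject_coefs.mean(axis=0)


@dataclass
class VariancePartition:
    full_r2: float
    nested_r2: dict[str, float]
    unique_r2: dict[str, float]
    per_subject: pd.DataFrame | None = None


def vectorize_rdm(rdm: RDM) -> np.ndarray:
    """Upper triangle excluding the diagonal, fixed row-major pair order."""
    return rdm.vector


def devectorize_rdm(stimulus_ids, vector) -> RDM:
    return RDM.from_vector(stimulus_ids, vector)


def _check_aligned(a: RDM, b: RDM) -> None:
    if a.stimulus_ids != b.stimulus_ids:
        raise ValueError("RDMs must share stimuli and stimulus order")


def spearman_rsa(neural: RDM, model: RDM) -> float:
    """Spearman rank correlation between two vectorized RDMs (average ranks)."""
    _check_aligned(neural, model)
    x, y = neural.vector, model.vector
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant RDM vector: Spearman correlation undefined")
    return float(spearmanr(x, y).statistic)


def isc_noise_ceiling(subject_rdms: list[RDM]) -> tuple[list[float], float]:
    """Leave-one-out intersubject correlation of RDMs.

    Each subject's RDM vector is Spearman-correlated with the element-wise
    mean of the other subjects' RDMs; the group value is the Fisher-z mean
    back-transformed.  Returns (per-subject rho, group mean).
    """
    if len(subject_rdms) < 2:
        raise ValueError("need >= 2 subjects for a noise ceiling")
    for r in subject_rdms[1:]:
        _check_aligned(subject_rdms[0], r)
    vecs = np.stack([r.vector for r in subject_rdms])
    n = len(subject_rdms)
    total = vecs.sum(axis=0)
    rhos = []
    for s in range(n):
        others = (total - vecs[s]) / (n - 1)
        rhos.append(float(spearmanr(vecs[s], others).statistic))
    return rhos, fisher_mean(rhos)


def _rank_standardize(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)  # average ranks for ties
    sd = r.std()
    if sd == 0:
        raise ValueError("constant vector cannot be rank-standardized")
    return (r - r.mean()) / sd


def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    Xi = np.column_stack([X, np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst
    return beta[:-1], r2


def joint_regression_r2(
    neural: RDM | list[RDM],
    models: dict[str, RDM] | list[RDM],
    rank_response: bool = True,
    allow_collinear: bool = False,
) -> JointFit:
    """OLS fit of rank-standardized model RDM vectors to the neural RDM.

    Accepts a single neural RDM or one per subject; returns per-subject
    standardized coefficients and R2 (R2 = 1 - SSE/SST, intercept handled
    internally).  With ``rank_response=False`` the response vector is only
    mean/SD standardized, not ranked.  Perfectly collinear predictors are an
    error unless ``allow_collinear`` (R2 stays well-defined through the
    minimum-norm least-squares fit; individual coefficients do not).
    """
    if isinstance(models, dict):
        names = list(models)
        model_list = [models[n] for n in names]
    else:
        names = [m.meta.get("model", f"model{i}") for i, m in enumerate(models)]
        model_list = list(models)
    if not model_list:
        raise ValueError("need >= 1 model")
    neurals = [neural] if isinstance(neural, RDM) else list(neural)
    for m in model_list:
        _check_aligned(neurals[0], m)
    X = np.column_stack([_rank_standardize(m.vector) for m in model_list])
    if (
        not allow_collinear
        and X.shape[1] > 1
        and np.linalg.matrix_rank(X, tol=1e-10) < X.shape[1]
    ):
        raise ValueError(f"collinear model RDMs among {names}")
    coefs, r2s = [], []
    for nr in neurals:
        _check_aligned(neurals[0], nr)
        y = nr.vector
        if rank_response:
            y = _rank_standardize(y)
        else:
            sd = y.std()
            if sd == 0:
                raise ValueError("constant neural RDM vector")
            y = (y - y.mean()) / sd
        beta, r2 = _ols_r2(y, X)
        coefs.append(beta)
        r2s.append(r2)
    return JointFit(
        model_names=names,
        per_subject_coefs=np.stack(coefs),
        per_subject_r2=r2s,
        meta={"rank_response": rank_response},
    )


def variance_partition(
    neural: RDM | list[RDM],
    all_models: dict[str, RDM],
    groups: dict[str, list[str]],
    rank_response: bool = True,
) -> VariancePartition:
    """Unique R2 per model group via hierarchical regression.

    The full model uses all model RDMs; for each named group a nested model
    excludes that group's members, and unique R2 = full R2 - nested R2.
    Computed per subject, then averaged.
    """
    names = list(all_models)
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} is empty")
        unknown = set(members) - set(names)
        if unknown:
            raise ValueError(f"group {gname!r} references unknown models {unknown}")
        if set(members) == set(names):
            raise ValueError(f"group {gname!r} equals the full model set")
    neurals = [neural] if isinstance(neural, RDM) else list(neural)
    full = joint_regression_r2(neurals, all_models, rank_response, allow_collinear=True)
    full_per_subj = np.array(full.per_subject_r2)
    nested_per_subj = {}
    for gname, members in groups.items():
        nested_models = {n: all_models[n] for n in names if n not in members}
        fit = joint_regression_r2(neurals, nested_models, rank_response, allow_collinear=True)
        nested_per_subj[gname] = np.array(fit.per_subject_r2)
    rows = []
    for s in range(len(neurals)):
        row = {"subject": s, "full_r2": full_per_subj[s]}
        for gname in groups:
            row[f"nested_r2_{gname}"] = nested_per_subj[gname][s]
            row[f"unique_r2_{gname}"] = full_per_subj[s] - nested_per_subj[gname][s]
        rows.append(row)
    per_subject = pd.DataFrame(rows).set_index("subject")
    nested = {g: float(v.mean()) for g, v in nested_per_subj.items()}
    return VariancePartition(
        full_r2=float(full_per_subj.mean()),
        nested_r2=nested,
        unique_r2={g: float(full_per_subj.mean() - v) for g, v in nested.items()},
        per_subject=per_subject,
    )


def neighborhood_map(
    patterns_s1: pd.DataFrame,
    patterns_s2: pd.DataFrame,
    neighborhoods: dict[int, list[int]],
    analysis,
) -> pd.DataFrame:
    """Apply an RDM analysis within each unit neighborhood.

    For each center, both sessions' patterns are restricted to the member
    units, a split-data RDM is built, and ``analysis(rdm) -> float`` is
    applied.  Neighborhoods with fewer than 2 members yield NaN (logged via
    the returned table's ``n_members`` column).  Returns a tidy frame
    (center, value, n_members).
    """
    rows = []
    for center, members in neighborhoods.items():
        if len(members) < 2:
            rows.append({"center": center, "value": np.nan, "n_members": len(members)})
            continue
        cols1 = patterns_s1.columns[members]
        cols2 = patterns_s2.columns[members]
        rdm = split_data_rdm(patterns_s1[cols1], patterns_s2[cols2])
        rows.append(
            {"center": center, "value": float(analysis(rdm)), "n_members": len(members)}
        )
    return pd.DataFrame(rows).set_index("center")
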