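"""Delimited-text readers and writers for every pipeline artifact.

All on-disk formats are plain text: square-matrix CSV or long-form TSV for
RDMs, tidy TSV tables for designs, arrangement logs, gaze logs, pattern
tables and embeddings, and JSON sidecars for seeds/configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSequence, Run, SubsetPlan
from .rdm import RDM, ArrangementTrial, GazeTrajectory

__all__ = [
    "write_rdm",
    "read_rdm",
    "write_rdm_long",
    "read_rdm_long",
    "write_pattern_table",
    "read_pattern_table",
    "write_design",
    "write_subset_plan",
    "read_subset_plan",
    "write_arrangements",
    "read_arrangements",
    "write_gaze",
    "read_gaze",
    "write_embeddings",
    "read_embeddings",
    "write_manifest",
    "read_manifest",
]


# ----------------------------------------------------------------- RDMs

def write_rdm(rdm: RDM, path) -> None:
    """Square-matrix CSV with stimulus ids as header row and column."""
    df = pd.DataFrame(rdm.matrix, index=rdm.stimulus_ids, columns=rdm.stimulus_ids)
    df.to_csv(path)


def read_rdm(path, meta=None) -> RDM:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        df = df.loc[df.columns]  # tolerate row order differing from columns
    return RDM(list(df.columns), df.to_numpy(dtype=float), meta or {})


def write_rdm_long(rdm: RDM, path) -> None:
    """Long-form TSV: stim_i, stim_j, dissimilarity (upper triangle)."""
    iu = np.triu_indices(rdm.n_stimuli, 1)
    rows = {
        "stim_i": [rdm.stimulus_ids[i] for i in iu[0]],
        "stim_j": [rdm.stimulus_ids[j] for j in iu[1]],
        "dissimilarity": rdm.matrix[iu],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rdm_long(path, meta=None) -> RDM:
    df = pd.read_csv(path, sep="\t")
    ids = sorted(set(df["stim_i"]) | set(df["stim_j"]))
    pos = {s: i for i, s in enumerate(ids)}
    m = len(ids)
    mat = np.zeros((m, m))
    seen = np.zeros((m, m), dtype=bool)
    for _, row in df.iterrows():
        i, j = pos[row["stim_i"]], pos[row["stim_j"]]
        mat[i, j] = mat[j, i] = row["dissimilarity"]
        seen[i, j] = seen[j, i] = True
    iu = np.triu_indices(m, 1)
    if not seen[iu].all():
        raise ValueError("long-form RDM is missing pairs")
    return RDM(ids, mat, meta or {})


# ------------------------------------------------------------- patterns

def write_pattern_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="stimulus_id")


def read_pattern_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="stimulus_id")


# --------------------------------------------------------------- design

def write_design(runs: list[Run], path, sidecar: dict | None = None) -> None:
    """One row per trial: run, trial_index, onset, duration, role, category,
    exemplar, ISI.  Context trials get negative trial indices."""
    rows = []
    for run in runs:
        for k, t in enumerate(run.context_trials):
            rows.append(
                dict(run=run.run_index, trial_index=k - len(run.context_trials),
                     onset_s=t.onset_s, duration_s=t.duration_s, type_role=t.role,
                     category=t.category or "", exemplar_id=t.exemplar_id or "",
                     isi_s=t.isi_s)
            )
        for k, t in enumerate(run.trials):
            rows.append(
                dict(run=run.run_index, trial_index=k, onset_s=t.onset_s,
                     duration_s=t.duration_s, type_role=t.role,
                     category=t.category or "", exemplar_id=t.exemplar_id or "",
                     isi_s=t.isi_s)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        write_manifest(sidecar, Path(path).with_suffix(".json"))


def write_subset_plan(plan: SubsetPlan, path) -> None:
    rows = [
        {"subset_index": i, "stimulus_id": s}
        for i, subset in enumerate(plan.subsets)
        for s in subset
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_subset_plan(path) -> SubsetPlan:
    df = pd.read_csv(path, sep="\t")
    subsets = [
        list(df.loc[df["subset_index"] == i, "stimulus_id"])
        for i in sorted(df["subset_index"].unique())
    ]
    n = len(subsets[0])
    cover = set()
    for sub in subsets[1:]:
        pos = {s: i for i, s in enumerate(subsets[0])}
        idx = [pos[s] for s in sub]
        cover.update((min(a, b), max(a, b)) for a in idx for b in idx if a != b)
    return SubsetPlan(subsets=subsets, unique_pair_count=len(cover))


# ---------------------------------------------------------- arrangements

def write_arrangements(trials: list[ArrangementTrial], path) -> None:
    rows = []
    for t in trials:
        for s, (x, y) in zip(t.subset, t.coords):
            rows.append(
                dict(task=t.task, participant=t.participant,
                     trial_index=t.trial_index, stimulus_id=s, x_px=x, y_px=y)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_arrangements(path) -> list[ArrangementTrial]:
    df = pd.read_csv(path, sep="\t")
    trials = []
    for (task, participant, idx), grp in df.groupby(
        ["task", "participant", "trial_index"], sort=True
    ):
        trials.append(
            ArrangementTrial(
                task=task,
                subset=list(grp["stimulus_id"]),
                coords=grp[["x_px", "y_px"]].to_numpy(dtype=float),
                participant=participant,
                trial_index=int(idx),
            )
        )
    return trials


# ----------------------------------------------------------------- gaze

def write_gaze(trajectories: list[GazeTrajectory], path) -> None:
    frames = []
    for t in trajectories:
        frames.append(
            pd.DataFrame(
                dict(participant=t.participant_id, block=t.block,
                     stimulus_id=t.stimulus_id, t_ms=t.t_ms, x_px=t.x,
                     y_px=t.y, valid=t.valid.astype(int))
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gaze(path) -> list[GazeTrajectory]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (pid, block, stim), grp in df.groupby(
        ["participant", "block", "stimulus_id"], sort=True
    ):
        grp = grp.sort_values("t_ms")
        out.append(
            GazeTrajectory(
                t_ms=grp["t_ms"].to_numpy(float),
                x=grp["x_px"].to_numpy(float),
                y=grp["y_px"].to_numpy(float),
                valid=grp["valid"].to_numpy(bool),
                stimulus_id=stim, participant_id=pid, block=int(block),
            )
        )
    return out


# ------------------------------------------------------------ embeddings

def write_embeddings(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="token")


def read_embeddings(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="token")


# -------------------------------------------------------------- manifest

def write_manifest(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=str) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
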