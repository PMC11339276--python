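"""Delimited-text readers and writers for the pipeline's data types.

All formats are plain text: PatternSets as CSV matrices with a stimulus-id
index column and voxel-id header, RDMs as square labeled CSV matrices, trial
sequences as tidy tables, pupil traces as a two-column samples file plus an
events file. Every writer/reader pair round-trips losslessly within float
precision; schema violations raise errors naming the offending column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rsa import RDM
from .synthdata import PatternSet, PupilTrace, TrialSequence

_TRIAL_COLUMNS = ["onset", "stim_id", "pair_index", "role", "condition", "baseline_after"]


def write_pattern_set(ps: PatternSet, path: str | Path) -> None:
    df = pd.DataFrame(ps.data, index=pd.Index(ps.stim_ids, name="stim_id"),
                      columns=[f"v{j}" for j in range(ps.n_voxels)])
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# roi={ps.roi} condition={ps.condition} group={ps.group}\n")
        df.to_csv(fh, float_format="%.17g")


def read_pattern_set(path: str | Path) -> PatternSet:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, index_col=0)
    return PatternSet(data=df.to_numpy(dtype=float), stim_ids=list(df.index),
                      roi=meta.get("roi", ""), condition=meta.get("condition", ""),
                      group=meta.get("group", ""))


def write_rdm(rdm: RDM, path: str | Path) -> None:
    df = pd.DataFrame(rdm.matrix, index=pd.Index(rdm.labels, name="stim_id"),
                      columns=rdm.labels)
    with open(path, "w") as fh:
        fh.write(f"# metric={rdm.metric} level={rdm.level}\n")
        df.to_csv(fh, float_format="%.17g")


def read_rdm(path: str | Path) -> RDM:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh, index_col=0)
    return RDM(matrix=df.to_numpy(dtype=float), labels=list(df.index),
               metric=meta.get("metric", "cosine"), level=meta.get("level", "first"))


def write_trial_sequence(seq: TrialSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phase={seq.phase} tr={seq.tr}\n")
        seq.table[_TRIAL_COLUMNS].to_csv(fh, index=False, float_format="%.17g")


def read_trial_sequence(path: str | Path) -> TrialSequence:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial sequence file missing columns: {missing}")
    return TrialSequence(table=df, phase=meta.get("phase", "test"),
                         tr=float(meta.get("tr", 2.0)))


def write_pupil_trace(trace: PupilTrace, samples_path: str | Path,
                      events_path: str | Path) -> None:
    t = np.arange(trace.samples.size) / trace.rate_hz
    pd.DataFrame({"time_s": t, "area": trace.samples}).to_csv(
        samples_path, index=False, float_format="%.17g")
    events = {
        "rate_hz": trace.rate_hz,
        "entrainment_strength": trace.entrainment_strength,
        "image_onsets": trace.image_onsets.tolist(),
        "pair_onsets": trace.pair_onsets.tolist(),
        "block_bounds": [list(b) for b in trace.block_bounds],
    }
    Path(events_path).write_text(json.dumps(events))


def read_pupil_trace(samples_path: str | Path, events_path: str | Path) -> PupilTrace:
    df = pd.read_csv(samples_path)
    for col in ("time_s", "area"):
        if col not in df.columns:
            raise ValueError(f"pupil samples file missing column: {col!r}")
    ev = json.loads(Path(events_path).read_text())
    return PupilTrace(
        samples=df["area"].to_numpy(dtype=float),
        rate_hz=float(ev["rate_hz"]),
        image_onsets=np.asarray(ev["image_onsets"], dtype=float),
        pair_onsets=np.asarray(ev["pair_onsets"], dtype=float),
        block_bounds=[tuple(b) for b in ev["block_bounds"]],
        entrainment_strength=float(ev.get("entrainment_strength", 0.0)),
    )
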