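"""Plain-text I/O: long-format intensity CSV, trial logs, design/ground-truth JSON.

Formats
-------
raw intensity CSV : columns ``time_s, channel, wavelength_nm, intensity``
trial log CSV     : columns ``participant, tilt, block_level, trial_index,
                    operand_a, operator, operand_b, result, correct_response,
                    response, rt_s, onset_s`` (UTF-8, '.' decimal separator)
design JSON       : (participant_index, seed, block orders, timing); sessions
                    are reproducible from (participant_index, seed) alone and
                    the stored orders are verified on load.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .processing import RawRecording
from .simulate import Artifact, BehaviorEffects, GroundTruth, HRFParams, OscComponent
from .task import SessionDesign, TrialResponse, build_session

__all__ = [
    "raw_to_csv",
    "raw_from_csv",
    "trials_to_frame",
    "responses_from_frame",
    "design_to_json",
    "design_from_json",
    "ground_truth_to_json",
    "ground_truth_from_json",
]

TRIAL_COLUMNS = [
    "participant",
    "tilt",
    "block_level",
    "trial_index",
    "operand_a",
    "operator",
    "operand_b",
    "result",
    "correct_response",
    "response",
    "rt_s",
    "onset_s",
]


def raw_to_csv(raw: RawRecording, path: str | Path) -> None:
    t = np.arange(raw.n_samples) / raw.fs
    frames = [
        pd.DataFrame(
            {"time_s": t, "channel": ch, "wavelength_nm": wl, "intensity": series}
        )
        for (ch, wl), series in raw.intensity.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def raw_from_csv(path: str | Path) -> RawRecording:
    df = pd.read_csv(path)
    intensity = {}
    fs = None
    for (ch, wl), grp in df.groupby(["channel", "wavelength_nm"], sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        if len(t) > 1:
            fs_here = 1.0 / np.median(np.diff(t))
            if fs is None:
                fs = fs_here
            elif abs(fs_here - fs) > 1e-6 * fs:
                raise ValueError("inconsistent sampling rates across channels")
        intensity[(str(ch), int(wl))] = grp["intensity"].to_numpy(dtype=float)
    if fs is None:
        raise ValueError("cannot infer sampling rate from a single sample")
    return RawRecording(fs=float(fs), intensity=intensity)


def trials_to_frame(
    design: SessionDesign,
    responses: dict[tuple[str, int], list[TrialResponse]] | None = None,
    participant: int | None = None,
) -> pd.DataFrame:
    """Flatten a session (optionally with responses) into the trial-log layout."""
    rows = []
    for tilt in design.tilt_sequence:
        for slot, block in enumerate(design.blocks_by_tilt[tilt]):
            resp_by_idx = {}
            if responses is not None:
                resp_by_idx = {r.trial_index: r for r in responses.get((tilt, slot), [])}
            for trial in block.trials:
                r = resp_by_idx.get(trial.index)
                rows.append(
                    {
                        "participant": participant
                        if participant is not None
                        else design.participant_index,
                        "tilt": tilt,
                        "block_level": block.level,
                        "trial_index": trial.index,
                        "operand_a": trial.operand_a,
                        "operator": trial.operator,
                        "operand_b": trial.operand_b,
                        "result": trial.result,
                        "correct_response": trial.correct_response or "",
                        "response": r.response if r else "",
                        "rt_s": r.response_time if r and r.response_time is not None else "",
                        "onset_s": trial.onset,
                    }
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def responses_from_frame(df: pd.DataFrame) -> dict[tuple[str, int], list[TrialResponse]]:
    """Rebuild per-block response lists; blocks keyed (tilt, slot) in file order."""
    out: dict[tuple[str, int], list[TrialResponse]] = {}
    for (_p, tilt), grp in df.groupby(["participant", "tilt"], sort=False):
        for slot, (_lv, block_grp) in enumerate(grp.groupby("block_level", sort=False)):
            resp = []
            for _, row in block_grp.iterrows():
                r = str(row["response"]) if not pd.isna(row["response"]) else ""
                rt = row["rt_s"]
                rt = None if (pd.isna(rt) or rt == "") else float(rt)
                resp.append(TrialResponse(int(row["trial_index"]), r or "none", rt))
            out[(tilt, slot)] = resp
    return out


def design_to_json(design: SessionDesign, path: str | Path | None = None) -> dict:
    doc = {
        "participant_index": design.participant_index,
        "seed": design.seed,
        "tilt_sequence": list(design.tilt_sequence),
        "tilt_duration_s": design.tilt_duration_s,
        "task_offset_s": design.task_offset_s,
        "n_trials": design.blocks_by_tilt[design.tilt_sequence[0]][0].n_trials,
        "block_orders": {t: list(design.block_order(t)) for t in design.tilt_sequence},
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def design_from_json(doc: dict | str | Path) -> SessionDesign:
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    design = build_session(
        doc["participant_index"], rng_seed=doc["seed"], n_trials=doc.get("n_trials", 20)
    )
    for tilt, order in doc.get("block_orders", {}).items():
        if list(design.block_order(tilt)) != list(order):
            raise ValueError(
                f"stored block order for {tilt} does not match the (participant, seed) "
                "reconstruction; the file may be hand-edited or from another version"
            )
    return design


def ground_truth_to_json(gt: GroundTruth, path: str | Path | None = None) -> dict:
    doc = dataclasses.asdict(gt)
    doc["oscillations"] = [dataclasses.asdict(o) for o in gt.oscillations]
    doc["artifacts"] = [dataclasses.asdict(a) for a in gt.artifacts]
    doc["hrf"] = dataclasses.asdict(gt.hrf)
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def ground_truth_from_json(doc: dict | str | Path) -> GroundTruth:
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    doc = dict(doc)
    doc["oscillations"] = tuple(OscComponent(**o) for o in doc.get("oscillations", []))
    doc["artifacts"] = tuple(Artifact(**a) for a in doc.get("artifacts", []))
    doc["hrf"] = HRFParams(**doc.get("hrf", {}))
    return GroundTruth(**doc)


def behavior_effects_from_dict(doc: dict) -> BehaviorEffects:
    return BehaviorEffects(**doc)
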