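"""Readers and writers for the pipeline's delimited-text and array formats.

Eye traces are two-column CSV (time_s, position_deg); saccade events and
fixations are CSV tables with headers; cell traces travel in an ``.npz``
container with named arrays; ground truth is JSON; frame stacks are
multipage TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import EyeTrace, SaccadeEvent, FixationInterval
from .sta_analysis import CellTrace


def write_eye_trace(path: str | Path, trace: EyeTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "position_deg": trace.position_deg}
    ).to_csv(path, index=False)


def read_eye_trace(path: str | Path, eye_label: str = "left") -> EyeTrace:
    df = pd.read_csv(path)
    return EyeTrace(
        df["time_s"].to_numpy(), df["position_deg"].to_numpy(), eye_label=eye_label
    )


def write_events(path: str | Path, events: list[SaccadeEvent]) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset_time_s for e in events],
            "direction": [e.direction for e in events],
            "amplitude_deg": [e.amplitude_deg for e in events],
            "peak_velocity_deg_s": [e.peak_velocity_deg_s for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[SaccadeEvent]:
    df = pd.read_csv(path)
    return [
        SaccadeEvent(
            onset_time_s=float(r.onset_s),
            direction=str(r.direction),
            amplitude_deg=float(r.amplitude_deg),
            peak_velocity_deg_s=float(r.peak_velocity_deg_s),
        )
        for r in df.itertuples()
    ]


def write_fixations(path: str | Path, fixations: list[FixationInterval]) -> None:
    pd.DataFrame(
        {
            "start_s": [f.start_s for f in fixations],
            "end_s": [f.end_s for f in fixations],
            "duration_s": [f.duration_s for f in fixations],
            "preceding_direction": [f.preceding_direction for f in fixations],
            "following_direction": [f.following_direction for f in fixations],
        }
    ).to_csv(path, index=False)


def save_cells(path: str | Path, cells: list[CellTrace]) -> None:
    """Store cell traces in a single ``.npz`` (cells share a time grid)."""
    if not cells:
        raise ValueError("no cells to save")
    np.savez_compressed(
        path,
        time_s=cells[0].time_s,
        F=np.stack([c.F for c in cells]),
        dFF=np.stack([c.dFF for c in cells]),
        deconv=np.stack([c.deconv for c in cells]),
        xyz_um=np.stack([c.xyz_um for c in cells]),
        cell_ids=np.array([c.cell_id for c in cells]),
    )


def load_cells(path: str | Path) -> list[CellTrace]:
    with np.load(path, allow_pickle=False) as data:
        return [
            CellTrace(
                time_s=data["time_s"],
                F=data["F"][i],
                dFF=data["dFF"][i],
                deconv=data["deconv"][i],
                xyz_um=data["xyz_um"][i],
                cell_id=str(data["cell_ids"][i]),
            )
            for i in range(data["F"].shape[0])
        ]


def write_frames(path: str | Path, frames: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def read_frames(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_experiments(path: str | Path, experiments) -> None:
    """Ablation records as long-format CSV (animal, group, condition, duration)."""
    rows = []
    for exp in experiments:
        for cond, durs in (
            ("before", exp.fixations_before),
            ("after", exp.fixations_after),
        ):
            for d in durs:
                rows.append(
                    {
                        "animal_id": exp.animal_id,
                        "group": exp.group,
                        "condition": cond,
                        "fixation_duration_s": d,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_experiments(path: str | Path):
    from .ablation_analysis import AblationExperiment

    df = pd.read_csv(path)
    out = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        out.append(
            AblationExperiment(
                animal_id=str(animal),
                group=str(group),
                fixations_before=sub.loc[
                    sub["condition"] == "before", "fixation_duration_s"
                ].to_numpy(),
                fixations_after=sub.loc[
                    sub["condition"] == "after", "fixation_duration_s"
                ].to_numpy(),
            )
        )
    return out
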