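"""File formats: HDF5 pulse containers, dose tables, YAML plans, JSON reports.

The waveform container is a single HDF5 file holding a 2-D dataset
``samples`` of shape (n_pulses, n_samples) with attributes ``sample_rate``
(Hz) and ``excitation_freq`` (Hz) and an optional 1-D ``pulse_times``
dataset (seconds).  NIfTI volume I/O lives on :class:`~cavimap.grids.VolumeGrid`.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .acoustic import CavitationDose, CavitationLevels, PulseRecord
from .errors import InvalidInputError
from .opening import VoiSpec
from .targeting import TargetPlan

__all__ = [
    "write_pulses_h5",
    "read_pulses_h5",
    "write_dose_report",
    "read_plan_yaml",
    "write_plan_yaml",
    "read_voi_yaml",
]


def write_pulses_h5(path, pulses: list[PulseRecord]) -> None:
    if not pulses:
        raise InvalidInputError("no pulses to write")
    n = {p.samples.size for p in pulses}
    if len(n) != 1:
        raise InvalidInputError("all pulses must have the same length")
    with h5py.File(str(path), "w") as f:
        f.create_dataset(
            "samples", data=np.stack([p.samples for p in pulses]), compression="gzip"
        )
        f.create_dataset("pulse_times", data=np.array([p.timestamp for p in pulses]))
        f.attrs["sample_rate"] = pulses[0].sample_rate
        f.attrs["excitation_freq"] = pulses[0].excitation_freq


def read_pulses_h5(path) -> list[PulseRecord]:
    with h5py.File(str(path), "r") as f:
        samples = np.asarray(f["samples"])
        times = (
            np.asarray(f["pulse_times"])
            if "pulse_times" in f
            else np.zeros(samples.shape[0])
        )
        rate = float(f.attrs["sample_rate"])
        f0 = float(f.attrs["excitation_freq"])
    return [
        PulseRecord(
            samples=row, sample_rate=rate, excitation_freq=f0, pulse_index=i,
            timestamp=float(times[i]),
        )
        for i, row in enumerate(samples)
    ]


def write_dose_report(
    out_prefix, levels: list[CavitationLevels], dose: CavitationDose
) -> tuple[Path, Path]:
    """Per-pulse CSV plus JSON dose summary; returns the two paths."""
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    pd.DataFrame(
        [
            {"pulse_index": lv.pulse_index, "dSCDh": lv.dSCDh, "dSCDu": lv.dSCDu, "dICD": lv.dICD}
            for lv in levels
        ]
    ).to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(
            {
                "SCDh": dose.SCDh,
                "SCDu": dose.SCDu,
                "ICD": dose.ICD,
                "total": dose.total,
                "n_pulses": dose.n_pulses,
                "baseline_subtracted": dose.baseline_subtracted,
            },
            indent=2,
        )
    )
    return csv_path, json_path


def write_plan_yaml(path, plan: TargetPlan) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "focus_mm": [float(v) for v in plan.focus],
                "trajectory": [float(v) for v in plan.trajectory],
            }
        )
    )


def read_plan_yaml(path) -> TargetPlan:
    d = yaml.safe_load(Path(path).read_text())
    return TargetPlan(focus=tuple(d["focus_mm"]), trajectory=tuple(d["trajectory"]))


def read_voi_yaml(path) -> VoiSpec:
    d = yaml.safe_load(Path(path).read_text())
    return VoiSpec(
        center=tuple(d["center_mm"]),
        extents=tuple(d.get("extents_mm", (10.0, 10.0, 32.5))),
        mirror_plane_x=float(d.get("mirror_plane_x_mm", 0.0)),
    )
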