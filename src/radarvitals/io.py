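"""On-disk formats: HDF5 radar cubes with ground truth, CSV traces, JSON
reports.

Cube layout: ``/cube`` (frames x chirps x samples, float32), ``/config``
attributes mirroring :class:`~radarvitals.config.RadarConfig`, optional
``/truth/*`` arrays (valley times, IBI series, clean displacement, frame
times) plus scalar attributes (true BR/HR).
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .config import RadarConfig
from .synthetic import GroundTruth, RadarCube
from .range_processing import BinDisplacementSet
from .vitals import VitalsReport

__all__ = [
    "write_cube", "read_cube", "write_displacements", "read_displacements",
    "write_truth_csv", "write_report", "report_json",
]


def write_cube(path: str, cube: RadarCube, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=np.asarray(cube.samples, dtype=np.float32),
                          compression="gzip", compression_opts=1)
        fh.create_dataset("timestamps", data=cube.timestamps)
        grp = fh.create_group("config")
        for key, value in cube.config.to_dict().items():
            grp.attrs[key] = value
        if truth is not None:
            tg = fh.create_group("truth")
            tg.create_dataset("valley_times", data=truth.valley_times)
            tg.create_dataset("ibi_series", data=truth.ibi_series)
            tg.create_dataset("displacement_clean", data=truth.displacement_clean)
            tg.create_dataset("frame_times", data=truth.frame_times)
            tg.attrs["br_true"] = truth.br_true
            tg.attrs["hr_true"] = truth.hr_true


def read_cube(path: str) -> tuple[RadarCube, GroundTruth | None]:
    with h5py.File(path, "r") as fh:
        attrs = dict(fh["config"].attrs)
        field_names = {f.name for f in dataclasses.fields(RadarConfig)}
        config = RadarConfig(**{k: (int(v) if k in ("samples_per_chirp", "chirps_per_frame") else float(v))
                                for k, v in attrs.items() if k in field_names})
        cube = RadarCube(fh["cube"][()], config, fh["timestamps"][()])
        truth = None
        if "truth" in fh:
            tg = fh["truth"]
            truth = GroundTruth(
                valley_times=tg["valley_times"][()],
                ibi_series=tg["ibi_series"][()],
                br_true=float(tg.attrs["br_true"]),
                hr_true=float(tg.attrs["hr_true"]),
                displacement_clean=tg["displacement_clean"][()],
                frame_times=tg["frame_times"][()],
            )
    return cube, truth


def write_displacements(path: str, disp: BinDisplacementSet,
                        spike_masks: np.ndarray | None = None) -> None:
    """CSV with columns time_s, bin<k>_mm [, bin<k>_spike]."""
    header = ["time_s"] + [f"bin{b}_mm" for b in disp.bin_ids]
    columns = [disp.frame_times] + list(disp.traces)
    if spike_masks is not None:
        header += [f"bin{b}_spike" for b in disp.bin_ids]
        columns += [m.astype(int) for m in np.atleast_2d(spike_masks)]
    data = np.column_stack(columns)
    np.savetxt(path, data, delimiter=",", header=",".join(header), comments="")


def read_displacements(path: str, prf: float | None = None) -> BinDisplacementSet:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    times = data[:, 0]
    bin_cols = [(i, int(name[3:name.index("_")]))
                for i, name in enumerate(header)
                if name.startswith("bin") and name.endswith("_mm")]
    traces = np.stack([data[:, i] for i, _ in bin_cols])
    if prf is None:
        prf = 1.0 / float(np.median(np.diff(times)))
    return BinDisplacementSet(traces, [b for _, b in bin_cols], prf, times)


def write_imfs(path: str, imfs) -> None:
    """CSV dump of a decomposition for inspection: one column per mode
    (header carries the centre frequencies) plus the residual."""
    header = [f"mode{k}_cf{cf:.3f}Hz" for k, cf in
              enumerate(imfs.center_frequencies)] + ["residual"]
    data = np.column_stack([imfs.modes.T, imfs.residual])
    np.savetxt(path, data, delimiter=",", header=",".join(header), comments="")


def write_truth_csv(path: str, truth: GroundTruth) -> None:
    data = np.column_stack([truth.frame_times, truth.displacement_clean])
    np.savetxt(path, data, delimiter=",", header="time_s,disp_mm", comments="")


def report_json(report: VitalsReport) -> str:
    """Deterministic JSON rendering (stable key order, fixed rounding)."""
    return json.dumps(report.to_dict(), sort_keys=True, indent=2)


def write_report(path: str, report: VitalsReport) -> None:
    with open(path, "w") as fh:
        fh.write(report_json(report) + "\n")
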