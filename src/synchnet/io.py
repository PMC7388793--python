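"""Plain-text I/O for recordings and cohorts, plus optional EDF reading.

Recordings are stored as a TSV matrix (channels x samples) next to a JSON
sidecar holding the sampling rate, channel labels, EOG designation, and
reference state. Cohorts add a metadata TSV and a ground-truth JSON.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .preprocess import RawRecording


def save_recording(directory, subject: str, raw: RawRecording) -> pathlib.Path:
    """Write ``<subject>.tsv`` plus ``<subject>.json`` under ``directory``."""
    out = pathlib.Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / f"{subject}.tsv", raw.data, delimiter="\t", fmt="%.6g")
    header = {"fs": raw.fs, "labels": list(raw.labels),
              "eog_channels": list(raw.eog_channels),
              "reference": raw.reference}
    with open(out / f"{subject}.json", "w") as fh:
        json.dump(header, fh, indent=2)
    return out / f"{subject}.tsv"


def load_recording(directory, subject: str) -> RawRecording:
    path = pathlib.Path(directory)
    data = np.loadtxt(path / f"{subject}.tsv", delimiter="\t", ndmin=2)
    with open(path / f"{subject}.json") as fh:
        header = json.load(fh)
    return RawRecording(data=data, fs=header["fs"],
                        labels=tuple(header["labels"]),
                        eog_channels=tuple(header["eog_channels"]),
                        reference=header.get("reference", "original"))


def save_cohort(directory, cohort) -> None:
    """Write per-subject recordings, the metadata TSV, and ground truth."""
    out = pathlib.Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.subjects:
        save_recording(out, rec.subject, rec.recording)
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2)


def load_cohort_recordings(directory) -> tuple[dict[str, RawRecording],
                                               pd.DataFrame, dict]:
    """Load what :func:`save_cohort` wrote: recordings, metadata, ground truth."""
    path = pathlib.Path(directory)
    metadata = pd.read_csv(path / "metadata.tsv", sep="\t")
    with open(path / "ground_truth.json") as fh:
        truth = json.load(fh)
    recordings = {s: load_recording(path, s) for s in metadata["subject"]}
    return recordings, metadata, truth


def read_edf(path, eog_channels: tuple[str, ...] = ()) -> RawRecording:
    """Read an EDF recording into a :class:`RawRecording` (data in uV).

    Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' extra") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return RawRecording(data=data, fs=float(raw.info["sfreq"]),
                        labels=tuple(raw.ch_names),
                        eog_channels=tuple(eog_channels),
                        reference="original")
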