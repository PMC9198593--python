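"""Dataset container on disk, plus real-mode readers (WAV, EDF, BrainVision).

Layout written by :func:`write_dataset`::

    <root>/
      cohort.json                  # grid, subject ids, SRT_50 values
      behavior.csv                 # subject, delta_snr_db, intelligibility_pct, ...
      <subject>/cond_<ΔSNR>/
        envelope.npy  eeg.npy  meta.json   # fs, labels, condition

Arrays are stored as .npy with JSON sidecars; the round trip is lossless.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError
from .containers import BehavioralSample, Cohort, EEGRecording, Envelope, SubjectData

log = logging.getLogger("speechtrf.io")


def _cond_dirname(dsnr: float) -> str:
    return f"cond_{dsnr:+g}".replace(".", "p")


def write_dataset(cohort: Cohort, path: str | Path) -> Path:
    """Serialize a cohort; returns the dataset root."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    behavior_rows = []
    meta = {
        "delta_snr_grid_db": list(cohort.delta_snr_grid_db),
        "subjects": [],
    }
    for sub in cohort.subjects:
        meta["subjects"].append({"id": sub.subject_id, "srt50_db": sub.srt50_db})
        for dsnr in sub.conditions:
            cdir = root / sub.subject_id / _cond_dirname(dsnr)
            cdir.mkdir(parents=True, exist_ok=True)
            env = sub.envelopes[dsnr]
            np.save(cdir / "envelope.npy", env.samples)
            side = {
                "delta_snr_db": dsnr,
                "envelope_fs_hz": env.fs_hz,
                "compression_exponent": env.compression_exponent,
                "envelope_filtered": env.filtered,
            }
            if dsnr in sub.eeg:
                eeg = sub.eeg[dsnr]
                np.save(cdir / "eeg.npy", eeg.data)
                side["eeg_fs_hz"] = eeg.fs_hz
                side["channel_names"] = list(eeg.channel_names)
            with open(cdir / "meta.json", "w") as fh:
                json.dump(side, fh, indent=1)
            if dsnr in sub.behavior:
                b = sub.behavior[dsnr]
                behavior_rows.append(
                    {
                        "subject": sub.subject_id,
                        "delta_snr_db": dsnr,
                        "intelligibility_pct": b.intelligibility_pct,
                        "n_sentences": b.n_sentences,
                        "words_per_sentence": b.words_per_sentence,
                    }
                )
    pd.DataFrame(behavior_rows).to_csv(root / "behavior.csv", index=False)
    with open(root / "cohort.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    log.info("wrote dataset with %d subjects to %s", cohort.n_subjects, root)
    return root


def read_dataset(path: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_dataset`."""
    root = Path(path)
    meta_file = root / "cohort.json"
    if not meta_file.exists():
        raise DataError(f"not a dataset: missing {meta_file}")
    behavior_file = root / "behavior.csv"
    if not behavior_file.exists():
        raise DataError(f"missing behavior table: {behavior_file}")
    with open(meta_file) as fh:
        meta = json.load(fh)
    for key in ("delta_snr_grid_db", "subjects"):
        if key not in meta:
            raise DataError(f"{meta_file}: missing field {key!r}")
    behavior = pd.read_csv(behavior_file)
    subjects = []
    for entry in meta["subjects"]:
        sub = SubjectData(subject_id=entry["id"], srt50_db=float(entry["srt50_db"]))
        for dsnr in meta["delta_snr_grid_db"]:
            cdir = root / sub.subject_id / _cond_dirname(dsnr)
            side_file = cdir / "meta.json"
            if not side_file.exists():
                raise DataError(f"missing condition sidecar: {side_file}")
            with open(side_file) as fh:
                side = json.load(fh)
            env = Envelope(
                samples=np.load(cdir / "envelope.npy"),
                fs_hz=side["envelope_fs_hz"],
                compression_exponent=side.get("compression_exponent", 0.6),
                condition=dsnr,
                filtered=side.get("envelope_filtered", False),
            )
            sub.envelopes[dsnr] = env
            if (cdir / "eeg.npy").exists():
                sub.eeg[dsnr] = EEGRecording(
                    data=np.load(cdir / "eeg.npy"),
                    fs_hz=side["eeg_fs_hz"],
                    channel_names=list(side["channel_names"]),
                    condition=dsnr,
                )
            rows = behavior[
                (behavior["subject"] == sub.subject_id)
                & (behavior["delta_snr_db"] == dsnr)
            ]
            if len(rows):
                r = rows.iloc[0]
                sub.behavior[dsnr] = BehavioralSample(
                    delta_snr_db=dsnr,
                    intelligibility_pct=float(r["intelligibility_pct"]),
                    n_sentences=int(r.get("n_sentences", 20)),
                    words_per_sentence=int(r.get("words_per_sentence", 5)),
                )
        subjects.append(sub)
    return Cohort(subjects=subjects, delta_snr_grid_db=list(meta["delta_snr_grid_db"]))


def read_audio(path: str | Path) -> tuple[np.ndarray, float]:
    """Mono waveform and sampling rate from a WAV file."""
    from scipy.io import wavfile

    fs, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        info = np.iinfo(np.asarray(raw).dtype)
        data = data / max(abs(info.min), info.max)  # integer PCM -> [-1, 1]
    return data, float(fs)


def read_eeg(path: str | Path) -> EEGRecording:
    """Import an EEG recording from EDF or BrainVision via MNE."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise DataError(
            "reading EDF/BrainVision requires the optional 'mne' dependency"
        ) from exc
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise DataError(f"unsupported EEG container: {path.suffix}")
    return EEGRecording(
        data=raw.get_data(),
        fs_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )
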