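"""File contracts: fixture array containers, EDF+ recordings, and TSV tables.

Fixture format: one ``.npz`` per object plus a ``.json`` sidecar holding the
sampling rate, montage (labels/positions/regions), annotations, group and
subject id.  This is the cheap, lossless interchange format between pipeline
stages.

EDF+ support: recordings are written as EDF+C (16-bit, 1-s data records) with
the EO/EC intervals as EDF+ annotations, and read back through
``mne.io.read_raw_edf``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .group_stats import EdgeTestResult
from .montage import Montage
from .preprocessing import EpochSet
from .spectral import CoherenceProfile
from .synthetic import Recording

# ---------------------------------------------------------------------------
# fixture container


def _montage_to_dict(m: Montage) -> dict:
    return {"labels": list(m.labels), "positions": [list(p) for p in m.positions],
            "regions": list(m.regions)}


def _montage_from_dict(d: dict) -> Montage:
    return Montage(labels=tuple(d["labels"]),
                   positions=tuple(tuple(p) for p in d["positions"]),
                   regions=tuple(d["regions"]))


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording as ``<path>.npz`` + ``<path>.json``."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=rec.data)
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "fs": rec.fs,
        "montage": _montage_to_dict(rec.montage),
        "annotations": [[c, int(a), int(b)] for c, a, b in rec.annotations],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        data = z["data"]
    return Recording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        data=data,
        fs=float(meta["fs"]),
        montage=_montage_from_dict(meta["montage"]),
        annotations=[(c, int(a), int(b)) for c, a, b in meta["annotations"]],
    )


def save_epochset(es: EpochSet, path: str | Path) -> None:
    """Write an EpochSet as ``<path>.npz`` + ``<path>.json``."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        **{f"epoch_{i}": e for i, e in enumerate(es.epochs)})
    meta = {
        "subject_id": es.subject_id,
        "group": es.group,
        "condition": es.condition,
        "fs": es.fs,
        "montage": _montage_to_dict(es.montage),
        "rejected_channels": list(es.rejected_channels),
        "n_epochs": len(es.epochs),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochset(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        epochs = [z[f"epoch_{i}"] for i in range(meta["n_epochs"])]
    return EpochSet(
        subject_id=meta["subject_id"],
        group=meta["group"],
        condition=meta["condition"],
        epochs=epochs,
        fs=float(meta["fs"]),
        montage=_montage_from_dict(meta["montage"]),
        rejected_channels=list(meta["rejected_channels"]),
    )


# ---------------------------------------------------------------------------
# EDF+ writer / reader


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise DataError(f"EDF header field too long: {text!r} (> {width})")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as EDF+C with EO/EC intervals as annotations.

    16-bit samples, 1-s data records (requires an integer sampling rate);
    the last record is zero-padded if the recording length is not a whole
    number of seconds.  Physical units are labelled uV.
    """
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise DataError("EDF export needs an integer sampling rate")
    fs = int(round(rec.fs))
    n_ch = len(rec.montage)
    n_records = math.ceil(rec.n_samples / fs)
    ann_spr = 32  # 64 bytes of annotation payload per record

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : rec.n_samples] = rec.data
    phys_max = np.maximum(np.abs(padded).max(axis=1) * 1.0001, 1e-6)
    phys_max = np.array([float(f"{v:.6g}") for v in phys_max])
    digital = np.round(padded / phys_max[:, None] * 32767.0).astype("<i2")

    n_signals = n_ch + 1
    header_bytes = 256 * (n_signals + 1)
    patient = f"{rec.subject_id or 'X'} X X {rec.group or 'X'}"
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(patient, 80))
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("EDF+C", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_signals), 4))

        labels = list(rec.montage.labels) + ["EDF Annotations"]
        for lab in labels:
            f.write(_pad(lab, 16))
        for _ in labels:
            f.write(_pad("", 80))  # transducer
        for i in range(n_signals):
            f.write(_pad("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            f.write(_pad(f"{-phys_max[i]:.6g}" if i < n_ch else "-1", 8))
        for i in range(n_signals):
            f.write(_pad(f"{phys_max[i]:.6g}" if i < n_ch else "1", 8))
        for _ in range(n_signals):
            f.write(_pad("-32767", 8))
        for _ in range(n_signals):
            f.write(_pad("32767", 8))
        for _ in range(n_signals):
            f.write(_pad("", 80))  # prefiltering
        for i in range(n_signals):
            f.write(_pad(str(fs if i < n_ch else ann_spr), 8))
        for _ in range(n_signals):
            f.write(_pad("", 32))

        # group interval annotations by the record containing their onset
        by_record: dict[int, list[bytes]] = {}
        for cond, start, end in rec.annotations:
            onset = start / rec.fs
            dur = (end - start) / rec.fs
            tal = f"+{onset:g}\x15{dur:g}\x14{cond}\x14\x00".encode("ascii")
            by_record.setdefault(int(onset), []).append(tal)

        for r in range(n_records):
            for i in range(n_ch):
                f.write(digital[i, r * fs : (r + 1) * fs].tobytes())
            payload = f"+{r}\x14\x14\x00".encode("ascii") + b"".join(by_record.get(r, []))
            if len(payload) > 2 * ann_spr:
                raise DataError("annotation payload exceeds record capacity")
            f.write(payload.ljust(2 * ann_spr, b"\x00"))


def read_edf(path: str | Path, montage: Montage | None = None) -> Recording:
    """Read an EDF/EDF+ file into a Recording via mne.

    EDF carries no region tags, so a Montage must be supplied unless the
    channel labels match the default fixture montage.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch for ch in raw.ch_names if ch != "EDF Annotations"]
    if montage is None:
        from .montage import default_montage

        dm = default_montage()
        if set(labels) <= set(dm.labels):
            montage = dm.subset(labels)
        else:
            raise DataError("channel labels do not match the default montage; pass one")
    else:
        montage = montage.subset(labels)
    data = raw.get_data(picks=labels) * 1e6  # mne returns volts for uV channels
    fs = float(raw.info["sfreq"])
    annotations = []
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if desc in ("EO", "EC"):
            start = int(round(onset * fs))
            annotations.append((desc, start, start + int(round(dur * fs))))
    subject_id, group = Path(path).stem, ""
    patient = raw.info.get("subject_info") or {}
    if patient.get("his_id"):
        subject_id = patient["his_id"].split(" ")[0]
    if patient.get("last_name"):
        group = patient["last_name"]
    return Recording(
        subject_id=subject_id,
        group=group if group in ("case", "control") else "",
        data=data,
        fs=fs,
        montage=montage,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# TSV contracts


def profiles_to_frame(profiles: list[CoherenceProfile]) -> pd.DataFrame:
    """Long-format table: subject, group, condition, band, chan_i, chan_j, coherence."""
    rows = []
    for p in profiles:
        n = len(p.channels)
        for band, mat in p.band_matrices.items():
            for i in range(n):
                for j in range(i + 1, n):
                    rows.append(
                        (p.subject_id, p.group, p.condition, band,
                         p.channels[i], p.channels[j], mat[i, j])
                    )
    return pd.DataFrame(
        rows, columns=["subject", "group", "condition", "band", "chan_i", "chan_j", "coherence"]
    )


def write_profiles_tsv(profiles: list[CoherenceProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def load_profiles_tsv(path: str | Path) -> list[CoherenceProfile]:
    """Rebuild CoherenceProfiles from the long-format table."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (subject, group, condition), sub in df.groupby(
        ["subject", "group", "condition"], sort=True
    ):
        channels = list(dict.fromkeys(pd.concat([sub["chan_i"], sub["chan_j"]])))
        idx = {c: k for k, c in enumerate(channels)}
        mats: dict[str, np.ndarray] = {}
        for band, bsub in sub.groupby("band", sort=True):
            m = np.ones((len(channels), len(channels)))
            for ci, cj, v in zip(bsub["chan_i"], bsub["chan_j"], bsub["coherence"]):
                m[idx[ci], idx[cj]] = v
                m[idx[cj], idx[ci]] = v
            mats[band] = m
        profiles.append(
            CoherenceProfile(
                subject_id=str(subject), group=str(group), condition=str(condition),
                channels=tuple(channels), band_matrices=mats,
            )
        )
    return profiles


def edge_results_to_frame(results: list[EdgeTestResult]) -> pd.DataFrame:
    rows = [
        (r.band, r.condition, r.pair[0], r.pair[1], r.U, r.p, r.q,
         r.median_case, r.median_control,
         "case<control" if r.case_deficit else "case>=control")
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["band", "condition", "chan_i", "chan_j", "U", "p", "q",
                 "median_case", "median_control", "direction"],
    )


def write_edge_results_tsv(results: list[EdgeTestResult], path: str | Path) -> None:
    edge_results_to_frame(results).to_csv(path, sep="\t", index=False)
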