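"""Reading and writing continuous EEG with movement-onset triggers.

Supported formats are BrainVision (.vhdr/.eeg/.vmrk triplet, the native
format of the recording amplifier) and EDF.  Reading goes through
:mod:`mne`; writing uses compact writers implemented here (BrainVision as
IEEE float32 multiplexed binary with Stimulus markers; EDF as standard
16-bit records with triggers in a plain-text sidecar, one onset time in
seconds per line).  Signal values are microvolts throughout.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np

from .recording import Recording, RecordingMeta

__all__ = ["load_recording", "save_recording"]

_EOG_LABELS = ("EOG", "EOG+", "EOG-", "HEOG", "VEOG")


# ---------------------------------------------------------------------------
# writers


def _write_brainvision(rec: Recording, vhdr_path: Path) -> list[Path]:
    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; written by muresp",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(rec.channels)}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channels, start=1):
        header.append(f"Ch{i}={ch},,1,µV")
    vhdr_path.write_text("\n".join(header) + "\n", encoding="utf-8")

    stamp = datetime.datetime(2000, 1, 1).strftime("%Y%m%d%H%M%S") + "000000"
    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        f"Mk1=New Segment,,1,1,0,{stamp}",
    ]
    for k, t in enumerate(rec.triggers, start=2):
        pos = int(round(t * rec.fs)) + 1  # marker positions are 1-based
        markers.append(f"Mk{k}=Stimulus,S  1,{pos},1,0")
    vmrk_path.write_text("\n".join(markers) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg_path)
    return [vhdr_path, vmrk_path, eeg_path]


def _write_edf(rec: Recording, edf_path: Path) -> list[Path]:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s data record
    n_ch = len(rec.channels)
    n_samples = rec.n_samples
    n_records = int(np.ceil(n_samples / spr))

    # physical scaling per channel onto the 16-bit digital range
    dmin, dmax = -32768, 32767
    pmins, pmaxs, digital = [], [], []
    for x in rec.data:
        pmin, pmax = float(x.min()), float(x.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        step = (pmax - pmin) / (dmax - dmin)
        if step > 0.5:
            warnings.warn(
                f"EDF quantization step {step:.2f} µV is coarse for a "
                f"{pmax - pmin:.0f} µV signal range; amplitudes are rescaled "
                "to the 16-bit digital span",
                stacklevel=3,
            )
        d = np.round((x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
        digital.append(d.astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {s!r}")
        return b.ljust(width)

    hdr = b"".join([
        pad("0", 8),
        pad(rec.meta.subject or "X", 80),
        pad("muresp recording", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    sig_hdr = b"".join([
        b"".join(pad(ch, 16) for ch in rec.channels),
        b"".join(pad("", 80) for _ in rec.channels),
        b"".join(pad("uV", 8) for _ in rec.channels),
        b"".join(pad(f"{p:.8g}"[:8], 8) for p in pmins),
        b"".join(pad(f"{p:.8g}"[:8], 8) for p in pmaxs),
        b"".join(pad(str(dmin), 8) for _ in rec.channels),
        b"".join(pad(str(dmax), 8) for _ in rec.channels),
        b"".join(pad("", 80) for _ in rec.channels),
        b"".join(pad(str(spr), 8) for _ in rec.channels),
        b"".join(pad("", 32) for _ in rec.channels),
    ])

    with open(edf_path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_records):
            i0, i1 = r * spr, (r + 1) * spr
            for d in digital:
                chunk = d[i0:i1]
                if chunk.size < spr:  # pad the final record with the edge value
                    fill = chunk[-1] if chunk.size else np.int16(0)
                    chunk = np.concatenate([chunk, np.full(spr - chunk.size, fill, "<i2")])
                fh.write(chunk.tobytes())

    events_path = _default_sidecar(edf_path)
    events_path.write_text("".join(f"{t:.6f}\n" for t in rec.triggers))
    return [edf_path, events_path]


def _default_sidecar(path: Path) -> Path:
    return path.with_suffix(".events.txt")


def save_recording(
    rec: Recording, path: str | Path, format: str | None = None
) -> list[Path]:
    """Write a recording to disk; returns the paths written.

    ``format`` is ``"brainvision"`` (a .vhdr/.vmrk/.eeg triplet; triggers
    become Stimulus markers) or ``"edf"`` (plus a plain-text trigger
    sidecar).  Inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower(), "")
    if format == "brainvision":
        return _write_brainvision(rec, path.with_suffix(".vhdr"))
    if format == "edf":
        return _write_edf(rec, path.with_suffix(".edf"))
    raise ValueError(f"unknown format {format!r} for {path.name} (use 'brainvision' or 'edf')")


# ---------------------------------------------------------------------------
# readers


def _read_sidecar(path: Path) -> np.ndarray:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return np.asarray([float(ln) for ln in lines])


def load_recording(
    path: str | Path, events: str | Path | None = None
) -> Recording:
    """Read a BrainVision header or EDF file into a :class:`Recording`.

    Triggers come from ``events`` (a plain-text sidecar, one onset time in
    seconds per line) when given; otherwise from embedded Stimulus markers
    (BrainVision) or from a ``<name>.events.txt`` sidecar next to the file
    (EDF).  Channel values are returned in microvolts; run metadata
    (designated IMI, moving hand) is not stored by either format and is
    left at defaults for the caller to fill in.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(
            path, eog=_EOG_LABELS, preload=True, verbose="error"
        )
    elif suffix == ".edf":
        raw = mne.io.read_raw_edf(path, eog=_EOG_LABELS, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown recording extension {path.suffix!r}")

    data_uv = raw.get_data() * 1e6
    triggers = None
    if events is not None:
        triggers = _read_sidecar(Path(events))
    elif suffix == ".vhdr":
        onsets = [
            ann["onset"]
            for ann in raw.annotations
            if str(ann["description"]).startswith("Stimulus")
        ]
        if onsets:
            triggers = np.asarray(onsets, dtype=float)
    if triggers is None and _default_sidecar(path).exists():
        triggers = _read_sidecar(_default_sidecar(path))
    if triggers is None or triggers.size == 0:
        raise ValueError(f"no triggers found for {path.name} (markers or sidecar)")
    triggers = np.sort(np.asarray(triggers, dtype=float))
    if np.any(np.diff(triggers) <= 0):
        raise ValueError("trigger onsets are not strictly increasing after sorting")

    return Recording(
        channels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data_uv,
        triggers=triggers,
        meta=RecordingMeta(),
    )
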