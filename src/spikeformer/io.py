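"""Dataset readers, fixture writers, caching and run configuration.

Formats handled:

- WFDB: minimal ``.hea``/``.dat`` reader (formats 16 and 212) and the MIT
  annotation format used by minute-wise apnea annotations (``.apn``); a
  matching writer exists so synthetic fixtures can be built.  Annotation
  code 8 ('A') marks an apneic minute, code 1 ('N') a normal one.
- EDF: read through :mod:`mne`; a minimal EDF writer is provided for
  synthetic fixtures only.  Respiratory-event annotations come from the
  plain-text event files shipped with the polysomnography recordings; all
  event types (obstructive, central, mixed, hypopnea) map to "apnea".
- GDF: read through :mod:`mne` (cue annotations 769/770/771/772 are the
  left-hand/right-hand/feet/tongue classes).

Caches are ``.npz`` arrays plus a CSV sidecar (recording, offset, label),
content-addressed by a hash of the generating configuration.  Readers never
modify source files.
"""

from __future__ import annotations

import hashlib
import re
import struct
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import ECGRecord, SegmentSet
from .eeg import EEGSession
from .model import ModelConfig
from .spiking import SpikeActivationConfig
from .train import TrainConfig

__all__ = [
    "read_wfdb",
    "write_wfdb",
    "read_apnea_annotations",
    "write_apnea_annotations",
    "read_apnea_ecg",
    "write_edf",
    "parse_respiratory_events",
    "read_ucddb_record",
    "read_bci2a",
    "UCDDB_EXCLUDED_SUBJECTS",
    "BCI2A_EVENT_CODES",
    "save_segment_set",
    "load_segment_set",
    "config_hash",
    "RunConfig",
]

# subjects without any recorded apnea events are excluded from analysis
UCDDB_EXCLUDED_SUBJECTS = ("ucddb008", "ucddb011", "ucddb013", "ucddb018")

# GDF cue annotation codes -> class ids (binary task uses 0/1 only)
BCI2A_EVENT_CODES = {"769": 0, "770": 1, "771": 2, "772": 3}
_BCI2A_NONCLASS_CODES = {
    "276", "277", "768", "783", "1023", "1072", "32766", "1077", "1078",
    "1079", "1081",
}

_APN_NORMAL, _APN_APNEA = 1, 8  # MIT annotation codes 'N' and 'A'
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# ---------------------------------------------------------------------------
# WFDB signals


def read_wfdb(record_path) -> tuple[np.ndarray, float, str]:
    """Read a single-signal WFDB record; returns (physical signal, fs, id)."""
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    if len(lines) < 1 + n_sig:
        raise ValueError(f"truncated header {hea}: {n_sig} signals declared")
    sig_line = lines[1].split()
    dat_file, fmt = sig_line[0], sig_line[1].split("x")[0]
    gain_field = sig_line[2] if len(sig_line) > 2 else "200"
    m = re.match(r"([-\d.]+)(?:\(([-\d]+)\))?", gain_field)
    gain = float(m.group(1)) if m else 200.0
    if gain == 0:
        gain = 200.0
    baseline = int(m.group(2)) if m and m.group(2) else (
        int(sig_line[4]) if len(sig_line) > 4 else 0
    )
    raw = (record_path.parent / dat_file).read_bytes()
    if fmt == "16":
        digital = np.frombuffer(raw, dtype="<i2")
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        digital = np.column_stack([s0, s1]).ravel()
        digital = np.where(digital > 2047, digital - 4096, digital)
    else:
        raise ValueError(f"unsupported WFDB format {fmt}")
    if n_sig > 1:
        digital = digital[: (len(digital) // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    if n_samp and len(digital) < n_samp:
        raise ValueError(
            f"truncated data file for {name}: {len(digital)} < {n_samp} samples"
        )
    if n_samp:
        digital = digital[:n_samp]
    return (digital.astype(float) - baseline) / gain, fs, name


def write_wfdb(record_path, signal: np.ndarray, fs: float, gain: float = 200.0):
    """Write a single-signal format-16 WFDB record (fixture/export helper)."""
    record_path = Path(record_path)
    name = record_path.stem
    digital = np.clip(np.round(np.asarray(signal) * gain), -32768, 32767).astype("<i2")
    record_path.with_suffix(".hea").write_text(
        f"{name} 1 {fs:g} {len(digital)}\n"
        f"{name}.dat 16 {gain:g}(0) 16 0 {int(digital[0])} 0 0 ECG\n"
    )
    record_path.with_suffix(".dat").write_bytes(digital.tobytes())


# ---------------------------------------------------------------------------
# MIT annotations (.apn)


def read_apnea_annotations(path, fs: float) -> np.ndarray:
    """Decode minute-wise apnea annotations; returns 0/1 per labelled minute."""
    raw = Path(path).read_bytes()
    t = 0
    pos = 0
    events: list[tuple[int, int]] = []
    while pos + 1 < len(raw):
        word = raw[pos] | (raw[pos + 1] << 8)
        pos += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi = raw[pos] | (raw[pos + 1] << 8)
            lo = raw[pos + 2] | (raw[pos + 3] << 8)
            pos += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            pos += delta + (delta & 1)
            continue
        t += delta
        events.append((t, code))
    if not events:
        return np.zeros(0, dtype=np.int64)
    minutes = [int(round(s / (60.0 * fs))) for s, _ in events]
    labels = np.zeros(max(minutes) + 1, dtype=np.int64)
    for m, (_, code) in zip(minutes, events):
        labels[m] = 1 if code == _APN_APNEA else 0
    return labels


def write_apnea_annotations(path, minute_labels: np.ndarray, fs: float):
    """Encode one annotation per minute in the MIT format (fixture helper)."""
    out = bytearray()
    prev = 0
    for m, lab in enumerate(np.asarray(minute_labels).astype(int)):
        t = int(round(m * 60 * fs))
        delta = t - prev
        prev = t
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        code = _APN_APNEA if lab else _APN_NORMAL
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(out))


def read_apnea_ecg(root) -> dict[str, list[ECGRecord]]:
    """Read all annotated recordings under ``root``.

    Recordings named ``a*/b*/c*`` form the released (development) set and
    ``x*`` the withheld (test) set.  Recordings with a missing annotation
    file are collected and reported in one error.
    """
    root = Path(root)
    headers = sorted(root.glob("*.hea"))
    if not headers:
        raise FileNotFoundError(f"no WFDB headers under {root}")
    released, withheld, missing = [], [], []
    for hea in headers:
        apn = hea.with_suffix(".apn")
        if not apn.exists():
            missing.append(hea.stem)
            continue
        signal, fs, name = read_wfdb(hea.with_suffix(""))
        labels = read_apnea_annotations(apn, fs)
        rec = ECGRecord(signal, fs, minute_labels=labels, record_id=name)
        (withheld if name.startswith("x") else released).append(rec)
    if missing:
        raise FileNotFoundError(
            f"recordings missing .apn annotations: {', '.join(missing)}"
        )
    return {"released": released, "withheld": withheld}


# ---------------------------------------------------------------------------
# EDF


def write_edf(
    path,
    signal: np.ndarray,
    fs: float,
    channel: str = "ECG",
    start: str = "01.01.02 23.30.00",
    phys_range: tuple[float, float] = (-4.0, 4.0),
):
    """Write a minimal one-channel EDF file (synthetic fixtures only)."""
    signal = np.asarray(signal, dtype=float)
    spr = int(fs)  # samples per 1-s record
    n_rec = len(signal) // spr
    date, time_ = start.split()
    lo, hi = phys_range

    def pad(x, n):
        s = str(x)[:n]
        return s + " " * (n - len(s))

    h = (
        pad("0", 8) + pad("synthetic", 80) + pad("synthetic fixture", 80)
        + pad(date, 8) + pad(time_, 8) + pad(256 + 256, 8) + pad("", 44)
        + pad(n_rec, 8) + pad("1", 8) + pad("1", 4)
    )
    h += (
        pad(channel, 16) + pad("synthetic", 80) + pad("mV", 8)
        + pad(f"{lo:g}", 8) + pad(f"{hi:g}", 8)
        + pad("-32768", 8) + pad("32767", 8) + pad("", 80) + pad(spr, 8) + pad("", 32)
    )
    scale = 65535.0 / (hi - lo)
    digital = np.clip(
        np.round((signal[: n_rec * spr] - lo) * scale) - 32768, -32768, 32767
    ).astype("<i2")
    Path(path).write_bytes(h.encode("ascii") + digital.tobytes())


def parse_respiratory_events(
    path, start_time: datetime, total_seconds: int
) -> np.ndarray:
    """Second-resolution apnea labels from a plain-text event table.

    Each event line carries a clock time (HH:MM:SS), an event type and a
    duration in seconds; obstructive/central/mixed apneas and hypopneas all
    map to label 1.  Clock times earlier than the recording start are taken
    to be past midnight.
    """
    labels = np.zeros(total_seconds, dtype=np.int64)
    pattern = re.compile(
        r"^\s*(\d{1,2}):(\d{2}):(\d{2})\s+(\S+).*?(\d+(?:\.\d+)?)", re.ASCII
    )
    start_s = start_time.hour * 3600 + start_time.minute * 60 + start_time.second
    for line in Path(path).read_text().splitlines():
        m = pattern.match(line)
        if not m:
            continue
        hh, mm, ss = int(m.group(1)), int(m.group(2)), int(m.group(3))
        ev_type = m.group(4).upper()
        if not any(k in ev_type for k in ("APNEA", "HYP", "OBS", "CENTRAL", "MIXED", "-C", "-O", "-M")):
            continue
        duration = float(m.group(5))
        ev_s = hh * 3600 + mm * 60 + ss
        onset = ev_s - start_s
        if onset < 0:
            onset += 24 * 3600
        lo = max(int(onset), 0)
        hi = min(int(np.ceil(onset + duration)), total_seconds)
        if lo < total_seconds:
            labels[lo:hi] = 1
    return labels


def read_ucddb_record(edf_path, respevt_path) -> ECGRecord:
    """Read one polysomnography ECG (EDF) with second-wise apnea labels."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    ecg_idx = [i for i, ch in enumerate(raw.ch_names) if "ECG" in ch.upper()]
    if not ecg_idx:
        raise ValueError(f"no ECG channel in {edf_path}: {raw.ch_names}")
    fs = float(raw.info["sfreq"])
    signal = raw.get_data(picks=[ecg_idx[0]])[0]
    meas = raw.info["meas_date"] or datetime(2002, 1, 1, tzinfo=timezone.utc)
    total_s = int(len(signal) // fs)
    labels = parse_respiratory_events(respevt_path, meas, total_s)
    return ECGRecord(
        signal, fs, second_labels=labels, record_id=Path(edf_path).stem
    )


# ---------------------------------------------------------------------------
# GDF (motor-imagery sessions)


def read_bci2a(root, subjects=range(1, 10)) -> dict[int, dict[str, tuple]]:
    """Read per-subject session pairs (T and E) from GDF files.

    Returns ``{subject: {"T": (EEGSession, events), "E": ...}}`` where
    ``events`` is a list of ``(cue_sample, class_id)``.  Unknown annotation
    codes raise an error carrying the full code dump.
    """
    import mne

    root = Path(root)
    out: dict[int, dict[str, tuple]] = {}
    for s in subjects:
        sessions = {}
        for tag in ("T", "E"):
            path = root / f"A0{s}{tag}.gdf"
            if not path.exists():
                raise FileNotFoundError(f"missing session file {path}")
            raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
            codes = {
                str(int(float(d))) if d.replace(".", "").isdigit() else d
                for d in raw.annotations.description
            }
            unknown = codes - set(BCI2A_EVENT_CODES) - _BCI2A_NONCLASS_CODES
            if unknown:
                raise ValueError(
                    f"{path.name}: unknown event codes {sorted(unknown)}; "
                    f"full dump: {sorted(codes)}"
                )
            fs = float(raw.info["sfreq"])
            events = []
            for onset, desc in zip(
                raw.annotations.onset, raw.annotations.description
            ):
                key = str(int(float(desc))) if desc.replace(".", "").isdigit() else desc
                if key in BCI2A_EVENT_CODES:
                    events.append((int(round(onset * fs)), BCI2A_EVENT_CODES[key]))
            sessions[tag] = (
                EEGSession(raw.get_data(), fs, list(raw.ch_names)),
                events,
            )
        out[s] = sessions
    return out


# ---------------------------------------------------------------------------
# caching and configuration


def save_segment_set(path, segments: SegmentSet):
    """Persist features as .npz with a CSV sidecar (recording, offset, label)."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        features=segments.features,
        labels=segments.labels,
        n_faulty=np.array([segments.n_faulty]),
    )
    pd.DataFrame(
        [
            {"recording": rid, "offset": off, "label": int(lab)}
            for (rid, off), lab in zip(segments.segment_index, segments.labels)
        ]
    ).to_csv(path.with_suffix(".csv"), index=False)


def load_segment_set(path) -> SegmentSet:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        features = npz["features"]
        labels = npz["labels"]
        n_faulty = int(npz["n_faulty"][0])
    meta = pd.read_csv(path.with_suffix(".csv"))
    index = [(str(r), int(o)) for r, o in zip(meta["recording"], meta["offset"])]
    return SegmentSet(features, labels, index, n_faulty=n_faulty)


def config_hash(config: dict) -> str:
    """Content hash of a configuration (for cache addressing)."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Everything one run needs; serialised into every results directory."""

    task: str = "synth_ecg"
    seed: int = 1
    data_dir: str | None = None
    n_recordings: int = 40
    duration_min: int = 60
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["model"]["conv_filters"] = list(self.model.conv_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("model"), dict):
            md = dict(d["model"])
            if isinstance(md.get("spike"), dict):
                md["spike"] = SpikeActivationConfig(**md["spike"])
            md["conv_filters"] = tuple(md["conv_filters"])
            d["model"] = ModelConfig(**md)
        if isinstance(d.get("train"), dict):
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())
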