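"""Minimal BrainVision file-triplet reader and writer.

Supports the common dialect: a .vhdr INI-style header, a .vmrk marker
file, and a multiplexed binary .eeg data file in IEEE float-32 or signed
16-bit integers with per-channel resolution scaling. Values are held in
µV throughout.
"""

from __future__ import annotations

import configparser
import os

import numpy as np

from .preprocessing import RawRecording

__all__ = ["read_brainvision", "write_brainvision"]

_CODECS = {
    "IEEE_FLOAT_32": np.dtype("<f4"),
    "INT_16": np.dtype("<i2"),
}


def _parse_vhdr(path: str) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(interpolation=None)
    cp.optionxform = str  # keys are case sensitive (Ch1, Ch2, ...)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if "Brain Vision Data Exchange Header File" not in first:
            raise ValueError(f"{path} is not a BrainVision header file")
        cp.read_string(fh.read())
    return cp


def read_brainvision(header_path: str) -> RawRecording:
    """Read a .vhdr/.vmrk/.eeg triplet into a RawRecording (µV)."""
    cp = _parse_vhdr(header_path)
    common = cp["Common Infos"]
    base = os.path.dirname(os.path.abspath(header_path))
    data_file = os.path.join(base, common["DataFile"])
    marker_file = os.path.join(base, common.get("MarkerFile", ""))
    for f, kind in ((data_file, "data"), (marker_file, "marker")):
        if f and not os.path.exists(f):
            raise FileNotFoundError(f"missing companion {kind} file: {f}")
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])  # interval is in µs

    fmt = cp["Binary Infos"]["BinaryFormat"]
    if fmt not in _CODECS:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")
    dtype = _CODECS[fmt]

    labels, resolutions = [], []
    ch_section = cp["Channel Infos"]
    if len(ch_section) != n_ch:
        raise ValueError(
            f"header advertises {n_ch} channels but lists "
            f"{len(ch_section)} channel entries"
        )
    for i in range(1, n_ch + 1):
        key = f"Ch{i}"
        if key not in ch_section:
            raise ValueError(f"header advertises {n_ch} channels but {key} is missing")
        parts = ch_section[key].split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_ch != 0:
        raise ValueError(
            f"data file holds {raw.size} values, not a multiple of {n_ch} channels"
        )
    data = raw.reshape(-1, n_ch).T.astype(float)
    if fmt == "INT_16":
        data = data * np.asarray(resolutions)[:, None]

    participant = common.get("Participant", os.path.splitext(os.path.basename(header_path))[0])
    condition = common.get("Condition", "closed")
    return RawRecording(
        participant=participant,
        condition=condition,
        channel_labels=tuple(labels),
        samples=data,
        sampling_rate=fs,
    )


def write_brainvision(
    recording: RawRecording, header_path: str, binary_format: str = "IEEE_FLOAT_32",
    resolution_uV: float = 0.1,
) -> None:
    """Write a minimal standard-conformant .vhdr/.vmrk/.eeg triplet."""
    if recording.samples.size == 0:
        raise ValueError("refusing to write an empty recording")
    if binary_format not in _CODECS:
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}")
    base, ext = os.path.splitext(header_path)
    if ext != ".vhdr":
        raise ValueError("header path must end in .vhdr")
    name = os.path.basename(base)
    data_path, marker_path = base + ".eeg", base + ".vmrk"

    n_ch = recording.samples.shape[0]
    interval_us = 1e6 / recording.sampling_rate
    res = resolution_uV if binary_format == "INT_16" else 1.0
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={interval_us:g}",
        f"Participant={recording.participant}",
        f"Condition={recording.condition}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,{res:g},µV")
    with open(header_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")

    with open(marker_path, "w", encoding="utf-8") as fh:
        fh.write(
            "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
            "[Common Infos]\nCodepage=UTF-8\n"
            f"DataFile={name}.eeg\n\n[Marker Infos]\n"
            "Mk1=New Segment,,1,1,0\n"
        )

    data = recording.samples.T  # multiplexed: sample-major
    if binary_format == "INT_16":
        scaled = np.round(data / res)
        if np.any(np.abs(scaled) > 32767):
            raise ValueError("signal exceeds INT_16 range at this resolution")
        scaled.astype("<i2").tofile(data_path)
    else:
        data.astype("<f4").tofile(data_path)
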