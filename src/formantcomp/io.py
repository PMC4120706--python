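"""Readers and writers for the package's delimited text formats.

Track files are UTF-8 delimited text (comma or tab) with a header row and
columns ``time_s, f1_hz, a1, f2_hz, a2, f3_hz, a3`` at uniform 1-ms
spacing.  Transcript files carry one sentence per row with ``|``-separated
keywords and space-separated phoneme strings.  Stimulus manifests record
one row per rendered stimulus.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .contours import FormantTrack
from .exceptions import InvalidTrackError
from .paradigm import SentenceTracks
from .scoring import TranscriptPair

__all__ = [
    "read_track_file",
    "write_track_file",
    "read_transcripts",
    "read_homonyms",
    "write_manifest",
]

_TRACK_COLUMNS = ["time_s", "f1_hz", "a1", "f2_hz", "a2", "f3_hz", "a3"]


def write_track_file(sentence: SentenceTracks, path: str | Path) -> Path:
    """Write a sentence's F1-F3 tracks as delimited text."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": sentence.f1.times,
            "f1_hz": sentence.f1.freqs,
            "a1": sentence.f1.amps,
            "f2_hz": sentence.f2.freqs,
            "a2": sentence.f2.amps,
            "f3_hz": sentence.f3.freqs,
            "a3": sentence.f3.amps,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_track_file(path: str | Path, sentence_id: str | None = None) -> SentenceTracks:
    """Read a delimited track file; validates uniform, monotone 1-ms framing."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidTrackError(f"track file {path} missing columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidTrackError("track file must contain at least two frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidTrackError("time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise InvalidTrackError("frame spacing must be uniform")
    frame_period = float(dt[0])
    tracks = {}
    for i, name in enumerate(("F1", "F2", "F3"), start=1):
        tracks[name] = FormantTrack(
            freqs=df[f"f{i}_hz"].to_numpy(dtype=float),
            amps=df[f"a{i}"].to_numpy(dtype=float),
            frame_period=frame_period,
            label=name,
        )
    return SentenceTracks(
        id=sentence_id or path.stem,
        f1=tracks["F1"],
        f2=tracks["F2"],
        f3=tracks["F3"],
    )


def read_transcripts(path: str | Path) -> dict[str, TranscriptPair]:
    """Read a transcripts file into per-sentence :class:`TranscriptPair`.

    Expected columns: ``sentence_id``, ``ref_keywords`` (``|``-separated),
    ``ref_phonemes`` (space-separated), ``response_text``,
    ``response_phonemes`` (space-separated).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    out: dict[str, TranscriptPair] = {}
    for _, row in df.iterrows():
        out[str(row["sentence_id"])] = TranscriptPair(
            ref_keywords=tuple(str(row["ref_keywords"]).split("|")),
            ref_phonemes=tuple(str(row.get("ref_phonemes", "")).split()),
            response_text=str(row.get("response_text", "")),
            response_phonemes=tuple(str(row.get("response_phonemes", "")).split()),
        )
    return out


def read_homonyms(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column homonym map; entries are made symmetric."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["word", "alternative"])
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        a, b = str(row["word"]).lower(), str(row["alternative"]).lower()
        out.setdefault(a, set()).add(b)
        out.setdefault(b, set()).add(a)
    return out


def write_manifest(rows: list[Mapping], path: str | Path) -> Path:
    """Write a stimulus manifest (one row per rendered stimulus) as CSV."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
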