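"""Plain-text I/O: TSV tables for samples, events, behavior and epochs.

All tables are UTF-8, tab-separated, '.' decimal, with a header row.  Times
are block-relative seconds (floats); sample indexing is 0-based.  Blink and
saccade intervals are written as paired ``*_start`` / ``*_end`` rows and
merged back into interval events on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PupilRecording

_INTERVAL_TYPES = ("blink", "saccade")


def write_samples(rec: PupilRecording, path) -> None:
    """Write continuous samples as columns (t_s, pupil)."""
    pd.DataFrame({"t_s": rec.times, "pupil": rec.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_events(rec: PupilRecording, path) -> None:
    """Write events, expanding interval events into start/end rows."""
    rows = []
    for row in rec.events.itertuples():
        if row.type in _INTERVAL_TYPES and row.duration_s > 0:
            rows.append({"onset_s": row.onset_s, "type": f"{row.type}_start", "trial": row.trial})
            rows.append(
                {
                    "onset_s": row.onset_s + row.duration_s,
                    "type": f"{row.type}_end",
                    "trial": row.trial,
                }
            )
        else:
            rows.append({"onset_s": row.onset_s, "type": row.type, "trial": row.trial})
    pd.DataFrame(rows).sort_values("onset_s").to_csv(path, sep="\t", index=False)


def read_recording(samples_path, events_path, rate_hz: float, block_id=None) -> PupilRecording:
    """Rebuild a recording from sample and event TSVs."""
    samples = pd.read_csv(samples_path, sep="\t")
    raw_events = pd.read_csv(events_path, sep="\t")
    rows = []
    pending: dict = {}
    for row in raw_events.sort_values("onset_s").itertuples():
        base = str(row.type)
        if base.endswith("_start"):
            pending[base[:-6]] = row
        elif base.endswith("_end"):
            start = pending.pop(base[:-4], None)
            if start is not None:
                rows.append(
                    {
                        "onset_s": start.onset_s,
                        "duration_s": row.onset_s - start.onset_s,
                        "type": base[:-4],
                        "trial": start.trial,
                    }
                )
        else:
            rows.append(
                {"onset_s": row.onset_s, "duration_s": 0.0, "type": base, "trial": row.trial}
            )
    return PupilRecording(
        samples=samples["pupil"].to_numpy(),
        rate=rate_hz,
        events=pd.DataFrame(rows),
        block_id=block_id,
        t0=float(samples["t_s"].iloc[0]),
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def block_paths(directory, subject: int, block: int) -> dict:
    """Canonical file names for one block's outputs."""
    d = Path(directory)
    stem = f"sub-{subject:02d}_block-{block:02d}"
    return {
        "samples": d / f"{stem}_samples.tsv",
        "events": d / f"{stem}_events.tsv",
        "clean": d / f"{stem}_clean.tsv",
    }
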