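"""Readers and writers for the pipeline's tabular and EEG formats.

Awakening tables, electrode coordinates, band-power tables, cluster tables
and null distributions are plain CSV with period decimals (locale
independent); band tables carry a JSON sidecar with extraction metadata.
Raw segments are read from EDF or FIF via MNE and written as FIF.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .spectral import EEGSegment
from .synthetic import REPORT3_OF, REPORT5_LEVELS, SensorArray

__all__ = [
    "write_awakening_table",
    "read_awakening_table",
    "write_coordinates",
    "read_coordinates",
    "write_band_table",
    "read_band_table",
    "write_cluster_table",
    "write_segment",
    "read_segment",
]

MANDATORY_COLUMNS = (
    "record_id", "participant_id", "experiment", "night", "time",
    "report3", "sleep_depth", "sleepiness",
)
LIKERT_COLUMNS = ("sleep_depth", "sleepiness", "vividness",
                  "perceptual_vs_thought", "bizarreness",
                  "emotional_intensity", "dream_awareness")


def write_awakening_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.10g")


def read_awakening_table(path) -> pd.DataFrame:
    """Read and validate an awakening table.

    Violations are collected and reported together with 1-based data row
    numbers; any violation raises.
    """
    df = pd.read_csv(path)
    problems: list[str] = []
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    dup = df["record_id"][df["record_id"].duplicated()]
    for i in dup.index:
        problems.append(f"row {i + 1}: duplicate record_id {df['record_id'][i]!r}")
    bad3 = ~df["report3"].isin(list(REPORT3_OF.values()))
    for i in df.index[bad3]:
        problems.append(f"row {i + 1}: unknown report3 code {df['report3'][i]!r}")
    if "report5" in df.columns:
        given = df["report5"].notna()
        bad5 = given & ~df["report5"].isin(REPORT5_LEVELS)
        for i in df.index[bad5]:
            problems.append(
                f"row {i + 1}: unknown report5 code {df['report5'][i]!r}"
            )
        consistent = df["report5"].map(REPORT3_OF) == df["report3"]
        for i in df.index[given & ~bad5 & ~consistent]:
            problems.append(
                f"row {i + 1}: report5 {df['report5'][i]!r} inconsistent with "
                f"report3 {df['report3'][i]!r}"
            )
    for col in LIKERT_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & ~vals.isin([1, 2, 3, 4, 5])
        for i in df.index[bad]:
            problems.append(
                f"row {i + 1}: {col} = {df[col][i]!r} outside the 1-5 scale"
            )
    if problems:
        raise ValueError("invalid awakening table:\n" + "\n".join(problems))
    return df


def write_coordinates(sensors: SensorArray, path) -> None:
    pd.DataFrame(
        {"label": sensors.channel_labels,
         "x": sensors.positions[:, 0],
         "y": sensors.positions[:, 1],
         "z": sensors.positions[:, 2]}
    ).to_csv(path, index=False, float_format="%.10g")


def read_coordinates(path) -> SensorArray:
    df = pd.read_csv(path)
    need = {"label", "x", "y", "z"}
    if not need <= set(df.columns):
        raise ValueError(f"coordinate file needs columns {sorted(need)}")
    return SensorArray(tuple(df["label"].astype(str)),
                       df[["x", "y", "z"]].to_numpy(float))


def write_band_table(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    table.to_csv(path, float_format="%.10g")
    if metadata is not None:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2))


def read_band_table(path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    tab = pd.read_csv(path, index_col=0)
    tab.index.name = "record_id"
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    return tab, meta


def write_cluster_table(clusters, path) -> None:
    rows = [
        {"cluster_id": i + 1, "sign": "+" if c.sign > 0 else "-",
         "size": c.size, "mass": c.mass, "corrected_p": c.corrected_p,
         "electrodes": ";".join(c.members)}
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(
        rows, columns=["cluster_id", "sign", "size", "mass", "corrected_p",
                       "electrodes"]
    ).to_csv(path, index=False, float_format="%.10g")


def write_segment(segment: EEGSegment, path) -> None:
    """Write one segment as FIF (alarm index kept in the description)."""
    import mne

    info = mne.create_info(list(segment.channel_labels), segment.fs, "eeg")
    raw = mne.io.RawArray(segment.data * 1e-6, info, verbose="error")
    raw.info["description"] = json.dumps({"alarm_index": segment.alarm_index})
    raw.save(path, overwrite=True, verbose="error")


def read_segment(path, alarm_index: int | None = None) -> EEGSegment:
    """Read one EDF or FIF segment into an EEGSegment (microvolts).

    ``alarm_index`` defaults to the value stored in the FIF description,
    or to the final sample for formats that cannot carry it.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6
    if alarm_index is None:
        desc = raw.info.get("description") or ""
        try:
            alarm_index = int(json.loads(desc).get("alarm_index"))
        except (ValueError, TypeError, AttributeError):
            alarm_index = data.shape[1]
    return EEGSegment(data=data, fs=float(raw.info["sfreq"]),
                      channel_labels=list(raw.ch_names),
                      alarm_index=alarm_index)
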