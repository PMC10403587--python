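"""File formats: EDF recordings and the tabular intermediates.

Every intermediate artifact (cohort table, epoch store, marker tensor,
predictions) is a documented TSV so any pipeline stage can be rerun in
isolation; recordings travel as EDF/EDF+ with signals in microvolts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import EDFFormatError, read_edf, write_edf  # noqa: F401  (public API)
from .containers import Epoch

#: Column order of the cohort TSV; one row per EEG recording.
COHORT_HEADER = (
    "patient_id", "eeg_id", "cohort_split", "age", "sex", "asm_count",
    "ied_status", "focal_lesion", "slowing", "epilepsy_type",
    "outcome_recurrence_1y", "time_to_event_weeks", "event_observed",
    "followup_weeks", "latent_risk", "recording_seed",
)

_BOOL_COLS = ("focal_lesion", "slowing", "outcome_recurrence_1y", "event_observed")


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_HEADER if c in cohort.columns]
    cohort.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in _BOOL_COLS:
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def write_epoch_store(
    epochs: list[Epoch], channel_labels: tuple[str, ...], path: str | Path
) -> None:
    """Serialize repaired epochs keyed by (eeg_id, epoch_index, channel)."""
    rows = []
    for ep in epochs:
        for ci, ch in enumerate(channel_labels):
            rows.append(
                {
                    "eeg_id": ep.eeg_id,
                    "epoch_index": ep.epoch_index,
                    "onset_s": ep.onset_s,
                    "condition": ep.condition,
                    "channel": ch,
                    "sampling_rate": ep.sampling_rate,
                    "interpolated": int(ci in ep.interpolated_channels),
                    "samples": ",".join(f"{v:.4f}" for v in ep.data[ci]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_epoch_store(path: str | Path) -> tuple[list[Epoch], tuple[str, ...]]:
    df = pd.read_csv(Path(path), sep="\t")
    channel_labels = tuple(pd.unique(df["channel"]))
    epochs = []
    for (eeg_id, idx), grp in df.groupby(["eeg_id", "epoch_index"], sort=True):
        grp = grp.set_index("channel").loc[list(channel_labels)]
        data = np.array(
            [np.fromstring(s, sep=",") for s in grp["samples"]]
        )
        epochs.append(
            Epoch(
                eeg_id=str(eeg_id),
                epoch_index=int(idx),
                onset_s=float(grp["onset_s"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
                data=data,
                sampling_rate=float(grp["sampling_rate"].iloc[0]),
                interpolated_channels=frozenset(
                    np.flatnonzero(grp["interpolated"].to_numpy()).tolist()
                ),
            )
        )
    return epochs, channel_labels


def write_tensor_tsv(tensor: pd.DataFrame, path: str | Path) -> None:
    """Long-format marker tensor: eeg_id, epoch, channel, marker, sub_index."""
    tensor.to_csv(path, sep="\t", index=False)


def read_tensor_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    df["missing"] = df["missing"].astype(bool)
    return df


def write_predictions_tsv(per_eeg: pd.DataFrame, path: str | Path) -> None:
    per_eeg.to_csv(path, sep="\t", index=False)
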