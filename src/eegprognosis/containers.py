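"""In-memory containers shared across the pipeline.

A :class:`Recording` is one annotated multichannel routine EEG in microvolts;
an :class:`Epoch` is one 10-s, 19-channel analysis segment cut from it at a
protocol-defined time point (montage change, hyperventilation, photic
stimulation, eye opening/closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 scalp electrodes of the standard 10-20 placement, in package order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "F7", "F8",
    "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "O1", "O2",
)

#: Epoch condition tags derived from the technologist annotations.
CONDITIONS = (
    "montage_change",
    "hyperventilation",
    "post_hyperventilation",
    "photic",
    "eye_event",
)


@dataclass
class Annotation:
    onset_s: float
    duration_s: float
    label: str


@dataclass
class Recording:
    """One multichannel EEG recording in microvolts.

    ``signal`` is ``(n_channels, n_samples)``; ``reference`` records whether
    the data are as-recorded or average-referenced.
    """

    eeg_id: str
    patient_id: str
    sampling_rate: float
    channel_labels: tuple[str, ...]
    signal: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration_s
        for ann in self.annotations:
            if not (0.0 <= ann.onset_s <= dur):
                raise ValueError(
                    f"annotation {ann.label!r} onset {ann.onset_s} outside [0, {dur}]"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kwargs) -> "Recording":
        if "signal" not in kwargs:
            kwargs["signal"] = self.signal.copy()
        if "annotations" not in kwargs:
            kwargs["annotations"] = list(self.annotations)
        return replace(self, **kwargs)


@dataclass
class Epoch:
    """One fixed-length analysis segment (channels x samples, microvolts)."""

    eeg_id: str
    epoch_index: int
    onset_s: float
    condition: str
    data: np.ndarray
    sampling_rate: float
    bad_channel_mask: np.ndarray = None  # type: ignore[assignment]
    interpolated_channels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros(self.data.shape[0], dtype=bool)
        self.bad_channel_mask = np.asarray(self.bad_channel_mask, dtype=bool)
        if self.bad_channel_mask.shape[0] != self.data.shape[0]:
            raise ValueError("bad_channel_mask length must equal channel count")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]
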