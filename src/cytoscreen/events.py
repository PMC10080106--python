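"""Per-event intensity container shared by the simulation, gating and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EventMatrix", "SCATTER_CHANNELS", "VIABILITY_CHANNEL", "QC_LABELS"]

#: Light-scatter channels: never asinh-transformed, never unmixed.
SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")
VIABILITY_CHANNEL = "Viability"
#: Truth labels reserved for events that are not intact single live cells.
QC_LABELS = ("debris", "doublet", "dead")


@dataclass
class EventMatrix:
    """Events x channels intensity matrix with optional ground-truth labels.

    ``data`` columns are channel names (scatter, viability dye, markers for
    channel-space data; detector names for raw detector-space data).
    ``labels``, when present, name generator populations or one of the QC
    classes in :data:`QC_LABELS`.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("event intensities must be finite")
        if self.labels is not None:
            self.labels = pd.Series(
                np.asarray(self.labels, dtype=object), index=self.data.index
            )

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def marker_channels(self) -> list[str]:
        """All fluorescence channels (everything except light scatter)."""
        return [c for c in self.data.columns if c not in SCATTER_CHANNELS]

    def __len__(self) -> int:
        return len(self.data)
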