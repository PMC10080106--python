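"""Stain indices across antibody serial-dilution series.

The stain index (SI) quantifies how well an antibody concentration separates
its positive from its negative population:

    SI = (MFI_pos - MFI_neg) / (2 * rSD_neg)

with MFI the median fluorescence intensity and rSD the robust standard
deviation of the negative population, implemented here as 1.4826 x the median
absolute deviation (the consistent estimator of a normal sigma; acquisition
software may use a different robust estimator).  Working concentrations are
picked from a 2-fold dilution ladder as the lowest concentration retaining at
least 90% of the ladder's maximum SI — saving antibody without giving up
separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "robust_sd",
    "stain_index",
    "TitrationSeries",
    "StainIndexResult",
    "titration_curve",
    "NoSeparationError",
]

MAD_TO_SD = 1.4826022185056018  # 1 / Phi^-1(0.75)


class NoSeparationError(ValueError):
    """Raised when no concentration in a series separates pos from neg."""


def robust_sd(values) -> float:
    """1.4826 x median absolute deviation; robust normal-sigma estimate."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("robust_sd needs at least 2 values")
    return float(MAD_TO_SD * np.median(np.abs(values - np.median(values))))


def stain_index(positive_values, negative_values) -> float:
    """(median(pos) - median(neg)) / (2 * robust_sd(neg)).

    Raises on a degenerate negative population (rSD = 0) rather than
    returning infinity.
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both populations must be non-empty")
    rsd = robust_sd(neg)
    if rsd == 0:
        raise ValueError("negative population has zero robust SD; SI undefined")
    return float((np.median(pos) - np.median(neg)) / (2.0 * rsd))


@dataclass
class TitrationSeries:
    """Per-concentration positive/negative intensities for one reagent."""

    reagent: str
    entries: list[tuple[float, np.ndarray, np.ndarray]]  # (conc, pos, neg)

    def __post_init__(self):
        conc = [e[0] for e in self.entries]
        if any(c2 >= c1 for c1, c2 in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        for c, pos, neg in self.entries:
            if len(pos) < 50 or len(neg) < 50:
                raise ValueError(
                    f"concentration {c}: need >= 50 events per population"
                )

    @classmethod
    def from_event_series(cls, series) -> "TitrationSeries":
        """Build from ``generate_titration_series`` output (truth-labelled)."""
        entries = []
        reagent = None
        for conc, em in series:
            reagent = em.metadata.get("reagent", em.channels[0])
            col = em.data[reagent].to_numpy()
            lab = em.labels.to_numpy()
            entries.append((conc, col[lab == "positive"], col[lab == "negative"]))
        return cls(reagent or "reagent", entries)


@dataclass
class StainIndexResult:
    reagent: str
    table: pd.DataFrame  # concentration, mfi_pos, mfi_neg, rsd_neg, stain_index
    selected_concentration: float


def titration_curve(
    series: TitrationSeries, retention: float = 0.90
) -> StainIndexResult:
    """SI per concentration plus the selected working concentration.

    Selection rule: the lowest concentration whose SI is at least
    ``retention`` (default 90%) of the series maximum.  Raises
    :class:`NoSeparationError` when every SI is <= 0.
    """
    rows = []
    for conc, pos, neg in series.entries:
        rsd = robust_sd(neg)
        si = stain_index(pos, neg)
        rows.append(
            {
                "concentration": conc,
                "mfi_pos": float(np.median(pos)),
                "mfi_neg": float(np.median(neg)),
                "rsd_neg": rsd,
                "stain_index": si,
            }
        )
    table = pd.DataFrame(rows)
    max_si = table["stain_index"].max()
    if max_si <= 0:
        raise NoSeparationError(
            f"{series.reagent}: no concentration separates positive from "
            "negative (all stain indices <= 0)"
        )
    ok = table[table["stain_index"] >= retention * max_si]
    selected = float(ok["concentration"].min())
    return StainIndexResult(series.reagent, table, selected)
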