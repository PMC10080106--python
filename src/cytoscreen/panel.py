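"""Fluorophore spectral signatures, panel-compatibility indices, and unmixing.

A spectral cytometer records every event across all detectors of all lasers
(38 detectors for a 3-laser instrument), so each fluorophore is characterised
by its full-spectrum "fingerprint" rather than a single peak channel.  This
module models those fingerprints, scores how much the fluorophores of a panel
overlap (pairwise similarity index and a panel-level complexity score),
estimates reference signatures from single-stain controls, and separates
multi-colour events into per-fluorophore abundances by per-event ordinary
least squares ("unmixing").

The similarity index is the cosine of the angle between unit-normalised
signatures, and the complexity score is the sum of all pairwise indices above
the diagonal.  Both are open surrogates for the unpublished, trademarked
indices of commercial acquisition software and are not expected to reproduce
that software's printed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralSignature",
    "PanelChannel",
    "PanelDefinition",
    "SimilarityMatrix",
    "UnmixResult",
    "CollinearPanelError",
    "similarity_index",
    "similarity_matrix",
    "complexity_score",
    "estimate_signature",
    "unmix",
    "unmix_residual_report",
    "synthetic_signature",
    "AURORA_3L_DETECTORS",
]

CATEGORIES = ("lineage", "activation", "inhibitory", "maturation", "viability")

#: Detector centre wavelengths (nm) of a 3-laser layout: 16 violet (405 nm),
#: 14 blue (488 nm) and 8 red (640 nm) detectors, 38 in total.
AURORA_3L_DETECTORS: tuple[tuple[str, float, np.ndarray], ...] = (
    ("V", 405.0, np.linspace(428, 780, 16)),
    ("B", 488.0, np.linspace(508, 780, 14)),
    ("R", 640.0, np.linspace(660, 780, 8)),
)


class CollinearPanelError(ValueError):
    """Signature matrix is rank deficient; names the most similar pair."""

    def __init__(self, pair: tuple[str, str], similarity: float):
        self.pair = pair
        self.similarity = similarity
        super().__init__(
            f"signature matrix is effectively rank deficient; most similar "
            f"pair is {pair[0]!r} vs {pair[1]!r} (similarity {similarity:.6f})"
        )


def _normalize(intensities: np.ndarray) -> np.ndarray:
    v = np.asarray(intensities, dtype=float)
    if v.ndim != 1:
        raise ValueError("signature intensities must be a 1-D vector")
    v = np.clip(v, 0.0, None)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("signature is all zero (degenerate input)")
    return v / norm


@dataclass(frozen=True)
class SpectralSignature:
    """Unit-norm, non-negative per-detector emission fingerprint."""

    fluorophore_name: str
    intensities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "intensities", _normalize(self.intensities))

    @property
    def n_detectors(self) -> int:
        return self.intensities.shape[0]


@dataclass(frozen=True)
class PanelChannel:
    marker: str
    fluorophore: str
    signature: SpectralSignature | None = None
    category: str = "lineage"
    concentration_ul_per_test: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


@dataclass
class PanelDefinition:
    """Ordered marker <-> fluorophore assignment of one staining panel."""

    name: str
    channels: list[PanelChannel] = field(default_factory=list)

    def __post_init__(self):
        fluors = [c.fluorophore for c in self.channels]
        markers = [c.marker for c in self.channels]
        if len(set(fluors)) != len(fluors):
            raise ValueError("duplicate fluorophore in panel")
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate marker in panel")
        lengths = {
            c.signature.n_detectors for c in self.channels if c.signature is not None
        }
        if len(lengths) > 1:
            raise ValueError("all signatures in a panel must have equal length")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def markers(self) -> list[str]:
        return [c.marker for c in self.channels]

    @property
    def fluorophores(self) -> list[str]:
        return [c.fluorophore for c in self.channels]

    def channel_for_marker(self, marker: str) -> PanelChannel:
        for c in self.channels:
            if c.marker == marker:
                return c
        raise KeyError(f"marker {marker!r} not in panel {self.name!r}")

    def signatures(self) -> list[SpectralSignature]:
        sigs = [c.signature for c in self.channels]
        if any(s is None for s in sigs):
            missing = [c.fluorophore for c in self.channels if c.signature is None]
            raise ValueError(f"panel channels lack signatures: {missing}")
        return sigs  # type: ignore[return-value]


@dataclass(frozen=True)
class SimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels do not match matrix size")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class UnmixResult:
    """Per-event fluorophore abundances plus per-event detector residual RMS."""

    fluorophores: tuple[str, ...]
    abundances: np.ndarray  # events x fluorophores
    residual_rms: np.ndarray  # events
    residuals: np.ndarray  # events x detectors


def similarity_index(sig_a: SpectralSignature, sig_b: SpectralSignature) -> float:
    """Cosine similarity of two signatures: 0 = disjoint spectra, 1 = identical."""
    if sig_a.n_detectors != sig_b.n_detectors:
        raise ValueError(
            f"signature lengths differ: {sig_a.n_detectors} vs {sig_b.n_detectors}"
        )
    # signatures are unit-norm and non-negative, so the dot product is in [0, 1]
    return float(np.clip(np.dot(sig_a.intensities, sig_b.intensities), 0.0, 1.0))


def similarity_matrix(panel: PanelDefinition) -> SimilarityMatrix:
    """All pairwise similarity indices of a panel (symmetric, unit diagonal)."""
    sigs = panel.signatures()
    if len(sigs) < 2:
        raise ValueError("similarity matrix needs at least 2 channels")
    S = np.stack([s.intensities for s in sigs])
    values = np.clip(S @ S.T, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(tuple(panel.fluorophores), values)


def complexity_score(sim: SimilarityMatrix) -> float:
    """Panel-level spectral overlap: sum of the strictly-upper-triangle indices.

    0 for a fully orthogonal panel; strictly increasing in every pairwise index.
    """
    v = sim.values
    iu = np.triu_indices(v.shape[0], k=1)
    return float(v[iu].sum())


def estimate_signature(
    single_stain_events: np.ndarray,
    negative_events: np.ndarray,
    fluorophore_name: str = "reference",
) -> SpectralSignature:
    """Estimate a reference signature from single-stain and unstained controls.

    The per-detector median of the negative (unstained) events is subtracted
    from the per-detector median of the single-stain events, negative residues
    are clipped at zero, and the result is normalised to unit L2 norm.  Using
    medians makes the estimate robust to the minority of unstained carrier
    events present in single-stain tubes, and subtracting the negative control
    removes any common additive background.
    """
    pos = np.asarray(single_stain_events, dtype=float)
    neg = np.asarray(negative_events, dtype=float)
    if pos.ndim != 2 or neg.ndim != 2:
        raise ValueError("control events must be 2-D (events x detectors)")
    if pos.shape[1] != neg.shape[1]:
        raise ValueError(
            f"detector counts differ: {pos.shape[1]} vs {neg.shape[1]}"
        )
    diff = np.clip(np.median(pos, axis=0) - np.median(neg, axis=0), 0.0, None)
    if not np.any(diff > 0):
        raise ValueError(
            "signature estimation failed: no positive signal above the "
            "negative control"
        )
    return SpectralSignature(fluorophore_name, diff)


def _stack_signatures(signatures: list[SpectralSignature]) -> np.ndarray:
    if not signatures:
        raise ValueError("no signatures supplied")
    n = signatures[0].n_detectors
    if any(s.n_detectors != n for s in signatures):
        raise ValueError("signatures have unequal detector counts")
    return np.stack([s.intensities for s in signatures])


def unmix(
    raw: np.ndarray,
    signatures: list[SpectralSignature],
    include_autofluorescence: bool = False,
    autofluorescence: SpectralSignature | None = None,
    condition_limit: float = 1e8,
) -> UnmixResult:
    """Ordinary-least-squares unmixing of detector-space events.

    Solves ``raw ~ abundances @ S`` per event, where the rows of ``S`` are the
    unit-norm signatures (plus one autofluorescence row when requested).
    Deterministic; no non-negativity constraint is imposed, matching standard
    spectral-unmixing practice.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw events must be 2-D (events x detectors)")
    sigs = list(signatures)
    names = [s.fluorophore_name for s in sigs]
    if include_autofluorescence:
        if autofluorescence is None:
            raise ValueError("autofluorescence signature required when flagged")
        sigs = sigs + [autofluorescence]
        names = names + ["AF"]
    S = _stack_signatures(sigs)
    if S.shape[0] > S.shape[1]:
        raise ValueError(
            f"{S.shape[0]} signatures exceed {S.shape[1]} detectors"
        )
    if raw.shape[1] != S.shape[1]:
        raise ValueError(
            f"event detector count {raw.shape[1]} != signature length {S.shape[1]}"
        )
    gram = S @ S.T
    if np.linalg.cond(gram) > condition_limit:
        off = gram - np.eye(gram.shape[0])
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise CollinearPanelError((names[i], names[j]), float(gram[i, j]))
    # normal equations: A = raw S^T (S S^T)^-1, solved via Cholesky-stable solve
    abundances = np.linalg.solve(gram, S @ raw.T).T
    residuals = raw - abundances @ S
    if raw.shape[1]:
        residual_rms = np.sqrt(np.mean(residuals**2, axis=1))
    else:  # zero-detector degenerate input
        residual_rms = np.zeros(raw.shape[0])
    return UnmixResult(tuple(names), abundances, residual_rms, residuals)


def unmix_residual_report(result: UnmixResult, detector_names=None) -> pd.DataFrame:
    """Numeric unmixing QC: mean and percentile absolute residual per detector.

    Stands in for the visual NxN-plot inspection of unmixing quality: large
    residuals on a detector indicate a signature that does not explain the
    measured spectra there.
    """
    res = np.abs(result.residuals)
    n_det = res.shape[1]
    if detector_names is None:
        detector_names = [f"D{i}" for i in range(n_det)]
    if res.shape[0] == 0:
        return pd.DataFrame(
            columns=["detector", "mean_abs", "p50_abs", "p95_abs"]
        ).astype({"detector": str})
    return pd.DataFrame(
        {
            "detector": list(detector_names),
            "mean_abs": res.mean(axis=0),
            "p50_abs": np.percentile(res, 50, axis=0),
            "p95_abs": np.percentile(res, 95, axis=0),
        }
    )


def _gaussian(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def synthetic_signature(
    fluorophore_name: str,
    emission_peak_nm: float,
    excitation: dict[str, float],
    width_nm: float = 28.0,
    detectors=AURORA_3L_DETECTORS,
) -> SpectralSignature:
    """Build a smooth synthetic full-spectrum fingerprint for a fluorophore.

    The emission along each laser's detector array is a Gaussian bump centred
    at the emission peak (zero below the laser line), scaled by that laser's
    excitation efficiency.  Purely synthetic: real dye spectra are asymmetric
    with long red tails, but the construction yields realistic pairwise
    overlap structure and full-rank panels.
    """
    parts = []
    for laser, laser_nm, wavelengths in detectors:
        eff = float(excitation.get(laser, 0.0))
        band = eff * _gaussian(wavelengths, emission_peak_nm, width_nm)
        band[wavelengths < laser_nm + 5.0] = 0.0
        parts.append(band)
    return SpectralSignature(fluorophore_name, np.concatenate(parts))
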