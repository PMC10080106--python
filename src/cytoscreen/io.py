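"""Configuration loading: panels, population fixtures, gating trees, effects.

All configuration is YAML (JSON is a YAML subset and loads through the same
path).  The package ships default fixtures under ``cytoscreen/resources``:
two 22-colour staining panels (a broad PBMC panel and a T-cell panel), the
matching healthy-donor population compositions whose subset fractions encode
published across-donor means, the two gating hierarchies, and stimulation /
disease condition-effect presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import yaml

from .gating import GateNode, GatingTree
from .panel import PanelChannel, PanelDefinition, synthetic_signature
from .simulate import (
    ConditionEffect,
    MarkerExpr,
    PopulationNode,
    PopulationTree,
)

__all__ = [
    "load_panel",
    "load_population_tree",
    "load_gating_tree",
    "load_effect",
    "packaged_resource_path",
    "list_packaged_resources",
    "RunManifest",
    "load_manifest",
]


def _read_yaml(source) -> dict:
    if isinstance(source, dict):
        return source
    text = Path(source).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"expected a mapping at top level of {source}")
    return doc


def packaged_resource_path(name: str) -> Path:
    """Filesystem path of a packaged YAML fixture (e.g. ``pbmc_panel``)."""
    fname = name if name.endswith(".yaml") else f"{name}.yaml"
    ref = importlib_resources.files("cytoscreen.resources") / fname
    with importlib_resources.as_file(ref) as p:
        return Path(p)


def list_packaged_resources() -> list[str]:
    ref = importlib_resources.files("cytoscreen.resources")
    return sorted(
        p.name.removesuffix(".yaml")
        for p in ref.iterdir()
        if p.name.endswith(".yaml")
    )


def _resolve(source):
    """Accept a dict, a path, or a packaged fixture name."""
    if isinstance(source, dict):
        return source
    p = Path(source)
    if not p.exists() and "/" not in str(source):
        p = packaged_resource_path(str(source))
    return _read_yaml(p)


# --- panels ----------------------------------------------------------------


def load_panel(source, build_signatures: bool = True) -> PanelDefinition:
    """Load a staining panel (marker, fluorophore, category, concentration).

    When emission/excitation fields are present and ``build_signatures`` is
    set, a synthetic full-spectrum signature is constructed per fluorophore;
    panels without spectra still load for gating-only use.
    """
    doc = _resolve(source)
    if "channels" not in doc:
        raise ValueError("panel file lacks a 'channels' key")
    channels = []
    for ch in doc["channels"]:
        signature = None
        if build_signatures and "emission_peak_nm" in ch:
            signature = synthetic_signature(
                ch["fluorophore"],
                float(ch["emission_peak_nm"]),
                {k: float(v) for k, v in ch.get("excitation", {"V": 1.0}).items()},
                width_nm=float(ch.get("width_nm", 28.0)),
            )
        channels.append(
            PanelChannel(
                marker=str(ch["marker"]),
                fluorophore=str(ch["fluorophore"]),
                signature=signature,
                category=str(ch.get("category", "lineage")),
                concentration_ul_per_test=ch.get("concentration_ul_per_test"),
            )
        )
    return PanelDefinition(doc.get("name", "panel"), channels)


# --- population fixtures ---------------------------------------------------


def _parse_marker_expr(
    spec, levels: dict[str, float], sigma: float
) -> MarkerExpr:
    if isinstance(spec, str):
        if spec not in levels:
            raise ValueError(f"unknown expression level {spec!r}")
        return MarkerExpr.single(levels[spec], sigma)
    if isinstance(spec, (int, float)):
        return MarkerExpr.single(float(spec), sigma)
    if isinstance(spec, dict):
        if "mix" in spec:
            comps = []
            for w, part in spec["mix"]:
                base = _parse_marker_expr(part, levels, sigma)
                (_, mu, s) = base.components[0]
                comps.append((float(w), mu, s))
            return MarkerExpr(tuple(comps))
        if "median" in spec:
            return MarkerExpr.single(
                float(spec["median"]), float(spec.get("sigma", sigma))
            )
    raise ValueError(f"cannot parse marker expression spec {spec!r}")


def load_population_tree(source) -> PopulationTree:
    doc = _resolve(source)
    levels = {k: float(v) for k, v in doc.get("levels", {}).items()} or None
    sigma = float(doc.get("sigma", 0.45))
    markers = [str(m) for m in doc["markers"]]
    lv = levels or {"neg": 120.0, "low": 900.0, "pos": 5000.0, "high": 20000.0}
    nodes = []
    for p in doc["populations"]:
        expression = {
            m: _parse_marker_expr(s, lv, sigma)
            for m, s in (p.get("markers") or {}).items()
        }
        unknown = set(expression) - set(markers)
        if unknown:
            raise ValueError(
                f"population {p['name']!r} uses unknown markers {sorted(unknown)}"
            )
        nodes.append(
            PopulationNode(
                name=str(p["name"]),
                parent=p.get("parent"),
                fraction_of_parent=float(p["fraction"]),
                expression=expression,
            )
        )
    return PopulationTree(
        nodes, markers, levels, sigma, name=doc.get("name", "populations")
    )


# --- gating trees ----------------------------------------------------------

_NODE_PARAM_KEYS = {
    "threshold": ("channel", "side", "source"),
    "ratio": ("numerator", "denominator", "lo", "hi"),
    "rect": ("channel_x", "channel_y", "x_lo", "x_hi", "y_lo", "y_hi"),
    "quadrant": ("channel_x", "channel_y", "quadrant", "source", "source_x", "source_y"),
    "markers": ("terms",),
    "boolean": ("expr",),
}


def load_gating_tree(source) -> GatingTree:
    doc = _resolve(source)
    nodes = []
    for nd in doc["nodes"]:
        kind = str(nd["kind"])
        if kind not in _NODE_PARAM_KEYS:
            raise ValueError(f"unknown gate kind {kind!r} for node {nd.get('id')}")
        params = {k: nd[k] for k in _NODE_PARAM_KEYS[kind] if k in nd}
        nodes.append(
            GateNode(
                id=str(nd["id"]),
                parent=nd.get("parent"),
                kind=kind,
                params=params,
                exclusive=bool(nd.get("exclusive", True)),
            )
        )
    return GatingTree(
        nodes,
        name=doc.get("name", "gating"),
        cofactor=float(doc.get("cofactor", 150.0)),
        denominator=doc.get("denominator"),
        auto_methods=tuple(doc.get("auto_methods", ("kde_valley", "gmm2"))),
    )


# --- condition effects -----------------------------------------------------


def load_effect(source) -> ConditionEffect:
    doc = _resolve(source)
    factors = {}
    for row in doc.get("marker_factors", []):
        factors[(str(row["population"]), str(row["marker"]))] = float(row["factor"])
    return ConditionEffect(
        name=doc.get("name", "effect"),
        marker_factors=factors,
        composition={
            str(k): float(v) for k, v in (doc.get("composition") or {}).items()
        },
        composition_balance=doc.get("composition_balance"),
    )


# --- run manifests ---------------------------------------------------------


@dataclass
class RunManifest:
    """Sample sheet tying FCS files to donor/group/condition metadata."""

    samples: dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    tool_version: str = ""

    def __post_init__(self):
        for sid, row in self.samples.items():
            path = row.get("path")
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(
                    f"manifest sample {sid!r} references missing file {path}"
                )


def load_manifest(source) -> RunManifest:
    doc = _resolve(source)
    samples = {}
    for row in doc.get("samples", []):
        sid = str(row["sample_id"])
        if sid in samples:
            raise ValueError(f"duplicate sample id {sid!r} in manifest")
        samples[sid] = dict(row)
    return RunManifest(
        samples=samples,
        seed=int(doc.get("seed", 0)),
        tool_version=str(doc.get("tool_version", "")),
    )
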