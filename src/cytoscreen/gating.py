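"""Declarative hierarchical gating with automatic 1-D threshold placement.

The PBMC and T-cell classification hierarchies used in immunophenotyping are
encoded as trees of gate nodes (thresholds, rectangles, quadrants, ratio
windows, marker-predicate combinations and boolean combinations of sibling
gates).  Where an analyst would place a gate by eye, this module places the
threshold automatically on the parent population: a kernel-density valley
between the two dominant modes by default, a two-component Gaussian-mixture
boundary as fallback, and an empirical quantile as last resort.

Gating runs on asinh-transformed fluorescence values (scatter channels stay
raw); subset statistics (percent of parent, event counts) come from the
resulting per-node membership masks, and marker MFIs are always reported on
the raw scale — the median commutes with the monotone asinh map, so the
choice of display scale never changes a reported MFI.

Tie-break convention, stated once and used everywhere: a value equal to the
threshold is on the positive side (``value >= threshold`` is positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .events import EventMatrix, SCATTER_CHANNELS

__all__ = [
    "NoValleyError",
    "GatingConfigError",
    "transform_asinh",
    "inverse_asinh",
    "auto_threshold",
    "GateNode",
    "GatingTree",
    "GatingResult",
    "apply_gating",
    "subset_frequencies",
    "subset_mfi",
    "summarize_frequencies",
]

DEFAULT_COFACTOR = 150.0
MIN_AUTO_EVENTS = 50
KDE_MAX_SAMPLE = 20_000
KDE_GRID = 512


class NoValleyError(ValueError):
    """Raised when kde_valley finds no density minimum between two modes."""


class GatingConfigError(ValueError):
    """Raised for gating trees referencing missing channels or nodes."""


def transform_asinh(
    events: EventMatrix, cofactor: float = DEFAULT_COFACTOR
) -> EventMatrix:
    """asinh(x / cofactor) on fluorescence channels; scatter untouched."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    data = events.data.copy()
    for c in events.marker_channels():
        data[c] = np.arcsinh(data[c] / cofactor)
    meta = dict(events.metadata)
    meta["asinh_cofactor"] = cofactor
    return EventMatrix(data, labels=events.labels, metadata=meta)


def inverse_asinh(
    events: EventMatrix, cofactor: float = DEFAULT_COFACTOR
) -> EventMatrix:
    """Exact inverse of :func:`transform_asinh`."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    data = events.data.copy()
    for c in events.marker_channels():
        data[c] = np.sinh(data[c]) * cofactor
    meta = dict(events.metadata)
    meta.pop("asinh_cofactor", None)
    return EventMatrix(data, labels=events.labels, metadata=meta)


def _kde_valley(values: np.ndarray, rng: np.random.Generator) -> float:
    if values.size > KDE_MAX_SAMPLE:
        values = rng.choice(values, size=KDE_MAX_SAMPLE, replace=False)
    if np.ptp(values) == 0:
        raise NoValleyError("all values identical; no valley exists")
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), KDE_GRID)
    dens = kde(grid)
    interior = np.arange(1, KDE_GRID - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    modes = interior[is_max]
    # grid endpoints can also be modes
    if dens[0] > dens[1]:
        modes = np.concatenate([[0], modes])
    if dens[-1] > dens[-2]:
        modes = np.concatenate([modes, [KDE_GRID - 1]])
    if modes.size < 2:
        raise NoValleyError("density is unimodal; no valley between modes")
    top2 = modes[np.argsort(dens[modes])][-2:]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        raise NoValleyError("dominant modes are adjacent; no valley between them")
    between = np.arange(lo + 1, hi)
    return float(grid[between[np.argmin(dens[between])]])


def _gmm2_boundary(values: np.ndarray, seed: int) -> float:
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=seed, n_init=1)
    gm.fit(values.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    grid = np.linspace(means[0], means[1], 1001)
    post = gm.predict_proba(grid.reshape(-1, 1))
    lo_comp = int(np.argmin(gm.means_.ravel()))
    crossing = np.argmin(np.abs(post[:, lo_comp] - 0.5))
    return float(grid[crossing])


def auto_threshold(
    values: np.ndarray, method: str = "kde_valley", seed: int = 0, q: float = 0.5
) -> float:
    """Place a 1-D split on (transformed) intensities.

    ``kde_valley``: deepest density minimum between the two highest KDE modes
    (Gaussian kernel, Silverman bandwidth); raises :class:`NoValleyError` on
    unimodal data.  ``gmm2``: equal-posterior boundary of a 2-component
    Gaussian mixture.  ``quantile``: the empirical ``q`` quantile.
    Deterministic for a given seed.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if method == "quantile":
        if values.size < 1:
            raise ValueError("quantile threshold needs at least one value")
        return float(np.quantile(values, q))
    if values.size < MIN_AUTO_EVENTS:
        raise ValueError(
            f"{method} needs >= {MIN_AUTO_EVENTS} events, got {values.size}"
        )
    if method == "kde_valley":
        return _kde_valley(values, np.random.default_rng(seed))
    if method == "gmm2":
        return _gmm2_boundary(values, seed)
    raise ValueError(f"unknown threshold method {method!r}")


def _cascade_threshold(values: np.ndarray, methods: Iterable[str], seed: int) -> float:
    """Try methods in order; final fallback is the median."""
    last: Exception | None = None
    for m in methods:
        try:
            return auto_threshold(values, method=m, seed=seed)
        except (NoValleyError, ValueError) as exc:
            last = exc
    if values.size:
        return float(np.quantile(values, 0.5))
    raise GatingConfigError(f"cannot place threshold on empty data: {last}")


# ---------------------------------------------------------------------------
# gate tree


@dataclass
class GateNode:
    """One node of a gating hierarchy.

    ``kind`` is one of ``threshold``, ``rect``, ``quadrant``, ``ratio``,
    ``markers`` (AND of per-channel +/- predicates with auto thresholds) or
    ``boolean`` (expression over sibling gate ids with ``& | !`` and
    parentheses).  ``exclusive`` nodes take part in per-event labelling;
    overlay gates (e.g. Th subsets sharing one CD4 parent) set it to False
    and are reported through their membership masks only.
    """

    id: str
    parent: str | None
    kind: str
    params: dict = field(default_factory=dict)
    exclusive: bool = True


class GatingTree:
    def __init__(
        self,
        nodes: list[GateNode],
        name: str = "gating",
        cofactor: float = DEFAULT_COFACTOR,
        denominator: str | None = None,
        auto_methods: tuple[str, ...] = ("kde_valley", "gmm2"),
    ):
        self.name = name
        self.cofactor = cofactor
        self.denominator = denominator
        self.auto_methods = tuple(auto_methods)
        self.nodes: dict[str, GateNode] = {}
        order: list[str] = []
        for n in nodes:
            if n.id in self.nodes:
                raise GatingConfigError(f"duplicate gate id {n.id!r}")
            if n.parent is not None and n.parent not in self.nodes:
                raise GatingConfigError(
                    f"gate {n.id!r} listed before its parent {n.parent!r}"
                )
            self.nodes[n.id] = n
            order.append(n.id)
        self.order = order  # topological by construction

    def children(self, node_id: str | None) -> list[GateNode]:
        return [n for n in self.nodes.values() if n.parent == node_id]

    def required_channels(self) -> set[str]:
        chans: set[str] = set()
        for n in self.nodes.values():
            p = n.params
            if n.kind == "threshold":
                chans.add(p["channel"])
            elif n.kind == "rect":
                chans.update((p["channel_x"], p["channel_y"]))
            elif n.kind == "quadrant":
                chans.update((p["channel_x"], p["channel_y"]))
            elif n.kind == "ratio":
                chans.update((p["numerator"], p["denominator"]))
            elif n.kind == "markers":
                chans.update(t["channel"] for t in p["terms"])
        return chans


@dataclass
class GatingResult:
    tree: GatingTree
    memberships: dict[str, np.ndarray]  # node id -> boolean mask over events
    labels: pd.Series  # deepest exclusive node per event ("root" if none)
    thresholds: dict[str, float]  # "node/channel" -> transformed-scale value

    def count(self, node_id: str) -> int:
        return int(self.memberships[node_id].sum())


# --- boolean expression parser (tokens: ids, & | ! ( ) ) -------------------


def _eval_boolean(expr: str, masks: dict[str, np.ndarray], n: int) -> np.ndarray:
    tokens: list[str] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
        elif c in "&|!()":
            tokens.append(c)
            i += 1
        else:
            j = i
            while j < len(expr) and (expr[j].isalnum() or expr[j] in "_-"):
                j += 1
            if j == i:
                raise GatingConfigError(f"bad character {c!r} in boolean gate")
            tokens.append(expr[i:j])
            i = j
    pos = 0

    def parse_or() -> np.ndarray:
        nonlocal pos
        left = parse_and()
        while pos < len(tokens) and tokens[pos] == "|":
            pos += 1
            left = left | parse_and()
        return left

    def parse_and() -> np.ndarray:
        nonlocal pos
        left = parse_not()
        while pos < len(tokens) and tokens[pos] == "&":
            pos += 1
            left = left & parse_not()
        return left

    def parse_not() -> np.ndarray:
        nonlocal pos
        if pos < len(tokens) and tokens[pos] == "!":
            pos += 1
            return ~parse_not()
        return parse_atom()

    def parse_atom() -> np.ndarray:
        nonlocal pos
        if pos >= len(tokens):
            raise GatingConfigError(f"truncated boolean expression {expr!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            inner = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise GatingConfigError(f"unbalanced parentheses in {expr!r}")
            pos += 1
            return inner
        pos += 1
        if tok not in masks:
            raise GatingConfigError(
                f"boolean gate references unknown sibling {tok!r}"
            )
        return masks[tok]

    out = parse_or()
    if pos != len(tokens):
        raise GatingConfigError(f"trailing tokens in boolean expression {expr!r}")
    if out.shape != (n,):
        raise GatingConfigError("boolean expression produced wrong shape")
    return out


# --- application -----------------------------------------------------------


def _resolve_threshold(
    node_values: np.ndarray,
    source: dict,
    tree: GatingTree,
    seed: int,
    transformed: bool,
    cofactor: float,
) -> float:
    """Return a threshold on the analysis scale of the channel."""
    if "fixed" in source:
        v = float(source["fixed"])
        # fixed thresholds are written on the raw scale; move them to the
        # transformed scale for fluorescence channels
        return float(np.arcsinh(v / cofactor)) if transformed else v
    if "quantile" in source:
        return auto_threshold(node_values, method="quantile", q=float(source["quantile"]))
    methods = source.get("auto", list(tree.auto_methods))
    if isinstance(methods, str):
        methods = [methods] + [m for m in tree.auto_methods if m != methods]
    return _cascade_threshold(node_values, methods, seed)


def apply_gating(
    events: EventMatrix, tree: GatingTree, seed: int = 0
) -> GatingResult:
    """Assign every event to the gating hierarchy.

    Deterministic for a given seed (which controls KDE subsampling and GMM
    initialisation).  Quadrant thresholds are placed once per quadrant family
    on the shared parent population.  An empty parent simply yields empty
    descendants.  Per-event labels are the deepest exclusive node containing
    the event; events matching no child stay labelled with their parent, and
    events failing the root gates are labelled ``"root"``.
    """
    missing = sorted(tree.required_channels() - set(events.channels))
    if missing:
        raise GatingConfigError(f"events lack gating channels: {missing}")

    n = events.n_events
    cofactor = tree.cofactor
    fluor = set(events.marker_channels())
    tdata: dict[str, np.ndarray] = {}
    for c in tree.required_channels():
        x = events.data[c].to_numpy(dtype=float)
        tdata[c] = np.arcsinh(x / cofactor) if c in fluor else x

    memberships: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    quadrant_cache: dict[tuple, tuple[float, float]] = {}

    def parent_mask(node: GateNode) -> np.ndarray:
        if node.parent is None:
            return np.ones(n, dtype=bool)
        return memberships[node.parent]

    def threshold_for(
        node: GateNode, channel: str, pmask: np.ndarray, source: dict, key: str
    ) -> float:
        vals = tdata[channel][pmask]
        thr = _resolve_threshold(
            vals, source, tree, seed, channel in fluor, cofactor
        )
        thresholds[key] = thr
        return thr

    for node_id in tree.order:
        node = tree.nodes[node_id]
        pmask = parent_mask(node)
        p = node.params
        if node.kind == "threshold":
            ch = p["channel"]
            if pmask.sum() == 0:
                memberships[node_id] = np.zeros(n, dtype=bool)
                continue
            thr = threshold_for(
                node, ch, pmask, p.get("source", {}), f"{node_id}/{ch}"
            )
            side = p.get("side", "+")
            cond = tdata[ch] >= thr if side == "+" else tdata[ch] < thr
            memberships[node_id] = pmask & cond
        elif node.kind == "ratio":
            num = tdata[p["numerator"]]
            den = tdata[p["denominator"]]
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(den != 0, num / den, np.inf)
            memberships[node_id] = pmask & (r >= p["lo"]) & (r < p["hi"])
        elif node.kind == "rect":
            x, y = tdata[p["channel_x"]], tdata[p["channel_y"]]
            memberships[node_id] = (
                pmask
                & (x >= p["x_lo"]) & (x < p["x_hi"])
                & (y >= p["y_lo"]) & (y < p["y_hi"])
            )
        elif node.kind == "quadrant":
            chx, chy = p["channel_x"], p["channel_y"]
            fam = (node.parent, chx, chy)
            if pmask.sum() == 0:
                memberships[node_id] = np.zeros(n, dtype=bool)
                continue
            if fam not in quadrant_cache:
                sx = p.get("source_x", p.get("source", {}))
                sy = p.get("source_y", p.get("source", {}))
                tx = threshold_for(node, chx, pmask, sx, f"{node.parent}/{chx}")
                ty = threshold_for(node, chy, pmask, sy, f"{node.parent}/{chy}")
                quadrant_cache[fam] = (tx, ty)
            tx, ty = quadrant_cache[fam]
            qx, qy = p["quadrant"]
            condx = tdata[chx] >= tx if qx == "+" else tdata[chx] < tx
            condy = tdata[chy] >= ty if qy == "+" else tdata[chy] < ty
            memberships[node_id] = pmask & condx & condy
        elif node.kind == "markers":
            mask = pmask.copy()
            for term in p["terms"]:
                ch = term["channel"]
                if mask.sum() == 0:
                    mask[:] = False
                    break
                source = term.get("source", {})
                if term.get("scope") == "parent":
                    scope_mask = pmask
                else:
                    # quantile-style terms are placed on the events surviving
                    # the preceding terms (e.g. PD-1-high within CXCR5- memory)
                    scope_mask = mask if "quantile" in source else pmask
                thr = _resolve_threshold(
                    tdata[ch][scope_mask],
                    source,
                    tree,
                    seed,
                    ch in fluor,
                    cofactor,
                )
                thresholds[f"{node_id}/{ch}"] = thr
                side = term.get("side", "+")
                cond = tdata[ch] >= thr if side == "+" else tdata[ch] < thr
                mask &= cond
            memberships[node_id] = mask
        elif node.kind == "boolean":
            sibling_masks = {
                s.id: memberships[s.id]
                for s in tree.children(node.parent)
                if s.id in memberships
            }
            memberships[node_id] = pmask & _eval_boolean(
                p["expr"], sibling_masks, n
            )
        else:
            raise GatingConfigError(f"unknown gate kind {node.kind!r}")

    labels = np.full(n, "root", dtype=object)
    for node_id in tree.order:  # parents precede children; deepest wins
        node = tree.nodes[node_id]
        if node.exclusive:
            labels[memberships[node_id]] = node_id
    return GatingResult(tree, memberships, pd.Series(labels, index=events.data.index), thresholds)


# --- statistics ------------------------------------------------------------


def subset_frequencies(
    result: GatingResult, sample_id: str = "sample"
) -> pd.DataFrame:
    """Per-subset event counts and percentages.

    ``pct_of_parent`` is 100 * n_child / n_parent (missing when the parent is
    empty, never reported as 0); ``pct_of_denominator`` is relative to the
    tree's denominator node (e.g. viable singlets) where configured.
    """
    tree = result.tree
    denom = None
    if tree.denominator is not None:
        denom = result.count(tree.denominator)
    rows = []
    for node_id in tree.order:
        node = tree.nodes[node_id]
        n_child = result.count(node_id)
        n_parent = (
            result.count(node.parent)
            if node.parent is not None
            else len(result.labels)
        )
        rows.append(
            {
                "sample_id": sample_id,
                "subset": node_id,
                "parent": node.parent if node.parent is not None else "root",
                "n_events": n_child,
                "pct_of_parent": 100.0 * n_child / n_parent if n_parent else np.nan,
                "pct_of_denominator": (
                    100.0 * n_child / denom if denom else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def subset_mfi(
    events: EventMatrix,
    result: GatingResult,
    markers: list[str],
    min_events: int = 20,
    sample_id: str = "sample",
    subsets: list[str] | None = None,
) -> pd.DataFrame:
    """Raw-scale median fluorescence intensity per (subset, marker).

    Subsets with fewer than ``min_events`` events are reported missing — a
    median over a handful of events is too unstable to feed into screening
    statistics.
    """
    missing = [m for m in markers if m not in events.channels]
    if missing:
        raise GatingConfigError(f"events lack MFI markers: {missing}")
    subset_ids = subsets if subsets is not None else list(result.tree.order)
    raw = events.data[markers].to_numpy()
    rows = []
    for node_id in subset_ids:
        mask = result.memberships[node_id]
        n_evt = int(mask.sum())
        med = (
            np.median(raw[mask], axis=0)
            if n_evt >= min_events
            else np.full(len(markers), np.nan)
        )
        for j, m in enumerate(markers):
            rows.append(
                {
                    "sample_id": sample_id,
                    "subset": node_id,
                    "marker": m,
                    "n_events": n_evt,
                    "mfi": med[j],
                }
            )
    return pd.DataFrame(rows)


def summarize_frequencies(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-donor mean and interquartile range of subset percentages."""
    combined = pd.concat(tables, ignore_index=True)

    def iqr(x):
        x = x.dropna()
        if x.empty:
            return np.nan
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    return (
        combined.groupby("subset", sort=False)
        .agg(
            mean_pct_of_parent=("pct_of_parent", "mean"),
            iqr_pct_of_parent=("pct_of_parent", iqr),
            mean_pct_of_denominator=("pct_of_denominator", "mean"),
            iqr_pct_of_denominator=("pct_of_denominator", iqr),
            n_samples=("sample_id", "nunique"),
        )
        .reset_index()
    )
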