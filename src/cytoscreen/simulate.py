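"""Seeded synthetic cytometry data with known ground truth.

No public PBMC dataset accompanies the workflow this package implements, so
every downstream stage (unmixing, gating, titration, screening statistics) is
exercised against simulated events whose composition, marker expression and
treatment effects are known exactly.

The generative model:

* A hierarchical population tree assigns each leaf population a fraction of
  its parent and a per-marker expression spec.  Marker intensities are drawn
  log-normally on the raw scale (the standard model for cytometry
  fluorescence); positive/negative/low/high status is encoded purely through
  the log-location, and bimodal markers are mixtures of log-normal components.
* Donors perturb the leaf composition with multiplicative log-normal jitter
  on the odds scale followed by renormalisation, emulating biological
  variance between subjects.
* Stimulation and drug conditions act multiplicatively on the raw-scale
  median of targeted (population, marker) pairs: a factor ``k`` shifts the
  log-location by ``ln k``, so the population median scales exactly by ``k``
  and the implied ground-truth fractional difference is ``k - 1``.
* Debris (low forward scatter), doublets (FSC-H ~ FSC-A/2) and dead cells
  (bright viability-dye signal) are mixed in at configurable rates so the
  pre-gating steps have something to remove.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventMatrix, QC_LABELS, SCATTER_CHANNELS, VIABILITY_CHANNEL
from .panel import PanelDefinition, SpectralSignature

__all__ = [
    "MarkerExpr",
    "PopulationNode",
    "PopulationTree",
    "DonorSpec",
    "ConditionEffect",
    "generate_donor_events",
    "apply_condition",
    "synthesize_spectral_raw",
    "generate_titration_series",
    "generate_cohort",
    "truth_subset_mfi",
    "cohort_feature_matrix",
    "DEFAULT_LEVELS",
]

#: Raw-scale medians for the named expression levels.  "neg" is dye/carryover
#: background, "low" a dim positive, "pos" a clearly positive population and
#: "high" a bright one (e.g. PD-1 on Tph cells, CD56 on early NK cells).
DEFAULT_LEVELS: dict[str, float] = {
    "neg": 120.0,
    "low": 900.0,
    "pos": 5000.0,
    "high": 20000.0,
}
DEFAULT_LOG_SIGMA = 0.45


@dataclass(frozen=True)
class MarkerExpr:
    """Mixture of log-normal components: (weight, log-location, log-scale)."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        w = sum(c[0] for c in self.components)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError(f"mixture weights sum to {w}, expected 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("log-scale sigma must be > 0")

    @classmethod
    def single(cls, median: float, sigma: float = DEFAULT_LOG_SIGMA) -> "MarkerExpr":
        if median <= 0:
            raise ValueError("raw-scale median must be > 0")
        return cls(((1.0, math.log(median), sigma),))

    def scaled(self, k: float) -> "MarkerExpr":
        """Multiply the raw-scale distribution (hence its median) by k > 0."""
        if k <= 0:
            raise ValueError("multiplicative factor must be > 0")
        return MarkerExpr(
            tuple((w, mu + math.log(k), s) for w, mu, s in self.components)
        )

    def median(self) -> float:
        """Raw-scale median (exact for one component, numeric for mixtures)."""
        if len(self.components) == 1:
            return math.exp(self.components[0][1])
        grid = np.linspace(-5, 15, 4001)
        cdf = np.zeros_like(grid)
        from scipy.stats import norm

        for w, mu, s in self.components:
            cdf += w * norm.cdf(grid, loc=mu, scale=s)
        return float(np.exp(np.interp(0.5, cdf, grid)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if len(self.components) == 1:
            _, mu, s = self.components[0]
            return rng.lognormal(mu, s, size=n)
        weights = np.array([c[0] for c in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights)
        mus = np.array([c[1] for c in self.components])[idx]
        sds = np.array([c[2] for c in self.components])[idx]
        return np.exp(rng.normal(mus, sds))


@dataclass
class PopulationNode:
    name: str
    parent: str | None  # None for children of the root
    fraction_of_parent: float
    expression: dict[str, MarkerExpr] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.fraction_of_parent <= 1.0):
            raise ValueError(
                f"fraction_of_parent of {self.name!r} must be in [0, 1]"
            )


class PopulationTree:
    """Hierarchy of populations; leaves carry resolved marker expression."""

    def __init__(
        self,
        nodes: list[PopulationNode],
        markers: list[str],
        levels: dict[str, float] | None = None,
        sigma: float = DEFAULT_LOG_SIGMA,
        name: str = "populations",
    ):
        self.name = name
        self.markers = list(markers)
        self.levels = dict(levels or DEFAULT_LEVELS)
        self.sigma = sigma
        self.nodes: dict[str, PopulationNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate population {node.name!r}")
            self.nodes[node.name] = node
        self._children: dict[str | None, list[str]] = {}
        for node in nodes:
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(
                    f"population {node.name!r} references unknown parent "
                    f"{node.parent!r}"
                )
            self._children.setdefault(node.parent, []).append(node.name)
        for parent, kids in self._children.items():
            total = sum(self.nodes[k].fraction_of_parent for k in kids)
            if total > 1.0 + 1e-9:
                label = parent if parent is not None else "root"
                raise ValueError(
                    f"children of {label!r} have fractions summing to "
                    f"{total:.4f} > 1"
                )

    def children(self, name: str | None) -> list[str]:
        return list(self._children.get(name, []))

    def leaves(self) -> list[str]:
        return [n for n in self.nodes if not self._children.get(n)]

    def leaf_fractions(self) -> dict[str, float]:
        """Absolute fraction of each leaf among all (live, single) cells."""
        out: dict[str, float] = {}
        for leaf in self.leaves():
            f, cur = 1.0, self.nodes[leaf]
            while True:
                f *= cur.fraction_of_parent
                if cur.parent is None:
                    break
                cur = self.nodes[cur.parent]
            out[leaf] = f
        return out

    def descendant_leaves(self, name: str) -> list[str]:
        kids = self._children.get(name)
        if not kids:
            return [name]
        out: list[str] = []
        for k in kids:
            out.extend(self.descendant_leaves(k))
        return out

    def resolved_expression(self, leaf: str) -> dict[str, MarkerExpr]:
        """Leaf expression with ancestor inheritance; unspecified -> 'neg'."""
        chain: list[PopulationNode] = []
        cur: PopulationNode | None = self.nodes[leaf]
        while cur is not None:
            chain.append(cur)
            cur = self.nodes[cur.parent] if cur.parent is not None else None
        default = MarkerExpr.single(self.levels["neg"], self.sigma)
        out = {m: default for m in self.markers}
        for node in reversed(chain):  # root-most first, leaf overrides
            out.update(node.expression)
        return out

    def copy(self) -> "PopulationTree":
        nodes = [
            PopulationNode(n.name, n.parent, n.fraction_of_parent, dict(n.expression))
            for n in self.nodes.values()
        ]
        return PopulationTree(nodes, self.markers, self.levels, self.sigma, self.name)


@dataclass
class DonorSpec:
    """One simulated subject: composition jitter scale, seed and metadata."""

    donor_id: str
    composition_jitter: float = 0.15
    seed: int = 0
    group_label: str = "HC"
    condition: str = "unstim"


@dataclass
class ConditionEffect:
    """Multiplicative marker effects of a stimulation or drug condition.

    ``marker_factors`` maps (population, marker) -> factor k > 0 applied to
    that population's raw-scale median; a population may name an internal node
    (the factor then applies to all its leaves) or "*" for every population.
    ``composition`` optionally overrides leaf fractions-of-parent, with the
    balance absorbed by ``composition_balance`` (a sibling leaf), modelling
    disease-associated shifts in subset frequencies.
    """

    name: str = "effect"
    marker_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    composition: dict[str, float] = field(default_factory=dict)
    composition_balance: str | None = None

    def ground_truth_fd(self) -> dict[tuple[str, str], float]:
        """Implied fractional difference (k - 1) per targeted pair."""
        return {key: k - 1.0 for key, k in self.marker_factors.items()}


def apply_condition(tree: PopulationTree, effect: ConditionEffect) -> PopulationTree:
    """Return a new tree with the condition's multiplicative effects applied.

    Marker factors shift the targeted populations' log-locations by ln k (the
    raw-scale median scales exactly by k); composition overrides adjust leaf
    fractions with the balance leaf absorbing the difference, so sibling
    fractions remain a valid composition.
    """
    new = tree.copy()
    for (pop, marker), k in effect.marker_factors.items():
        if k <= 0:
            raise ValueError(f"factor for ({pop}, {marker}) must be > 0")
        if marker not in new.markers:
            raise KeyError(f"unknown marker {marker!r} in effect {effect.name!r}")
        if pop == "*":
            targets = new.leaves()
        elif pop in new.nodes:
            targets = new.descendant_leaves(pop)
        else:
            raise KeyError(f"unknown population {pop!r} in effect {effect.name!r}")
        for leaf in targets:
            expr = new.resolved_expression(leaf)[marker]
            new.nodes[leaf].expression[marker] = expr.scaled(k)
    if effect.composition:
        delta = 0.0
        for pop, frac in effect.composition.items():
            if pop not in new.nodes:
                raise KeyError(f"unknown population {pop!r} in composition shift")
            delta += new.nodes[pop].fraction_of_parent - frac
            new.nodes[pop].fraction_of_parent = frac
        if effect.composition_balance is not None:
            bal = new.nodes[effect.composition_balance]
            bal.fraction_of_parent += delta
            if bal.fraction_of_parent < 0:
                raise ValueError("composition shift drives balance leaf below 0")
    return new


def _jitter_composition(
    fractions: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb composition on the log-odds scale and renormalise."""
    if sigma == 0:
        return fractions
    f = np.clip(fractions, 1e-12, 1 - 1e-12)
    logit = np.log(f / (1 - f)) + rng.normal(0.0, sigma, size=f.shape)
    odds = np.exp(logit)
    p = odds / (1 + odds)
    return p / p.sum() * fractions.sum()


def generate_donor_events(
    tree: PopulationTree,
    donor: DonorSpec,
    n_events: int,
    seed: int | None = None,
    debris_fraction: float = 0.05,
    doublet_fraction: float = 0.05,
    dead_fraction: float = 0.10,
) -> EventMatrix:
    """Simulate one acquisition tube for one donor, with truth labels.

    Event counts per class (debris / doublet / dead / each leaf population)
    are drawn multinomially; live single cells follow the donor-perturbed leaf
    composition.  A fixed seed yields byte-identical output.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    for frac in (debris_fraction, doublet_fraction, dead_fraction):
        if not (0.0 <= frac < 1.0):
            raise ValueError("QC fractions must be in [0, 1)")
    if debris_fraction + doublet_fraction + dead_fraction >= 1.0:
        raise ValueError("QC fractions must sum to < 1")
    rng = np.random.default_rng(donor.seed if seed is None else seed)

    leaves = tree.leaves()
    leaf_frac = np.array([tree.leaf_fractions()[l] for l in leaves])
    # unspecified remainder of the composition becomes an unlabeled "other"
    # population with background expression everywhere
    rest = max(0.0, 1.0 - leaf_frac.sum())
    leaf_frac = _jitter_composition(leaf_frac, donor.composition_jitter, rng)

    live_fraction = 1.0 - debris_fraction - doublet_fraction - dead_fraction
    class_names = list(QC_LABELS) + leaves + ["other"]
    class_p = np.concatenate(
        [
            [debris_fraction, doublet_fraction, dead_fraction],
            live_fraction * leaf_frac,
            [live_fraction * rest],
        ]
    )
    class_p = class_p / class_p.sum()
    counts = rng.multinomial(n_events, class_p)

    markers = tree.markers
    n_cols = len(SCATTER_CHANNELS) + 1 + len(markers)
    data = np.empty((n_events, n_cols))
    labels = np.empty(n_events, dtype=object)
    columns = list(SCATTER_CHANNELS) + [VIABILITY_CHANNEL] + markers

    neg = MarkerExpr.single(tree.levels["neg"], tree.sigma)
    live_stain = neg
    dead_stain = MarkerExpr.single(tree.levels["high"], tree.sigma)

    start = 0
    cell_classes = leaves + ["other"]
    other_expr = {m: neg for m in markers}
    for cname, n_cls in zip(class_names, counts):
        if n_cls == 0:
            continue
        sl = slice(start, start + n_cls)
        labels[sl] = cname
        if cname == "debris":
            fsc = np.clip(rng.normal(25_000, 8_000, n_cls), 2_000, 48_000)
            data[sl, 0] = fsc
            data[sl, 1] = fsc * rng.normal(0.95, 0.05, n_cls)
            data[sl, 2] = np.abs(rng.normal(8_000, 4_000, n_cls))
            data[sl, 3] = live_stain.sample(n_cls, rng)
            for j in range(len(markers)):
                data[sl, 4 + j] = neg.sample(n_cls, rng)
        else:
            fsc = np.clip(rng.normal(150_000, 22_000, n_cls), 60_000, None)
            if cname == "doublet":
                # two aggregated cells: pulse area doubles, height does not
                data[sl, 0] = 2.0 * fsc
                data[sl, 1] = 2.0 * fsc * np.clip(
                    rng.normal(0.50, 0.05, n_cls), 0.3, 0.68
                )
            else:
                data[sl, 0] = fsc
                data[sl, 1] = fsc * np.clip(rng.normal(0.97, 0.04, n_cls), 0.76, 1.2)
            data[sl, 2] = np.abs(rng.normal(60_000, 20_000, n_cls))
            data[sl, 3] = (
                dead_stain.sample(n_cls, rng)
                if cname == "dead"
                else live_stain.sample(n_cls, rng)
            )
            if cname in ("doublet", "dead"):
                # markers of a random live population (x ~2 for aggregates)
                src = cell_classes[rng.integers(len(cell_classes))]
                expr = other_expr if src == "other" else tree.resolved_expression(src)
                scale = 1.9 if cname == "doublet" else 1.0
                for j, m in enumerate(markers):
                    data[sl, 4 + j] = scale * expr[m].sample(n_cls, rng)
            else:
                expr = other_expr if cname == "other" else tree.resolved_expression(cname)
                for j, m in enumerate(markers):
                    data[sl, 4 + j] = expr[m].sample(n_cls, rng)
        start += n_cls

    perm = rng.permutation(n_events)
    frame = pd.DataFrame(data[perm], columns=columns)
    return EventMatrix(
        frame,
        labels=pd.Series(labels[perm]),
        metadata={
            "donor": donor.donor_id,
            "group": donor.group_label,
            "condition": donor.condition,
            "seed": donor.seed if seed is None else seed,
            "tree": tree.name,
        },
    )


def synthesize_spectral_raw(
    events: EventMatrix,
    panel: PanelDefinition,
    autofluorescence: SpectralSignature | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EventMatrix:
    """Mix channel-space marker intensities into detector space.

    Detector intensities are the abundance-weighted sum of the panel's
    signatures, optionally plus a fixed-amplitude autofluorescence component
    and additive Gaussian detector noise.  Scatter channels pass through
    untouched.  The viability dye channel maps to the panel's viability entry.
    """
    rng = np.random.default_rng(seed)
    marker_cols = events.marker_channels()
    viability_channel = None
    for c in panel.channels:
        if c.category == "viability":
            viability_channel = c
    sigs, cols = [], []
    for m in marker_cols:
        if m == VIABILITY_CHANNEL and viability_channel is not None:
            ch = viability_channel
        else:
            try:
                ch = panel.channel_for_marker(m)
            except KeyError as exc:
                raise KeyError(
                    f"marker channel {m!r} has no fluorophore in panel "
                    f"{panel.name!r}"
                ) from exc
        if ch.signature is None:
            raise ValueError(f"panel channel {ch.marker!r} lacks a signature")
        sigs.append(ch.signature.intensities)
        cols.append(m)
    S = np.stack(sigs)
    abundance = events.data[cols].to_numpy()
    raw = abundance @ S
    if autofluorescence is not None:
        raw = raw + 150.0 * autofluorescence.intensities[None, :]
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    det_names = [f"D{i}" for i in range(S.shape[1])]
    frame = pd.DataFrame(raw, columns=det_names, index=events.data.index)
    for c in SCATTER_CHANNELS:
        if c in events.data:
            frame.insert(0, c, events.data[c])
    meta = dict(events.metadata)
    meta.update({"space": "detector", "panel": panel.name, "noise_sd": noise_sd})
    return EventMatrix(frame, labels=events.labels, metadata=meta)


#: Default 2-fold serial-dilution ladder (µL/test), highest first.
DEFAULT_LADDER = (20.0, 10.0, 5.0, 2.5, 1.25, 0.625, 0.3125)


def generate_titration_series(
    reagent: str,
    concentrations=DEFAULT_LADDER,
    n_events: int = 4000,
    seed: int = 0,
    pos_fraction: float = 0.3,
    mfi_max: float = 20_000.0,
    half_saturation: float = 1.0,
    background: float = 100.0,
    background_slope: float = 40.0,
    sigma: float = 0.35,
) -> list[tuple[float, EventMatrix]]:
    """Simulate a 2-fold antibody dilution ladder with pos/neg truth labels.

    The positive-population median follows a saturating binding curve
    ``mfi_max * c / (c + K)`` on top of the background, while the negative
    background rises linearly with concentration (``background +
    background_slope * c``), emulating the non-specific staining that makes
    over-titrated antibodies lose separation.  The linear background model is
    a synthetic-only device chosen so the stain index is unimodal across the
    ladder.
    """
    conc = [float(c) for c in concentrations]
    if any(c <= 0 for c in conc):
        raise ValueError("concentrations must be positive")
    if any(c2 >= c1 for c1, c2 in zip(conc, conc[1:])):
        raise ValueError("concentrations must be strictly decreasing")
    for c1, c2 in zip(conc, conc[1:]):
        if not math.isclose(c1 / c2, 2.0, rel_tol=1e-6):
            raise ValueError("ladder must be a 2-fold serial dilution")
    rng = np.random.default_rng(seed)
    out = []
    for c in conc:
        bg = background + background_slope * c
        pos_median = mfi_max * c / (c + half_saturation) + bg
        n_pos = int(round(pos_fraction * n_events))
        n_neg = n_events - n_pos
        pos = np.exp(rng.normal(math.log(pos_median), sigma, n_pos))
        neg = np.exp(rng.normal(math.log(bg), sigma, n_neg))
        values = np.concatenate([pos, neg])
        labels = np.array(["positive"] * n_pos + ["negative"] * n_neg, dtype=object)
        perm = rng.permutation(n_events)
        frame = pd.DataFrame({reagent: values[perm]})
        out.append(
            (
                c,
                EventMatrix(
                    frame,
                    labels=pd.Series(labels[perm]),
                    metadata={"reagent": reagent, "concentration_ul_per_test": c},
                ),
            )
        )
    return out


def generate_cohort(
    tree: PopulationTree,
    case_effect: ConditionEffect,
    donors_per_group: int = 5,
    n_events: int = 20_000,
    seed: int = 0,
    groups: tuple[str, str] = ("HC", "RA"),
    composition_jitter: float = 0.15,
    conditions: tuple[str, ...] = ("unstim",),
) -> tuple[dict[str, EventMatrix], pd.DataFrame]:
    """Simulate a two-group patient cohort (controls vs cases).

    The case group's tree is the control tree with ``case_effect`` applied
    (activation-marker shifts and subset-composition changes).  Returns the
    per-sample event matrices keyed by sample id plus a metadata table with
    one row per donor x condition.
    """
    if donors_per_group < 1:
        raise ValueError("need at least one donor per group")
    ss = np.random.SeedSequence(seed)
    trees = {groups[0]: tree, groups[1]: apply_condition(tree, case_effect)}
    samples: dict[str, EventMatrix] = {}
    rows = []
    child_seeds = iter(ss.generate_state(2 * donors_per_group * len(conditions)))
    for group in groups:
        for i in range(donors_per_group):
            donor_id = f"{group}{i + 1}"
            for condition in conditions:
                s = int(next(child_seeds)) % (2**31)
                donor = DonorSpec(
                    donor_id,
                    composition_jitter=composition_jitter,
                    seed=s,
                    group_label=group,
                    condition=condition,
                )
                sample_id = f"{donor_id}_{condition}"
                samples[sample_id] = generate_donor_events(
                    trees[group], donor, n_events
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "donor": donor_id,
                        "group": group,
                        "condition": condition,
                        "seed": s,
                    }
                )
    return samples, pd.DataFrame(rows)


def truth_subset_mfi(
    events: EventMatrix,
    tree: PopulationTree,
    subsets: list[str],
    markers: list[str],
    min_events: int = 20,
) -> pd.DataFrame:
    """Raw-scale per-(subset, marker) medians using ground-truth labels.

    ``subsets`` may name internal tree nodes (pooling their descendant
    leaves).  Mirrors the gated MFI extraction but bypasses gating, which is
    useful for isolating the statistics pipeline from gating error.
    """
    if events.labels is None:
        raise ValueError("events carry no truth labels")
    rows = []
    lab = events.labels
    for sub in subsets:
        if sub in tree.nodes:
            leaves = set(tree.descendant_leaves(sub))
        else:
            raise KeyError(f"unknown population {sub!r}")
        mask = lab.isin(leaves).to_numpy()
        n_evt = int(mask.sum())
        med = (
            events.data.loc[mask, markers].median()
            if n_evt >= min_events
            else pd.Series(np.nan, index=markers)
        )
        for m in markers:
            rows.append(
                {"subset": sub, "marker": m, "n_events": n_evt, "mfi": med[m]}
            )
    return pd.DataFrame(rows)


def cohort_feature_matrix(
    samples: dict[str, EventMatrix],
    tree: PopulationTree,
    subsets: list[str],
    markers: list[str],
    min_events: int = 20,
) -> pd.DataFrame:
    """Donors x (subset, marker) MFI feature matrix from truth labels.

    Features missing in any sample (too few events) are dropped column-wise
    so the downstream normalisation sees a complete matrix.
    """
    feats = {}
    for sid, em in samples.items():
        t = truth_subset_mfi(em, tree, subsets, markers, min_events)
        feats[sid] = {
            (r.subset, r.marker): r.mfi for r in t.itertuples(index=False)
        }
    frame = pd.DataFrame(feats).T
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame.dropna(axis=1)
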