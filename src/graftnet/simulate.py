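"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its parameters and seed, so reruns are
byte-identical.  The default study design mirrors the experimental setting
the pipeline targets: a 4-timepoint (D1, D3, W2, W4) kinetic proteome with 3
biological replicates per timepoint in two conditions (vein graft VG vs
control vein IVC) over 1357 quantified proteins, a multigroup static design
(IVC / NEO / ADV / WT), a preferential-attachment (scale-free) interactome,
planted pathway memberships around a hub target, and disease modules at
controlled proximity classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import AbundanceTable, GeneSet, GeneSetCollection
from .proximity import build_degree_bins, default_min_bin_size, sample_matched_pair

DEFAULT_TIMEPOINTS = ("D1", "D3", "W2", "W4")
DEFAULT_STATIC_GROUPS = (("IVC", 3), ("NEO", 3), ("ADV", 3), ("WT", 3))
PROXIMITY_CLASSES = ("overlapping", "neighboring", "random")


# -- truth containers ---------------------------------------------------------


@dataclass(frozen=True)
class KineticTruth:
    """Planted trend templates and per-profile template assignments (1-based)."""

    templates: np.ndarray  # (K_true, T) fractional vectors
    assignments: pd.DataFrame  # protein_id, condition, template_id

    def labels(self) -> pd.Series:
        idx = self.assignments.set_index(["protein_id", "condition"])
        return idx["template_id"]


@dataclass(frozen=True)
class StaticTruth:
    """Planted differential flags, directions and log2 effects per protein."""

    table: pd.DataFrame  # protein_id, differential, direction, effect_log2

    def differential_set(self) -> frozenset:
        return frozenset(self.table.loc[self.table["differential"], "protein_id"])


# -- kinetic proteome ---------------------------------------------------------


def default_templates(timepoints: int = 4, n_templates: int = 10) -> np.ndarray:
    """Well-separated fractional trend templates: sharp and extreme single
    peaks at each timepoint, a flat profile, and a rising ramp."""
    T = timepoints
    if T < 2:
        raise ParameterError("need at least 2 timepoints")
    shapes = []
    for peak in (0.55, 0.85):
        low = (1.0 - peak) / (T - 1)
        for t in range(T):
            v = np.full(T, low)
            v[t] = peak
            shapes.append(v)
    shapes.append(np.full(T, 1.0 / T))
    ramp = np.arange(1, T + 1, dtype=float)
    shapes.append(ramp / ramp.sum())
    shapes.append(ramp[::-1] / ramp.sum())
    if n_templates > len(shapes):
        raise ParameterError(f"at most {len(shapes)} built-in templates for T={T}")
    return np.array(shapes[:n_templates])


def _validate_templates(templates, timepoints: int) -> np.ndarray:
    arr = np.asarray(templates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != timepoints:
        raise ParameterError(f"templates must be vectors of length {timepoints}")
    if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
        raise ParameterError("each template must sum to 1 (±1e-9)")
    if (arr < 0).any():
        raise ParameterError("templates must be non-negative")
    return arr


def synth_kinetic_proteome(
    n_proteins: int = 1357,
    timepoints: int = 4,
    replicates: int = 3,
    templates=None,
    noise_sd: float = 0.03,
    seed: int = 0,
    conditions=("VG", "IVC"),
    timepoint_names=None,
    protein_ids=None,
):
    """Two-condition kinetic proteome with planted trend-cluster truth.

    Per protein and condition a template is drawn uniformly (independently per
    condition); each replicate abundance is ``scale * max(template + noise, 0)``
    with a per-profile log-normal scale.  Returns ``(AbundanceTable,
    KineticTruth)``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if replicates < 1 or n_proteins < 1:
        raise ParameterError("need >= 1 replicate and >= 1 protein")
    if templates is None:
        templates = default_templates(timepoints)
    templates = _validate_templates(templates, timepoints)
    if timepoint_names is None:
        timepoint_names = (
            DEFAULT_TIMEPOINTS if timepoints == 4 else tuple(f"T{i+1}" for i in range(timepoints))
        )
    if protein_ids is None:
        width = len(str(n_proteins - 1))
        protein_ids = [f"PR{i:0{width}d}" for i in range(n_proteins)]
    elif len(protein_ids) != n_proteins:
        raise ParameterError("protein_ids length must equal n_proteins")
    K = len(templates)
    rng = np.random.default_rng(seed)
    columns, col_values, ann_rows, truth_rows = [], [], [], []
    for cond in conditions:
        tid = rng.integers(0, K, size=n_proteins)
        scale = rng.lognormal(mean=np.log(1e4), sigma=0.5, size=n_proteins)
        noise = rng.normal(0.0, noise_sd, size=(n_proteins, timepoints, replicates))
        vals = np.maximum(templates[tid][:, :, None] + noise, 0.0) * scale[:, None, None]
        for t, tp in enumerate(timepoint_names):
            for r in range(replicates):
                sample = f"{cond}_{tp}_R{r+1}"
                columns.append(sample)
                col_values.append(vals[:, t, r])
                ann_rows.append((sample, cond, tp, r + 1))
        for pid, k in zip(protein_ids, tid):
            truth_rows.append((str(pid).upper(), cond, int(k) + 1))
    data = pd.DataFrame(np.column_stack(col_values), index=protein_ids, columns=columns)
    annotations = pd.DataFrame(ann_rows, columns=["sample_id", "condition", "timepoint", "replicate"])
    truth = KineticTruth(
        templates=templates,
        assignments=pd.DataFrame(truth_rows, columns=["protein_id", "condition", "template_id"]),
    )
    return AbundanceTable(data, annotations), truth


# -- static proteome ----------------------------------------------------------


def synth_static_proteome(
    groups=None,
    n_proteins: int = 1357,
    frac_differential: float = 0.2,
    effect_log2: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    lesion_conditions=None,
    protein_ids=None,
    differential_proteins=None,
    directions=None,
):
    """Multigroup static proteome (log-normal) with planted differential proteins.

    Differential proteins are shifted by ``direction * effect_log2`` log2 units
    in the lesion conditions (default: every group but the first).  With
    ``effect_log2 = 0`` no protein is flagged differential.  The planted set
    can be pinned with ``differential_proteins`` (and per-protein ±1
    ``directions``); otherwise exactly ``round(frac_differential * n_proteins)``
    proteins are drawn.  Returns ``(AbundanceTable, StaticTruth)``.
    """
    if groups is None:
        groups = DEFAULT_STATIC_GROUPS
    groups = [(str(c), int(n)) for c, n in groups]
    if len(groups) < 2 or any(n < 2 for _, n in groups):
        raise ParameterError("need >= 2 groups with >= 2 samples each")
    if not 0 <= frac_differential <= 1:
        raise ParameterError("frac_differential must lie in [0, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if protein_ids is None:
        width = len(str(n_proteins - 1))
        protein_ids = [f"PR{i:0{width}d}" for i in range(n_proteins)]
    protein_ids = [str(p).upper() for p in protein_ids]
    if len(protein_ids) != n_proteins:
        raise ParameterError("protein_ids length must equal n_proteins")
    conditions = [c for c, _ in groups]
    if lesion_conditions is None:
        lesion_conditions = conditions[1:]
    lesion_conditions = set(lesion_conditions)
    if not lesion_conditions <= set(conditions):
        raise ParameterError("lesion_conditions must be among the group conditions")

    rng = np.random.default_rng(seed)
    base = rng.normal(20.0, 2.0, size=n_proteins)
    id_index = {p: i for i, p in enumerate(protein_ids)}
    if differential_proteins is None:
        n_diff = int(round(frac_differential * n_proteins))
        diff_idx = rng.choice(n_proteins, size=n_diff, replace=False)
    else:
        missing = [p for p in differential_proteins if str(p).upper() not in id_index]
        if missing:
            raise ParameterError(f"unknown differential proteins: {missing[:5]}")
        diff_idx = np.array(sorted(id_index[str(p).upper()] for p in differential_proteins), dtype=int)
    if directions is None:
        dirs = rng.choice([-1, 1], size=len(diff_idx))
    else:
        dirs = np.asarray(directions, dtype=int)
        if dirs.shape != diff_idx.shape or not set(np.unique(dirs)) <= {-1, 1}:
            raise ParameterError("directions must be ±1, one per differential protein")
    effect = np.zeros(n_proteins)
    if effect_log2 != 0:
        effect[diff_idx] = dirs * effect_log2

    columns, col_values, ann_rows = [], [], []
    for cond, n_samples in groups:
        shift = effect if cond in lesion_conditions else 0.0
        for r in range(n_samples):
            sample = f"{cond}_R{r+1}"
            columns.append(sample)
            log2_vals = base + shift + rng.normal(0.0, noise_sd, size=n_proteins)
            col_values.append(np.exp2(log2_vals))
            ann_rows.append((sample, cond, "static", r + 1))
    data = pd.DataFrame(np.column_stack(col_values), index=protein_ids, columns=columns)
    annotations = pd.DataFrame(ann_rows, columns=["sample_id", "condition", "timepoint", "replicate"])
    differential = np.zeros(n_proteins, dtype=bool)
    direction_col = np.zeros(n_proteins, dtype=int)
    if effect_log2 != 0:
        differential[diff_idx] = True
        direction_col[diff_idx] = dirs
    truth = StaticTruth(
        table=pd.DataFrame(
            {
                "protein_id": protein_ids,
                "differential": differential,
                "direction": direction_col,
                "effect_log2": np.where(differential, direction_col * effect_log2, 0.0),
            }
        )
    )
    return AbundanceTable(data, annotations), truth


# -- interactome, modules, pathways -------------------------------------------


def synth_interactome(n_nodes: int, attachment: int, seed: int = 0) -> nx.Graph:
    """Connected preferential-attachment (scale-free) simple graph.

    Node ids are zero-padded ``P...`` tokens; the edge count is exactly
    ``attachment * (n_nodes - attachment)``.
    """
    if attachment < 1 or n_nodes <= attachment:
        raise ParameterError("need n_nodes > attachment >= 1")
    graph = nx.barabasi_albert_graph(n_nodes, attachment, seed=seed)
    width = len(str(n_nodes - 1))
    return nx.relabel_nodes(graph, {i: f"P{i:0{width}d}" for i in graph.nodes})


def _bfs_order(graph: nx.Graph, source, rng: np.random.Generator) -> list:
    """Breadth-first node order with rng-shuffled neighbor exploration."""
    seen = {source}
    order = [source]
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            nbrs = sorted(n for n in graph.neighbors(node) if n not in seen)
            rng.shuffle(nbrs)
            for n in nbrs:
                seen.add(n)
                order.append(n)
                nxt.append(n)
        frontier = nxt
    return order


def synth_modules(graph: nx.Graph, module_size: int, proximity_class: str, seed: int = 0, min_bin_size=None):
    """A pair of planted modules at a controlled proximity class.

    ``overlapping``: both grown by breadth-first expansion from one seed node,
    sharing >= 30% of members.  ``neighboring``: disjoint, grown from adjacent
    seed nodes.  ``random``: disjoint degree-matched random sets drawn through
    the same degree-binned sampler used by the proximity null.
    """
    if module_size < 5:
        raise ParameterError("module_size must be >= 5")
    if proximity_class not in PROXIMITY_CLASSES:
        raise ParameterError(f"proximity_class must be one of {PROXIMITY_CLASSES}")
    nodes = sorted(graph.nodes)
    if 2 * module_size > len(nodes):
        raise ParameterError("module_size too large for this graph")
    rng = np.random.default_rng(seed)
    if proximity_class == "overlapping":
        shared = max(int(np.ceil(0.3 * module_size)), 1)
        source = nodes[int(rng.integers(len(nodes)))]
        order = _bfs_order(graph, source, rng)
        if len(order) < 2 * module_size - shared:
            raise ParameterError("graph component too small for overlapping modules")
        a = order[:module_size]
        b = order[:shared] + order[module_size : 2 * module_size - shared]
        return frozenset(a), frozenset(b)
    if proximity_class == "neighboring":
        edges = sorted(tuple(sorted(e)) for e in graph.edges)
        s, t = edges[int(rng.integers(len(edges)))]
        a = [n for n in _bfs_order(graph, s, rng) if n != t][:module_size]
        a_set = set(a)
        b = [n for n in _bfs_order(graph, t, rng) if n not in a_set][:module_size]
        if len(a) < module_size or len(b) < module_size:
            raise ParameterError("graph too small for neighboring modules")
        return frozenset(a), frozenset(b)
    # random: disjoint uniform references resampled through the degree-bin sampler
    bins = build_degree_bins(graph, min_bin_size or default_min_bin_size(graph))
    perm = list(np.array(nodes)[rng.permutation(len(nodes))])
    ref_a, ref_b = perm[:module_size], perm[module_size : 2 * module_size]
    a, b, _ = sample_matched_pair(bins, ref_a, ref_b, rng)
    return frozenset(a), frozenset(b)


def synth_pathways(
    graph: nx.Graph,
    n_sets: int = 12,
    size_range=(15, 35),
    hub_target=None,
    seed: int = 0,
    n_hub_sets: int = 3,
) -> GeneSetCollection:
    """Pathway collection of breadth-first neighborhoods with a planted hub.

    At least ``n_hub_sets`` (>= 3) sets are neighborhoods of ``hub_target``
    (default: the highest-degree node), so the hub sits on many shared-protein
    edges of the downstream pathway network.
    """
    lo, hi = int(size_range[0]), int(size_range[1])
    n = graph.number_of_nodes()
    if not 2 <= lo <= hi <= n:
        raise ParameterError(f"size_range {size_range} infeasible for {n} nodes")
    if n_hub_sets < 3 or n_sets < n_hub_sets:
        raise ParameterError("need n_sets >= n_hub_sets >= 3")
    if hub_target is None:
        hub_target = max(sorted(graph.nodes), key=lambda v: (graph.degree(v), v))
    hub_target = str(hub_target).upper()
    if hub_target not in graph:
        raise ParameterError(f"hub target {hub_target!r} not in the interactome")
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        source = hub_target if i < n_hub_sets else nodes[int(rng.integers(len(nodes)))]
        order = _bfs_order(graph, source, rng)
        if len(order) < size:
            raise ParameterError("graph component smaller than the requested set size")
        sets.append(
            GeneSet(
                set_id=f"PW{i:02d}",
                description=f"synthetic neighborhood of {source}",
                members=frozenset(order[:size]),
            )
        )
    return GeneSetCollection(sets)


# -- bundle -------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """All pipeline inputs plus the planted truth of one synthetic study."""

    interactome: nx.Graph
    hub_target: str
    pathways: GeneSetCollection
    static_table: AbundanceTable
    static_truth: StaticTruth
    kinetic_table: AbundanceTable
    kinetic_truth: KineticTruth
    disease_modules: GeneSetCollection
    up_in_lesion: frozenset
    up_in_control: frozenset
    paths: dict = field(default_factory=dict)


def synth_bundle(
    seed: int = 0,
    n_nodes: int = 300,
    attachment: int = 2,
    n_pathways: int = 12,
    pathway_size=(15, 35),
    n_control_differential: int = 60,
    noise_sd_static: float = 0.25,
    effect_log2: float = 2.0,
    noise_sd_kinetic: float = 0.03,
) -> SyntheticBundle:
    """A coherent desk-scale study: one identifier namespace across stages.

    The interactome nodes are the quantified proteome; the planted up-in-lesion
    differential set is the union of the hub-containing pathways, so the
    end-to-end run can rediscover the hub as the consensus central target.
    An equal-sized random up-in-control set gives the bipartition two real
    clusters.
    """
    ss = np.random.SeedSequence(seed)
    s_graph, s_path, s_static, s_kin, s_mod = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    graph = synth_interactome(n_nodes, attachment, seed=s_graph)
    hub = max(sorted(graph.nodes), key=lambda v: (graph.degree(v), v))
    pathways = synth_pathways(
        graph, n_sets=n_pathways, size_range=pathway_size, hub_target=hub, seed=s_path
    )
    hub_sets = [sid for sid in sorted(pathways) if hub in pathways.members(sid)][:3]
    up_lesion = sorted(set().union(*(pathways.members(s) for s in hub_sets)))
    rng = np.random.default_rng(s_mod)
    remaining = sorted(set(graph.nodes) - set(up_lesion))
    n_ctrl = min(n_control_differential, len(remaining))
    up_control = sorted(np.array(remaining)[rng.permutation(len(remaining))[:n_ctrl]])
    proteins = sorted(graph.nodes)
    diff = up_lesion + up_control
    dirs = np.array([1] * len(up_lesion) + [-1] * len(up_control))
    order = np.argsort(diff)
    static_table, static_truth = synth_static_proteome(
        groups=DEFAULT_STATIC_GROUPS,
        n_proteins=len(proteins),
        protein_ids=proteins,
        differential_proteins=list(np.array(diff)[order]),
        directions=dirs[order],
        effect_log2=effect_log2,
        noise_sd=noise_sd_static,
        seed=s_static,
        lesion_conditions=("NEO", "ADV"),
    )
    kinetic_table, kinetic_truth = synth_kinetic_proteome(
        n_proteins=len(proteins),
        protein_ids=proteins,
        noise_sd=noise_sd_kinetic,
        seed=s_kin,
    )
    # disease modules: two lesion-region neighborhoods and two random sets
    hub_ball = _bfs_order(graph, hub, rng)
    avf = frozenset(hub_ball[1:16])
    athero = frozenset(hub_ball[5:25])
    pad, ckd = synth_modules(graph, 15, "random", seed=s_mod + 1)
    disease = GeneSetCollection(
        [
            GeneSet("AVF_FAILURE", "synthetic arterialized-vein disease module", avf),
            GeneSet("ATHEROSCLEROSIS", "synthetic atherosclerosis module", athero),
            GeneSet("PAD", "synthetic random disease module", pad),
            GeneSet("CKD", "synthetic random disease module", ckd),
        ]
    )
    return SyntheticBundle(
        interactome=graph,
        hub_target=hub,
        pathways=pathways,
        static_table=static_table,
        static_truth=static_truth,
        kinetic_table=kinetic_table,
        kinetic_truth=kinetic_truth,
        disease_modules=disease,
        up_in_lesion=frozenset(up_lesion),
        up_in_control=frozenset(up_control),
    )
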