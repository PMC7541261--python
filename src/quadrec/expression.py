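"""Co-expression module detection and neuron-class expression calls.

Module detection follows the hybrid weighted co-expression network recipe:
Pearson correlation -> signed-hybrid soft-threshold adjacency
(``a_ij = r_ij**beta`` for positive correlations, 0 otherwise) ->
topological overlap similarity (TOM) -> average-linkage hierarchical
clustering of ``1 - TOM`` -> static tree cut at an absolute dissimilarity
height with a minimum module size.  The signed-hybrid adjacency keeps
anti-correlated expression programs (e.g. prenatal-high vs postnatal-high
trajectories) in *separate* modules — an unsigned network would fuse two
perfectly anti-correlated blocks into one — and, unlike the fully signed
transform ``((1+r)/2)**beta``, it sends uncorrelated pairs to ~0 at the low
soft-threshold powers used here (4 for spatiotemporal brain matrices, 3 for
laminar neocortex matrices), so noise genes stay unassigned.

Neuron-type calls compare a gene's average expression across excitatory
neuron types against inhibitory types with a two-sided Wilcoxon rank-sum
test; a gene is called excitatory- or inhibitory-preferring when p < alpha
with a consistent direction of the type-mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .burden import two_list_fisher
from .errors import InputError, InvariantError

DEFAULT_CUT_HEIGHT = 0.9  # absolute height on the 1 - TOM scale
DEFAULT_MIN_MODULE_SIZE = 10
UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    gene: str
    module: str  # "M1", "M2", ... or "unassigned"
    eigengene_profile: np.ndarray | None
    power: float


@dataclass
class NeuronClassCall:
    gene: str
    mean_expr_exc: float
    mean_expr_inh: float
    p_value: float
    call: str  # "excitatory" | "inhibitory" | "no_difference"


def signed_hybrid_adjacency(r: np.ndarray, power: float) -> np.ndarray:
    """Signed-hybrid weighted adjacency: ``r ** power`` for positive
    correlations, zero for negative ones; zero diagonal."""
    a = np.where(r > 0, r, 0.0) ** power
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """TOM similarity: shared-neighbourhood overlap of a weighted adjacency.

    ``tom_ij = (a_ij + sum_u a_iu a_uj) / (min(k_i, k_j) + 1 - a_ij)`` with a
    unit diagonal; symmetric, values in [0, 1] for adjacency in [0, 1].
    """
    if not np.allclose(adj, adj.T):
        raise InvariantError("adjacency must be symmetric")
    k = adj.sum(axis=1)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (adj + shared) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _module_eigengene(submatrix: np.ndarray) -> np.ndarray:
    """First principal component of the standardized module submatrix
    (genes x samples), signed to correlate positively with the module mean."""
    z = _zscore_rows(submatrix)
    # PC over samples: SVD of the centred gene x sample matrix
    u, s, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True), full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    return eig


def _zscore_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (m - mu) / sd


def detect_modules(
    expr: pd.DataFrame,
    power: float,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    seed: int | None = None,
    *,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> list[ModuleAssignment]:
    """Cluster genes into co-expression modules.

    ``expr`` is genes x samples.  Modules are labelled M1, M2, ... in
    decreasing size; genes in clusters smaller than ``min_module_size`` are
    unassigned.  The procedure is deterministic given the matrix and the cut
    parameters (``seed`` is accepted for interface symmetry only).
    """
    if expr.shape[1] < 8:
        raise InputError("need at least 8 samples for module detection")
    if expr.shape[0] < 2 * min_module_size:
        raise InputError("need at least 2 * min_module_size genes")
    mat = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    sd = mat.std(axis=1)
    dropped = [g for g, s in zip(genes, sd) if s == 0]
    keep = sd > 0
    mat = mat[keep]
    kept_genes = [g for g, k in zip(genes, keep) if k]

    r = np.corrcoef(mat)
    r = np.clip(r, -1.0, 1.0)
    adj = signed_hybrid_adjacency(r, power)
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw_labels = fcluster(tree, t=cut_height, criterion="distance")

    sizes = pd.Series(raw_labels).value_counts()
    module_clusters = [c for c in sizes.index if sizes[c] >= min_module_size]
    module_clusters.sort(key=lambda c: (-sizes[c], c))
    label_map = {c: f"M{i + 1}" for i, c in enumerate(module_clusters)}

    eigengenes: dict[str, np.ndarray] = {}
    for c, name in label_map.items():
        idx = np.where(raw_labels == c)[0]
        eigengenes[name] = _module_eigengene(mat[idx])

    out = []
    for g, lab in zip(kept_genes, raw_labels):
        name = label_map.get(lab, UNASSIGNED)
        out.append(
            ModuleAssignment(
                gene=g, module=name,
                eigengene_profile=eigengenes.get(name), power=power,
            )
        )
    for g in dropped:
        out.append(ModuleAssignment(gene=g, module=UNASSIGNED,
                                    eigengene_profile=None, power=power))
    return out


def module_profile(
    assignments: list[ModuleAssignment],
    expr: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Normalized per-module expression trajectory.

    Per-gene z-scores across samples are averaged within module, then within
    metadata cells: (stage x region) when both columns are present, else the
    single ``layer`` column.  Returns modules x cells."""
    if list(expr.columns) != list(sample_meta.index):
        raise InputError("sample metadata index must match expression columns")
    if {"stage", "region"} <= set(sample_meta.columns):
        cells = list(zip(sample_meta["stage"], sample_meta["region"]))
        cell_index = pd.MultiIndex.from_tuples(cells, names=["stage", "region"])
    elif "layer" in sample_meta.columns:
        cell_index = pd.Index(sample_meta["layer"], name="layer")
    else:
        raise InputError("sample metadata needs stage+region or layer columns")

    z = pd.DataFrame(
        _zscore_rows(expr.to_numpy(dtype=float)), index=expr.index, columns=expr.columns
    )
    rows = {}
    for module in sorted({a.module for a in assignments if a.module != UNASSIGNED}):
        members = [a.gene for a in assignments if a.module == module and a.gene in z.index]
        if not members:
            continue
        per_sample = z.loc[members].mean(axis=0)
        per_sample.index = cell_index
        rows[module] = per_sample.groupby(level=list(range(cell_index.nlevels))).mean()
    return pd.DataFrame(rows).T


def neuron_class_calls(
    sc_expr: pd.DataFrame,
    type_labels: pd.Series,
    alpha: float = 0.05,
) -> list[NeuronClassCall]:
    """Excitatory vs inhibitory preference per gene.

    ``sc_expr`` is genes x neuron-type average expression; ``type_labels``
    maps each column to ``"excitatory"`` or ``"inhibitory"``.  The two-sided
    Wilcoxon rank-sum test compares the per-type means between classes
    (exact null distribution when there are no ties)."""
    labels = type_labels.reindex(sc_expr.columns)
    if labels.isna().any():
        raise InputError("every neuron-type column needs an exc/inh label")
    exc_cols = labels[labels == "excitatory"].index
    inh_cols = labels[labels == "inhibitory"].index
    if len(exc_cols) == 0 or len(inh_cols) == 0:
        raise InputError("both neuron classes must be represented")

    out = []
    for gene, row in sc_expr.iterrows():
        exc = row[exc_cols].to_numpy(dtype=float)
        inh = row[inh_cols].to_numpy(dtype=float)
        if np.all(exc == exc[0]) and np.all(inh == inh[0]) and exc[0] == inh[0]:
            p = 1.0
        else:
            _, p = mannwhitneyu(exc, inh, alternative="two-sided")
            p = float(p)
        mean_exc, mean_inh = float(exc.mean()), float(inh.mean())
        if p < alpha and mean_exc > mean_inh:
            call = "excitatory"
        elif p < alpha and mean_inh > mean_exc:
            call = "inhibitory"
        else:
            call = "no_difference"
        out.append(NeuronClassCall(gene, mean_exc, mean_inh, p, call))
    return out


def module_membership_contrast(
    assignments: list[ModuleAssignment],
    rigs: list[str],
    dngs: list[str],
    module_label: str,
) -> tuple[float, float]:
    """DNG-vs-RIG membership contrast for one module.

    Hits are the set members assigned to the module; denominators are the
    full DNG and RIG list sizes.  Returns (odds_ratio, p) oriented as DNG
    relative to RIG (OR > 1 means DNGs are over-represented)."""
    members = {a.gene for a in assignments if a.module == module_label}
    dng_hits = len(members & set(dngs))
    rig_hits = len(members & set(rigs))
    return two_list_fisher(dng_hits, len(set(dngs)), rig_hits, len(set(rigs)))
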