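"""Functional network of recessive inherited genes (RIGs) and de novo genes
(DNGs): brain co-expression, protein-protein interaction, and a
covariate-matched permutation test of inter-set connectivity.

Gene pairs are co-expressed when the Pearson correlation of their expression
across brain samples satisfies ``|r| >= 0.8`` and interact when the PPI
confidence score is ``>= 400`` (both thresholds inclusive).  The permutation
null redraws a size-matched replacement for the RIG set while preserving two
confounders that drive connectivity in such networks — gene-level background
de novo mutation rate and coding length — by sampling within quantile-bin
strata of the (rate x length) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, InvariantError

COEXPRESSION_R_MIN = 0.8
PPI_SCORE_MIN = 400


@dataclass(frozen=True)
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    r: float

    def __post_init__(self) -> None:
        if not (self.gene_a < self.gene_b):
            raise InvariantError("edge endpoints must be in canonical order (a < b)")
        if not (-1.0 <= self.r <= 1.0):
            raise InvariantError(f"correlation {self.r} outside [-1, 1]")


@dataclass(frozen=True)
class PPIEdge:
    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if not (self.gene_a < self.gene_b):
            raise InvariantError("edge endpoints must be in canonical order (a < b)")


@dataclass
class PermutationResult:
    observed_genes: int
    observed_connections: int
    null_genes: list[int]
    null_connections: list[int]
    p_genes: float
    p_connections: float
    n_perm: int
    seed: int
    merged_bins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.null_genes) != self.n_perm or len(self.null_connections) != self.n_perm:
            raise InvariantError("null distribution length must equal n_perm")


def coexpression_edges(
    expr: pd.DataFrame,
    genes: list[str],
    *,
    r_min: float = COEXPRESSION_R_MIN,
) -> tuple[list[CoexpressionEdge], dict]:
    """All co-expressed pairs (|r| >= ``r_min``) among ``genes``.

    ``expr`` is a genes x samples matrix.  Genes absent from the matrix or
    with zero expression variance are skipped and tallied in the returned
    diagnostics dict."""
    if expr.shape[1] < 3:
        raise InputError("need at least 3 samples to estimate correlations")
    present = [g for g in genes if g in expr.index]
    absent = sorted(set(genes) - set(present))
    sub = expr.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    keep = sd > 0
    skipped_zero_var = [g for g, k in zip(present, keep) if not k]
    names = [g for g, k in zip(present, keep) if k]
    sub = sub[keep]

    edges: list[CoexpressionEdge] = []
    if len(names) >= 2:
        r = np.corrcoef(sub)
        n = len(names)
        iu, ju = np.triu_indices(n, k=1)
        mask = np.abs(r[iu, ju]) >= r_min
        for i, j in zip(iu[mask], ju[mask]):
            a, b = sorted((names[i], names[j]))
            edges.append(CoexpressionEdge(a, b, float(np.clip(r[i, j], -1.0, 1.0))))
    diags = {"absent_genes": absent, "zero_variance_genes": skipped_zero_var}
    return sorted(edges, key=lambda e: (e.gene_a, e.gene_b)), diags


def read_ppi_edges(path, *, score_min: float = PPI_SCORE_MIN) -> list[PPIEdge]:
    """3-column TSV (gene_a, gene_b, combined_score in 0-1000) -> retained edges."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "combined_score"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: PPI TSV needs columns {sorted(required)}")
    edges = []
    for row in df.itertuples(index=False):
        if row.combined_score >= score_min:
            a, b = sorted((str(row.gene_a), str(row.gene_b)))
            if a != b:
                edges.append(PPIEdge(a, b, float(row.combined_score)))
    return sorted(set(edges), key=lambda e: (e.gene_a, e.gene_b))


def _edge_pairs(edges) -> list[tuple[str, str]]:
    out = []
    for e in edges:
        if isinstance(e, (CoexpressionEdge, PPIEdge)):
            out.append((e.gene_a, e.gene_b))
        else:
            a, b = e[0], e[1]
            out.append((min(a, b), max(a, b)))
    return out


def rig_dng_connections(
    rigs: list[str], dngs: list[str], edges
) -> tuple[int, int]:
    """(#DNGs with >=1 edge to any RIG, #RIG-DNG edges); within-set edges ignored."""
    rig_set, dng_set = set(rigs), set(dngs)
    touched: set[str] = set()
    n_conn = 0
    for a, b in _edge_pairs(edges):
        if a in rig_set and b in dng_set:
            touched.add(b)
            n_conn += 1
        elif b in rig_set and a in dng_set:
            touched.add(a)
            n_conn += 1
    return len(touched), n_conn


def _quantile_bins(values: pd.Series, n_bins: int) -> pd.Series:
    return pd.qcut(values.rank(method="first"), q=n_bins, labels=False)


def matched_permutation_test(
    rigs: list[str],
    dngs: list[str],
    edges,
    covariates: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    n_bins: int = 5,
) -> PermutationResult:
    """Permutation test of RIG-DNG connectivity with covariate matching.

    Genes are stratified into (quintile of dnv_rate) x (quintile of
    coding_length) bins over the gene universe (covariate table minus the DNG
    set).  Each permutation redraws a size-matched replacement for the RIG
    set within bins, without replacement; empirical p-values use the +1
    correction ``p = (1 + #{null >= obs}) / (1 + n_perm)``.

    Bins with fewer members than required are merged with their nearest
    neighbour on the flattened bin grid (merges are logged in the result).
    """
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    for col in ("dnv_rate", "coding_length"):
        if col not in covariates.columns:
            raise InputError(f"covariates must include {col!r}")
    dng_set = set(dngs)
    universe = covariates.index[~covariates.index.isin(dng_set)]
    missing = sorted(set(rigs) - set(universe))
    if missing:
        raise InputError(f"RIGs without covariates (or clashing with DNGs): {missing[:5]}")

    uni = covariates.loc[universe]
    bin_rate = _quantile_bins(uni["dnv_rate"], n_bins)
    bin_len = _quantile_bins(uni["coding_length"], n_bins)
    flat = (bin_rate * n_bins + bin_len).astype(int)

    rig_index = pd.Index(rigs)
    rig_bins = flat.loc[rig_index]

    # members per flat bin, with small-bin merging
    required = rig_bins.value_counts().to_dict()
    pools: dict[int, list[str]] = {
        int(b): list(idx) for b, idx in flat.groupby(flat).groups.items()
    }
    merged_log: list[str] = []
    while True:
        deficient = [
            b for b, need in required.items() if need and len(pools.get(b, [])) < need
        ]
        if not deficient:
            break
        b = deficient[0]
        neighbours = sorted((abs(o - b), o) for o in pools if o != b)
        if not neighbours:
            raise InvariantError("gene universe too small for the requested sampling")
        _, tgt = neighbours[0]
        pools[tgt] = pools[tgt] + pools.pop(b)
        required[tgt] = required.get(tgt, 0) + required.pop(b)
        merged_log.append(f"bin {b} merged into {tgt}")

    gene_pos = {g: i for i, g in enumerate(universe)}
    n_dng = len(dngs)
    dng_pos = {g: i for i, g in enumerate(dngs)}
    adj = np.zeros((len(universe), n_dng), dtype=bool)
    for a, b in _edge_pairs(edges):
        if a in gene_pos and b in dng_pos:
            adj[gene_pos[a], dng_pos[b]] = True
        if b in gene_pos and a in dng_pos:
            adj[gene_pos[b], dng_pos[a]] = True

    def stats_for(idx: np.ndarray) -> tuple[int, int]:
        sub = adj[idx]
        return int(sub.any(axis=0).sum()), int(sub.sum())

    obs_idx = np.array([gene_pos[g] for g in rigs], dtype=int)
    obs_genes, obs_conn = stats_for(obs_idx)

    rng = np.random.default_rng(seed)
    pool_arrays = {
        b: np.array([gene_pos[g] for g in genes], dtype=int)
        for b, genes in pools.items()
        if required.get(b, 0)
    }
    null_genes = np.empty(n_perm, dtype=int)
    null_conn = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        draw = [
            rng.choice(pool_arrays[b], size=need, replace=False)
            for b, need in required.items()
            if need
        ]
        idx = np.concatenate(draw)
        g, c = stats_for(idx)
        null_genes[k] = g
        null_conn[k] = c

    p_genes = (1 + int((null_genes >= obs_genes).sum())) / (1 + n_perm)
    p_conn = (1 + int((null_conn >= obs_conn).sum())) / (1 + n_perm)
    return PermutationResult(
        observed_genes=obs_genes,
        observed_connections=obs_conn,
        null_genes=null_genes.tolist(),
        null_connections=null_conn.tolist(),
        p_genes=float(p_genes),
        p_connections=float(p_conn),
        n_perm=n_perm,
        seed=seed,
        merged_bins=merged_log,
    )


def assemble_network(
    rigs: list[str],
    dngs: list[str],
    coexp_edges: list[CoexpressionEdge],
    ppi_edges: list[PPIEdge],
) -> nx.Graph:
    """Union graph over RIG+DNG nodes: an edge when two genes are co-expressed
    or interact; isolated genes are not included."""
    members = set(rigs) | set(dngs)
    g = nx.Graph()
    for e in coexp_edges:
        if e.gene_a in members and e.gene_b in members:
            g.add_edge(e.gene_a, e.gene_b, source="coexpression", r=e.r)
    for e in ppi_edges:
        if e.gene_a in members and e.gene_b in members:
            if g.has_edge(e.gene_a, e.gene_b):
                g[e.gene_a][e.gene_b]["source"] = "both"
                g[e.gene_a][e.gene_b]["score"] = e.score
            else:
                g.add_edge(e.gene_a, e.gene_b, source="ppi", score=e.score)
    rig_set = set(rigs)
    dng_set = set(dngs)
    for node in g.nodes:
        in_r, in_d = node in rig_set, node in dng_set
        g.nodes[node]["set"] = "both" if (in_r and in_d) else ("RIG" if in_r else "DNG")
    return g


def write_network(g: nx.Graph, edge_tsv_path, graphml_path) -> None:
    with open(edge_tsv_path, "w") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('source', '')}\n")
    nx.write_graphml(g, graphml_path)
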