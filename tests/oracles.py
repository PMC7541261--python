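"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own calling logic: recessive events
are derived by exhaustive enumeration of parental-origin assignments, and
the Wilcoxon rank-sum p-value by exhaustive enumeration of group relabelings.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_biallelic(
    child_gts: list[str],
    father_gts: list[str],
    mother_gts: list[str],
    categories: list[str],
) -> set[tuple]:
    """Qualifying biallelic events for one child by exhaustive phase enumeration.

    Genotypes are 'ref'/'het'/'hom'.  Returns a set of
    ``(mode, group, variant_index_tuple)`` after keeping one strongest event
    (PTV > Dmis > Syn) as the pipeline does.
    """
    pair_group = {
        frozenset(["PTV"]): "biallelic_PTV",
        frozenset(["PTV", "Dmis"]): "biallelic_PTV",
        frozenset(["Dmis"]): "biallelic_Dmis",
        frozenset(["synonymous"]): "biallelic_Syn",
    }
    hom_group = {"PTV": "biallelic_PTV", "Dmis": "biallelic_Dmis",
                 "synonymous": "biallelic_Syn"}
    carries = {"ref": False, "het": True, "hom": True}

    events = set()
    n = len(child_gts)
    # homozygous events: one alt allele must come from each parent
    for i in range(n):
        if child_gts[i] != "hom":
            continue
        if carries[father_gts[i]] and carries[mother_gts[i]]:
            g = hom_group.get(categories[i])
            if g:
                events.add(("biallelic_hom", g, (i,)))

    # compound het: enumerate per-variant origin assignments; a pair counts
    # only if every consistent assignment places the two variants in trans
    het_idx = [i for i in range(n) if child_gts[i] == "het"]
    origins = {}
    for i in het_idx:
        opts = []
        if carries[father_gts[i]]:
            opts.append("F")
        if carries[mother_gts[i]]:
            opts.append("M")
        origins[i] = opts
    for i, j in itertools.combinations(het_idx, 2):
        if not origins[i] or not origins[j]:
            continue  # de novo member: not inherited
        combos = list(itertools.product(origins[i], origins[j]))
        if all(a != b for a, b in combos):
            g = pair_group.get(frozenset([categories[i], categories[j]]))
            if g:
                events.add(("biallelic_chet", g, (i, j)))

    if not events:
        return set()
    rank = {"biallelic_PTV": 0, "biallelic_Dmis": 1, "biallelic_Syn": 2}
    best = min(events, key=lambda e: (rank[e[1]], e[0], e[2]))
    return {best}


def brute_force_x_hemizygous(
    child_gts: list[str],
    father_gts: list[str],
    mother_gts: list[str],
    categories: list[str],
) -> set[tuple]:
    """Qualifying maternally inherited hemizygous events for one male child.

    Child/father genotypes are 'ref'/'hemi'; mother 'ref'/'het'/'hom'.
    """
    group = {"PTV": "x_PTV", "Dmis": "x_Dmis", "synonymous": "x_Syn"}
    events = set()
    for i, g in enumerate(child_gts):
        if g != "hemi":
            continue
        if father_gts[i] == "hemi":
            continue  # father-to-son X transmission is impossible: genotype error
        if mother_gts[i] == "ref":
            continue  # de novo
        gr = group.get(categories[i])
        if gr:
            events.add(("x_hemizygous", gr, (i,)))
    if not events:
        return set()
    rank = {"x_PTV": 0, "x_Dmis": 1, "x_Syn": 2}
    best = min(events, key=lambda e: (rank[e[1]], e[2]))
    return {best}


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p by exhaustive enumeration (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    nx = len(x)
    obs = ranks[:nx].sum()
    total = 0
    extreme = 0
    n = len(pooled)
    mean = nx * (n + 1) / 2
    for combo in itertools.combinations(range(n), nx):
        s = sum(ranks[list(combo)])
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            extreme += 1
    assert total == comb(n, nx)
    return extreme / total
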