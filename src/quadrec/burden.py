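"""Carrier-burden testing: probands vs unaffected siblings.

For each event group the unit of counting is the *sample*: a child counts
once per group no matter how many qualifying genes it carries.  Odds ratios
are the sample cross-product ratio on the 2x2 carrier table; p-values are
two-sided Fisher exact (minimum-likelihood-sum convention); the 95% CI is
the exact conditional (noncentral hypergeometric) interval, with the method
recorded in the output.  No multiple-testing correction is applied across
groups — raw p-values are reported.

The same 2x2 machinery serves generic gene-list membership contrasts
(functional clusters, expression modules, neuron classes) via
:func:`two_list_fisher`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio_ci

from .cohort import Quad, Sex
from .errors import InvariantError
from .inheritance import EventGroup, InheritedEvent


class Restriction(str, enum.Enum):
    ALL_GENES = "all_genes"
    BRAIN_CONSTRAINED = "brain_constrained"


# constrained = tolerant of at most 5 homozygous/hemizygous Dmis and at most
# 2 homozygous/hemizygous PTVs in the population reference; brain-expressed =
# mean fetal-brain expression >= 1 RPKM
BRAIN_RPKM_MIN = 1.0
MAX_HOM_DMIS = 5
MAX_HOM_PTV = 2


def is_brain_constrained(gene: str, gene_info: pd.DataFrame) -> bool:
    if gene not in gene_info.index:
        return False
    row = gene_info.loc[gene]
    return (
        row["brain_rpkm"] >= BRAIN_RPKM_MIN
        and row["gnomad_hom_dmis"] <= MAX_HOM_DMIS
        and row["gnomad_hom_ptv"] <= MAX_HOM_PTV
    )


@dataclass
class BurdenTable:
    group: EventGroup
    restriction: Restriction
    n_proband_carriers: int
    n_proband_total: int
    n_sibling_carriers: int
    n_sibling_total: int
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    shared_count: int = 0
    ci_method: str = "exact_conditional"
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_proband_carriers > self.n_proband_total:
            raise InvariantError("proband carriers exceed total")
        if self.n_sibling_carriers > self.n_sibling_total:
            raise InvariantError("sibling carriers exceed total")


def carrier_counts(
    events: list[InheritedEvent],
    quads: list[Quad],
    group: EventGroup,
    restriction: Restriction = Restriction.ALL_GENES,
    gene_info: pd.DataFrame | None = None,
) -> tuple[int, int, int, int]:
    """(proband carriers, proband total, sibling carriers, sibling total).

    ``events`` must already have shared events removed.  For X-linked groups
    the denominators are the male probands / male siblings only."""
    if restriction is Restriction.BRAIN_CONSTRAINED and gene_info is None:
        raise InvariantError("brain_constrained restriction requires gene_info")

    if group.is_x:
        probands = {q.proband.sample_id for q in quads if q.proband.sex is Sex.MALE}
        siblings = {q.sibling.sample_id for q in quads if q.sibling.sex is Sex.MALE}
    else:
        probands = {q.proband.sample_id for q in quads}
        siblings = {q.sibling.sample_id for q in quads}

    pro_carriers: set[str] = set()
    sib_carriers: set[str] = set()
    for e in events:
        if e.group is not group:
            continue
        if restriction is Restriction.BRAIN_CONSTRAINED and not is_brain_constrained(
            e.gene, gene_info
        ):
            continue
        if e.child_id in probands:
            pro_carriers.add(e.child_id)
        elif e.child_id in siblings:
            sib_carriers.add(e.child_id)
    return len(pro_carriers), len(probands), len(sib_carriers), len(siblings)


def _cross_product_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_burden(
    counts: tuple[int, int, int, int],
    *,
    group: EventGroup | None = None,
    restriction: Restriction = Restriction.ALL_GENES,
    shared_count: int = 0,
    compute_ci: bool = True,
) -> BurdenTable:
    """Fisher exact burden test from (carriers_pro, total_pro, carriers_sib, total_sib)."""
    a, n_pro, c, n_sib = counts
    if min(a, n_pro, c, n_sib) < 0 or a > n_pro or c > n_sib:
        raise InvariantError(f"bad carrier counts {counts}")
    b, d = n_pro - a, n_sib - c
    table = [[a, b], [c, d]]
    _, p = fisher_exact(table, alternative="two-sided")
    orr = _cross_product_or(a, b, c, d)
    note = ""
    if math.isnan(orr) or math.isinf(orr):
        note = "odds ratio undefined: zero margin"
        ci = (math.nan, math.nan)
    elif compute_ci:
        res = _odds_ratio_ci(table, kind="conditional")
        interval = res.confidence_interval(confidence_level=0.95)
        ci = (float(interval.low), float(interval.high))
    else:
        ci = (math.nan, math.nan)
    return BurdenTable(
        group=group if group is not None else EventGroup.BIALLELIC_PTV,
        restriction=restriction,
        n_proband_carriers=a, n_proband_total=n_pro,
        n_sibling_carriers=c, n_sibling_total=n_sib,
        odds_ratio=orr, ci95=ci, p_value=float(p),
        shared_count=shared_count, note=note,
    )


def two_list_fisher(
    set_a_hits: int, set_a_total: int, set_b_hits: int, set_b_total: int
) -> tuple[float, float]:
    """Membership contrast between two gene lists.

    Returns the cross-product odds ratio for list A vs list B on
    ``[[a, A-a], [b, B-b]]`` and the two-sided Fisher exact p-value."""
    if set_a_hits > set_a_total or set_b_hits > set_b_total:
        raise InvariantError("hits exceed totals")
    a, b = set_a_hits, set_a_total - set_a_hits
    c, d = set_b_hits, set_b_total - set_b_hits
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return _cross_product_or(a, b, c, d), float(p)


def burden_report(
    events: list[InheritedEvent],
    quads: list[Quad],
    gene_info: pd.DataFrame,
    shared_counts: dict[EventGroup, int] | None = None,
) -> list[BurdenTable]:
    """All six groups x both restrictions, mirroring the carrier-burden table layout."""
    shared_counts = shared_counts or {}
    out = []
    for restriction in (Restriction.ALL_GENES, Restriction.BRAIN_CONSTRAINED):
        for group in EventGroup:
            counts = carrier_counts(events, quads, group, restriction, gene_info)
            out.append(
                fisher_burden(
                    counts, group=group, restriction=restriction,
                    shared_count=shared_counts.get(group, 0),
                )
            )
    return out


def burden_frame(tables: list[BurdenTable]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [t.group.value for t in tables],
            "restriction": [t.restriction.value for t in tables],
            "shared": [t.shared_count for t in tables],
            "proband_carriers": [t.n_proband_carriers for t in tables],
            "proband_total": [t.n_proband_total for t in tables],
            "sibling_carriers": [t.n_sibling_carriers for t in tables],
            "sibling_total": [t.n_sibling_total for t in tables],
            "odds_ratio": [t.odds_ratio for t in tables],
            "ci95_low": [t.ci95[0] for t in tables],
            "ci95_high": [t.ci95[1] for t in tables],
            "p_value": [t.p_value for t in tables],
            "ci_method": [t.ci_method for t in tables],
        }
    )
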