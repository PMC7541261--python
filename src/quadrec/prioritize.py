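"""Candidate recessive-gene prioritization.

Starting from proband events (PTV groups, optionally also Dmis groups), four
filters are applied in a documented order; each is a pure predicate, so the
surviving set is order-independent, and the trace records the first filter a
gene failed:

1. drop events containing any ClinVar-benign variant (a biallelic event with
   one benign allele is no longer a qualifying biallelic hit);
2. drop X-linked events whose variant is seen in more than 10 hemizygous
   males in the population reference;
3. drop genes harbouring a qualifying event in *any* unaffected sibling in
   the cohort (autosomal biallelic events in siblings / X-linked events in
   male siblings, within the selected groups);
4. drop X-linked genes with pLI < 0.5 (loss-of-function-tolerant X genes);
   an X gene absent from the metadata table cannot be evaluated and is
   excluded with a trace note.
"""

from __future__ import annotations

import enum
from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

from .cohort import AnnotatedVariant, is_x
from .inheritance import EventGroup, InheritedEvent

MAX_GNOMAD_MALE_CARRIERS = 10
MIN_X_PLI = 0.5


class EventGroups(str, enum.Enum):
    """Which proband event groups feed prioritization."""

    PTV_ONLY = "ptv_only"
    PTV_AND_DMIS = "ptv_and_dmis"

    def groups(self) -> frozenset[EventGroup]:
        base = {EventGroup.BIALLELIC_PTV, EventGroup.X_PTV}
        if self is EventGroups.PTV_AND_DMIS:
            base |= {EventGroup.BIALLELIC_DMIS, EventGroup.X_DMIS}
        return frozenset(base)


@dataclass
class CandidateGene:
    gene: str
    chrom_class: str  # "autosomal" | "x_linked"
    supporting_events: list[InheritedEvent]
    n_probands: int
    filter_trace: list[tuple[str, str]] = field(default_factory=list)


FILTER_NAMES = ("clinvar_benign", "gnomad_male_carriers", "sibling_overlap", "x_pli")


def prioritize(
    events: list[InheritedEvent],
    gene_info: pd.DataFrame,
    sibling_events: list[InheritedEvent],
    variants: Mapping[str, AnnotatedVariant],
    event_groups: EventGroups = EventGroups.PTV_AND_DMIS,
) -> tuple[list[CandidateGene], list[CandidateGene]]:
    """Apply the filter cascade to proband events.

    Parameters
    ----------
    events:
        Proband events after shared-event removal.
    sibling_events:
        Sibling events from the same pipeline (post shared-removal).
    variants:
        Lookup variant_id -> :class:`AnnotatedVariant` for the event members.

    Returns
    -------
    (candidates, excluded):
        Both carry per-filter traces; candidates passed every applicable
        filter.
    """
    selected = event_groups.groups()
    pro_by_gene: dict[str, list[InheritedEvent]] = {}
    for e in events:
        if e.group in selected:
            pro_by_gene.setdefault(e.gene, []).append(e)

    sib_genes_autosomal = {
        e.gene for e in sibling_events if e.group in selected and not e.group.is_x
    }
    sib_genes_x = {
        e.gene for e in sibling_events if e.group in selected and e.group.is_x
    }

    candidates: list[CandidateGene] = []
    excluded: list[CandidateGene] = []
    for gene in sorted(pro_by_gene):
        evs = pro_by_gene[gene]
        x_linked = evs[0].group.is_x
        trace: list[tuple[str, str]] = []
        failed = False

        surviving = [
            e for e in evs
            if not any(variants[vid].clinvar_benign for vid in e.variant_ids)
        ]
        trace.append(("clinvar_benign", "pass" if surviving else "fail"))
        failed = not surviving

        if not failed and x_linked:
            surviving = [
                e for e in surviving
                if all(
                    variants[vid].gnomad_male_carriers <= MAX_GNOMAD_MALE_CARRIERS
                    for vid in e.variant_ids
                )
            ]
        if not failed:
            trace.append(("gnomad_male_carriers", "pass" if surviving else "fail"))
            failed = not surviving

        if not failed:
            in_sib = gene in (sib_genes_x if x_linked else sib_genes_autosomal)
            trace.append(("sibling_overlap", "fail" if in_sib else "pass"))
            failed = in_sib

        if not failed and x_linked:
            if gene not in gene_info.index:
                trace.append(("x_pli", "fail:gene_missing_from_metadata"))
                failed = True
            elif gene_info.loc[gene, "pli"] < MIN_X_PLI:
                trace.append(("x_pli", "fail"))
                failed = True
            else:
                trace.append(("x_pli", "pass"))
        elif not failed:
            trace.append(("x_pli", "pass"))  # not applicable to autosomal genes

        record = CandidateGene(
            gene=gene,
            chrom_class="x_linked" if x_linked else "autosomal",
            supporting_events=surviving if not failed else evs,
            n_probands=len({e.child_id for e in (surviving if not failed else evs)}),
            filter_trace=trace,
        )
        (excluded if failed else candidates).append(record)
    return candidates, excluded


def carrier_fraction(candidates: list[CandidateGene], n_probands_total: int) -> float:
    """Fraction of probands carrying at least one qualifying event in any
    candidate gene."""
    carriers = {
        e.child_id for c in candidates for e in c.supporting_events
    }
    if n_probands_total <= 0:
        raise ValueError("n_probands_total must be positive")
    return len(carriers) / n_probands_total


def candidates_frame(
    candidates: list[CandidateGene],
    variants: Mapping[str, AnnotatedVariant],
    gene_info: pd.DataFrame,
) -> pd.DataFrame:
    """Candidate table patterned on the published per-variant layout
    (gene, proband, event type, location, effect, frequency, pLI)."""
    rows = []
    for c in candidates:
        for e in c.supporting_events:
            for vid in e.variant_ids:
                v = variants[vid]
                rows.append(
                    dict(
                        gene=c.gene,
                        chrom_class=c.chrom_class,
                        proband=e.child_id,
                        type={"biallelic_hom": "Homo", "biallelic_chet": "Chet",
                              "x_hemizygous": "Hem"}[e.mode.value],
                        location=f"chr{v.chrom}:{v.pos}" if not v.chrom.startswith("chr")
                        else f"{v.chrom}:{v.pos}",
                        ref=v.ref, alt=v.alt,
                        effect=v.effect.value,
                        gnomad_af=v.gnomad_af,
                        pli=float(gene_info.loc[c.gene, "pli"])
                        if c.gene in gene_info.index else float("nan"),
                    )
                )
    return pd.DataFrame(rows)
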