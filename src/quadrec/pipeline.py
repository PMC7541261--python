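"""End-to-end orchestration of the recessive-variant analysis stages.

These functions wire the per-module operations together: quality and rarity
filtering, per-gene event calling in every quad, shared-event removal,
carrier-burden testing and candidate-gene prioritization.  They operate on
in-memory objects; the CLI adds file I/O around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .burden import BurdenTable, burden_report
from .cohort import AnnotatedVariant, Genotype, Quad, is_x, quality_filter
from .inheritance import (
    CallDiagnostics,
    EventGroup,
    InheritedEvent,
    call_biallelic,
    call_x_hemizygous,
    maf_filter,
    remove_shared,
)
from .prioritize import CandidateGene, EventGroups, prioritize


@dataclass
class CallingResult:
    events: list[InheritedEvent]          # post shared-removal
    events_pre_shared: list[InheritedEvent]
    diagnostics: CallDiagnostics
    n_variants_pass: int


def call_inherited_events(
    quads: list[Quad],
    variants: list[AnnotatedVariant],
    *,
    autosomal_maf: float = 0.01,
    x_maf: float = 0.001,
) -> CallingResult:
    """Filter variants (quality, rarity), call biallelic and hemizygous
    events per quad and gene, and remove proband-sibling shared events."""
    diags = CallDiagnostics()
    passing = [
        v for v in variants
        if quality_filter(v)
        and maf_filter(v, autosomal_threshold=autosomal_maf, x_threshold=x_maf)
    ]

    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in passing:
        by_gene.setdefault(v.gene, []).append(v)

    quad_of: dict[str, Quad] = {}
    child_ids: set[str] = set()
    for q in quads:
        for s in q.members:
            quad_of[s.sample_id] = q
        child_ids.add(q.proband.sample_id)
        child_ids.add(q.sibling.sample_id)

    events: list[InheritedEvent] = []
    for gene, gvs in by_gene.items():
        # only families where a child carries an alternate allele can yield events
        fams: dict[str, Quad] = {}
        for v in gvs:
            carriers = (
                v.genotypes.carriers if hasattr(v.genotypes, "carriers")
                else {s: g for s, g in v.genotypes.items() if g is not Genotype.HOM_REF}
            )
            for sid, g in carriers.items():
                if g.carries_alt() and sid in child_ids:
                    q = quad_of[sid]
                    fams[q.family_id] = q
        on_x = is_x(gvs[0].chrom)
        for q in fams.values():
            if on_x:
                events.extend(call_x_hemizygous(q, gvs, diags))
            else:
                events.extend(call_biallelic(q, gvs, diags))

    retained = remove_shared(events, quads, diags)
    return CallingResult(
        events=retained, events_pre_shared=events, diagnostics=diags,
        n_variants_pass=len(passing),
    )


def run_burden(
    quads: list[Quad],
    variants: list[AnnotatedVariant],
    gene_info: pd.DataFrame,
    *,
    autosomal_maf: float = 0.01,
    x_maf: float = 0.001,
) -> tuple[list[BurdenTable], CallingResult]:
    """Carrier-burden tables for all six groups x both gene restrictions."""
    calling = call_inherited_events(
        quads, variants, autosomal_maf=autosomal_maf, x_maf=x_maf
    )
    shared = {
        EventGroup(g): n for g, n in calling.diagnostics.shared_removed.items()
    }
    tables = burden_report(calling.events, quads, gene_info, shared)
    return tables, calling


def run_prioritization(
    quads: list[Quad],
    variants: list[AnnotatedVariant],
    gene_info: pd.DataFrame,
    *,
    event_groups: EventGroups = EventGroups.PTV_AND_DMIS,
    autosomal_maf: float = 0.01,
    x_maf: float = 0.001,
) -> tuple[list[CandidateGene], list[CandidateGene], CallingResult]:
    """Candidate-gene prioritization from proband events."""
    calling = call_inherited_events(
        quads, variants, autosomal_maf=autosomal_maf, x_maf=x_maf
    )
    proband_ids = {q.proband.sample_id for q in quads}
    pro = [e for e in calling.events if e.child_id in proband_ids]
    sib = [e for e in calling.events if e.child_id not in proband_ids]
    vmap = {v.variant_id: v for v in variants}
    candidates, excluded = prioritize(
        pro, gene_info, sib, vmap, event_groups=event_groups
    )
    return candidates, excluded, calling
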