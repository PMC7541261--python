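"""Calling of rare recessive inherited events in quad families.

Two event shapes are recognised, per child and per gene:

* **biallelic** (autosomes): a homozygous variant with both parents carrying
  the allele, or a compound-heterozygous pair phased *in trans* through the
  pedigree — one variant carried by the father only and one by the mother
  only, both transmitted.  Pairs whose phase cannot be resolved (some parent
  carries both variants, so a *cis* configuration is possible) are excluded
  and tallied.
* **X-linked hemizygous** (males): a maternally transmitted variant on the
  male child's single X.  A carrier father at the site is a genotype error
  (father-to-son X transmission is impossible) and the call is rejected.

Events are grouped by functional content: a pair of PTVs — or one PTV with
one Dmis in trans — is a biallelic-PTV event; Dmis+Dmis a biallelic-Dmis
event; synonymous pairs the negative-control group.  Mixed pairs outside
these rules (e.g. PTV+synonymous) do not qualify.

Proband-sibling shared events (same gene, identical variant-id set, within a
family) are removed from burden analysis; X-linked sharing applies only
between two male children.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .classify import FunctionalCategory, classify
from .cohort import AnnotatedVariant, Genotype, Quad, Role, Sample, is_x
from .errors import InvariantError


class EventMode(str, enum.Enum):
    BIALLELIC_HOM = "biallelic_hom"
    BIALLELIC_CHET = "biallelic_chet"
    X_HEMIZYGOUS = "x_hemizygous"


class EventGroup(str, enum.Enum):
    BIALLELIC_PTV = "biallelic_PTV"
    BIALLELIC_DMIS = "biallelic_Dmis"
    BIALLELIC_SYN = "biallelic_Syn"
    X_PTV = "x_PTV"
    X_DMIS = "x_Dmis"
    X_SYN = "x_Syn"

    @property
    def is_x(self) -> bool:
        return self in (EventGroup.X_PTV, EventGroup.X_DMIS, EventGroup.X_SYN)


class Origin(str, enum.Enum):
    FATHER = "father"
    MOTHER = "mother"
    EITHER = "either"


# strongest group wins when one gene supports several candidate events
_GROUP_RANK = {
    EventGroup.BIALLELIC_PTV: 0,
    EventGroup.X_PTV: 0,
    EventGroup.BIALLELIC_DMIS: 1,
    EventGroup.X_DMIS: 1,
    EventGroup.BIALLELIC_SYN: 2,
    EventGroup.X_SYN: 2,
}

_HOM_GROUP = {
    FunctionalCategory.PTV: (EventGroup.BIALLELIC_PTV, EventGroup.X_PTV),
    FunctionalCategory.DMIS: (EventGroup.BIALLELIC_DMIS, EventGroup.X_DMIS),
    FunctionalCategory.SYNONYMOUS: (EventGroup.BIALLELIC_SYN, EventGroup.X_SYN),
}

_PAIR_GROUP = {
    frozenset([FunctionalCategory.PTV]): EventGroup.BIALLELIC_PTV,
    frozenset([FunctionalCategory.PTV, FunctionalCategory.DMIS]): EventGroup.BIALLELIC_PTV,
    frozenset([FunctionalCategory.DMIS]): EventGroup.BIALLELIC_DMIS,
    frozenset([FunctionalCategory.SYNONYMOUS]): EventGroup.BIALLELIC_SYN,
}


@dataclass(frozen=True)
class InheritedEvent:
    family_id: str
    child_id: str
    gene: str
    mode: EventMode
    group: EventGroup
    variant_ids: tuple[str, ...]
    parental_origin: tuple[tuple[str, Origin], ...]  # (variant_id, origin)

    def __post_init__(self) -> None:
        if self.mode is EventMode.BIALLELIC_CHET:
            if len(set(self.variant_ids)) != 2:
                raise InvariantError("compound het needs exactly 2 distinct variants")
            origins = {o for _, o in self.parental_origin}
            if origins != {Origin.FATHER, Origin.MOTHER}:
                raise InvariantError("compound het origins must be one paternal, one maternal")
        elif len(self.variant_ids) != 1:
            raise InvariantError(f"{self.mode.value} event needs exactly 1 variant")
        if self.mode is EventMode.X_HEMIZYGOUS:
            if dict(self.parental_origin)[self.variant_ids[0]] is not Origin.MOTHER:
                raise InvariantError("hemizygous inherited variant must be maternal")

    @property
    def variant_id_set(self) -> frozenset[str]:
        return frozenset(self.variant_ids)


@dataclass
class CallDiagnostics:
    """Tallies making the event partition auditable:
    retained + shared + phase-ambiguous + Mendelian-rejected = all candidates."""

    mendelian_rejected: int = 0
    phase_ambiguous: int = 0
    x_de_novo: int = 0
    x_father_carrier: int = 0
    parent_missing: int = 0
    shared_removed: dict = field(default_factory=dict)  # EventGroup -> n family-pairs

    def add_shared(self, group: EventGroup) -> None:
        self.shared_removed[group] = self.shared_removed.get(group, 0) + 1


def maf_filter(
    v: AnnotatedVariant,
    *,
    autosomal_threshold: float = 0.01,
    x_threshold: float = 0.001,
) -> bool:
    """Rare-variant filter: both the cohort-side and the population reference
    frequency must be at or below 1% (autosomes) / 0.1% (X)."""
    threshold = x_threshold if v.is_x else autosomal_threshold
    return max(v.cohort_af, v.gnomad_af) <= threshold


def _carrier_parents(v: AnnotatedVariant, quad: Quad) -> frozenset[Role] | None:
    """Which parents carry the alternate allele; None if a parent is missing."""
    out = set()
    for parent in (quad.father, quad.mother):
        g = v.genotypes[parent.sample_id]
        if g is Genotype.MISSING:
            return None
        if g.carries_alt():
            out.add(parent.role)
    return frozenset(out)


def _best_events(
    candidates: list[InheritedEvent],
) -> list[InheritedEvent]:
    """One event per (child, gene): the strongest group, deterministic tie-break."""
    by_key: dict[tuple[str, str], list[InheritedEvent]] = {}
    for e in candidates:
        by_key.setdefault((e.child_id, e.gene), []).append(e)
    out = []
    for evs in by_key.values():
        evs.sort(key=lambda e: (_GROUP_RANK[e.group], e.mode.value, e.variant_ids))
        out.append(evs[0])
    return sorted(out, key=lambda e: (e.child_id, e.gene, e.variant_ids))


def call_biallelic(
    quad: Quad,
    gene_variants: list[AnnotatedVariant],
    diagnostics: CallDiagnostics | None = None,
) -> list[InheritedEvent]:
    """Biallelic inherited events (homozygous or in-trans compound het) for
    both children of one quad in one gene.

    ``gene_variants`` must be autosomal, same-gene, and already quality- and
    MAF-filtered.  The output is independent of input variant order.
    """
    diags = diagnostics if diagnostics is not None else CallDiagnostics()
    if not gene_variants:
        return []
    gene = gene_variants[0].gene
    if any(v.gene != gene for v in gene_variants):
        raise InvariantError("call_biallelic: variants from multiple genes")
    if any(is_x(v.chrom) for v in gene_variants):
        raise InvariantError("call_biallelic: X variants passed to autosomal caller")
    variants = sorted(gene_variants, key=lambda v: (v.pos, v.variant_id))

    candidates: list[InheritedEvent] = []
    for child in quad.children:
        cid = child.sample_id
        homs: list[tuple[AnnotatedVariant, FunctionalCategory]] = []
        hets: list[tuple[AnnotatedVariant, FunctionalCategory, frozenset[Role]]] = []
        for v in variants:
            g = v.genotypes[cid]
            if g not in (Genotype.HET, Genotype.HOM_ALT):
                continue
            cat = classify(v)
            parents = _carrier_parents(v, quad)
            if parents is None:
                diags.parent_missing += 1
                continue
            if g is Genotype.HOM_ALT:
                if parents != {Role.FATHER, Role.MOTHER}:
                    # child has two alt alleles but some parent has none
                    diags.mendelian_rejected += 1
                    continue
                homs.append((v, cat))
            else:
                if not parents:
                    diags.mendelian_rejected += 1  # allele absent from both parents
                    continue
                hets.append((v, cat, parents))

        for v, cat in homs:
            groups = _HOM_GROUP.get(cat)
            if groups is None:
                continue
            candidates.append(
                InheritedEvent(
                    family_id=quad.family_id, child_id=cid, gene=gene,
                    mode=EventMode.BIALLELIC_HOM, group=groups[0],
                    variant_ids=(v.variant_id,),
                    parental_origin=((v.variant_id, Origin.EITHER),),
                )
            )

        for i in range(len(hets)):
            for j in range(i + 1, len(hets)):
                (va, ca, pa), (vb, cb, pb) = hets[i], hets[j]
                group = _PAIR_GROUP.get(frozenset([ca, cb]))
                if group is None:
                    continue
                if (pa & pb):
                    # some parent carries both variants: cis possible, phase unresolved
                    diags.phase_ambiguous += 1
                    continue
                if pa == {Role.FATHER} and pb == {Role.MOTHER}:
                    pat, mat = va, vb
                elif pa == {Role.MOTHER} and pb == {Role.FATHER}:
                    pat, mat = vb, va
                else:
                    continue
                ids = tuple(sorted([va.variant_id, vb.variant_id]))
                candidates.append(
                    InheritedEvent(
                        family_id=quad.family_id, child_id=cid, gene=gene,
                        mode=EventMode.BIALLELIC_CHET, group=group,
                        variant_ids=ids,
                        parental_origin=(
                            (pat.variant_id, Origin.FATHER),
                            (mat.variant_id, Origin.MOTHER),
                        ),
                    )
                )
    return _best_events(candidates)


def call_x_hemizygous(
    quad: Quad,
    gene_variants: list[AnnotatedVariant],
    diagnostics: CallDiagnostics | None = None,
) -> list[InheritedEvent]:
    """Maternally inherited hemizygous events in male children for one X gene.

    Female children produce no events.  A hemizygous child variant carried by
    the father is rejected as a genotype error; one carried by neither parent
    is rejected as non-inherited (de novo)."""
    diags = diagnostics if diagnostics is not None else CallDiagnostics()
    if not gene_variants:
        return []
    gene = gene_variants[0].gene
    if any(v.gene != gene for v in gene_variants):
        raise InvariantError("call_x_hemizygous: variants from multiple genes")
    if any(not is_x(v.chrom) for v in gene_variants):
        raise InvariantError("call_x_hemizygous: autosomal variants passed to X caller")
    variants = sorted(gene_variants, key=lambda v: (v.pos, v.variant_id))

    candidates: list[InheritedEvent] = []
    for child in quad.children:
        if child.sex.value != "male":
            continue
        cid = child.sample_id
        for v in variants:
            if v.genotypes[cid] is not Genotype.HEMI_ALT:
                continue
            cat = classify(v)
            groups = _HOM_GROUP.get(cat)
            father_g = v.genotypes[quad.father.sample_id]
            mother_g = v.genotypes[quad.mother.sample_id]
            if father_g is Genotype.MISSING or mother_g is Genotype.MISSING:
                diags.parent_missing += 1
                continue
            if father_g.carries_alt():
                diags.x_father_carrier += 1
                continue
            if not mother_g.carries_alt():
                diags.x_de_novo += 1
                continue
            if groups is None:
                continue
            candidates.append(
                InheritedEvent(
                    family_id=quad.family_id, child_id=cid, gene=gene,
                    mode=EventMode.X_HEMIZYGOUS, group=groups[1],
                    variant_ids=(v.variant_id,),
                    parental_origin=((v.variant_id, Origin.MOTHER),),
                )
            )
    return _best_events(candidates)


def remove_shared(
    events: list[InheritedEvent],
    quads: list[Quad],
    diagnostics: CallDiagnostics | None = None,
) -> list[InheritedEvent]:
    """Drop proband-sibling shared events within each family.

    Two events are *shared* iff they belong to the same family and gene and
    have identical variant-id sets.  Both members of a shared pair are
    removed and tallied once.  For X-linked events the rule applies only when
    both children are male (a hemizygous event only exists in males anyway;
    the check is kept explicit)."""
    diags = diagnostics if diagnostics is not None else CallDiagnostics()
    by_family = {q.family_id: q for q in quads}
    keyed: dict[tuple, list[InheritedEvent]] = {}
    for e in events:
        keyed.setdefault((e.family_id, e.gene, e.variant_id_set), []).append(e)

    retained: list[InheritedEvent] = []
    for (fam, _gene, _ids), evs in keyed.items():
        quad = by_family.get(fam)
        if quad is None:
            raise InvariantError(f"event family {fam} not in pedigree")
        roles = {e.child_id for e in evs}
        is_pair = (
            quad.proband.sample_id in roles and quad.sibling.sample_id in roles
        )
        if is_pair and evs[0].group.is_x:
            both_male = (
                quad.proband.sex.value == "male" and quad.sibling.sex.value == "male"
            )
            if not both_male:
                is_pair = False
        if is_pair:
            diags.add_shared(evs[0].group)
        else:
            retained.extend(evs)
    return sorted(retained, key=lambda e: (e.family_id, e.child_id, e.gene, e.variant_ids))


def write_events(events: list[InheritedEvent], quads: list[Quad], path) -> None:
    """Events TSV: family, child, role, gene, mode, group, variant ids, origins."""
    role_of = {}
    for q in quads:
        role_of[q.proband.sample_id] = Role.PROBAND.value
        role_of[q.sibling.sample_id] = Role.SIBLING.value
    with open(path, "w") as fh:
        fh.write("family_id\tchild_id\trole\tgene\tmode\tgroup\tvariant_ids\torigins\n")
        for e in events:
            origins = ";".join(f"{vid}={o.value}" for vid, o in e.parental_origin)
            fh.write(
                "\t".join([
                    e.family_id, e.child_id, role_of.get(e.child_id, "?"), e.gene,
                    e.mode.value, e.group.value, ";".join(e.variant_ids), origins,
                ]) + "\n"
            )
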