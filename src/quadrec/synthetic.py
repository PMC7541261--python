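"""Synthetic quad cohorts, expression matrices and PPI graphs.

The cohort generator emulates the data-generating structure of a
simplex-family exome study: ~1800 quads (proband 87% male, sibling ~47%
male), rare coding variants transmitted Mendelianly, and recessive carrier
rates planted per event group at the rates observed in unaffected siblings,
with a proband excess in constrained brain-expressed genes expressed as a
target carrier odds ratio.

Design choices that make the generator a usable oracle:

* All *qualifying* recessive events come from explicit planting.  Background
  rare variants in qualifying categories are constructed with at most one
  carrier parent per family and gene (X-linked ones are carried by fathers,
  whose X never reaches a son), so they can never assemble into a biallelic
  or maternally inherited hemizygous event.  Planted rates therefore realize
  the target odds ratios exactly in expectation, and the truth manifest
  lists every event the pipeline should call.
* For proband-specific (or sibling-specific) planted events the other
  child's genotype is drawn conditional on *not* reproducing the event;
  proband-sibling shared events are planted separately at their own rates.
* Everything is drawn from one ``numpy`` generator seeded from the spec, so
  identical specs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    AnnotatedVariant,
    Effect,
    Genotype,
    Quad,
    Role,
    Sample,
    Sex,
    SparseGenotypes,
    is_x,
)
from .errors import InputError
from .inheritance import EventGroup, EventMode, InheritedEvent, Origin

_BASES = "ACGT"

# per-child planted carrier rates observed in unaffected siblings
# (group -> (rate in any gene, portion in constrained brain-expressed genes));
# X-linked rates are per *male* child
_DEFAULT_BASE_RATES = {
    "biallelic_PTV": (19 / 1799, 2 / 1799),
    "biallelic_Dmis": (30 / 1799, 15 / 1799),
    "biallelic_Syn": (61 / 1799, 35 / 1799),
    "x_PTV": (15 / 847, 4 / 847),
    "x_Dmis": (55 / 847, 29 / 847),
    "x_Syn": (202 / 847, 133 / 847),
}

# per-family probability of a proband+sibling shared event (X groups: per
# family with two male children)
_DEFAULT_SHARED_RATES = {
    "biallelic_PTV": 8 / 1799,
    "biallelic_Dmis": 7 / 1799,
    "biallelic_Syn": 27 / 1799,
    "x_PTV": 2 / 740,
    "x_Dmis": 4 / 740,
    "x_Syn": 93 / 740,
}


@dataclass
class CohortSpec:
    """Study conditions for a synthetic quad cohort."""

    n_quads: int = 1799
    male_fraction_probands: float = 1571 / 1799
    male_fraction_siblings: float = 847 / 1799
    n_genes: int = 400
    x_gene_fraction: float = 0.12
    background_variants_per_gene: float = 2.0
    background_common_fraction: float = 0.2
    category_mix: dict = field(
        default_factory=lambda: {
            "PTV": 0.10, "Dmis": 0.15, "Tmis": 0.30,
            "synonymous": 0.35, "nonframeshift": 0.10,
        }
    )
    base_rates: dict = field(default_factory=lambda: dict(_DEFAULT_BASE_RATES))
    shared_rates: dict = field(default_factory=lambda: dict(_DEFAULT_SHARED_RATES))
    planted_or_biallelic_ptv: float = 5.02
    planted_or_x_ptv: float = 3.13
    chet_fraction: float = 0.6
    ptv_dmis_chet_fraction: float = 0.3
    constrained_gene_fraction: float = 0.3
    brain_expressed_fraction: float = 0.7
    qual_fail_rate: float = 0.02
    missing_rate: float = 0.002
    benign_event_rate: float = 0.05
    high_male_carrier_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("male_fraction_probands", "male_fraction_siblings",
                     "constrained_gene_fraction", "brain_expressed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v} outside [0,1]")
        for name in ("planted_or_biallelic_ptv", "planted_or_x_ptv"):
            if getattr(self, name) < 1.0:
                raise InputError(f"{name} must be >= 1 (use 1.0 for null cohorts)")


@dataclass
class SimulatedCohort:
    quads: list[Quad]
    variants: list[AnnotatedVariant]
    gene_info: pd.DataFrame
    manifest: dict


def _odds(p: float) -> float:
    return p / (1.0 - p)


def _inv_odds(o: float) -> float:
    return o / (1.0 + o)


def proband_rate_for_or(base_rate: float, odds_ratio: float) -> float:
    """Proband carrier probability whose odds are ``odds_ratio`` times the
    sibling's.  Raises with the feasible range if the target is unreachable."""
    if not (0.0 < base_rate < 1.0):
        raise InputError(f"base rate {base_rate} must be in (0,1)")
    target = _inv_odds(odds_ratio * _odds(base_rate))
    if target > 0.5:
        # a planted *rare-event* carrier probability above 50% is outside the
        # regime the generator models
        feasible = _odds(0.5) / _odds(base_rate)
        raise InputError(
            f"planted OR {odds_ratio} infeasible at base rate {base_rate}; "
            f"feasible range is [1, {feasible:.1f}]"
        )
    return target


_GROUP_ENUM = {g.value: g for g in EventGroup}


class _VariantFactory:
    """Allocates unique variant sites and accumulates sparse genotypes."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.records: list[dict] = []
        self._pos_counter: dict[str, int] = {}

    def new_variant(
        self, gene: str, chrom: str, category: str, *, rare: bool = True,
        maf: float | None = None, max_maf: float = 5e-3,
    ) -> dict:
        idx = self._pos_counter.get(gene, 0)
        self._pos_counter[gene] = idx + 1
        gene_no = int(gene[1:])
        pos = gene_no * 100_000 + 1_000 + idx * 10
        rng = self.rng
        if category == "PTV":
            effect = Effect(
                str(rng.choice(["stop_gain", "frameshift_indel", "splice_site", "stop_loss"],
                               p=[0.4, 0.3, 0.25, 0.05]))
            )
        elif category in ("Dmis", "Tmis"):
            effect = Effect.MISSENSE
        elif category == "synonymous":
            effect = Effect.SYNONYMOUS
        else:
            effect = Effect.NONFRAMESHIFT_INDEL
        ref = _BASES[rng.integers(4)]
        if effect is Effect.FRAMESHIFT_INDEL:
            alt = ref + _BASES[rng.integers(4)]
        elif effect is Effect.NONFRAMESHIFT_INDEL:
            alt = ref + "".join(_BASES[rng.integers(4)] for _ in range(3))
        else:
            alt = _BASES[(( _BASES.index(ref)) + 1 + rng.integers(3)) % 4]
        if category == "Dmis":
            reve = float(rng.uniform(0.75, 1.0))
        elif category == "Tmis":
            reve = float(rng.uniform(0.0, 0.7))
        else:
            reve = None
        if maf is None:
            maf = float(min(max_maf, max(1e-5, rng.beta(0.3, 3000)))) if rare \
                else float(rng.uniform(0.015, 0.05))
        rec = dict(
            gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
            effect=effect, reve=reve, gnomad_af=maf,
            gnomad_male_carriers=0, clinvar_benign=False,
            depth_ok=True, gq_ok=True, callrate_ok=True,
            carriers={},  # sample_id -> Genotype
            category=category,
        )
        self.records.append(rec)
        return rec


def _plant_biallelic(
    fac: _VariantFactory, rng: np.random.Generator, quad: Quad, child: Sample,
    other: Sample, gene: str, chrom: str, group: str, spec: CohortSpec,
    shared: bool,
) -> tuple[tuple[dict, ...], dict[str, str]]:
    """Create variant records and genotypes for one planted autosomal event.
    Returns the member records (1 for hom, 2 for chet) and their origins."""
    category = {"biallelic_PTV": "PTV", "biallelic_Dmis": "Dmis",
                "biallelic_Syn": "synonymous"}[group]
    chet = rng.random() < spec.chet_fraction
    if not chet:
        v = fac.new_variant(gene, chrom, category)
        v["carriers"][quad.father.sample_id] = Genotype.HET
        v["carriers"][quad.mother.sample_id] = Genotype.HET
        v["carriers"][child.sample_id] = Genotype.HOM_ALT
        if shared:
            v["carriers"][other.sample_id] = Genotype.HOM_ALT
        else:
            # transmission conditional on the other child not being hom-alt
            if rng.random() < 2 / 3:
                v["carriers"][other.sample_id] = Genotype.HET
        return (v,), {_vid_of(v): "either"}
    cat_b = category
    if group == "biallelic_PTV" and rng.random() < spec.ptv_dmis_chet_fraction:
        cat_b = "Dmis"
    va = fac.new_variant(gene, chrom, category)
    vb = fac.new_variant(gene, chrom, cat_b)
    va["carriers"][quad.father.sample_id] = Genotype.HET
    vb["carriers"][quad.mother.sample_id] = Genotype.HET
    va["carriers"][child.sample_id] = Genotype.HET
    vb["carriers"][child.sample_id] = Genotype.HET
    if shared:
        va["carriers"][other.sample_id] = Genotype.HET
        vb["carriers"][other.sample_id] = Genotype.HET
    else:
        # other child inherits at most one member (uniform over the 3 allowed)
        u = rng.integers(3)
        if u == 0:
            va["carriers"][other.sample_id] = Genotype.HET
        elif u == 1:
            vb["carriers"][other.sample_id] = Genotype.HET
    return (va, vb), {_vid_of(va): "father", _vid_of(vb): "mother"}


def _vid_of(rec: dict) -> str:
    return f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}"


def _plant_x(
    fac: _VariantFactory, rng: np.random.Generator, quad: Quad, child: Sample,
    other: Sample, gene: str, group: str, spec: CohortSpec, shared: bool,
) -> tuple[tuple[dict, ...], dict[str, str]]:
    category = {"x_PTV": "PTV", "x_Dmis": "Dmis", "x_Syn": "synonymous"}[group]
    # planted hemizygous events must stay under the 0.1% X rarity filter
    v = fac.new_variant(gene, "X", category, max_maf=5e-4)
    if rng.random() < spec.high_male_carrier_rate:
        v["gnomad_male_carriers"] = int(rng.integers(11, 31))
    else:
        v["gnomad_male_carriers"] = int(rng.integers(0, 6))
    v["carriers"][quad.mother.sample_id] = Genotype.HET
    v["carriers"][child.sample_id] = Genotype.HEMI_ALT
    if shared:
        v["carriers"][other.sample_id] = Genotype.HEMI_ALT
    elif other.sex is Sex.FEMALE and rng.random() < 0.5:
        v["carriers"][other.sample_id] = Genotype.HET
    # male non-shared sibling: conditioned to not inherit (stays reference)
    return (v,), {_vid_of(v): "mother"}


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw a full cohort in memory (quads, variants, gene metadata, manifest)."""
    rng = np.random.default_rng(spec.seed)

    # --- families -----------------------------------------------------------
    quads: list[Quad] = []
    for i in range(spec.n_quads):
        fam = f"F{i:05d}"
        pro_sex = Sex.MALE if rng.random() < spec.male_fraction_probands else Sex.FEMALE
        sib_sex = Sex.MALE if rng.random() < spec.male_fraction_siblings else Sex.FEMALE
        quads.append(
            Quad(
                family_id=fam,
                proband=Sample(f"{fam}.p1", fam, Role.PROBAND, pro_sex),
                sibling=Sample(f"{fam}.s1", fam, Role.SIBLING, sib_sex),
                father=Sample(f"{fam}.fa", fam, Role.FATHER, Sex.MALE),
                mother=Sample(f"{fam}.mo", fam, Role.MOTHER, Sex.FEMALE),
            )
        )
    samples_tuple = tuple(
        s.sample_id for q in quads for s in (q.father, q.mother, q.proband, q.sibling)
    )

    # --- gene table ---------------------------------------------------------
    n_x = max(4, int(round(spec.n_genes * spec.x_gene_fraction)))
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    x_genes = set(rng.choice(spec.n_genes, size=n_x, replace=False).tolist())
    rows = []
    gene_chrom: dict[str, str] = {}
    autosome_cycle = 0
    # draw constrained/brain flags first, then guarantee that each
    # (chromosome class x constrained-brain status) pool is non-trivially
    # populated so event placement cannot exhaust a pool at unlucky seeds
    flag_constrained = rng.random(spec.n_genes) < spec.constrained_gene_fraction
    flag_expressed = rng.random(spec.n_genes) < spec.brain_expressed_fraction
    min_pool = 6
    for on_x in (True, False):
        idx = [i for i in range(spec.n_genes) if (i in x_genes) == on_x]
        for want_cb in (True, False):
            members = [i for i in idx
                       if (flag_constrained[i] and flag_expressed[i]) == want_cb]
            short = min(min_pool, len(idx) // 2) - len(members)
            if short > 0:
                others = [i for i in idx if i not in members]
                for j in rng.permutation(len(others))[:short]:
                    i = others[int(j)]
                    flag_constrained[i] = want_cb
                    flag_expressed[i] = True if want_cb else flag_expressed[i]
    for i, g in enumerate(genes):
        if i in x_genes:
            chrom = "X"
        else:
            autosome_cycle = autosome_cycle % 22 + 1
            chrom = str(autosome_cycle)
        gene_chrom[g] = chrom
        constrained = bool(flag_constrained[i])
        expressed = bool(flag_expressed[i])
        hom_dmis = int(rng.integers(0, 6)) if constrained else int(rng.integers(6, 40))
        hom_ptv = int(rng.integers(0, 3)) if constrained else int(rng.integers(0, 15))
        if not constrained and hom_dmis <= 5 and hom_ptv <= 2:
            hom_ptv = 3 + int(rng.integers(0, 10))
        rpkm = float(np.round(rng.lognormal(1.5, 0.8), 3)) + 1.0 if expressed \
            else float(np.round(rng.uniform(0.0, 0.99), 3))
        if chrom == "X":
            pli = float(rng.uniform(0.5, 1.0)) if rng.random() < 0.6 \
                else float(rng.uniform(0.0, 0.5))
        else:
            pli = float(rng.uniform(0.0, 1.0))
        rows.append(
            dict(gene=g, chrom=chrom, pli=round(pli, 4), brain_rpkm=rpkm,
                 gnomad_hom_dmis=hom_dmis, gnomad_hom_ptv=hom_ptv,
                 dnv_rate=float(np.round(rng.lognormal(-9.0, 1.0), 12)),
                 coding_length=int(rng.lognormal(7.5, 0.6)) + 200)
        )
    gene_info = pd.DataFrame(rows).set_index("gene")

    def _cb(g: str) -> bool:
        r = gene_info.loc[g]
        return bool(r["brain_rpkm"] >= 1.0 and r["gnomad_hom_dmis"] <= 5
                    and r["gnomad_hom_ptv"] <= 2)

    aut = [g for g in genes if gene_chrom[g] != "X"]
    xg = [g for g in genes if gene_chrom[g] == "X"]
    pools = {
        ("aut", True): [g for g in aut if _cb(g)],
        ("aut", False): [g for g in aut if not _cb(g)],
        ("x", True): [g for g in xg if _cb(g)],
        ("x", False): [g for g in xg if not _cb(g)],
    }
    for key, pool in pools.items():
        if not pool:
            raise InputError(f"gene pool {key} empty; increase n_genes or fractions")

    # --- planted event rates ------------------------------------------------
    planted_or = {
        "biallelic_PTV": spec.planted_or_biallelic_ptv,
        "x_PTV": spec.planted_or_x_ptv,
    }
    proband_rates: dict[str, tuple[float, float]] = {}
    for group, (q_all, q_cb) in spec.base_rates.items():
        q_nc = q_all - q_cb
        orr = planted_or.get(group, 1.0)
        c1 = proband_rate_for_or(q_cb, orr) if orr != 1.0 else q_cb
        proband_rates[group] = (q_nc, c1)

    fac = _VariantFactory(rng)
    events: list[dict] = []
    used_genes_by_family: dict[str, set] = {q.family_id: set() for q in quads}

    def _pick_gene(fam: str, chrom_class: str, cb: bool) -> str:
        pool = pools[(chrom_class, cb)]
        used = used_genes_by_family[fam]
        for idx in rng.permutation(len(pool)):
            g = pool[int(idx)]
            if g not in used:
                used.add(g)
                return g
        raise InputError(
            f"gene pool {chrom_class}/{'cb' if cb else 'other'} exhausted for "
            "family-unique event placement; increase n_genes"
        )

    def _record_event(quad, child, gene, group, members, origins, shared):
        mode = (EventMode.X_HEMIZYGOUS if group.startswith("x_")
                else (EventMode.BIALLELIC_CHET if len(members) == 2
                      else EventMode.BIALLELIC_HOM))
        events.append(
            dict(family_id=quad.family_id, child_id=child.sample_id,
                 role=child.role.value, gene=gene, mode=mode.value, group=group,
                 variant_ids=sorted(_vid_of(m) for m in members),
                 origins=origins, shared=shared, constrained_brain=_cb(gene))
        )

    for quad in quads:
        fam = quad.family_id
        for group in ("biallelic_PTV", "biallelic_Dmis", "biallelic_Syn"):
            q_all, q_cb = spec.base_rates[group]
            # shared event for the family
            if rng.random() < spec.shared_rates[group]:
                cb = rng.random() < (q_cb / q_all)
                gene = _pick_gene(fam, "aut", cb)
                members, origins = _plant_biallelic(
                    fac, rng, quad, quad.proband, quad.sibling, gene,
                    gene_chrom[gene], group, spec, True)
                _record_event(quad, quad.proband, gene, group, members, origins, True)
                _record_event(quad, quad.sibling, gene, group, members, origins, True)
            for child, other, rates in (
                (quad.proband, quad.sibling, proband_rates[group]),
                (quad.sibling, quad.proband, (q_all - q_cb, q_cb)),
            ):
                rate_nc, rate_cb = rates
                for cb, rate in ((False, rate_nc), (True, rate_cb)):
                    if rng.random() < rate:
                        gene = _pick_gene(fam, "aut", cb)
                        members, origins = _plant_biallelic(
                            fac, rng, quad, child, other, gene,
                            gene_chrom[gene], group, spec, False)
                        _record_event(quad, child, gene, group, members, origins, False)

        both_male = quad.proband.sex is Sex.MALE and quad.sibling.sex is Sex.MALE
        for group in ("x_PTV", "x_Dmis", "x_Syn"):
            q_all, q_cb = spec.base_rates[group]
            if both_male and rng.random() < spec.shared_rates[group]:
                cb = rng.random() < (q_cb / q_all)
                gene = _pick_gene(fam, "x", cb)
                members, origins = _plant_x(fac, rng, quad, quad.proband,
                                            quad.sibling, gene, group, spec, True)
                _record_event(quad, quad.proband, gene, group, members, origins, True)
                _record_event(quad, quad.sibling, gene, group, members, origins, True)
            for child, other, rates in (
                (quad.proband, quad.sibling, proband_rates[group]),
                (quad.sibling, quad.proband, (q_all - q_cb, q_cb)),
            ):
                if child.sex is not Sex.MALE:
                    continue
                rate_nc, rate_cb = rates
                for cb, rate in ((False, rate_nc), (True, rate_cb)):
                    if rng.random() < rate:
                        gene = _pick_gene(fam, "x", cb)
                        members, origins = _plant_x(fac, rng, quad, child, other,
                                                    gene, group, spec, False)
                        _record_event(quad, child, gene, group, members, origins, False)

    # event-variant attribute noise exercising the prioritization filters
    event_vids = {vid for e in events for vid in e["variant_ids"]}
    for rec in fac.records:
        if _vid_of(rec) in event_vids and rng.random() < spec.benign_event_rate:
            rec["clinvar_benign"] = True

    # --- background variants ------------------------------------------------
    qualifying = {"PTV", "Dmis", "synonymous"}
    cats = list(spec.category_mix)
    cat_p = np.array([spec.category_mix[c] for c in cats], dtype=float)
    cat_p = cat_p / cat_p.sum()
    fam_ids = [q.family_id for q in quads]
    quad_by_fam = {q.family_id: q for q in quads}
    planted_fams_by_gene: dict[str, set] = {}
    for e in events:
        planted_fams_by_gene.setdefault(e["gene"], set()).add(e["family_id"])

    n_bg = rng.poisson(spec.background_variants_per_gene, size=spec.n_genes)
    for gi, gene in enumerate(genes):
        chrom = gene_chrom[gene]
        on_x = chrom == "X"
        used_fams = set(planted_fams_by_gene.get(gene, set()))
        for _ in range(int(n_bg[gi])):
            common = rng.random() < spec.background_common_fraction
            category = str(rng.choice(cats, p=cat_p))
            rec = fac.new_variant(gene, chrom, category, rare=not common)
            maf = rec["gnomad_af"]
            if rng.random() < spec.qual_fail_rate:
                rec[str(rng.choice(["depth_ok", "gq_ok", "callrate_ok"]))] = False
            if category in ("PTV", "Dmis") and rng.random() < 0.1:
                rec["clinvar_benign"] = True
            if on_x:
                rec["gnomad_male_carriers"] = int(rng.poisson(maf * 50_000))

            if common:
                _draw_common(rec, quads, rng, on_x)
                continue
            # rare background: sparse carrier parents
            k = rng.poisson(4 * spec.n_quads * maf)
            if k == 0:
                continue
            if category in qualifying:
                avail = [f for f in fam_ids if f not in used_fams]
                if not avail:
                    continue
                chosen = rng.choice(len(avail), size=min(k, len(avail)), replace=False)
                for ci in np.atleast_1d(chosen):
                    famid = avail[int(ci)]
                    used_fams.add(famid)
                    quad = quad_by_fam[famid]
                    _seed_rare_parent(rec, quad, rng, on_x, father_only=on_x)
            else:
                chosen = rng.choice(spec.n_quads, size=min(k, spec.n_quads),
                                    replace=False)
                for ci in np.atleast_1d(chosen):
                    quad = quads[int(ci)]
                    _seed_rare_parent(rec, quad, rng, on_x, father_only=False)
            # sparse missingness on background variants
            if spec.missing_rate > 0:
                n_miss = rng.poisson(spec.missing_rate * 4 * spec.n_quads)
                for _ in range(int(n_miss)):
                    sid = samples_tuple[int(rng.integers(len(samples_tuple)))]
                    if sid not in rec["carriers"]:
                        rec["carriers"][sid] = Genotype.MISSING

    # --- assemble AnnotatedVariants ----------------------------------------
    chrom_order = {str(c): c for c in range(1, 23)}
    chrom_order["X"] = 23
    fac.records.sort(key=lambda r: (chrom_order[r["chrom"]], r["pos"]))
    variants: list[AnnotatedVariant] = []
    male = {s.sample_id: s.sex is Sex.MALE for q in quads for s in q.members}
    father_ids = {q.father.sample_id for q in quads}
    mother_ids = {q.mother.sample_id for q in quads}
    for rec in fac.records:
        on_x = rec["chrom"] == "X"
        alt_alleles = 0
        denom = (3 if on_x else 4) * spec.n_quads
        for sid, g in rec["carriers"].items():
            is_father = sid in father_ids
            if not (is_father or sid in mother_ids):
                continue
            if g is Genotype.MISSING:
                denom -= 1 if (on_x and is_father) else 2
            elif g is Genotype.HOM_ALT:
                alt_alleles += 2
            elif g.carries_alt():
                alt_alleles += 1
        af = alt_alleles / denom if denom else 0.0
        v = AnnotatedVariant(
            variant_id=f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}",
            chrom=rec["chrom"], pos=rec["pos"], ref=rec["ref"], alt=rec["alt"],
            gene=rec["gene"], effect=rec["effect"], reve_score=rec["reve"],
            gnomad_af=rec["gnomad_af"], cohort_af=af,
            gnomad_male_carriers=rec["gnomad_male_carriers"],
            clinvar_benign=rec["clinvar_benign"], depth_ok=rec["depth_ok"],
            gq_ok=rec["gq_ok"], callrate_ok=rec["callrate_ok"],
            genotypes=SparseGenotypes(samples_tuple, dict(rec["carriers"])),
        )
        variants.append(v)

    manifest = _build_manifest(spec, quads, events, gene_info, variants)
    return SimulatedCohort(quads=quads, variants=variants, gene_info=gene_info,
                           manifest=manifest)


def _draw_common(rec: dict, quads: list[Quad], rng: np.random.Generator,
                 on_x: bool) -> None:
    """HWE parental genotypes + Mendelian transmission for a common variant."""
    maf = rec["gnomad_af"]
    for q in quads:
        if on_x:
            fa_alt = rng.random() < maf
            mo = rng.binomial(2, maf)
            if fa_alt:
                rec["carriers"][q.father.sample_id] = Genotype.HEMI_ALT
            if mo == 1:
                rec["carriers"][q.mother.sample_id] = Genotype.HET
            elif mo == 2:
                rec["carriers"][q.mother.sample_id] = Genotype.HOM_ALT
            for child in q.children:
                mat = (mo == 2) or (mo == 1 and rng.random() < 0.5)
                if child.sex is Sex.MALE:
                    if mat:
                        rec["carriers"][child.sample_id] = Genotype.HEMI_ALT
                else:
                    n = int(mat) + int(fa_alt)
                    if n == 1:
                        rec["carriers"][child.sample_id] = Genotype.HET
                    elif n == 2:
                        rec["carriers"][child.sample_id] = Genotype.HOM_ALT
        else:
            fa = rng.binomial(2, maf)
            mo = rng.binomial(2, maf)
            if fa == 1:
                rec["carriers"][q.father.sample_id] = Genotype.HET
            elif fa == 2:
                rec["carriers"][q.father.sample_id] = Genotype.HOM_ALT
            if mo == 1:
                rec["carriers"][q.mother.sample_id] = Genotype.HET
            elif mo == 2:
                rec["carriers"][q.mother.sample_id] = Genotype.HOM_ALT
            for child in q.children:
                pat = (fa == 2) or (fa == 1 and rng.random() < 0.5)
                mat = (mo == 2) or (mo == 1 and rng.random() < 0.5)
                n = int(pat) + int(mat)
                if n == 1:
                    rec["carriers"][child.sample_id] = Genotype.HET
                elif n == 2:
                    rec["carriers"][child.sample_id] = Genotype.HOM_ALT


def _seed_rare_parent(rec: dict, quad: Quad, rng: np.random.Generator,
                      on_x: bool, *, father_only: bool) -> None:
    """One carrier parent + Mendelian transmission for a rare background variant."""
    if on_x:
        if father_only or rng.random() < 1 / 3:
            rec["carriers"][quad.father.sample_id] = Genotype.HEMI_ALT
            for child in quad.children:
                if child.sex is Sex.FEMALE:
                    rec["carriers"][child.sample_id] = Genotype.HET
        else:
            rec["carriers"][quad.mother.sample_id] = Genotype.HET
            for child in quad.children:
                if rng.random() < 0.5:
                    rec["carriers"][child.sample_id] = (
                        Genotype.HEMI_ALT if child.sex is Sex.MALE else Genotype.HET
                    )
    else:
        parent = quad.father if rng.random() < 0.5 else quad.mother
        rec["carriers"][parent.sample_id] = Genotype.HET
        for child in quad.children:
            if rng.random() < 0.5:
                rec["carriers"][child.sample_id] = Genotype.HET


def _build_manifest(spec, quads, events, gene_info, variants) -> dict:
    """Truth manifest: every planted event plus all expected pipeline outputs."""
    by_fam = {q.family_id: q for q in quads}
    retained = [e for e in events if not e["shared"]]
    shared_counts: dict[str, int] = {}
    for e in events:
        if e["shared"] and e["role"] == "proband":
            shared_counts[e["group"]] = shared_counts.get(e["group"], 0) + 1

    male_pro = sum(q.proband.sex is Sex.MALE for q in quads)
    male_sib = sum(q.sibling.sex is Sex.MALE for q in quads)

    counts: dict[str, dict[str, list[int]]] = {}
    for group in _DEFAULT_BASE_RATES:
        counts[group] = {}
        for restriction in ("all_genes", "brain_constrained"):
            pro = {e["child_id"] for e in retained
                   if e["group"] == group and e["role"] == "proband"
                   and (restriction == "all_genes" or e["constrained_brain"])}
            sib = {e["child_id"] for e in retained
                   if e["group"] == group and e["role"] == "sibling"
                   and (restriction == "all_genes" or e["constrained_brain"])}
            counts[group][restriction] = [len(pro), len(sib)]

    # expected candidate genes under the default (PTV+Dmis) prioritization
    vmap = {v.variant_id: v for v in variants}
    sel = {"biallelic_PTV", "x_PTV", "biallelic_Dmis", "x_Dmis"}
    sib_aut = {e["gene"] for e in retained
               if e["role"] == "sibling" and e["group"] in sel
               and not e["group"].startswith("x_")}
    sib_x = {e["gene"] for e in retained
             if e["role"] == "sibling" and e["group"] in sel
             and e["group"].startswith("x_")}
    cand: dict[str, set] = {}
    for e in retained:
        if e["role"] != "proband" or e["group"] not in sel:
            continue
        if any(vmap[vid].clinvar_benign for vid in e["variant_ids"]):
            continue
        on_x = e["group"].startswith("x_")
        if on_x and any(vmap[vid].gnomad_male_carriers > 10 for vid in e["variant_ids"]):
            continue
        if e["gene"] in (sib_x if on_x else sib_aut):
            continue
        if on_x and gene_info.loc[e["gene"], "pli"] < 0.5:
            continue
        cand.setdefault(e["gene"], set()).add(e["child_id"])

    return dict(
        seed=spec.seed,
        n_quads=spec.n_quads,
        n_male_probands=int(male_pro),
        n_male_siblings=int(male_sib),
        n_variants=len(variants),
        n_families=len(by_fam),
        events=events,
        expected_shared_counts=shared_counts,
        expected_carrier_counts=counts,
        expected_candidates=sorted(cand),
        expected_candidate_probands={g: sorted(p) for g, p in sorted(cand.items())},
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

@dataclass
class CohortFiles:
    ped: Path
    vcf: Path
    annotation: Path
    gene_info: Path
    manifest: Path


_GT_STR = {
    Genotype.HOM_REF: "0/0", Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_cohort(sim: SimulatedCohort, out_dir: str | Path) -> CohortFiles:
    """Emit PED, VCF, annotation TSV, gene-metadata TSV and the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = out / "cohort.ped"
    vcf = out / "cohort.vcf"
    ann = out / "annotations.tsv"
    ginfo = out / "gene_info.tsv"
    manifest = out / "manifest.json"

    with open(ped, "w") as fh:
        for q in sim.quads:
            fa, mo = q.father.sample_id, q.mother.sample_id
            for s in (q.father, q.mother, q.proband, q.sibling):
                sex = "1" if s.sex is Sex.MALE else "2"
                pheno = "2" if s.role is Role.PROBAND else "1"
                par = ("0", "0") if s.role in (Role.FATHER, Role.MOTHER) else (fa, mo)
                fh.write(f"{q.family_id}\t{s.sample_id}\t{par[0]}\t{par[1]}\t{sex}\t{pheno}\n")

    samples = [s.sample_id for q in sim.quads
               for s in (q.father, q.mother, q.proband, q.sibling)]
    male = {s.sample_id: s.sex is Sex.MALE for q in sim.quads for s in q.members}
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in [str(i) for i in range(1, 23)] + ["X"]:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in sim.variants:
            on_x = is_x(v.chrom)
            gts = []
            carriers = v.genotypes.carriers if isinstance(v.genotypes, SparseGenotypes) \
                else v.genotypes
            for sid in samples:
                g = carriers.get(sid, Genotype.HOM_REF)
                if on_x and male[sid]:
                    if g is Genotype.MISSING:
                        gts.append(".")
                    elif g is Genotype.HEMI_ALT:
                        gts.append("1")
                    else:
                        gts.append("0")
                else:
                    gts.append(_GT_STR[g])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")

    with open(ann, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\teffect\treve_score\tgnomad_af\t"
                 "gnomad_male_carriers\tclinvar_benign\tdepth_ok\tgq_ok\tcallrate_ok\n")
        for v in sim.variants:
            reve = "" if v.reve_score is None else repr(v.reve_score)
            fh.write("\t".join([
                v.chrom, str(v.pos), v.ref, v.alt, v.gene, v.effect.value, reve,
                repr(v.gnomad_af), str(v.gnomad_male_carriers),
                str(int(v.clinvar_benign)), str(int(v.depth_ok)),
                str(int(v.gq_ok)), str(int(v.callrate_ok)),
            ]) + "\n")

    sim.gene_info.reset_index().to_csv(ginfo, sep="\t", index=False)
    with open(manifest, "w") as fh:
        json.dump(sim.manifest, fh, indent=1, sort_keys=True)
    return CohortFiles(ped=ped, vcf=vcf, annotation=ann, gene_info=ginfo,
                       manifest=manifest)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortFiles:
    """Simulate a cohort and write all pipeline input files plus the manifest."""
    return write_cohort(simulate_cohort(spec), out_dir)


def manifest_events(manifest: dict) -> list[InheritedEvent]:
    """Reconstruct the planted, non-shared events as InheritedEvent objects."""
    out = []
    for e in manifest["events"]:
        if e["shared"]:
            continue
        mode = EventMode(e["mode"])
        vids = tuple(sorted(e["variant_ids"]))
        if mode is EventMode.BIALLELIC_CHET:
            by_origin = {o: vid for vid, o in e["origins"].items()}
            origin = ((by_origin["father"], Origin.FATHER),
                      (by_origin["mother"], Origin.MOTHER))
        elif mode is EventMode.X_HEMIZYGOUS:
            origin = ((vids[0], Origin.MOTHER),)
        else:
            origin = ((vids[0], Origin.EITHER),)
        out.append(
            InheritedEvent(
                family_id=e["family_id"], child_id=e["child_id"], gene=e["gene"],
                mode=mode, group=EventGroup(e["group"]), variant_ids=vids,
                parental_origin=origin,
            )
        )
    return out


# ---------------------------------------------------------------------------
# expression and PPI generators
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    """Block-correlated expression matrix with planted modules.

    ``within_module_r`` is the expected pairwise Pearson correlation inside a
    module at ``noise_sd = 1``; ``noise_sd = 0`` collapses each module onto
    its latent factor (r = 1)."""

    n_genes: int = 160
    n_samples: int = 200
    n_modules: int = 2
    module_size: int = 40
    within_module_r: float = 0.8
    module_trends: tuple = ("prenatal_high", "postnatal_high")
    noise_sd: float = 1.0
    kind: str = "spatiotemporal"  # or "laminar"
    n_stages: int = 17
    n_regions: int = 16
    n_layers: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_module_r < 1.0):
            raise InputError("within_module_r must be in [0, 1)")
        if self.n_modules * self.module_size > self.n_genes:
            raise InputError("modules larger than the gene universe")


_TRENDS = {
    "prenatal_high": lambda t: 1.5 - 3.0 * t,
    "postnatal_high": lambda t: -1.5 + 3.0 * t,
    "middle_high": lambda t: 1.8 - 4.0 * np.abs(t - 0.5),
    "deep_high": lambda t: -1.8 + 4.0 * np.abs(t - 0.5),
    "flat": lambda t: 0.0 * t,
}


def generate_expression(
    spec: ExpressionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str | None]]:
    """Returns (expression genes x samples, sample metadata, truth labels)."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples
    genes = [f"G{i:04d}" for i in range(n)]
    sample_ids = [f"S{j:04d}" for j in range(m)]

    if spec.kind == "spatiotemporal":
        stage_idx = (np.arange(m) * spec.n_stages) // m
        region_idx = np.arange(m) % spec.n_regions
        meta = pd.DataFrame(
            {"stage": [f"stage{i + 1:02d}" for i in stage_idx],
             "region": [f"R{i + 1:02d}" for i in region_idx]},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        t = stage_idx / max(1, spec.n_stages - 1)
    else:
        layer_idx = (np.arange(m) * spec.n_layers) // m
        meta = pd.DataFrame(
            {"layer": [f"L{i + 1}" for i in layer_idx]},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        t = layer_idx / max(1, spec.n_layers - 1)

    order = rng.permutation(n)
    truth: dict[str, str | None] = {g: None for g in genes}
    expr = np.empty((n, m))
    rho = spec.within_module_r
    gene_pos = 0
    for mod in range(spec.n_modules):
        trend_name = spec.module_trends[mod % len(spec.module_trends)]
        f = _TRENDS[trend_name](t) + rng.normal(0.0, 1.0, size=m)
        fz = (f - f.mean()) / f.std()
        for _ in range(spec.module_size):
            gi = order[gene_pos]
            gene_pos += 1
            eps = rng.normal(0.0, 1.0, size=m)
            expr[gi] = np.sqrt(rho) * fz + np.sqrt(max(0.0, 1 - rho)) * spec.noise_sd * eps
            truth[genes[gi]] = f"module{mod + 1}"
    while gene_pos < n:
        gi = order[gene_pos]
        gene_pos += 1
        expr[gi] = rng.normal(0.0, 1.0, size=m)

    base = rng.uniform(2.0, 8.0, size=n)[:, None]
    df = pd.DataFrame(base + expr, index=pd.Index(genes, name="gene"),
                      columns=sample_ids)
    return df, meta, truth


def generate_neuron_expression(
    genes: list[str],
    *,
    n_exc: int = 24,
    n_inh: int = 45,
    exc_shifted: list[str] | None = None,
    inh_shifted: list[str] | None = None,
    fold: float = 2.0,
    sd_log2: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-neuron-type average expression (log2 scale) for excitatory and
    inhibitory neuron types, with optional planted class-shifted genes."""
    rng = np.random.default_rng(seed)
    exc_cols = [f"Exc{i + 1:02d}" for i in range(n_exc)]
    inh_cols = [f"Inh{i + 1:02d}" for i in range(n_inh)]
    exc_shifted = set(exc_shifted or [])
    inh_shifted = set(inh_shifted or [])
    shift = np.log2(fold)
    rows = []
    for g in genes:
        base = rng.uniform(2.0, 6.0)
        exc = base + rng.normal(0.0, sd_log2, size=n_exc)
        inh = base + rng.normal(0.0, sd_log2, size=n_inh)
        if g in exc_shifted:
            exc = exc + shift
        if g in inh_shifted:
            inh = inh + shift
        rows.append(np.concatenate([exc, inh]))
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene"),
                      columns=exc_cols + inh_cols)
    labels = pd.Series(
        ["excitatory"] * n_exc + ["inhibitory"] * n_inh, index=df.columns,
        name="neuron_class",
    )
    return df, labels


def generate_ppi(
    genes: list[str],
    rigs: list[str],
    dngs: list[str],
    *,
    background_edge_p: float = 0.02,
    enrichment_factor: float = 1.0,
    seed: int = 0,
    subthreshold_edge_p: float = 0.01,
) -> pd.DataFrame:
    """Erdos-Renyi PPI background with RIG-DNG pairs wired at
    ``background_edge_p * enrichment_factor``; wired edges get confidence
    scores >= 400, plus decoy edges below the threshold."""
    if enrichment_factor < 1.0:
        raise InputError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    rig_set, dng_set = set(rigs), set(dngs)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    garr = np.asarray(genes)
    a_is_rig = np.isin(garr[iu], list(rig_set))
    b_is_rig = np.isin(garr[ju], list(rig_set))
    a_is_dng = np.isin(garr[iu], list(dng_set))
    b_is_dng = np.isin(garr[ju], list(dng_set))
    cross = (a_is_rig & b_is_dng) | (a_is_dng & b_is_rig)
    p_edge = np.where(cross, min(1.0, background_edge_p * enrichment_factor),
                      background_edge_p)
    u = rng.random(len(iu))
    wired = u < p_edge
    decoy = (~wired) & (rng.random(len(iu)) < subthreshold_edge_p)

    rows = []
    for i, j in zip(iu[wired], ju[wired]):
        a, b = sorted((genes[i], genes[j]))
        rows.append((a, b, int(rng.integers(400, 1000))))
    for i, j in zip(iu[decoy], ju[decoy]):
        a, b = sorted((genes[i], genes[j]))
        rows.append((a, b, int(rng.integers(150, 400))))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def spec_to_dict(spec) -> dict:
    return asdict(spec)
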