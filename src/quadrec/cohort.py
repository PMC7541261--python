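"""Data model and I/O for quad pedigrees, genotypes, annotations and gene metadata.

A *quad* is a family of four: an affected proband, an unaffected sibling and
their two unaffected parents.  Genotypes arrive as VCF (plain or bgzipped),
per-variant functional annotations and per-gene metadata as TSV.  Variants are
held in :class:`AnnotatedVariant` records whose genotype map is stored sparsely
(reference-homozygous samples are implicit), which keeps cohort-scale variant
streams small.

Coordinates are 1-based as in VCF.  Multiallelic records must be pre-split
(one ALT per record); records violating this are rejected.  Any non-reference
male X genotype is normalized to hemizygous-alternate: variant callers emit
diploid-style calls on male X inconsistently, and the inheritance logic wants
a single convention.
"""

from __future__ import annotations

import enum
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import InputError, InvariantError

X_NAMES = {"X", "chrX", "x", "chrx"}


def is_x(chrom: str) -> bool:
    """True if ``chrom`` names the X chromosome."""
    return chrom in X_NAMES


class Role(str, enum.Enum):
    PROBAND = "proband"
    SIBLING = "sibling"
    FATHER = "father"
    MOTHER = "mother"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)


class Effect(str, enum.Enum):
    SPLICE_SITE = "splice_site"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    family_id: str
    role: Role
    sex: Sex

    def __post_init__(self) -> None:
        if self.role is Role.FATHER and self.sex is not Sex.MALE:
            raise InvariantError(f"father {self.sample_id} must be male")
        if self.role is Role.MOTHER and self.sex is not Sex.FEMALE:
            raise InvariantError(f"mother {self.sample_id} must be female")


@dataclass(frozen=True)
class Quad:
    """One proband, one unaffected sibling and their two unaffected parents."""

    family_id: str
    proband: Sample
    sibling: Sample
    father: Sample
    mother: Sample

    def __post_init__(self) -> None:
        members = [self.proband, self.sibling, self.father, self.mother]
        ids = {s.sample_id for s in members}
        if len(ids) != 4:
            raise InvariantError(f"family {self.family_id}: sample ids not distinct")
        for s in members:
            if s.family_id != self.family_id:
                raise InvariantError(
                    f"sample {s.sample_id} family {s.family_id} != quad {self.family_id}"
                )

    @property
    def children(self) -> tuple[Sample, Sample]:
        return (self.proband, self.sibling)

    @property
    def members(self) -> tuple[Sample, Sample, Sample, Sample]:
        return (self.proband, self.sibling, self.father, self.mother)


class SparseGenotypes(Mapping):
    """Mapping sample_id -> Genotype storing only non-reference calls.

    Samples absent from ``carriers`` are implicitly ``HOM_REF``.  The sample
    universe is shared (one tuple per cohort), so a variant costs memory
    proportional to its carrier count only.
    """

    __slots__ = ("_samples", "_carriers")

    def __init__(self, samples: tuple[str, ...], carriers: dict[str, Genotype]):
        self._samples = samples
        self._carriers = carriers

    def __getitem__(self, sample_id: str) -> Genotype:
        gt = self._carriers.get(sample_id)
        if gt is not None:
            return gt
        if sample_id in self._sample_set():
            return Genotype.HOM_REF
        raise KeyError(sample_id)

    def _sample_set(self) -> frozenset:
        # One frozenset per shared sample tuple; the cache keeps the tuple
        # alive so id() keys stay valid.
        entry = _SAMPLE_SET_CACHE.get(id(self._samples))
        if entry is None or entry[1] is not self._samples:
            entry = (frozenset(self._samples), self._samples)
            _SAMPLE_SET_CACHE[id(self._samples)] = entry
        return entry[0]

    def __iter__(self) -> Iterator[str]:
        return iter(self._samples)

    def __len__(self) -> int:
        return len(self._samples)

    def __eq__(self, other) -> bool:
        if isinstance(other, SparseGenotypes):
            return (
                self._samples == other._samples and self._carriers == other._carriers
            )
        if isinstance(other, Mapping):
            return dict(self) == dict(other)
        return NotImplemented

    def __hash__(self):  # pragma: no cover - mappings are unhashable by convention
        raise TypeError("SparseGenotypes is unhashable")

    @property
    def carriers(self) -> dict[str, Genotype]:
        """Non-hom-ref calls only."""
        return self._carriers


_SAMPLE_SET_CACHE: dict = {}


@dataclass
class AnnotatedVariant:
    """A biallelic coding variant with per-sample genotypes and annotations."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect
    reve_score: float | None
    gnomad_af: float
    cohort_af: float
    gnomad_male_carriers: int
    clinvar_benign: bool
    depth_ok: bool
    gq_ok: bool
    callrate_ok: bool
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.effect is Effect.MISSENSE) != (self.reve_score is not None):
            raise InvariantError(
                f"{self.variant_id}: reve_score must be present iff effect is missense"
            )

    @property
    def is_x(self) -> bool:
        return is_x(self.chrom)

    def genotype(self, sample_id: str) -> Genotype:
        return self.genotypes[sample_id]


@dataclass(frozen=True)
class GeneInfo:
    gene: str
    chrom: str
    pli: float
    brain_rpkm: float
    gnomad_hom_dmis: int
    gnomad_hom_ptv: int
    dnv_rate: float
    coding_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pli <= 1.0):
            raise InvariantError(f"{self.gene}: pLI {self.pli} outside [0,1]")
        if self.gnomad_hom_dmis < 0 or self.gnomad_hom_ptv < 0:
            raise InvariantError(f"{self.gene}: negative gnomAD counts")


@dataclass
class SkipRecord:
    family_id: str
    reason: str


def read_pedigree(ped_path: str | Path) -> tuple[list[Quad], list[SkipRecord]]:
    """Parse a 6-column PED file into complete quads.

    Returns ``(quads, skipped)``: families that are not a complete quad (one
    affected child, one unaffected child, two unaffected parents) are reported
    in ``skipped`` rather than raising.  Malformed lines and duplicate sample
    ids do raise :class:`InputError`.
    """
    rows: list[dict] = []
    seen_ids: set[str] = set()
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise InputError(f"{ped_path}:{lineno}: expected 6 columns, got {len(parts)}")
            fam, iid, father, mother, sex, pheno = parts[:6]
            if iid in seen_ids:
                raise InputError(f"{ped_path}:{lineno}: duplicate sample id {iid!r}")
            seen_ids.add(iid)
            if sex not in ("1", "2"):
                raise InputError(f"{ped_path}:{lineno}: bad sex code {sex!r}")
            if pheno not in ("1", "2"):
                raise InputError(f"{ped_path}:{lineno}: bad phenotype code {pheno!r}")
            rows.append(
                dict(family=fam, iid=iid, father=father, mother=mother,
                     sex=Sex.MALE if sex == "1" else Sex.FEMALE,
                     affected=pheno == "2")
            )

    quads: list[Quad] = []
    skipped: list[SkipRecord] = []
    by_family: dict[str, list[dict]] = {}
    for r in rows:
        by_family.setdefault(r["family"], []).append(r)

    for fam, members in by_family.items():
        ids = {m["iid"]: m for m in members}
        children = [m for m in members if m["father"] in ids and m["mother"] in ids]
        founders = [m for m in members if m not in children]
        if len(members) != 4 or len(children) != 2 or len(founders) != 2:
            skipped.append(SkipRecord(fam, f"not a quad ({len(members)} members, {len(children)} children)"))
            continue
        affected = [c for c in children if c["affected"]]
        unaffected = [c for c in children if not c["affected"]]
        if len(affected) != 1 or len(unaffected) != 1:
            skipped.append(SkipRecord(fam, "need exactly one affected and one unaffected child"))
            continue
        pro, sib = affected[0], unaffected[0]
        if pro["father"] != sib["father"] or pro["mother"] != sib["mother"]:
            skipped.append(SkipRecord(fam, "children have different parents"))
            continue
        father = ids[pro["father"]]
        mother = ids[pro["mother"]]
        if father["affected"] or mother["affected"]:
            skipped.append(SkipRecord(fam, "parents must be unaffected"))
            continue
        if father["sex"] is not Sex.MALE or mother["sex"] is not Sex.FEMALE:
            skipped.append(SkipRecord(fam, "parental sex codes inconsistent with roles"))
            continue
        try:
            quads.append(
                Quad(
                    family_id=fam,
                    proband=Sample(pro["iid"], fam, Role.PROBAND, pro["sex"]),
                    sibling=Sample(sib["iid"], fam, Role.SIBLING, sib["sex"]),
                    father=Sample(father["iid"], fam, Role.FATHER, Sex.MALE),
                    mother=Sample(mother["iid"], fam, Role.MOTHER, Sex.FEMALE),
                )
            )
        except InvariantError as exc:
            raise InputError(f"{ped_path}: family {fam}: {exc}") from exc
    return quads, skipped


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "reve_score", "gnomad_af",
    "gnomad_male_carriers", "clinvar_benign", "depth_ok", "gq_ok", "callrate_ok",
]


def _to_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "t", "yes")
    return bool(x)


@dataclass
class ReadDiagnostics:
    """Counters accumulated while joining VCF records with annotations."""

    n_records: int = 0
    n_joined: int = 0
    n_unannotated: int = 0
    n_male_x_normalized: int = 0
    n_unmappable_genotypes: int = 0


def read_variants(
    vcf_path: str | Path,
    annotation_path: str | Path,
    quads: list[Quad],
) -> tuple[list[AnnotatedVariant], ReadDiagnostics]:
    """Join VCF genotypes with the annotation TSV.

    Variants failing quality flags are retained with flags set (filtering is a
    separate concern).  VCF records without an annotation row are skipped and
    counted.  A VCF sample absent from the pedigree raises :class:`InputError`.
    """
    from cyvcf2 import VCF

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise InputError(f"{annotation_path}: missing columns {sorted(missing_cols)}")
    ann_index: dict[tuple, dict] = {}
    for row in ann.itertuples(index=False):
        d = row._asdict()
        ann_index[(str(d["chrom"]), int(d["pos"]), d["ref"], d["alt"])] = d

    pedigree_samples = {s.sample_id: s for q in quads for s in q.members}

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in pedigree_samples]
    if unknown:
        raise InputError(f"{vcf_path}: samples absent from pedigree: {unknown[:5]}")
    samples_tuple = tuple(vcf_samples)
    male_x = {
        s: pedigree_samples[s].sex is Sex.MALE for s in vcf_samples
    }
    father_ids = {q.father.sample_id for q in quads}
    mother_ids = {q.mother.sample_id for q in quads}
    n_quads = len(quads)

    diags = ReadDiagnostics()
    variants: list[AnnotatedVariant] = []
    for rec in vcf:
        diags.n_records += 1
        if len(rec.ALT) != 1:
            raise InputError(
                f"{vcf_path}: multiallelic record at {rec.CHROM}:{rec.POS}; pre-split required"
            )
        chrom = rec.CHROM
        key = (str(chrom), int(rec.POS), rec.REF, rec.ALT[0])
        d = ann_index.get(key)
        if d is None:
            diags.n_unannotated += 1
            continue
        on_x = is_x(chrom)
        carriers: dict[str, Genotype] = {}
        arr = rec.genotype.array()
        a0, a1 = arr[:, 0], arr[:, 1]
        # skip reference-homozygous calls (a1 == -2 marks haploid)
        nonref = np.nonzero(~((a0 == 0) & ((a1 == 0) | (a1 == -2))))[0]
        for i in nonref:
            sid = vcf_samples[i]
            al0, al1 = int(a0[i]), int(a1[i])
            haploid = al1 == -2
            alleles = (al0,) if haploid else (al0, al1)
            if any(a < 0 for a in alleles):
                carriers[sid] = Genotype.MISSING
                continue
            if any(a > 1 for a in alleles):
                diags.n_unmappable_genotypes += 1
                carriers[sid] = Genotype.MISSING
                continue
            n_alt = sum(alleles)
            if haploid:
                g = Genotype.HEMI_ALT  # n_alt >= 1 here
                if not (on_x and male_x[sid]):
                    diags.n_unmappable_genotypes += 1
                    g = Genotype.MISSING
            else:
                g = Genotype.HET if n_alt == 1 else Genotype.HOM_ALT
                if on_x and male_x[sid]:
                    g = Genotype.HEMI_ALT
                    diags.n_male_x_normalized += 1
            carriers[sid] = g

        effect = Effect(d["effect"])
        reve = d["reve_score"]
        reve = None if pd.isna(reve) else float(reve)
        v = AnnotatedVariant(
            variant_id=f"{chrom}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
            chrom=str(chrom),
            pos=int(rec.POS),
            ref=rec.REF,
            alt=rec.ALT[0],
            gene=str(d["gene"]),
            effect=effect,
            reve_score=reve,
            gnomad_af=float(d["gnomad_af"]),
            cohort_af=0.0,
            gnomad_male_carriers=int(d["gnomad_male_carriers"]),
            clinvar_benign=_to_bool(d["clinvar_benign"]),
            depth_ok=_to_bool(d["depth_ok"]),
            gq_ok=_to_bool(d["gq_ok"]),
            callrate_ok=_to_bool(d["callrate_ok"]),
            genotypes=SparseGenotypes(samples_tuple, carriers),
        )
        # parents-only allele frequency from the sparse carrier map
        alt = 0
        denom = (3 if on_x else 4) * n_quads
        for sid, g in carriers.items():
            is_father = sid in father_ids
            if not (is_father or sid in mother_ids):
                continue
            if g is Genotype.MISSING:
                denom -= 1 if (on_x and is_father) else 2
            elif g is Genotype.HOM_ALT:
                alt += 2
            elif g.carries_alt():
                alt += 1
        if denom == 0:
            raise InvariantError(f"{v.variant_id}: zero informative parental chromosomes")
        v.cohort_af = alt / denom
        variants.append(v)
        diags.n_joined += 1
    if diags.n_unannotated:
        warnings.warn(
            f"{diags.n_unannotated} VCF records had no annotation row and were skipped",
            stacklevel=2,
        )
    return variants, diags


def quality_filter(v: AnnotatedVariant) -> bool:
    """True iff the variant passes all three site/genotype quality gates
    (sequencing depth > 20, genotype quality > 50, call rate > 0.9, consumed
    as precomputed boolean flags)."""
    return v.depth_ok and v.gq_ok and v.callrate_ok


def cohort_af(v: AnnotatedVariant, quads: list[Quad]) -> float:
    """Alternate-allele frequency over parental chromosomes only.

    Children are excluded: their alleles are copies of parental alleles and
    would be double-counted.  Fathers contribute one X chromosome, mothers
    two; both contribute two autosomal chromosomes.  Missing genotypes drop
    out of the denominator.
    """
    alt = 0
    chroms = 0
    on_x = v.is_x
    _ALT_COUNT = {
        Genotype.HOM_REF: 0,
        Genotype.HET: 1,
        Genotype.HOM_ALT: 2,
        Genotype.HEMI_ALT: 1,
    }
    for q in quads:
        for parent in (q.father, q.mother):
            g = v.genotypes[parent.sample_id]
            if g is Genotype.MISSING:
                continue
            if on_x and parent.role is Role.FATHER:
                n = 1
                a = 1 if g.carries_alt() else 0
            else:
                n = 2
                a = _ALT_COUNT[g]
            alt += a
            chroms += n
    if chroms == 0:
        raise InvariantError(f"{v.variant_id}: zero informative parental chromosomes")
    return alt / chroms


def read_gene_info(path: str | Path) -> pd.DataFrame:
    """Gene metadata TSV -> DataFrame indexed by gene symbol."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene", "chrom", "pli", "brain_rpkm", "gnomad_hom_dmis",
                "gnomad_hom_ptv", "dnv_rate", "coding_length"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if ((df["pli"] < 0) | (df["pli"] > 1)).any():
        raise InputError(f"{path}: pLI outside [0,1]")
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# AnnotatedVariant stream serialization (round-trippable TSV)
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "gene", "effect", "reve_score",
    "gnomad_af", "cohort_af", "gnomad_male_carriers", "clinvar_benign",
    "depth_ok", "gq_ok", "callrate_ok", "genotypes",
]


def write_variants(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Serialize a variant stream to TSV, preserving all fields exactly.

    Genotypes are written sparsely (``sample=gt`` pairs for non-reference
    calls) with the shared sample universe in a ``##samples=`` header line.
    """
    variants = list(variants)
    samples: tuple[str, ...] = ()
    for v in variants:
        if isinstance(v.genotypes, SparseGenotypes):
            samples = tuple(v.genotypes)
            break
        samples = tuple(v.genotypes)
        break
    with open(path, "w") as fh:
        fh.write("##samples=" + ",".join(samples) + "\n")
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for v in variants:
            carriers = (
                v.genotypes.carriers
                if isinstance(v.genotypes, SparseGenotypes)
                else {s: g for s, g in v.genotypes.items() if g is not Genotype.HOM_REF}
            )
            gt_str = ";".join(f"{s}={g.value}" for s, g in sorted(carriers.items()))
            row = [
                v.variant_id, v.chrom, str(v.pos), v.ref, v.alt, v.gene,
                v.effect.value,
                "" if v.reve_score is None else repr(v.reve_score),
                repr(v.gnomad_af), repr(v.cohort_af),
                str(v.gnomad_male_carriers),
                str(int(v.clinvar_benign)), str(int(v.depth_ok)),
                str(int(v.gq_ok)), str(int(v.callrate_ok)), gt_str,
            ]
            fh.write("\t".join(row) + "\n")


def read_variants_table(path: str | Path) -> list[AnnotatedVariant]:
    """Inverse of :func:`write_variants`."""
    variants: list[AnnotatedVariant] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("##samples="):
            raise InputError(f"{path}: missing ##samples header")
        samples = tuple(s for s in header[len("##samples="):].split(",") if s)
        cols = fh.readline().strip().split("\t")
        if cols != _VARIANT_COLUMNS:
            raise InputError(f"{path}: unexpected columns {cols}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            d = dict(zip(_VARIANT_COLUMNS, f))
            carriers = {}
            if d["genotypes"]:
                for pair in d["genotypes"].split(";"):
                    s, g = pair.split("=")
                    carriers[s] = Genotype(g)
            variants.append(
                AnnotatedVariant(
                    variant_id=d["variant_id"], chrom=d["chrom"], pos=int(d["pos"]),
                    ref=d["ref"], alt=d["alt"], gene=d["gene"],
                    effect=Effect(d["effect"]),
                    reve_score=None if d["reve_score"] == "" else float(d["reve_score"]),
                    gnomad_af=float(d["gnomad_af"]), cohort_af=float(d["cohort_af"]),
                    gnomad_male_carriers=int(d["gnomad_male_carriers"]),
                    clinvar_benign=bool(int(d["clinvar_benign"])),
                    depth_ok=bool(int(d["depth_ok"])),
                    gq_ok=bool(int(d["gq_ok"])),
                    callrate_ok=bool(int(d["callrate_ok"])),
                    genotypes=SparseGenotypes(samples, carriers),
                )
            )
    return variants
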