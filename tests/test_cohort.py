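"""Pedigree parsing, genotype I/O, quality gates and parental allele frequency."""

from __future__ import annotations

import random

import pytest

from quadrec.cohort import (
    Effect,
    Genotype,
    Quad,
    Role,
    Sample,
    Sex,
    SparseGenotypes,
    cohort_af,
    quality_filter,
    read_pedigree,
    read_variants,
    read_variants_table,
    write_variants,
)
from quadrec.errors import InputError, InvariantError

from .conftest import gts, make_variant

PED_QUAD = """FAM1 fa1 0 0 1 1
FAM1 mo1 0 0 2 1
FAM1 p1 fa1 mo1 1 2
FAM1 s1 fa1 mo1 2 1
"""


def _quads(n=50):
    out = []
    for i in range(n):
        fam = f"F{i}"
        out.append(Quad(
            family_id=fam,
            proband=Sample(f"p{i}", fam, Role.PROBAND, Sex.MALE),
            sibling=Sample(f"s{i}", fam, Role.SIBLING, Sex.FEMALE),
            father=Sample(f"fa{i}", fam, Role.FATHER, Sex.MALE),
            mother=Sample(f"mo{i}", fam, Role.MOTHER, Sex.FEMALE),
        ))
    return out


class TestReadPedigree:
    def test_valid_quad(self, tmp_path):
        ped = tmp_path / "a.ped"
        ped.write_text(PED_QUAD)
        quads, skipped = read_pedigree(ped)
        assert len(quads) == 1 and not skipped
        q = quads[0]
        assert q.proband.sample_id == "p1" and q.proband.sex is Sex.MALE
        assert q.sibling.sample_id == "s1" and q.sibling.sex is Sex.FEMALE

    def test_trio_skipped(self, tmp_path):
        ped = tmp_path / "trio.ped"
        ped.write_text(
            "T1 fa 0 0 1 1\nT1 mo 0 0 2 1\nT1 kid fa mo 1 2\n"
        )
        quads, skipped = read_pedigree(ped)
        assert quads == []
        assert len(skipped) == 1 and skipped[0].family_id == "T1"

    def test_malformed_line_names_lineno(self, tmp_path):
        ped = tmp_path / "bad.ped"
        ped.write_text("FAM1 fa1 0 0 1 1\nFAM1 mo1 0 0\n")
        with pytest.raises(InputError, match=":2:"):
            read_pedigree(ped)

    def test_duplicate_sample_id(self, tmp_path):
        ped = tmp_path / "dup.ped"
        ped.write_text("F1 a 0 0 1 1\nF1 a 0 0 2 1\n")
        with pytest.raises(InputError, match="duplicate"):
            read_pedigree(ped)

    def test_two_affected_children_skipped(self, tmp_path):
        ped = tmp_path / "aff.ped"
        ped.write_text(
            "F1 fa 0 0 1 1\nF1 mo 0 0 2 1\nF1 c1 fa mo 1 2\nF1 c2 fa mo 2 2\n"
        )
        quads, skipped = read_pedigree(ped)
        assert not quads and len(skipped) == 1

    def test_generated_cohort_count(self, cohort_dir, small_sim):
        quads, skipped = read_pedigree(cohort_dir.ped)
        assert len(quads) == small_sim.manifest["n_quads"]
        assert not skipped


@pytest.mark.parametrize(
    "flags,expected",
    [((True, True, True), True),
     ((True, True, False), False),
     ((False, True, True), False),
     ((True, False, True), False)],
)
def test_quality_filter(flags, expected):
    depth, gq, callrate = flags
    v = make_variant(depth_ok=depth, gq_ok=gq, callrate_ok=callrate)
    assert quality_filter(v) is expected


class TestCohortAF:
    def test_single_het_mother_autosome(self):
        quads = _quads(50)
        g = {s.sample_id: Genotype.HOM_REF for q in quads for s in q.members}
        g[quads[0].mother.sample_id] = Genotype.HET
        v = make_variant(genotypes=g)
        assert cohort_af(v, quads) == pytest.approx(1 / 200)

    def test_single_carrier_father_x(self):
        quads = _quads(50)
        g = {s.sample_id: Genotype.HOM_REF for q in quads for s in q.members}
        g[quads[0].father.sample_id] = Genotype.HEMI_ALT
        v = make_variant(chrom="X", genotypes=g)
        # fathers contribute one X chromosome, mothers two: 150 in 50 quads
        assert cohort_af(v, quads) == pytest.approx(1 / 150)

    def test_no_carriers(self):
        quads = _quads(10)
        g = {s.sample_id: Genotype.HOM_REF for q in quads for s in q.members}
        assert cohort_af(make_variant(genotypes=g), quads) == 0.0

    def test_children_do_not_count(self):
        quads = _quads(10)
        g = {s.sample_id: Genotype.HOM_REF for q in quads for s in q.members}
        g[quads[0].proband.sample_id] = Genotype.HOM_ALT
        g[quads[1].sibling.sample_id] = Genotype.HET
        assert cohort_af(make_variant(genotypes=g), quads) == 0.0

    def test_order_invariance(self):
        quads = _quads(20)
        g = {s.sample_id: Genotype.HOM_REF for q in quads for s in q.members}
        g[quads[3].father.sample_id] = Genotype.HET
        g[quads[7].mother.sample_id] = Genotype.HOM_ALT
        v = make_variant(genotypes=g)
        shuffled = quads[:]
        random.Random(5).shuffle(shuffled)
        assert cohort_af(v, quads) == cohort_af(v, shuffled)

    def test_missing_drops_from_denominator(self):
        quads = _quads(10)
        g = {s.sample_id: Genotype.HOM_REF for q in quads for s in q.members}
        g[quads[0].mother.sample_id] = Genotype.MISSING
        g[quads[1].father.sample_id] = Genotype.HET
        assert cohort_af(make_variant(genotypes=g), quads) == pytest.approx(1 / 38)

    def test_all_missing_raises(self):
        quads = _quads(1)
        g = {s.sample_id: Genotype.MISSING for q in quads for s in q.members}
        with pytest.raises(InvariantError):
            cohort_af(make_variant(genotypes=g), quads)


class TestReadVariants:
    def _write(self, tmp_path, vcf_body, ann_rows):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n##contig=<ID=X>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tfa1\tmo1\tp1\ts1\n"
            + vcf_body
        )
        ann = tmp_path / "a.tsv"
        header = ("chrom\tpos\tref\talt\tgene\teffect\treve_score\tgnomad_af\t"
                  "gnomad_male_carriers\tclinvar_benign\tdepth_ok\tgq_ok\tcallrate_ok\n")
        ann.write_text(header + "".join(ann_rows))
        ped = tmp_path / "p.ped"
        ped.write_text(PED_QUAD)
        quads, _ = read_pedigree(ped)
        return vcf, ann, quads

    def test_three_records_joined(self, tmp_path):
        body = (
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\t0/0\n"
            "1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t0/1\t0/0\n"
            "1\t300\t.\tT\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\n"
        )
        rows = [
            "1\t100\tA\tT\tG1\tstop_gain\t\t0.0001\t0\t0\t1\t1\t1\n",
            "1\t200\tG\tC\tG1\tmissense\t0.9\t0.0001\t0\t0\t1\t1\t1\n",
            "1\t300\tT\tA\tG2\tsynonymous\t\t0.0001\t0\t0\t1\t1\t1\n",
        ]
        vcf, ann, quads = self._write(tmp_path, body, rows)
        variants, diags = read_variants(vcf, ann, quads)
        assert len(variants) == 3 and diags.n_joined == 3
        assert variants[0].effect is Effect.STOP_GAIN
        assert variants[1].reve_score == 0.9
        # allele frequency over 4 parental chromosomes
        assert variants[0].cohort_af == pytest.approx(0.25)

    def test_male_x_het_normalized(self, tmp_path):
        body = "X\t500\t.\tA\tG\t.\tPASS\t.\tGT\t0\t0/1\t0/1\t0/0\n"
        rows = ["X\t500\tA\tG\tGX\tstop_gain\t\t0.0001\t0\t0\t1\t1\t1\n"]
        vcf, ann, quads = self._write(tmp_path, body, rows)
        variants, diags = read_variants(vcf, ann, quads)
        assert variants[0].genotypes["p1"] is Genotype.HEMI_ALT
        assert diags.n_male_x_normalized == 1

    def test_unannotated_record_skipped(self, tmp_path):
        body = (
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\t0/0\n"
            "1\t999\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\n"
        )
        rows = ["1\t100\tA\tT\tG1\tstop_gain\t\t0.0001\t0\t0\t1\t1\t1\n"]
        vcf, ann, quads = self._write(tmp_path, body, rows)
        with pytest.warns(UserWarning, match="no annotation"):
            variants, diags = read_variants(vcf, ann, quads)
        assert len(variants) == 1 and diags.n_unannotated == 1

    def test_unknown_sample_errors(self, tmp_path):
        body = "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/1\t0/0\n"
        rows = ["1\t100\tA\tT\tG1\tstop_gain\t\t0.0001\t0\t0\t1\t1\t1\n"]
        vcf, ann, quads = self._write(tmp_path, body, rows)
        quads = quads[:0] + [Quad(
            family_id="OTHER",
            proband=Sample("px", "OTHER", Role.PROBAND, Sex.MALE),
            sibling=Sample("sx", "OTHER", Role.SIBLING, Sex.FEMALE),
            father=Sample("fx", "OTHER", Role.FATHER, Sex.MALE),
            mother=Sample("mx", "OTHER", Role.MOTHER, Sex.FEMALE),
        )]
        with pytest.raises(InputError, match="absent from pedigree"):
            read_variants(vcf, ann, quads)

    def test_cohort_fixture_matches_manifest(self, cohort_dir, small_sim):
        quads, _ = read_pedigree(cohort_dir.ped)
        variants, diags = read_variants(cohort_dir.vcf, cohort_dir.annotation, quads)
        assert len(variants) == small_sim.manifest["n_variants"]
        assert diags.n_unannotated == 0


def test_variant_stream_round_trip(tmp_path, quad):
    samples = tuple(s.sample_id for s in quad.members)
    variants = [
        make_variant(pos=100, genotypes=SparseGenotypes(
            samples, {"p1": Genotype.HET, "mo1": Genotype.HET})),
        make_variant(pos=200, chrom="X", effect=Effect.MISSENSE, reve=0.81,
                     gnomad_af=0.0005, cohort_af=1 / 150,
                     genotypes=SparseGenotypes(samples, {"p1": Genotype.HEMI_ALT})),
        make_variant(pos=300, effect=Effect.SYNONYMOUS, clinvar_benign=True,
                     depth_ok=False,
                     genotypes=SparseGenotypes(samples, {"s1": Genotype.MISSING})),
    ]
    path = tmp_path / "variants.tsv"
    write_variants(variants, path)
    back = read_variants_table(path)
    assert back == variants
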