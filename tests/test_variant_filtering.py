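"""Three-criterion recessive filter and transcript-model annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from recessmap.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord
from recessmap.variant_filtering import (
    COMPLEX, INTERGENIC, INTRONIC, MISSENSE, SPLICE_ACCEPTOR, SPLICE_DONOR,
    STOP_GAINED, SYNONYMOUS, UTR,
    ConsequenceCall, FilterCriteria, GeneModel, SEVERITY_RANK,
    annotate_consequence, filter_recessive_candidates, rank_candidates,
    read_gene_model, write_gene_model,
)


# ---------------------------------------------------------------------------
# toy 60-bp forward-strand gene: 2 exons, 8-nt intron, 30-nt CDS
# ---------------------------------------------------------------------------

TOY_SEQ = (
    "ACCA"  # 1-4 intergenic
    "CTT"  # 5-7 5'UTR
    "ATGGCTGATGAATTCCTGAAA"  # 8-28 CDS part 1 (7 codons)
    "GTAAGTAG"  # 29-36 intron (GT...AG)
    "CGTGGGTAA"  # 37-45 CDS part 2 (2 codons + TAA stop)
    "CCTCACCATCA"  # 46-56 3'UTR
    "GGCA"  # 57-60 intergenic
)


def toy_model():
    return GeneModel(
        gene_id="toy", transcript_id="toy_tx", chromosome="7", strand="+",
        exons=[(5, 28), (37, 56)], cds_start=8, cds_end=45,
        seq=TOY_SEQ, seq_offset=1,
    )


def mirror_model(model: GeneModel) -> GeneModel:
    """The same gene on the opposite strand of the reverse-complemented locus."""
    L = len(model.seq)
    m = lambda p: 2 * model.seq_offset + L - 1 - p
    return GeneModel(
        gene_id=model.gene_id, transcript_id=model.transcript_id,
        chromosome=model.chromosome,
        strand="-" if model.strand == "+" else "+",
        exons=[(m(e), m(s)) for s, e in model.exons],
        cds_start=m(model.cds_end), cds_end=m(model.cds_start),
        seq=str(Seq(model.seq).reverse_complement()),
        seq_offset=model.seq_offset,
    )


def mirror_variant(model: GeneModel, v: VariantRecord) -> VariantRecord:
    L = len(model.seq)
    m = lambda p: 2 * model.seq_offset + L - 1 - p
    comp = lambda s: str(Seq(s).reverse_complement())
    return VariantRecord(
        chromosome=v.chromosome, position=m(v.end), ref=comp(v.ref), alt=comp(v.alt),
    )


def oracle_consequence(model: GeneModel, pos: int, alt: str) -> str:
    """Rebuild-and-translate oracle for SNVs on the forward-strand toy gene."""
    span = model.span
    if pos < span[0] or pos > span[1]:
        return INTERGENIC
    for s, e in model.introns:
        if s <= pos <= e:
            if pos in (s, s + 1):
                return SPLICE_DONOR
            if pos in (e - 1, e):
                return SPLICE_ACCEPTOR
            return INTRONIC
    if model.genomic_to_cds(pos) is None:
        return UTR

    def protein(m: GeneModel) -> str:
        cds = "".join(
            m.seq[max(s, m.cds_start) - 1 : min(e, m.cds_end)]
            for s, e in m.exons
            if max(s, m.cds_start) <= min(e, m.cds_end)
        )
        return str(Seq(cds).translate())

    mut_seq = model.seq[: pos - 1] + alt + model.seq[pos:]
    mut = GeneModel(
        gene_id="o", transcript_id="o", chromosome=model.chromosome,
        strand=model.strand, exons=list(model.exons),
        cds_start=model.cds_start, cds_end=model.cds_end,
        seq=mut_seq, seq_offset=model.seq_offset,
    )
    wt_prot, mut_prot = protein(model), protein(mut)
    if wt_prot == mut_prot:
        return SYNONYMOUS
    changed = next(i for i, (a, b) in enumerate(zip(wt_prot, mut_prot)) if a != b)
    return STOP_GAINED if mut_prot[changed] == "*" else MISSENSE


def _variant(pos, ref, alt, chrom="7", genotypes=None):
    return VariantRecord(
        chromosome=chrom, position=pos, ref=ref, alt=alt, genotypes=genotypes or {}
    )


class TestFilter:
    CRIT = FilterCriteria(
        region_chromosome="25", region_start=1_000, region_end=2_000,
        case_samples=("c1", "c2"), control_samples=("k1", "k2", "k3"),
    )

    @staticmethod
    def _v(pos, case=HOM_ALT, controls=(HOM_REF, HOM_REF, HOM_REF), chrom="25"):
        g = {"c1": case, "c2": case}
        g.update({f"k{i + 1}": c for i, c in enumerate(controls)})
        return _variant(pos, "A", "T", chrom=chrom, genotypes=g)

    def test_out_of_region_excluded(self):
        res = filter_recessive_candidates([self._v(5_000)], self.CRIT)
        assert res.survivors == [] and res.n_in_region == 0

    def test_control_homozygote_excluded(self):
        v = self._v(1_500, controls=(HOM_REF, HOM_ALT, HET))
        res = filter_recessive_candidates([v], self.CRIT)
        assert res.n_case_consistent == 1 and res.survivors == []

    def test_missing_control_genotype_not_hom_alt(self):
        v = self._v(1_500, controls=(MISSING, HET, HOM_REF))
        res = filter_recessive_candidates([v], self.CRIT)
        assert len(res.survivors) == 1

    def test_case_lacking_genotype_entry_rejected(self):
        v = _variant(1_500, "A", "T", chrom="25", genotypes={"c1": HOM_ALT})
        res = filter_recessive_candidates([v], self.CRIT)
        assert res.survivors == [] and res.n_rejected_missing_case == 1

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria("1", 1, 10, ("a",), ("a", "b"))
        with pytest.raises(ValueError):
            FilterCriteria("1", 1, 10, (), ("b",))

    def test_stage_counts_monotone_and_subset(self):
        rng = np.random.default_rng(77)
        variants = []
        for _ in range(200):
            pos = int(rng.integers(1, 4_000))
            variants.append(
                self._v(
                    pos,
                    case=int(rng.choice([HOM_ALT, HET])),
                    controls=tuple(rng.choice([HOM_REF, HET, HOM_ALT], size=3)),
                )
            )
        res = filter_recessive_candidates(variants, self.CRIT)
        assert res.n_input >= res.n_in_region >= res.n_case_consistent >= res.n_surviving
        assert all(v in variants for v in res.survivors)

    def test_adding_a_control_never_adds_a_survivor(self):
        rng = np.random.default_rng(78)
        variants = []
        for _ in range(100):
            g = {"c1": HOM_ALT, "c2": HOM_ALT}
            for k in ("k1", "k2", "k3", "k4"):
                g[k] = int(rng.choice([HOM_REF, HET, HOM_ALT]))
            variants.append(_variant(int(rng.integers(1_000, 2_001)), "A", "T", "25", g))
        small = FilterCriteria("25", 1_000, 2_000, ("c1", "c2"), ("k1", "k2"))
        big = FilterCriteria("25", 1_000, 2_000, ("c1", "c2"), ("k1", "k2", "k3", "k4"))
        surv_small = {id(v) for v in filter_recessive_candidates(variants, small).survivors}
        surv_big = {id(v) for v in filter_recessive_candidates(variants, big).survivors}
        assert surv_big <= surv_small


class TestAnnotation:
    def test_reverse_strand_donor_is_g_to_a_on_transcript(self, ccdc_fixture):
        call = annotate_consequence(ccdc_fixture.variant, ccdc_fixture.model)
        assert call.consequence == SPLICE_DONOR
        assert call.hgvs_like == "c.472+1G>A"

    def test_synonymous_third_position(self):
        # codon 2 GCT (Ala) at 11-13; GCT->GCC stays Ala
        call = annotate_consequence(_variant(13, "T", "C"), toy_model())
        assert call.consequence == SYNONYMOUS
        assert call.hgvs_like == "c.6T>C"

    def test_stop_gained(self):
        # codon 7 AAA at 26-28; AAA->TAA
        call = annotate_consequence(_variant(26, "A", "T"), toy_model())
        assert call.consequence == STOP_GAINED

    def test_every_toy_snv_matches_rebuild_translate_oracle(self):
        model = toy_model()
        for pos in range(1, len(TOY_SEQ) + 1):
            ref = TOY_SEQ[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = annotate_consequence(_variant(pos, ref, alt), model).consequence
                want = oracle_consequence(model, pos, alt)
                assert got == want, f"pos {pos} {ref}>{alt}: {got} != {want}"

    def test_strand_symmetry_for_all_toy_snvs(self):
        model = toy_model()
        mirrored = mirror_model(model)
        for pos in range(1, len(TOY_SEQ) + 1):
            ref = TOY_SEQ[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = _variant(pos, ref, alt)
                fwd = annotate_consequence(v, model).consequence
                rev = annotate_consequence(mirror_variant(model, v), mirrored).consequence
                assert fwd == rev

    def test_wrong_chromosome_rejected(self):
        with pytest.raises(ValueError):
            annotate_consequence(_variant(10, "A", "C", chrom="8"), toy_model())

    def test_junction_spanning_deletion_flagged_complex(self):
        # deletion covering the exon-1/intron boundary beyond the donor window
        v = _variant(26, "AAAGTAAG", "A")
        call = annotate_consequence(v, toy_model())
        # overlaps the donor window -> disrupts the donor site
        assert call.consequence == SPLICE_DONOR
        v2 = _variant(33, "GTAGCGTG", "G")  # intron tail into exon 2
        call2 = annotate_consequence(v2, toy_model())
        assert call2.consequence in (SPLICE_ACCEPTOR, COMPLEX)

    def test_in_cds_indel_surfaced_as_complex(self):
        call = annotate_consequence(_variant(11, "GCT", "G"), toy_model())
        assert call.consequence == COMPLEX

    def test_gene_model_roundtrip(self, tmp_path, ccdc_fixture):
        model = ccdc_fixture.model
        write_gene_model(model, tmp_path / "g.tsv", tmp_path / "g.fa")
        back = read_gene_model(tmp_path / "g.tsv", tmp_path / "g.fa")
        assert back.exons == model.exons
        assert (back.cds_start, back.cds_end) == (model.cds_start, model.cds_end)
        assert back.strand == model.strand and back.seq == model.seq
        assert back.seq_offset == model.seq_offset


class TestGeneModelValidation:
    def test_cds_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            GeneModel(
                gene_id="g", transcript_id="t", chromosome="1", strand="+",
                exons=[(5, 28)], cds_start=8, cds_end=27, seq=TOY_SEQ, seq_offset=1,
            )

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            GeneModel(
                gene_id="g", transcript_id="t", chromosome="1", strand="+",
                exons=[(5, 28), (20, 40)], cds_start=8, cds_end=25,
                seq=TOY_SEQ, seq_offset=1,
            )


class TestRanking:
    def _call(self, consequence, pos):
        return ConsequenceCall(
            variant=_variant(pos, "A", "C"), consequence=consequence,
            transcript_id="t", hgvs_like="x",
            severity_rank=SEVERITY_RANK[consequence],
        )

    def test_splice_donor_first(self):
        calls = [
            self._call(SYNONYMOUS, 100),
            self._call(SPLICE_DONOR, 200),
            self._call(INTRONIC, 300),
        ]
        ranked = rank_candidates(calls)
        assert [c.consequence for c in ranked] == [SPLICE_DONOR, SYNONYMOUS, INTRONIC]

    def test_same_class_position_order_preserved(self):
        calls = [self._call(MISSENSE, p) for p in (10, 20, 30)]
        assert [c.variant.position for c in rank_candidates(calls)] == [10, 20, 30]

    def test_mixed_list_matches_reference_sort(self):
        rng = np.random.default_rng(12)
        classes = list(SEVERITY_RANK)
        calls = [
            self._call(classes[int(rng.integers(len(classes)))], int(rng.integers(1, 500)))
            for _ in range(40)
        ]
        ranked = rank_candidates(calls)
        want = sorted(
            calls, key=lambda c: (-c.severity_rank, c.variant.position)
        )
        assert [(c.consequence, c.variant.position) for c in ranked] == [
            (c.consequence, c.variant.position) for c in want
        ]
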