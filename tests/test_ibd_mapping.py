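"""Shared-region intersection, IBD verdicts and carrier classification."""

import numpy as np
import pytest

from recessmap.genotype_io import HET, HOM_A, HOM_ALT, HOM_B, HOM_REF, MISSING, VariantRecord
from recessmap.ibd_mapping import (
    CarrierStatusCode, HaplotypeQuery, SharedRegion,
    classify_carrier, classify_carriers, concordance_check,
    haplotype_frequency, haplotype_identity, shared_roh_regions,
)
from recessmap.roh_detection import RohSegment
from recessmap.synthetic_data import PanelConfig, generate_panel

from conftest import make_panel


def seg(sample, chrom, start, end, n=30):
    return RohSegment(sample=sample, chromosome=chrom, start_bp=start, end_bp=end, n_snps=n)


class TestSharedRegions:
    def test_pairwise_intersection(self):
        regions = shared_roh_regions({
            "a": [seg("a", "1", 10_000_000, 20_000_000)],
            "b": [seg("b", "1", 15_000_000, 30_000_000)],
        })
        assert [(r.start_bp, r.end_bp) for r in regions] == [(15_000_000, 20_000_000)]
        assert regions[0].identical_haplotype is None

    def test_disjoint_roh_is_empty(self):
        assert shared_roh_regions({
            "a": [seg("a", "1", 1, 10)],
            "b": [seg("b", "1", 20, 30)],
        }) == []

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            shared_roh_regions({"a": []})

    def test_symmetric_and_associative(self):
        rng = np.random.default_rng(21)
        samples = {}
        for name in "abc":
            ivals = sorted(rng.integers(0, 1000, size=8).tolist())
            samples[name] = [
                seg(name, "1", ivals[i] * 1000 + 1, ivals[i + 1] * 1000 + 2000)
                for i in range(0, 8, 2)
            ]
        full = shared_roh_regions(samples)
        perm = shared_roh_regions({k: samples[k] for k in "cab"})
        assert [(r.start_bp, r.end_bp) for r in full] == [
            (r.start_bp, r.end_bp) for r in perm
        ]
        # incremental: intersect (a,b) first, then with c
        ab = shared_roh_regions({k: samples[k] for k in "ab"})
        ab_as_roh = [seg("ab", r.chromosome, r.start_bp, r.end_bp) for r in ab]
        inc = shared_roh_regions({"ab": ab_as_roh, "c": samples["c"]})
        assert [(r.start_bp, r.end_bp) for r in full] == [
            (r.start_bp, r.end_bp) for r in inc
        ]


class TestHaplotypeIdentity:
    def _panel(self, g1, g2, positions=None):
        n = len(g1)
        positions = positions or [10_000 * (i + 1) for i in range(n)]
        return make_panel([g1, g2], positions=positions, samples=["a", "b"])

    def test_identical_when_same_homozygote_everywhere(self):
        panel = self._panel([HOM_A] * 45, [HOM_A] * 45)
        region = SharedRegion("1", 1, 600_000, samples=("a", "b"))
        out = haplotype_identity(panel, region)
        assert out.identical_haplotype is True
        assert out.mismatch_count == 0
        assert out.n_snps == 45

    def test_three_opposite_homozygotes_mismatch(self):
        g2 = [HOM_A] * 45
        for i in (5, 10, 20):
            g2[i] = HOM_B
        out = haplotype_identity(
            self._panel([HOM_A] * 45, g2),
            SharedRegion("1", 1, 600_000, samples=("a", "b")),
        )
        assert out.mismatch_count == 3
        assert out.identical_haplotype is False

    def test_missing_calls_skipped_and_counted(self):
        g2 = [HOM_A, MISSING, HOM_B, HOM_A]
        out = haplotype_identity(
            self._panel([HOM_A] * 4, g2),
            SharedRegion("1", 1, 600_000, samples=("a", "b")),
        )
        assert out.mismatch_count == 1
        assert out.skipped_missing == 1

    def test_empty_region_is_an_error(self):
        panel = self._panel([HOM_A] * 3, [HOM_A] * 3)
        with pytest.raises(ValueError, match="uninformative"):
            haplotype_identity(panel, SharedRegion("1", 900_000, 999_999, samples=("a", "b")))


def _query_panel():
    """5-marker panel; query allele is allele_a everywhere."""
    rows = [
        [HOM_A] * 5,  # hom carrier
        [HET] * 5,  # het carrier
        [HOM_A, HOM_A, HET, HOM_A, HET],  # mixed: still carries everywhere
        [HOM_A, HOM_B, HOM_A, HOM_A, HOM_A],  # lacks at one marker
        [HOM_A, MISSING, HOM_A, HOM_A, HOM_A],  # missing blocks the call
    ]
    panel = make_panel(
        rows, positions=[10, 20, 30, 40, 50],
        samples=["hom", "het", "mixed", "non", "amb"],
    )
    query = HaplotypeQuery(
        markers=panel.markers, alleles=[m.allele_a for m in panel.markers]
    )
    return panel, query


class TestClassifyCarrier:
    @pytest.mark.parametrize(
        "sample,expected",
        [
            ("hom", CarrierStatusCode.HOM_CARRIER),
            ("het", CarrierStatusCode.HET_CARRIER),
            ("mixed", CarrierStatusCode.HET_CARRIER),
            ("non", CarrierStatusCode.NON_CARRIER),
            ("amb", CarrierStatusCode.AMBIGUOUS),
        ],
    )
    def test_statuses(self, sample, expected):
        panel, query = _query_panel()
        assert classify_carrier(panel, query, sample).status is expected

    def test_max_mismatch_tolerates_one_lacking_marker(self):
        panel, query = _query_panel()
        assert (
            classify_carrier(panel, query, "non", max_mismatch=1).status
            is CarrierStatusCode.HOM_CARRIER
        )

    def test_absent_query_marker_is_configuration_error(self):
        panel, query = _query_panel()
        from recessmap.genotype_io import Marker

        stranger = Marker(id="zz9", chromosome="9", position=999, allele_a="A", allele_b="G")
        bad = HaplotypeQuery(markers=[stranger], alleles=["A"])
        with pytest.raises(KeyError):
            classify_carrier(panel, bad, "hom")

    def test_marker_order_permutation_invariance(self):
        panel, query = _query_panel()
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(query.markers))
        shuffled = HaplotypeQuery(
            markers=[query.markers[i] for i in perm],
            alleles=[query.alleles[i] for i in perm],
        )
        for s in panel.samples:
            assert (
                classify_carrier(panel, query, s).status
                is classify_carrier(panel, shuffled, s).status
            )

    def test_planted_cohort_recovered_exactly(self):
        config = PanelConfig(
            seed=17, n_chromosomes=1, n_controls=200,
            planted={"chromosome": "1", "start_bp": 20_000_000, "end_bp": 23_000_000},
            n_planted_het_controls=11, n_planted_hom_controls=2,
        )
        panel, truth = generate_panel(config)
        statuses = classify_carriers(panel, truth.query, samples=truth.control_samples)
        got = {s.sample: s.status for s in statuses}
        assert got == {s: truth.statuses[s] for s in truth.control_samples}
        freq = haplotype_frequency(statuses)
        assert (freq.n_het, freq.n_hom) == (11, 2)


class TestHaplotypeFrequency:
    def test_cohort_of_8557(self):
        from recessmap.ibd_mapping import CarrierStatus

        statuses = [
            CarrierStatus(sample=str(i), status=s)
            for i, s in enumerate(
                [CarrierStatusCode.HET_CARRIER] * 426
                + [CarrierStatusCode.NON_CARRIER] * (8557 - 426)
            )
        ]
        freq = haplotype_frequency(statuses)
        assert freq.frequency == pytest.approx(426 / (2 * 8557))
        assert round(100 * freq.frequency, 1) == 2.5

    def test_no_carriers(self):
        panel, query = _query_panel()
        statuses = classify_carriers(panel, query, samples=["non"])
        assert haplotype_frequency(statuses).frequency == 0.0

    def test_all_ambiguous_is_error(self):
        panel, query = _query_panel()
        statuses = classify_carriers(panel, query, samples=["amb"])
        with pytest.raises(ValueError):
            haplotype_frequency(statuses)

    def test_planted_frequency_recovered_within_binomial_error(self):
        q = 0.28
        config = PanelConfig(
            seed=23, n_chromosomes=1, n_controls=100,
            planted={"chromosome": "1", "start_bp": 20_000_000, "end_bp": 23_000_000},
            carrier_frequency=q, exclude_homozygous_controls=False,
        )
        panel, truth = generate_panel(config)
        statuses = classify_carriers(panel, truth.query, samples=truth.control_samples)
        freq = haplotype_frequency(statuses)
        se = np.sqrt(q * (1 - q) / (2 * 100))
        assert abs(freq.frequency - q) <= 3 * se


class TestConcordance:
    def _statuses(self, panel, query, samples):
        return classify_carriers(panel, query, samples=samples)

    def test_fully_concordant(self):
        panel, query = _query_panel()
        statuses = self._statuses(panel, query, ["hom", "het", "non"])
        variant = VariantRecord(
            chromosome="1", position=25, ref="C", alt="T",
            genotypes={"hom": HOM_ALT, "het": HET, "non": HOM_REF},
        )
        res = concordance_check(statuses, variant)
        assert res.fraction == 1.0
        assert res.discordant_samples == []

    def test_single_discordant_sample_listed(self):
        panel, query = _query_panel()
        statuses = self._statuses(panel, query, ["hom", "het", "non"])
        variant = VariantRecord(
            chromosome="1", position=25, ref="C", alt="T",
            genotypes={"hom": HOM_ALT, "het": HOM_REF, "non": HOM_REF},
        )
        res = concordance_check(statuses, variant)
        assert res.fraction == pytest.approx(2 / 3)
        assert res.discordant_samples == ["het"]

    def test_disjoint_sample_sets_error(self):
        panel, query = _query_panel()
        statuses = self._statuses(panel, query, ["hom"])
        variant = VariantRecord(
            chromosome="1", position=25, ref="C", alt="T", genotypes={"other": HET}
        )
        with pytest.raises(ValueError):
            concordance_check(statuses, variant)

    def test_planted_perfect_ld_cohort(self):
        from recessmap.synthetic_data import generate_variant_cohort

        config = PanelConfig(
            seed=31, n_chromosomes=1, n_controls=118,
            planted={"chromosome": "1", "start_bp": 20_000_000, "end_bp": 23_000_000},
            n_planted_het_controls=30,
        )
        panel, truth = generate_panel(config)
        generate_variant_cohort(truth, 10, {"causal": 0.1}, seed=7)
        statuses = classify_carriers(panel, truth.query, samples=truth.control_samples)
        res = concordance_check(statuses, truth.causal_variant)
        assert res.fraction == 1.0
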