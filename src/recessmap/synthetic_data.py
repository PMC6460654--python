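"""Generators for every input the pipeline consumes, with exact ground truth.

The genotype model is deliberately minimal: markers are sampled
independently at a configurable background heterozygosity (no linkage
disequilibrium beyond the planted haplotype), because no pipeline stage
exploits background LD and independence makes every planted truth exact.
Three constructions keep the truth exact rather than merely likely:

* affected animals ("cases") are homozygous for the planted allele vector
  across the planted interval, embedded in a longer all-homozygous stretch,
  and the first marker flanking each homozygous stretch is forced
  heterozygous so the ROH scan terminates exactly at the planted boundary;
* heterozygous carrier controls carry the complement allele on their second
  haplotype at every planted marker (so at least one het call is certain);
* a non-carrier control whose random background happens to be compatible
  with carriage has one planted-interval genotype flipped to the opposite
  homozygote.

Missing calls are injected everywhere except planted-interval and
boundary markers. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from pydantic import BaseModel, Field, model_validator

from .genotype_io import (
    HET, HOM_A, HOM_ALT, HOM_B, HOM_REF, MISSING,
    GenotypePanel, Marker, VariantRecord, write_vcf_variants,
)
from .ibd_mapping import CarrierStatusCode, HaplotypeQuery
from .splice_consequence import PrimerPair
from .variant_filtering import GeneModel

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


class FixtureError(Exception):
    """Internal consistency check of a generated fixture failed."""


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

class PlantedHaplotype(BaseModel):
    chromosome: str = "25"
    start_bp: int = 25_490_468
    end_bp: int = 28_470_779


class PanelConfig(BaseModel):
    """Cohort structure for the synthetic SNP panel.

    Defaults emulate a ~40k-marker SNP array over 29 autosomes, two
    affected homozygotes and a low-frequency (2.5%) planted haplotype never
    homozygous in controls. Marker spacing defaults to ~42 kb so that a
    planted run clears the scanner's default marker-density bound
    (1 SNP / 50 kb) — a denser, stylized stand-in for real array maps whose
    local density varies around a sparser genome-wide mean.
    """

    n_chromosomes: int = 29
    markers_per_chromosome: int = 1434
    chromosome_length_bp: int = 60_000_000
    n_cases: int = 2
    n_controls: int = 100
    planted: PlantedHaplotype = Field(default_factory=PlantedHaplotype)
    carrier_frequency: float = 0.025
    background_heterozygosity: float = 0.35
    missing_rate: float = 0.0027
    exclude_homozygous_controls: bool = True
    n_planted_hom_controls: int = 0
    n_planted_het_controls: Optional[int] = None  # None: Bernoulli at 2q(1-q)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "PanelConfig":
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise ValueError("carrier_frequency must be in [0, 1]")
        if not 0.0 <= self.background_heterozygosity <= 1.0:
            raise ValueError("background_heterozygosity must be in [0, 1]")
        if not 1 <= int(self.planted.chromosome) <= self.n_chromosomes:
            raise ValueError("planted chromosome outside simulated chromosomes")
        if self.planted.end_bp > self.chromosome_length_bp:
            raise ValueError("planted interval exceeds chromosome length")
        spacing = self.chromosome_length_bp / self.markers_per_chromosome
        interval = self.planted.end_bp - self.planted.start_bp + 1
        n_markers = interval / spacing
        if n_markers < 20 or interval < 500_000:
            raise ValueError(
                f"planted interval ({interval} bp, ~{n_markers:.1f} markers at "
                f"{spacing:.0f} bp spacing) is below the minimum detectable run "
                "(20 contiguous markers / 500 kb); enlarge the interval or "
                "densify the map"
            )
        return self


@dataclass
class SyntheticTruth:
    """Everything needed to score every pipeline stage exactly."""

    case_samples: list[str]
    control_samples: list[str]
    statuses: dict[str, CarrierStatusCode]
    region_chromosome: str
    region_start_bp: int  # position of first planted marker
    region_end_bp: int  # position of last planted marker
    query: HaplotypeQuery
    planted_interval: tuple[int, int]
    causal_variant: Optional[VariantRecord] = None
    expected_stage_counts: Optional[dict[str, int]] = None
    decoy_classes: dict[str, int] = dc_field(default_factory=dict)


def _marker_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    spacing = length / n
    base = (np.arange(n) + 0.5) * spacing
    jitter = rng.uniform(-0.3, 0.3, size=n) * spacing
    pos = np.maximum(np.round(base + jitter).astype(np.int64), 1)
    return np.maximum.accumulate(pos) + np.arange(n)  # strictly increasing


def generate_panel(config: PanelConfig) -> tuple[GenotypePanel, SyntheticTruth]:
    """Generate the cohort panel and its exact ground truth."""
    rng = np.random.default_rng(config.seed)
    h = config.background_heterozygosity
    q = config.carrier_frequency

    markers: list[Marker] = []
    chrom_cols: dict[str, np.ndarray] = {}
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        pos = _marker_positions(rng, config.markers_per_chromosome, config.chromosome_length_bp)
        start_idx = len(markers)
        for k, p in enumerate(pos):
            a, b = rng.choice(4, size=2, replace=False)
            markers.append(
                Marker(
                    id=f"snp_{chrom}_{k + 1}",
                    chromosome=chrom,
                    position=int(p),
                    allele_a=_BASES[a],
                    allele_b=_BASES[b],
                )
            )
        chrom_cols[chrom] = np.arange(start_idx, len(markers))

    cases = [f"case_{i + 1}" for i in range(config.n_cases)]
    controls = [f"ctrl_{i + 1}" for i in range(config.n_controls)]
    samples = cases + controls
    n_samples, n_markers = len(samples), len(markers)

    # background genotypes
    u = rng.random((n_samples, n_markers))
    geno = np.full((n_samples, n_markers), HOM_A, dtype=np.int8)
    geno[u >= h] = np.where(
        rng.random((n_samples, n_markers)) < 0.5, HOM_A, HOM_B
    )[u >= h]
    geno[u < h] = HET

    # planted haplotype
    pl = config.planted
    ccols = chrom_cols[pl.chromosome]
    in_interval = np.array(
        [pl.start_bp <= markers[i].position <= pl.end_bp for i in ccols]
    )
    planted_cols = ccols[in_interval]
    if planted_cols.size < 2:
        raise ValueError("planted interval covers fewer than two markers")
    planted_is_b = rng.random(planted_cols.size) < 0.5
    planted_hom = np.where(planted_is_b, HOM_B, HOM_A).astype(np.int8)
    query = HaplotypeQuery(
        markers=[markers[i] for i in planted_cols],
        alleles=[
            markers[i].allele_b if b else markers[i].allele_a
            for i, b in zip(planted_cols, planted_is_b)
        ],
    )

    protected = set(planted_cols.tolist())
    statuses: dict[str, CarrierStatusCode] = {}

    # cases: planted homozygosity, first case padded by an extra homozygous margin
    first_c, last_c = int(planted_cols[0]), int(planted_cols[-1])
    chrom_first, chrom_last = int(ccols[0]), int(ccols[-1])
    for si, case in enumerate(cases):
        row = cases.index(case)
        geno[row, planted_cols] = planted_hom
        lo, hi = first_c, last_c
        if si == 0:
            lo = max(chrom_first, first_c - int(rng.integers(5, 16)))
            hi = min(chrom_last, last_c + int(rng.integers(5, 16)))
            for col in list(range(lo, first_c)) + list(range(last_c + 1, hi + 1)):
                geno[row, col] = HOM_A if rng.random() < 0.5 else HOM_B
                protected.add(col)
        if lo - 1 >= chrom_first:
            geno[row, lo - 1] = HET
            protected.add(lo - 1)
        if hi + 1 <= chrom_last:
            geno[row, hi + 1] = HET
            protected.add(hi + 1)
        statuses[case] = CarrierStatusCode.HOM_CARRIER

    # control carrier statuses
    n_ctrl = len(controls)
    ctrl_status = np.zeros(n_ctrl, dtype=np.int8)  # 0 non, 1 het, 2 hom
    if config.n_planted_het_controls is not None:
        chosen = rng.choice(n_ctrl, size=config.n_planted_het_controls, replace=False)
        ctrl_status[chosen] = 1
    else:
        copies = rng.binomial(2, q, size=n_ctrl)
        if config.exclude_homozygous_controls:
            copies[copies == 2] = 1  # demote rare homozygous draws to carriers
        ctrl_status[copies == 1] = 1
        ctrl_status[copies == 2] = 2
    if config.n_planted_hom_controls:
        non_idx = np.flatnonzero(ctrl_status == 0)
        hom_pick = rng.choice(non_idx, size=config.n_planted_hom_controls, replace=False)
        ctrl_status[hom_pick] = 2

    planted_het = np.full(planted_cols.size, HET, dtype=np.int8)
    opposite_hom = np.where(planted_is_b, HOM_A, HOM_B).astype(np.int8)
    for ci, ctrl in enumerate(controls):
        row = config.n_cases + ci
        if ctrl_status[ci] == 1:
            geno[row, planted_cols] = planted_het
            statuses[ctrl] = CarrierStatusCode.HET_CARRIER
        elif ctrl_status[ci] == 2:
            geno[row, planted_cols] = planted_hom
            statuses[ctrl] = CarrierStatusCode.HOM_CARRIER
        else:
            g = geno[row, planted_cols]
            lacks = (g != planted_hom) & (g != HET)
            if not lacks.any():
                mid = planted_cols.size // 2
                geno[row, planted_cols[mid]] = opposite_hom[mid]
            statuses[ctrl] = CarrierStatusCode.NON_CARRIER

    # missing calls, away from planted/boundary markers
    if config.missing_rate > 0:
        mask = rng.random((n_samples, n_markers)) < config.missing_rate
        mask[:, sorted(protected)] = False
        geno[mask] = MISSING

    panel = GenotypePanel(markers=markers, samples=samples, genotypes=geno)
    truth = SyntheticTruth(
        case_samples=cases,
        control_samples=controls,
        statuses=statuses,
        region_chromosome=pl.chromosome,
        region_start_bp=markers[first_c].position,
        region_end_bp=markers[last_c].position,
        query=query,
        planted_interval=(pl.start_bp, pl.end_bp),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# variant cohort generation
# ---------------------------------------------------------------------------

def generate_variant_cohort(
    truth: SyntheticTruth,
    n_variants: int,
    fractions: Mapping[str, float],
    seed: int,
    out_path: str | Path | None = None,
    fixture: "CcdcFixture | None" = None,
) -> list[VariantRecord]:
    """Variants with genotypes consistent with ``truth``.

    ``fractions`` gives the share of each planted class among ``n_variants``:
    ``causal`` (capped at one record; the splice-donor variant, at the
    fixture's donor position when a fixture is supplied), ``candidate``
    (survives all three filter criteria), ``control_hom`` (case-homozygous
    but homozygous in a control), ``out_of_region``; the remainder fails the
    case-homozygosity criterion (heterozygous in one case). Expected filter
    stage counts are recorded on ``truth``.
    """
    if sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("class fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    n_causal = min(1, int(round(fractions.get("causal", 0.0) * n_variants)))
    if fractions.get("causal", 0.0) > 0:
        n_causal = 1
    n_candidate = int(round(fractions.get("candidate", 0.0) * n_variants))
    n_control_hom = int(round(fractions.get("control_hom", 0.0) * n_variants))
    n_out = int(round(fractions.get("out_of_region", 0.0) * n_variants))
    n_case_het = n_variants - n_causal - n_candidate - n_control_hom - n_out
    if n_case_het < 0:
        raise ValueError("class counts exceed n_variants")

    chrom = truth.region_chromosome
    lo, hi = truth.region_start_bp, truth.region_end_bp
    forbidden: set[int] = set()
    if fixture is not None:
        span = fixture.model.span
        forbidden = set(range(span[0] - 2, span[1] + 3))

    used: set[int] = set()

    def draw_pos(in_region: bool) -> int:
        while True:
            if in_region:
                p = int(rng.integers(lo, hi + 1))
            else:
                p = int(rng.integers(1, lo)) if rng.random() < 0.5 else int(
                    rng.integers(hi + 1, hi + (hi - lo) + 1)
                )
            if p not in used and p not in forbidden:
                used.add(p)
                return p

    def alleles() -> tuple[str, str]:
        i, j = rng.choice(4, size=2, replace=False)
        return _BASES[i], _BASES[j]

    samples = truth.case_samples + truth.control_samples

    def background_controls(allow_hom: bool) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in truth.control_samples:
            r = rng.random()
            if allow_hom and r < 0.05:
                out[s] = HOM_ALT
            elif r < 0.3:
                out[s] = HET
            else:
                out[s] = HOM_REF
        return out

    records: list[VariantRecord] = []

    if n_causal:
        if fixture is not None:
            pos, ref, alt = fixture.variant.position, fixture.variant.ref, fixture.variant.alt
            used.add(pos)
        else:
            pos = draw_pos(True)
            ref, alt = alleles()
        gts = {s: HOM_ALT for s in truth.case_samples}
        code = {
            CarrierStatusCode.HOM_CARRIER: HOM_ALT,
            CarrierStatusCode.HET_CARRIER: HET,
            CarrierStatusCode.NON_CARRIER: HOM_REF,
        }
        for s in truth.control_samples:
            gts[s] = code.get(truth.statuses[s], HOM_REF)
        records.append(
            VariantRecord(chromosome=chrom, position=pos, ref=ref, alt=alt,
                          genotypes=gts, qualifiers={"planted_class": "causal"})
        )

    for _ in range(n_candidate):
        ref, alt = alleles()
        gts = {s: HOM_ALT for s in truth.case_samples}
        gts.update(background_controls(allow_hom=False))
        records.append(
            VariantRecord(chromosome=chrom, position=draw_pos(True), ref=ref, alt=alt,
                          genotypes=gts, qualifiers={"planted_class": "candidate"})
        )

    for _ in range(n_control_hom):
        ref, alt = alleles()
        gts = {s: HOM_ALT for s in truth.case_samples}
        gts.update(background_controls(allow_hom=False))
        lucky = truth.control_samples[int(rng.integers(len(truth.control_samples)))]
        gts[lucky] = HOM_ALT
        records.append(
            VariantRecord(chromosome=chrom, position=draw_pos(True), ref=ref, alt=alt,
                          genotypes=gts, qualifiers={"planted_class": "control_hom"})
        )

    for _ in range(n_case_het):
        ref, alt = alleles()
        gts = {s: HOM_ALT for s in truth.case_samples}
        gts[truth.case_samples[int(rng.integers(len(truth.case_samples)))]] = HET
        gts.update(background_controls(allow_hom=True))
        records.append(
            VariantRecord(chromosome=chrom, position=draw_pos(True), ref=ref, alt=alt,
                          genotypes=gts, qualifiers={"planted_class": "case_het"})
        )

    for _ in range(n_out):
        ref, alt = alleles()
        gts = {s: HOM_ALT for s in truth.case_samples}
        gts.update(background_controls(allow_hom=True))
        records.append(
            VariantRecord(chromosome=chrom, position=draw_pos(False), ref=ref, alt=alt,
                          genotypes=gts, qualifiers={"planted_class": "out_of_region"})
        )

    records.sort(key=lambda r: (r.chromosome, r.position))
    if n_causal:
        truth.causal_variant = next(
            r for r in records if r.qualifiers.get("planted_class") == "causal"
        )
    truth.decoy_classes = {
        "causal": n_causal, "candidate": n_candidate, "control_hom": n_control_hom,
        "case_het": n_case_het, "out_of_region": n_out,
    }
    truth.expected_stage_counts = {
        "input": n_variants,
        "in_region": n_variants - n_out,
        "case_hom_alt": n_causal + n_candidate + n_control_hom,
        "control_filtered": n_causal + n_candidate,
    }
    if out_path is not None:
        write_vcf_variants(records, samples, out_path)
    return records


# ---------------------------------------------------------------------------
# gene fixture
# ---------------------------------------------------------------------------

@dataclass
class CcdcFixture:
    """A reverse-strand nine-exon gene emulating the asthenospermia locus.

    Synthetic sequence (no real genomic DNA): the exon/intron geometry,
    reading-frame arithmetic and primer architecture embody the documented
    splice-disruption case — a canonical intron-4 donor whose loss activates
    a unique in-exon cryptic GT 10 transcript bases upstream, frameshifting
    the 332-residue protein from residue 155 with a premature stop at
    residue 200 and shortening the diagnostic RT-PCR product from 368 to
    358 bp.
    """

    model: GeneModel
    variant: VariantRecord  # forward-strand C>T at the donor +1 position
    primers: PrimerPair
    domain_c1a32: tuple[int, int] = (127, 221)  # residues; fixture metadata


# exon transcript lengths: 30 nt 5'UTR + 999 nt CDS + 60 nt 3'UTR;
# cumulative CDS per exon runs 100/220/350/472/582/722/822/912/999, placing
# the disrupted donor at coding position 472+1
_EXON_TX_LENGTHS = [130, 120, 130, 122, 110, 140, 100, 90, 147]
_UTR5, _CDS_LEN, _UTR3 = 30, 999, 60


def _random_codon(rng: np.random.Generator, avoid_stop: bool = True) -> str:
    while True:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if not avoid_stop or codon not in _STOPS:
            return codon


def _ac_codon(rng: np.random.Generator) -> str:
    return "".join("AC"[i] for i in rng.integers(0, 2, size=3))


def _build_cds(rng: np.random.Generator) -> str:
    """999-nt CDS satisfying the frameshift geometry; see module docstring."""
    for _ in range(2000):
        codons = ["ATG"]
        codons += [_random_codon(rng) for _ in range(2, 141)]  # codons 2..140
        codons += [_ac_codon(rng) for _ in range(141, 155)]  # codons 141..154
        codons += ["GTA", "ACC", "CAA"]  # 155..157; GT at CDS 463-464
        codon158 = "A" + _random_codon(rng)[:2]
        codons.append(codon158)
        codons += [_random_codon(rng) for _ in range(159, 203)]  # 159..202
        codons += ["ATG", "AAA"]  # 203..204 fix the mutant-frame stop at 608-610
        codons += [_random_codon(rng) for _ in range(205, 333)]  # 205..332
        codons.append("TAA")  # codon 333: wild-type stop
        cds = "".join(codons)
        assert len(cds) == _CDS_LEN

        if any(cds[i : i + 3] in _STOPS for i in range(0, _CDS_LEN - 3, 3)):
            continue
        # mutant frame: codons 155..199 read from CDS 473 in steps of 3
        shifted = [cds[472 + 3 * k : 475 + 3 * k] for k in range(45)]
        if any(t in _STOPS for t in shifted):
            continue
        if cds[608 - 1 : 611 - 1] != "TGA":
            continue
        if str(Seq(cds[472:475]).translate()) in ("V", "*"):
            continue  # mutant residue 155 must differ from wild-type Val
        # exonic search window (CDS 423..472) must hold exactly one GT
        window = cds[422:472]
        if sum(1 for i in range(len(window) - 1) if window[i : i + 2] == "GT") != 1:
            continue
        if window[40:42] != "GT":  # CDS 463-464
            continue
        return cds
    raise FixtureError("could not construct a CDS satisfying all constraints")


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = _BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def generate_ccdc189_fixture(
    seed: int = 0,
    chromosome: str = "25",
    donor_position: int = 27_138_357,
) -> CcdcFixture:
    """Construct the reverse-strand nine-exon gene fixture.

    ``donor_position`` anchors the genomic coordinate of the +1 base of
    intron 4 (transcript orientation), where the packaged forward-strand
    C>T variant destroys the canonical GT. The construction is verified by
    translating both isoforms before the fixture is returned.
    """
    rng = np.random.default_rng(seed)
    cds = _build_cds(rng)
    transcript = _random_seq(rng, _UTR5) + cds + _random_seq(rng, _UTR3)

    intron_lengths = [int(rng.integers(80, 201)) for _ in range(8)]
    intron_lengths[3] = 120
    introns: list[str] = []
    for i, L in enumerate(intron_lengths):
        if i == 3:
            body = _random_seq(rng, 50, "AC") + _random_seq(rng, L - 54)
        else:
            body = _random_seq(rng, L - 4)
        introns.append("GT" + body + "AG")

    # assemble pre-mRNA (transcript strand) and record feature indices
    pre_parts: list[str] = []
    exon_bounds_tx: list[tuple[int, int]] = []  # 0-based [start, end] in pre-mRNA
    intron_starts: list[int] = []
    cursor = 0
    tx_cursor = 0
    for i, L in enumerate(_EXON_TX_LENGTHS):
        exon_seq = transcript[tx_cursor : tx_cursor + L]
        pre_parts.append(exon_seq)
        exon_bounds_tx.append((cursor, cursor + L - 1))
        cursor += L
        tx_cursor += L
        if i < 8:
            intron_starts.append(cursor)
            pre_parts.append(introns[i])
            cursor += len(introns[i])
    pre_mrna = "".join(pre_parts)
    P = len(pre_mrna)

    flank = 50
    donor_idx = intron_starts[3]  # pre-mRNA index of the intron-4 G
    # reverse strand: genomic = flank + revcomp(pre_mrna) + flank
    locus_seq = (
        _random_seq(rng, flank)
        + str(Seq(pre_mrna).reverse_complement())
        + _random_seq(rng, flank)
    )
    # pre-mRNA index k maps to locus index flank + (P - 1 - k)
    seq_offset = donor_position - (flank + (P - 1 - donor_idx))
    if seq_offset < 1:
        raise FixtureError("donor_position too small to place the locus at >= 1")

    def g(k: int) -> int:  # genomic position of pre-mRNA index k
        return seq_offset + flank + (P - 1 - k)

    exons_genomic = sorted((g(b), g(a)) for a, b in exon_bounds_tx)
    cds_first_tx = _UTR5  # 0-based transcript index of CDS first base
    cds_last_tx = _UTR5 + _CDS_LEN - 1
    tx_to_pre = {}
    # transcript index -> pre-mRNA index (exons only)
    ti = 0
    for (a, b) in exon_bounds_tx:
        for k in range(a, b + 1):
            tx_to_pre[ti] = k
            ti += 1
    cds_end_g = g(tx_to_pre[cds_first_tx])  # highest genomic coordinate
    cds_start_g = g(tx_to_pre[cds_last_tx])

    model = GeneModel(
        gene_id="CCDC189_like",
        transcript_id="tx_ccdc189_like",
        chromosome=chromosome,
        strand="-",
        exons=exons_genomic,
        cds_start=cds_start_g,
        cds_end=cds_end_g,
        seq=locus_seq,
        seq_offset=seq_offset,
    )
    variant = VariantRecord(
        chromosome=chromosome, position=donor_position, ref="C", alt="T",
        qualifiers={"planted_class": "causal"},
    )

    fwd = transcript[370:390]  # spans the exon-3/4 junction (tx 371..390)
    rev_site = transcript[718:738]  # inside exon 6 (tx 719..738)
    primers = PrimerPair(
        forward=fwd, reverse=str(Seq(rev_site).reverse_complement())
    )

    _verify_fixture(model, transcript, cds, variant, primers)
    return CcdcFixture(model=model, variant=variant, primers=primers)


def _verify_fixture(
    model: GeneModel, transcript: str, cds: str,
    variant: VariantRecord, primers: PrimerPair,
) -> None:
    """Independent build-time translation of both isoforms (no predictor)."""
    # wild type
    protein = str(Seq(cds).translate())
    if not (protein.endswith("*") and "*" not in protein[:-1] and len(protein) == 333):
        raise FixtureError("wild-type CDS does not translate to 332 residues + stop")
    # the genomic model must reproduce the designed transcript
    rebuilt = "".join(model.tx_seq_of(s, e) for s, e in model.exons_tx())
    if rebuilt != transcript:
        raise FixtureError("genomic model does not reproduce the designed transcript")
    base = model.subseq(variant.position, variant.position)
    if base != variant.ref or model.tx_base(variant.position) != "G":
        raise FixtureError("donor +1 base is not the expected C (forward) / G (transcript)")
    # mutant isoform: drop the last 10 bases of exon 4 (CDS 463..472)
    mut_cds_region = cds[:462] + cds[472:]
    mut_prot, stop = "", False
    for i in range(0, len(mut_cds_region) - 2, 3):
        aa = str(Seq(mut_cds_region[i : i + 3]).translate())
        if aa == "*":
            stop = True
            break
        mut_prot += aa
    if not stop or len(mut_prot) != 199:
        raise FixtureError("mutant frame does not stop at residue 200")
    if mut_prot[:154] != protein[:154] or mut_prot[154] == protein[154]:
        raise FixtureError("mutant protein does not diverge exactly at residue 155")
    # amplicons by direct arithmetic on the designed transcript
    wt_product = 738 - 371 + 1
    if transcript[370:390] != primers.forward:
        raise FixtureError("forward primer does not match the transcript")
    if wt_product != 368:
        raise FixtureError("wild-type amplicon is not 368 bp")


# ---------------------------------------------------------------------------
# fertility tables
# ---------------------------------------------------------------------------

class FertilityTableConfig(BaseModel):
    label: str
    p_case: float
    p_control: float
    n_case: int
    n_control: int

    @model_validator(mode="after")
    def _validate(self) -> "FertilityTableConfig":
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("trial counts must be positive")
        for p in (self.p_case, self.p_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError("success probabilities must be in [0, 1]")
        return self


@dataclass(frozen=True)
class FertilityTable:
    label: str
    k_case: int
    n_case: int
    k_control: int
    n_control: int


def default_fertility_configs() -> list[FertilityTableConfig]:
    """Insemination and IVF outcome arms for affected vs. normal sires."""
    return [
        FertilityTableConfig(label="insemination_conception",
                             p_case=0.0, p_control=42 / 89, n_case=9, n_control=89),
        FertilityTableConfig(label="ivf_cleavage_42h",
                             p_case=36 / 320, p_control=105 / 150, n_case=320, n_control=150),
        FertilityTableConfig(label="ivf_embryo_yield_day9",
                             p_case=3 / 320, p_control=34 / 150, n_case=320, n_control=150),
    ]


def generate_fertility_tables(
    configs: Sequence[FertilityTableConfig] | None = None, seed: int = 0
) -> list[FertilityTable]:
    rng = np.random.default_rng(seed)
    out = []
    for c in configs or default_fertility_configs():
        out.append(
            FertilityTable(
                label=c.label,
                k_case=int(rng.binomial(c.n_case, c.p_case)),
                n_case=c.n_case,
                k_control=int(rng.binomial(c.n_control, c.p_control)),
                n_control=c.n_control,
            )
        )
    return out
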