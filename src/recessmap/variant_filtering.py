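"""Recessive candidate-variant filtering and transcript-model annotation.

The three-criterion recessive filter keeps variants that are (a) inside the
mapped autozygosity interval, (b) homozygous for the non-reference allele in
every affected animal and (c) never homozygous in any control animal.
Surviving variants are classified against a single-transcript gene model
(exons, strand, CDS, locus sequence): canonical splice-site positions are
the first/last two intronic bases in transcript orientation, coding SNVs are
translated in context, and candidates are ranked on a fixed severity ladder
(splice/stop > missense > synonymous > UTR > intronic > intergenic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .genotype_io import HOM_ALT, MISSING, VariantRecord

logger = logging.getLogger(__name__)

SPLICE_DONOR = "splice_donor"
SPLICE_ACCEPTOR = "splice_acceptor"
STOP_GAINED = "stop_gained"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
UTR = "utr"
INTRONIC = "intronic"
INTERGENIC = "intergenic"
COMPLEX = "complex"  # indel spanning an exon/intron boundary: surfaced, not guessed

SEVERITY_RANK = {
    SPLICE_DONOR: 7,
    SPLICE_ACCEPTOR: 7,
    STOP_GAINED: 7,
    MISSENSE: 6,
    SYNONYMOUS: 5,
    UTR: 4,
    INTRONIC: 3,
    INTERGENIC: 2,
    COMPLEX: 1,
}


# ---------------------------------------------------------------------------
# recessive filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterCriteria:
    region_chromosome: str
    region_start: int
    region_end: int
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.case_samples or not self.control_samples:
            raise ValueError("case and control sets must be non-empty")
        if set(self.case_samples) & set(self.control_samples):
            raise ValueError("case and control sets must be disjoint")
        if self.region_start > self.region_end:
            raise ValueError("region start must be <= end")


@dataclass
class FilterResult:
    survivors: list[VariantRecord]
    n_input: int
    n_in_region: int
    n_case_consistent: int
    n_surviving: int
    n_rejected_missing_case: int

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "in_region": self.n_in_region,
            "case_hom_alt": self.n_case_consistent,
            "control_filtered": self.n_surviving,
        }


def filter_recessive_candidates(
    variants: Iterable[VariantRecord], criteria: FilterCriteria
) -> FilterResult:
    """Apply the in-region / case-homozygous / control-absent filter.

    Missing control genotypes never count as homozygous-alternate; a record
    lacking a genotype entry for a case sample is rejected (conservative)
    and tallied separately.
    """
    variants = list(variants)
    in_region: list[VariantRecord] = []
    for v in variants:
        if (
            v.chromosome == criteria.region_chromosome
            and criteria.region_start <= v.position <= criteria.region_end
        ):
            in_region.append(v)

    case_ok: list[VariantRecord] = []
    n_missing_case = 0
    for v in in_region:
        missing_entry = [s for s in criteria.case_samples if s not in v.genotypes]
        if missing_entry:
            n_missing_case += 1
            logger.warning(
                "variant %s:%d lacks genotypes for case(s) %s; rejected",
                v.chromosome, v.position, ",".join(missing_entry),
            )
            continue
        if all(v.genotypes[s] == HOM_ALT for s in criteria.case_samples):
            case_ok.append(v)

    survivors = [
        v for v in case_ok
        if not any(
            v.genotypes.get(s, MISSING) == HOM_ALT for s in criteria.control_samples
        )
    ]
    result = FilterResult(
        survivors=survivors,
        n_input=len(variants),
        n_in_region=len(in_region),
        n_case_consistent=len(case_ok),
        n_surviving=len(survivors),
        n_rejected_missing_case=n_missing_case,
    )
    logger.info("recessive filter stage counts: %s", result.stage_counts)
    return result


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A single-transcript gene model over a locus sequence.

    ``exons`` are genomic (start, end) pairs, 1-based inclusive, sorted and
    non-overlapping; ``seq`` is the forward-strand locus sequence starting
    at genomic position ``seq_offset``. CDS bounds are genomic and include
    the stop codon; the spliced CDS length must be a multiple of three.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    seq: str
    seq_offset: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping and sorted")
        for s, e in self.exons:
            if s > e:
                raise ValueError("exon start must be <= end")
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise ValueError("cds_start falls outside exons")
        if not any(s <= self.cds_end <= e for s, e in self.exons):
            raise ValueError("cds_end falls outside exons")
        if self.span[0] < self.seq_offset or self.span[1] > self.seq_offset + len(self.seq) - 1:
            raise ValueError("locus sequence does not cover the gene span")
        if self.spliced_cds_length % 3 != 0:
            raise ValueError(
                f"spliced CDS length {self.spliced_cds_length} is not a multiple of 3"
            )

    # -- geometry ----------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic introns in genomic order."""
        return [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def exons_tx(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_tx(self) -> list[tuple[int, int]]:
        return self.introns if self.strand == "+" else list(reversed(self.introns))

    def subseq(self, start: int, end: int) -> str:
        """Forward-strand genomic slice, 1-based inclusive."""
        if start < self.seq_offset or end > self.seq_offset + len(self.seq) - 1:
            raise ValueError(f"positions {start}-{end} outside locus sequence")
        return self.seq[start - self.seq_offset : end - self.seq_offset + 1]

    def tx_seq_of(self, start: int, end: int) -> str:
        """Transcript-strand sequence of a genomic interval."""
        s = self.subseq(start, end)
        return s if self.strand == "+" else str(Seq(s).reverse_complement())

    def tx_base(self, pos: int) -> str:
        return self.tx_seq_of(pos, pos)

    @property
    def spliced_cds_length(self) -> int:
        total = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                total += hi - lo + 1
        return total

    def genomic_to_tx(self, pos: int) -> int | None:
        """1-based transcript coordinate of an exonic genomic position."""
        off = 0
        for s, e in self.exons_tx():
            if s <= pos <= e:
                return off + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            off += e - s + 1
        return None

    def tx_to_genomic(self, tx: int) -> int:
        off = 0
        for s, e in self.exons_tx():
            n = e - s + 1
            if tx <= off + n:
                k = tx - off  # 1-based within exon
                return s + k - 1 if self.strand == "+" else e - k + 1
            off += n
        raise ValueError(f"transcript position {tx} beyond transcript end")

    @property
    def cds_tx_bounds(self) -> tuple[int, int]:
        """Transcript coordinates of the CDS first and last base."""
        five = self.cds_start if self.strand == "+" else self.cds_end
        three = self.cds_end if self.strand == "+" else self.cds_start
        a, b = self.genomic_to_tx(five), self.genomic_to_tx(three)
        assert a is not None and b is not None
        return a, b

    def genomic_to_cds(self, pos: int) -> int | None:
        tx = self.genomic_to_tx(pos)
        if tx is None:
            return None
        lo, hi = self.cds_tx_bounds
        if lo <= tx <= hi:
            return tx - lo + 1
        return None


def read_gene_model(tsv_path: str | Path, fasta_path: str | Path) -> GeneModel:
    """Load a gene model from a feature TSV plus a locus FASTA.

    The TSV has a header ``seqid strand feature start end`` (tabs) with
    feature rows ``exon`` and ``CDS``; optional columns ``gene_id`` and
    ``transcript_id`` name the model. The FASTA record id is either the
    chromosome name (offset 1) or ``chrom:start-end`` giving the locus
    placement.
    """
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", dtype={"seqid": str})
    exons = [
        (int(r.start), int(r.end)) for r in df.itertuples() if r.feature == "exon"
    ]
    cds_rows = [(int(r.start), int(r.end)) for r in df.itertuples() if r.feature == "CDS"]
    if not exons or not cds_rows:
        raise ValueError("gene model TSV must contain exon and CDS rows")
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    rid = record.id
    if ":" in rid:
        chrom, rng = rid.split(":", 1)
        offset = int(rng.split("-")[0])
    else:
        chrom, offset = rid, 1
    return GeneModel(
        gene_id=str(df["gene_id"].iloc[0]) if "gene_id" in df else "gene",
        transcript_id=str(df["transcript_id"].iloc[0]) if "transcript_id" in df else "tx",
        chromosome=str(df["seqid"].iloc[0]),
        strand=str(df["strand"].iloc[0]),
        exons=exons,
        cds_start=min(s for s, _ in cds_rows),
        cds_end=max(e for _, e in cds_rows),
        seq=str(record.seq).upper(),
        seq_offset=offset,
    )


def write_gene_model(model: GeneModel, tsv_path: str | Path, fasta_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("seqid\tstrand\tfeature\tstart\tend\tgene_id\ttranscript_id\n")
        for s, e in model.exons:
            fh.write(
                f"{model.chromosome}\t{model.strand}\texon\t{s}\t{e}\t"
                f"{model.gene_id}\t{model.transcript_id}\n"
            )
        fh.write(
            f"{model.chromosome}\t{model.strand}\tCDS\t{model.cds_start}\t"
            f"{model.cds_end}\t{model.gene_id}\t{model.transcript_id}\n"
        )
    end = model.seq_offset + len(model.seq) - 1
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.chromosome}:{model.seq_offset}-{end}\n")
        for i in range(0, len(model.seq), 70):
            fh.write(model.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

@dataclass
class ConsequenceCall:
    variant: VariantRecord
    consequence: str
    transcript_id: str
    hgvs_like: str
    severity_rank: int
    details: dict[str, object] = field(default_factory=dict)


def _tx_allele(model: GeneModel, allele: str) -> str:
    return allele if model.strand == "+" else str(Seq(allele).reverse_complement())


def _splice_site_hit(model: GeneModel, lo: int, hi: int) -> tuple[str, int, int] | None:
    """Check overlap of genomic interval [lo, hi] with +-2 bp splice windows.

    Returns (kind, intron_tx_index, offset_of_lo_end) or None. Offsets are
    in transcript orientation (+1/+2 donor, -1/-2 acceptor).
    """
    for i, (s, e) in enumerate(model.introns_tx()):
        if model.strand == "+":
            donor = (s, min(s + 1, e))
            acceptor = (max(e - 1, s), e)
        else:
            donor = (max(e - 1, s), e)
            acceptor = (s, min(s + 1, e))
        if lo <= donor[1] and hi >= donor[0]:
            pos = hi if model.strand == "-" else lo
            off = (pos - s + 1) if model.strand == "+" else (e - pos + 1)
            return SPLICE_DONOR, i, min(off, 2)
        if lo <= acceptor[1] and hi >= acceptor[0]:
            pos = lo if model.strand == "-" else hi
            off = (e - pos + 1) if model.strand == "+" else (pos - s + 1)
            return SPLICE_ACCEPTOR, i, min(off, 2)
    return None


def _containing_intron(model: GeneModel, lo: int, hi: int) -> int | None:
    for i, (s, e) in enumerate(model.introns_tx()):
        if s <= lo and hi <= e:
            return i
    return None


def _containing_exon(model: GeneModel, lo: int, hi: int) -> int | None:
    for i, (s, e) in enumerate(model.exons_tx()):
        if s <= lo and hi <= e:
            return i
    return None


def _coding_position_label(model: GeneModel, pos: int) -> str:
    """c.-style coordinate for an exonic genomic position."""
    tx = model.genomic_to_tx(pos)
    assert tx is not None
    lo, hi = model.cds_tx_bounds
    if tx < lo:
        return f"-{lo - tx}"
    if tx > hi:
        return f"*{tx - hi}"
    return str(tx - lo + 1)


def annotate_consequence(variant: VariantRecord, model: GeneModel) -> ConsequenceCall:
    """Classify one variant against the transcript model.

    Exactly one consequence class per (variant, transcript). SNVs inside the
    CDS are translated in codon context; the first two intronic bases after
    an exon (transcript orientation) are the splice-donor window and the
    last two the acceptor window. Indels are anchored at their left-aligned
    reference interval; an indel spanning an exon/intron boundary (and any
    in-CDS indel, whose protein outcome is not a single-codon substitution)
    is surfaced as "complex" rather than guessed.
    """
    if variant.chromosome != model.chromosome:
        raise ValueError(
            f"variant chromosome {variant.chromosome} does not match model "
            f"chromosome {model.chromosome}"
        )
    lo, hi = variant.position, variant.end
    span = model.span

    def call(consequence: str, hgvs: str, **details: object) -> ConsequenceCall:
        return ConsequenceCall(
            variant=variant,
            consequence=consequence,
            transcript_id=model.transcript_id,
            hgvs_like=hgvs,
            severity_rank=SEVERITY_RANK[consequence],
            details=details,
        )

    g_hgvs = f"g.{variant.position}{variant.ref}>{variant.alt}"
    if hi < span[0] or lo > span[1]:
        return call(INTERGENIC, g_hgvs)

    ref_t = _tx_allele(model, variant.ref)
    alt_t = _tx_allele(model, variant.alt)

    splice = _splice_site_hit(model, lo, hi)
    if splice is not None:
        kind, intron_i, off = splice
        exons_tx = model.exons_tx()
        if kind == SPLICE_DONOR:
            anchor_exon = exons_tx[intron_i]
            anchor = anchor_exon[1] if model.strand == "+" else anchor_exon[0]
            label = _coding_position_label(model, anchor)
            hgvs = f"c.{label}+{off}{ref_t}>{alt_t}"
        else:
            anchor_exon = exons_tx[intron_i + 1]
            anchor = anchor_exon[0] if model.strand == "+" else anchor_exon[1]
            label = _coding_position_label(model, anchor)
            hgvs = f"c.{label}-{off}{ref_t}>{alt_t}"
        return call(kind, hgvs, intron_index=intron_i)

    if not variant.is_snv:
        exon_i = _containing_exon(model, lo, hi)
        intron_i = _containing_intron(model, lo, hi)
        if exon_i is None and intron_i is None:
            return call(COMPLEX, g_hgvs, reason="indel spans an exon/intron boundary")
        if intron_i is not None:
            return call(INTRONIC, g_hgvs)
        cds_lo = model.genomic_to_cds(lo)
        cds_hi = model.genomic_to_cds(hi)
        if cds_lo is None and cds_hi is None:
            return call(UTR, g_hgvs)
        return call(COMPLEX, g_hgvs, reason="in-CDS indel (not a codon substitution)")

    pos = variant.position
    intron_i = _containing_intron(model, pos, pos)
    if intron_i is not None:
        return call(INTRONIC, g_hgvs, intron_index=intron_i)

    # exonic SNV
    ref_locus = model.subseq(pos, pos)
    if ref_locus != variant.ref:
        logger.warning(
            "reference mismatch at %s:%d (locus %s, variant %s)",
            variant.chromosome, pos, ref_locus, variant.ref,
        )
    cds_pos = model.genomic_to_cds(pos)
    if cds_pos is None:
        label = _coding_position_label(model, pos)
        return call(UTR, f"c.{label}{ref_t}>{alt_t}")

    lo_tx, _ = model.cds_tx_bounds
    codon_index = (cds_pos - 1) // 3  # 0-based
    within = (cds_pos - 1) % 3
    codon_tx_start = lo_tx + 3 * codon_index
    ref_codon = "".join(
        model.tx_base(model.tx_to_genomic(codon_tx_start + k)) for k in range(3)
    )
    alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    hgvs = f"c.{cds_pos}{ref_t}>{alt_t}"
    details = {
        "codon_number": codon_index + 1,
        "ref_codon": ref_codon,
        "alt_codon": alt_codon,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
    }
    if alt_aa == ref_aa:
        return call(SYNONYMOUS, hgvs, **details)
    if alt_aa == "*":
        return call(STOP_GAINED, hgvs, **details)
    return call(MISSENSE, hgvs, **details)


def rank_candidates(calls: Sequence[ConsequenceCall]) -> list[ConsequenceCall]:
    """Sort by severity (descending), then genomic position, stably."""
    return [
        c for _, _, _, c in sorted(
            (
                (-c.severity_rank, c.variant.position, i, c)
                for i, c in enumerate(calls)
            ),
            key=lambda t: t[:3],
        )
    ]
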