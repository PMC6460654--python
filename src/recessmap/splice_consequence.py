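"""Transcript- and protein-level outcome of a splice-donor disruption.

When the canonical GT at a 5' splice donor is destroyed, the spliceosome
falls back on a nearby GT: either an exonic cryptic donor (truncating the
exon tail) or an intronic one (retaining intron head sequence); with no
candidate in range the exon is skipped. The model here is a minimal
nearest-GT rule with a configurable search window — no position-weight-
matrix scoring — which is sufficient to recover an experimentally
demonstrated cryptic site from sequence alone.

The mutant mRNA is rebuilt with the selected site, the coding sequence is
re-translated, and the outcome is summarised as: signed transcript-length
change, frameshift flag, first altered residue, premature-stop residue,
truncation fraction and (optionally) RT-PCR amplicon lengths for a primer
pair. A premature stop more than 50 nt upstream of the last exon-exon
junction is flagged as a likely nonsense-mediated-decay substrate (the
standard 50-nt rule; decay itself is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .genotype_io import VariantRecord
from .variant_filtering import SPLICE_DONOR, GeneModel, annotate_consequence

NMD_JUNCTION_RULE_NT = 50


class SpliceModelError(Exception):
    """The gene model violates a wild-type transcript invariant."""


@dataclass
class Transcript:
    """Mature mRNA with CDS placement and translation."""

    mrna: str
    cds_tx_start: int  # 1-based transcript coordinate of the CDS first base
    cds: str
    protein: str  # translated, stop not included
    exon_tx_lengths: list[int]


@dataclass
class SpliceOutcome:
    disrupted_donor: int  # genomic position of the +1 intronic base
    cryptic_site: Optional[int]  # genomic position of the cryptic GT (None = exon skip)
    cryptic_side: str  # "exonic" | "intronic" | "exon_skip"
    bases_changed: int  # transcript bases removed (<0) or retained (>0)
    frameshift: bool
    altered_from_residue: Optional[int]
    stop_residue: Optional[int]  # premature-stop codon index, 1-based
    truncation_fraction: float
    nmd_likely: bool
    mutant_mrna: str = field(repr=False, default="")
    mutant_protein: str = field(repr=False, default="")


@dataclass
class PrimerPair:
    """Primer sequences; forward in mRNA sense, reverse as its own 5'->3' strand."""

    forward: str
    reverse: str


def build_transcript(model: GeneModel) -> Transcript:
    """Concatenate exons in transcript order and translate the CDS.

    Raises :class:`SpliceModelError` if the wild-type CDS is not a multiple
    of three (already enforced by the model) or contains an internal stop.
    """
    mrna = "".join(model.tx_seq_of(s, e) for s, e in model.exons_tx())
    lo, hi = model.cds_tx_bounds
    cds = mrna[lo - 1 : hi]
    if len(cds) % 3 != 0:
        raise SpliceModelError("spliced CDS length not divisible by 3")
    aa = str(Seq(cds).translate())
    stop_i = aa.find("*")
    if 0 <= stop_i < len(aa) - 1:
        raise SpliceModelError(f"internal stop codon at residue {stop_i + 1}")
    protein = aa[:-1] if aa.endswith("*") else aa
    return Transcript(
        mrna=mrna,
        cds_tx_start=lo,
        cds=cds,
        protein=protein,
        exon_tx_lengths=[e - s + 1 for s, e in model.exons_tx()],
    )


def _donor_intron_index(model: GeneModel, variant: VariantRecord) -> int:
    ann = annotate_consequence(variant, model)
    if ann.consequence != SPLICE_DONOR:
        raise ValueError(
            f"variant {variant.chromosome}:{variant.position} is not a splice-donor "
            f"disruption (annotated {ann.consequence})"
        )
    return int(ann.details["intron_index"])


def _apply_snv(seq: str, offset: int, pos: int, ref: str, alt: str) -> str:
    i = pos - offset
    if seq[i : i + len(ref)] != ref:
        raise ValueError(f"reference allele mismatch at {pos}")
    return seq[:i] + alt + seq[i + len(ref) :]


def predict_splice_outcome(
    model: GeneModel,
    variant: VariantRecord,
    search_window_bp: int = 50,
) -> SpliceOutcome:
    """Select a cryptic donor near the disrupted site and rebuild the transcript.

    Candidate GT dinucleotides on the transcript strand are collected within
    ``search_window_bp`` upstream (exonic) and downstream (intronic) of the
    authentic donor in the *mutant* pre-mRNA; the candidate nearest to the
    authentic site wins, ties broken exonic-first. With no candidate in the
    window the disrupted exon is skipped.
    """
    intron_i = _donor_intron_index(model, variant)
    wt = build_transcript(model)

    mut_seq = _apply_snv(model.seq, model.seq_offset, variant.position, variant.ref, variant.alt)
    mut_model_seq = GeneModel(
        gene_id=model.gene_id, transcript_id=model.transcript_id,
        chromosome=model.chromosome, strand=model.strand, exons=list(model.exons),
        cds_start=model.cds_start, cds_end=model.cds_end,
        seq=mut_seq, seq_offset=model.seq_offset,
    )

    exons_tx = model.exons_tx()
    introns_tx = model.introns_tx()
    ex_s, ex_e = exons_tx[intron_i]
    in_s, in_e = introns_tx[intron_i]
    exon_seq = mut_model_seq.tx_seq_of(ex_s, ex_e)  # transcript-strand exon
    intron_seq = mut_model_seq.tx_seq_of(in_s, in_e)  # mutant intron, donor first

    e_len = len(exon_seq)
    w = search_window_bp
    exon_part = exon_seq[max(0, e_len - w):]
    intron_part = intron_seq[: w + 1]
    window_seq = exon_part + intron_part
    le = len(exon_part)

    candidates: list[tuple[int, int, int]] = []  # (distance, side_rank, j)
    for j in range(len(window_seq) - 1):
        if window_seq[j : j + 2] != "GT":
            continue
        if j < le:
            # exonic: splice after exon base (position of G) - 1
            p_exon = e_len - le + j + 1  # 1-based exon position of the G
            removed = e_len - p_exon + 1
            if 0 < removed <= w:
                candidates.append((removed, 0, j))
        else:
            p_intron = j - le + 1  # 1-based intron position of the G
            retained = p_intron - 1
            if 0 < retained <= w:
                candidates.append((retained, 1, j))

    if not candidates:
        return _exon_skip_outcome(model, wt, intron_i, variant)

    dist, side_rank, j = min(candidates)
    if side_rank == 0:
        bases_changed = -dist
        new_exon = exon_seq[: e_len - dist]
        side = "exonic"
        # genomic position of the cryptic G (transcript-strand)
        exon_pos = e_len - dist + 1
        cryptic_g = (
            ex_s + exon_pos - 1 if model.strand == "+" else ex_e - exon_pos + 1
        )
    else:
        bases_changed = dist
        new_exon = exon_seq + intron_seq[:dist]
        side = "intronic"
        intron_pos = dist + 1
        cryptic_g = (
            in_s + intron_pos - 1 if model.strand == "+" else in_e - intron_pos + 1
        )

    mut_mrna = _rebuild_mrna(model, intron_i, new_exon, mut_model_seq)
    return _finish_outcome(
        model, wt, mut_mrna, bases_changed, side, cryptic_g, variant, intron_i
    )


def _rebuild_mrna(
    model: GeneModel, replace_i: int, new_exon_seq: str | None, seq_model: GeneModel
) -> str:
    parts: list[str] = []
    for i, (s, e) in enumerate(model.exons_tx()):
        if i == replace_i:
            if new_exon_seq is not None:
                parts.append(new_exon_seq)
        else:
            parts.append(seq_model.tx_seq_of(s, e))
    return "".join(parts)


def _exon_skip_outcome(
    model: GeneModel, wt: Transcript, intron_i: int, variant: VariantRecord
) -> SpliceOutcome:
    skipped_len = wt.exon_tx_lengths[intron_i]
    mut_mrna = _rebuild_mrna(model, intron_i, None, model)
    return _finish_outcome(
        model, wt, mut_mrna, -skipped_len, "exon_skip", None, variant, intron_i
    )


def _finish_outcome(
    model: GeneModel,
    wt: Transcript,
    mut_mrna: str,
    bases_changed: int,
    side: str,
    cryptic_g: Optional[int],
    variant: VariantRecord,
    changed_exon_i: int,
) -> SpliceOutcome:
    # CDS start shifts only when the change lies upstream of it
    div = _first_divergence(wt.mrna, mut_mrna)
    cds_start = wt.cds_tx_start
    if div is not None and div < cds_start - 1:
        cds_start += len(mut_mrna) - len(wt.mrna)
    mut_cds_region = mut_mrna[cds_start - 1 :]
    mut_protein, stop_found = _translate_to_stop(mut_cds_region)

    wt_len = len(wt.protein)
    frameshift = bases_changed % 3 != 0

    altered_from: Optional[int] = None
    limit = min(len(mut_protein), wt_len)
    for i in range(limit):
        if mut_protein[i] != wt.protein[i]:
            altered_from = i + 1
            break
    if altered_from is None and len(mut_protein) != wt_len:
        altered_from = limit + 1

    # a stop is premature when the mutant terminates earlier than the length
    # the change itself implies: any shortening under a frameshift, and, for
    # in-frame changes, anything shorter than wild type +- the codon delta
    stop_residue: Optional[int] = None
    if stop_found:
        expected_len = wt_len if frameshift else wt_len + bases_changed // 3
        if len(mut_protein) < expected_len:
            stop_residue = len(mut_protein) + 1

    truncation = 0.0
    if stop_residue is not None:
        truncation = (wt_len - (stop_residue - 1)) / wt_len

    nmd = False
    if stop_residue is not None:
        stop_tx_end = cds_start - 1 + 3 * (stop_residue - 1) + 3  # last nt of stop codon
        junctions = _junction_positions(wt, changed_exon_i, bases_changed)
        if junctions and stop_tx_end < junctions[-1] - NMD_JUNCTION_RULE_NT:
            nmd = True

    return SpliceOutcome(
        disrupted_donor=variant.position,
        cryptic_site=cryptic_g,
        cryptic_side=side,
        bases_changed=bases_changed,
        frameshift=frameshift,
        altered_from_residue=altered_from,
        stop_residue=stop_residue,
        truncation_fraction=truncation,
        nmd_likely=nmd,
        mutant_mrna=mut_mrna,
        mutant_protein=mut_protein,
    )


def _first_divergence(a: str, b: str) -> int | None:
    for i in range(min(len(a), len(b))):
        if a[i] != b[i]:
            return i
    if len(a) != len(b):
        return min(len(a), len(b))
    return None


def _translate_to_stop(seq: str) -> tuple[str, bool]:
    aa: list[str] = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        res = str(Seq(codon).translate())
        if res == "*":
            return "".join(aa), True
        aa.append(res)
    return "".join(aa), False


def _junction_positions(wt: Transcript, changed_exon_i: int, bases_changed: int) -> list[int]:
    """Transcript coordinates of exon-exon junctions in the mutant mRNA.

    Junction k sits after the last base of mutant exon k; a skipped exon
    (length driven to zero) drops one junction, and a length change shifts
    every downstream junction.
    """
    lengths = list(wt.exon_tx_lengths)
    lengths[changed_exon_i] += bases_changed
    out: list[int] = []
    acc = 0
    for i, L in enumerate(lengths):
        if L <= 0:
            continue
        acc += L
        out.append(acc)
    return out[:-1]  # the transcript end is not a junction


def predict_amplicon(
    model: GeneModel,
    outcome: Optional[SpliceOutcome],
    primers: PrimerPair,
) -> Optional[int]:
    """RT-PCR product length on the wild-type (outcome=None) or mutant isoform.

    Primers anneal by exact match: the forward primer as given, the reverse
    primer via its reverse complement. Product length spans the primer outer
    ends. A primer whose sequence (e.g. one spanning an exon-exon junction)
    does not occur in the isoform yields no product (None).
    """
    mrna = build_transcript(model).mrna if outcome is None else outcome.mutant_mrna
    fwd = primers.forward.upper()
    rev_site = str(Seq(primers.reverse.upper()).reverse_complement())
    fi = mrna.find(fwd)
    ri = mrna.rfind(rev_site)
    if fi < 0 or ri < 0:
        return None
    end = ri + len(rev_site)
    if end <= fi:
        raise ValueError("reverse primer anneals upstream of the forward primer")
    if mrna.find(fwd, fi + 1) >= 0 or (ri > 0 and mrna.find(rev_site) != ri):
        raise ValueError("primer anneals at multiple transcript positions")
    return end - fi
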