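"""Reading, validating, filtering and writing SNP-panel genotypes and variants.

Genotype panels use the PLINK 1 binary trio (.bed/.bim/.fam); sequence
variants come from VCF 4.x files. Panel genotypes are stored as a dense
``int8`` matrix (samples x markers) with codes

====  ==========================================
code  meaning
====  ==========================================
 0    homozygous for allele A (.bim allele 1)
 1    heterozygous
 2    homozygous for allele B (.bim allele 2)
-1    missing call
====  ==========================================

Variant genotypes reuse the same integers with hom-ref / het / hom-alt
semantics. All genomic coordinates are 1-based and intervals are inclusive.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# panel genotype codes
HOM_A = 0
HET = 1
HOM_B = 2
MISSING = -1

# variant genotype codes (same integers, hom-ref/-alt semantics)
HOM_REF = 0
HOM_ALT = 2

_BED_MAGIC = b"\x6c\x1b"
_BED_MODE_VARIANT_MAJOR = 0x01
# PLINK 1 two-bit code -> internal code: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([HOM_A, MISSING, HET, HOM_B], dtype=np.int8)
# internal code (+1 so that -1 maps to slot 0) -> two-bit code
_BED_ENCODE = np.array([0b01, 0b00, 0b10, 0b11], dtype=np.uint8)


class GenotypeInputError(Exception):
    """A required input file is missing or unreadable."""


class BedFormatError(Exception):
    """The .bed file violates the PLINK 1 variant-major layout."""


class BedTruncationError(BedFormatError):
    """The .bed payload size is inconsistent with the .bim/.fam dimensions."""


class VcfParseError(Exception):
    """A VCF file could not be parsed."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with a physical map position (1-based)."""

    id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.id}: alleles must differ")


@dataclass
class GenotypePanel:
    """Samples x biallelic SNP genotypes with a physical marker map.

    ``genotypes`` has shape (n_samples, n_markers), dtype int8.
    """

    markers: list[Marker]
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        self._check_marker_order()

    def _check_marker_order(self) -> None:
        prev: tuple[str, int, str] | None = None
        for m in self.markers:
            key = (m.chromosome, m.position, m.id)
            if prev is not None and prev[0] == key[0] and (prev[1], prev[2]) > (key[1], key[2]):
                raise ValueError(
                    f"markers on chromosome {m.chromosome} are not sorted by "
                    f"position (tie-broken by id) near {m.id}"
                )
            prev = key

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in panel") from None

    def marker_callrate(self) -> np.ndarray:
        """Per-marker call rate, i.e. 1 - missing fraction, in [0, 1]."""
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return 1.0 - (self.genotypes == MISSING).mean(axis=0)

    def sample_callrate(self) -> np.ndarray:
        """Per-individual call rate (computed and logged, never filtered on)."""
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return 1.0 - (self.genotypes == MISSING).mean(axis=1)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chromosome, None)
        return list(seen)

    def marker_indices(self, chromosome: str) -> np.ndarray:
        return np.array(
            [i for i, m in enumerate(self.markers) if m.chromosome == chromosome],
            dtype=np.intp,
        )

    def subset_markers(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypePanel(
            markers=[self.markers[i] for i in idx],
            samples=list(self.samples),
            genotypes=self.genotypes[:, idx].copy(),
        )


@dataclass
class VariantRecord:
    """A biallelic sequence variant with per-sample genotype codes."""

    chromosome: str
    position: int
    ref: str
    alt: str
    genotypes: dict[str, int] = field(default_factory=dict)
    qualifiers: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def end(self) -> int:
        """Last reference base covered (1-based inclusive)."""
        return self.position + len(self.ref) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


# ---------------------------------------------------------------------------
# PLINK 1 binary trio
# ---------------------------------------------------------------------------

def _require_file(path: Path) -> Path:
    if not path.exists():
        raise GenotypeInputError(f"required input file is missing: {path}")
    return path


def read_plink_panel(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 variant-major binary trio ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    bed = _require_file(prefix.with_suffix(".bed"))
    bim = _require_file(prefix.with_suffix(".bim"))
    fam = _require_file(prefix.with_suffix(".fam"))

    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = [] if fam_df.empty else list(fam_df[1])
    if len(set(samples)) != len(samples):
        # fall back to FID_IID when within-family ids collide
        samples = [f"{f}_{i}" for f, i in zip(fam_df[0], fam_df[1])]

    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    markers = [
        Marker(id=r[1], chromosome=r[0], position=int(r[3]), allele_a=r[4], allele_b=r[5])
        for r in bim_df.itertuples(index=False)
    ]

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise BedFormatError(f"{bed}: bad magic bytes {raw[:2]!r}, expected 6c 1b")
    if len(raw) < 3 or raw[2] != _BED_MODE_VARIANT_MAJOR:
        raise BedFormatError(f"{bed}: mode byte is not variant-major (0x01)")
    n, m = len(samples), len(markers)
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise BedTruncationError(
            f"{bed}: payload is {len(raw) - 3} bytes, expected "
            f"{bytes_per_marker}*{m}={bytes_per_marker * m} for {n} samples x {m} markers"
        )

    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
    # low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11  # (m, bpm, 4)
    codes = codes.reshape(m, bytes_per_marker * 4)[:, :n]
    genotypes = _BED_DECODE[codes].T.copy()  # (n, m)

    panel = GenotypePanel(markers=markers, samples=samples, genotypes=genotypes)
    if n:
        cr = panel.sample_callrate()
        logger.info(
            "per-individual call-rate: %.2f%% - %.2f%% (mean %.2f%%)",
            100 * cr.min(), 100 * cr.max(), 100 * cr.mean(),
        )
    return panel


def write_plink_panel(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write ``panel`` as a PLINK 1 variant-major trio; round-trips byte-identically."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in panel.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for m in panel.markers:
            fh.write(f"{m.chromosome} {m.id} 0 {m.position} {m.allele_a} {m.allele_b}\n")

    n, m = panel.n_samples, panel.n_markers
    bytes_per_marker = (n + 3) // 4
    out = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    if n:
        out[:, :n] = _BED_ENCODE[panel.genotypes.T + 1]
    packed = (
        out.reshape(m, bytes_per_marker, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_BED_MODE_VARIANT_MAJOR]))
        fh.write(packed.tobytes())


def _is_autosome(chromosome: str) -> bool:
    name = chromosome.removeprefix("chr").removeprefix("Chr")
    return name.isdigit() and int(name) >= 1


def filter_by_callrate(
    panel: GenotypePanel, min_rate: float, autosomes_only: bool = False
) -> GenotypePanel:
    """Retain markers with call rate strictly greater than ``min_rate``.

    With ``autosomes_only``, non-numeric chromosomes (X, Y, MT, 0) are dropped
    as well. The sample set is unchanged and marker order is preserved.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    keep = panel.marker_callrate() > min_rate
    if autosomes_only:
        keep &= np.array([_is_autosome(m.chromosome) for m in panel.markers], dtype=bool)
    return panel.subset_markers(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _genotype_code_for_alt(alleles: tuple[int | None, ...], alt_index: int) -> int:
    """Collapse a called genotype to biallelic codes w.r.t. one alt allele."""
    if len(alleles) == 0 or any(a is None for a in alleles):
        return MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == len(alleles):
        return HOM_ALT
    if n_alt > 0:
        return HET
    return HOM_REF


def read_vcf_variants(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> list[VariantRecord]:
    """Read VCF records, splitting multiallelic sites into biallelic records.

    ``region`` is (chromosome, start, end), 1-based inclusive; records
    overlapping the region are returned. A region on an unknown chromosome
    yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeInputError(f"required input file is missing: {path}")
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: {exc}") from exc
    with vcf:
        sample_names = list(vcf.header.samples)
        try:
            for rec in vcf:
                if region is not None:
                    chrom, start, end = region
                    rec_end = rec.pos + len(rec.ref or "") - 1
                    if rec.chrom != chrom or rec_end < start or rec.pos > end:
                        continue
                for alt_i, alt in enumerate(rec.alts or (), start=1):
                    genotypes = {
                        s: _genotype_code_for_alt(
                            tuple(rec.samples[s].get("GT") or ()), alt_i
                        )
                        for s in sample_names
                    }
                    qualifiers: dict[str, object] = {}
                    if rec.qual is not None:
                        qualifiers["QUAL"] = rec.qual
                    records.append(
                        VariantRecord(
                            chromosome=rec.chrom,
                            position=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            genotypes=genotypes,
                            qualifiers=qualifiers,
                        )
                    )
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"{path}: malformed record: {exc}") from exc
    return records


def write_vcf_variants(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write biallelic records as a minimal VCF 4.2 file (GT only)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = sorted(records, key=lambda r: (r.chromosome, r.position, r.ref, r.alt))
    contigs: dict[str, None] = {}
    for r in recs:
        contigs.setdefault(r.chromosome, None)
    gt_strings = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for r in recs:
            cols = [
                r.chromosome, str(r.position), ".", r.ref, r.alt, ".", ".", ".", "GT",
            ] + [gt_strings[r.genotypes.get(s, MISSING)] for s in samples]
            fh.write("\t".join(cols) + "\n")
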