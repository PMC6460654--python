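"""Cross-sample intersection of ROH, haplotype identity (IBD) and carriers.

Within a run of homozygosity the genotype *is* the haplotype, so whether two
affected animals are autozygous for the same ancestral segment is decidable
from unphased genotypes alone: a shared homozygous region is identical by
descent exactly when the two animals never carry different homozygous
genotypes at the same marker inside it. Carrier classification in a cohort
uses the same unphased compatibility logic against a query allele vector.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype_io import HET, HOM_A, HOM_B, MISSING, GenotypePanel, Marker, VariantRecord
from .roh_detection import RohSegment

logger = logging.getLogger(__name__)


@dataclass
class SharedRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    samples: tuple[str, ...]
    n_snps: int | None = None
    identical_haplotype: bool | None = None
    mismatch_count: int | None = None
    skipped_missing: int = 0
    skipped_het: int = 0

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1e6


class CarrierStatusCode(str, enum.Enum):
    HOM_CARRIER = "hom_carrier"
    HET_CARRIER = "het_carrier"
    NON_CARRIER = "non_carrier"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CarrierStatus:
    sample: str
    status: CarrierStatusCode


@dataclass
class HaplotypeQuery:
    """An ordered run of adjacent markers with one associated allele each."""

    markers: list[Marker]
    alleles: list[str]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.alleles):
            raise ValueError("one allele per marker required")
        chroms = {m.chromosome for m in self.markers}
        if len(chroms) > 1:
            raise ValueError("query markers must lie on one chromosome")
        for m, a in zip(self.markers, self.alleles):
            if a not in (m.allele_a, m.allele_b):
                raise ValueError(f"allele {a} is not an allele of marker {m.id}")


@dataclass
class CarrierFrequency:
    n_het: int
    n_hom: int
    n_non: int
    n_ambiguous: int
    frequency: float

    @property
    def n_unambiguous(self) -> int:
        return self.n_het + self.n_hom + self.n_non


# ---------------------------------------------------------------------------
# shared regions and haplotype identity
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_roh_regions(
    roh_by_sample: Mapping[str, Sequence[RohSegment]]
) -> list[SharedRegion]:
    """Maximal intervals covered by an ROH in every sample.

    Symmetric in sample order and associative under incremental sample
    addition (interval intersection is). Haplotype identity is left unset.
    """
    if len(roh_by_sample) < 2:
        raise ValueError("shared regions need at least two samples")
    samples = tuple(sorted(roh_by_sample))
    chroms: dict[str, None] = {}
    for segs in roh_by_sample.values():
        for s in segs:
            chroms.setdefault(s.chromosome, None)
    regions: list[SharedRegion] = []
    for chrom in sorted(chroms, key=lambda c: (len(c), c)):
        current: list[tuple[int, int]] | None = None
        for sample in samples:
            ivals = _merge(
                [(s.start_bp, s.end_bp) for s in roh_by_sample[sample]
                 if s.chromosome == chrom]
            )
            current = ivals if current is None else _intersect(current, ivals)
            if not current:
                break
        for s, e in current or []:
            regions.append(
                SharedRegion(chromosome=chrom, start_bp=s, end_bp=e, samples=samples)
            )
    return regions


def haplotype_identity(panel: GenotypePanel, region: SharedRegion) -> SharedRegion:
    """Decide whether the contributing samples are IBD across ``region``.

    A marker mismatches when two samples carry *different homozygous*
    genotypes there; markers with a missing call in any sample are skipped
    and counted separately (as are heterozygous calls, which cannot occur
    inside a zero-het ROH but are tolerated here).
    """
    idx = [
        i for i in panel.marker_indices(region.chromosome)
        if region.start_bp <= panel.markers[i].position <= region.end_bp
    ]
    if not idx:
        raise ValueError(
            f"region {region.chromosome}:{region.start_bp}-{region.end_bp} "
            "contains no panel markers (uninformative)"
        )
    rows = [panel.sample_index(s) for s in region.samples]
    g = panel.genotypes[np.ix_(rows, idx)]
    missing_any = (g == MISSING).any(axis=0)
    het_any = (g == HET).any(axis=0)
    informative = ~missing_any & ~het_any
    gi = g[:, informative]
    mismatches = int(((gi == HOM_A).any(axis=0) & (gi == HOM_B).any(axis=0)).sum())
    return replace(
        region,
        n_snps=len(idx),
        mismatch_count=mismatches,
        identical_haplotype=(mismatches == 0),
        skipped_missing=int(missing_any.sum()),
        skipped_het=int((het_any & ~missing_any).sum()),
    )


# ---------------------------------------------------------------------------
# carrier classification
# ---------------------------------------------------------------------------

def _status_from_counts(n_hom_q: int, n_het_q: int, n_lack: int, max_mismatch: int) -> CarrierStatusCode:
    if n_lack > max_mismatch:
        return CarrierStatusCode.NON_CARRIER
    if n_het_q + n_lack <= max_mismatch and n_hom_q > 0:
        return CarrierStatusCode.HOM_CARRIER
    if n_het_q > 0:
        return CarrierStatusCode.HET_CARRIER
    return CarrierStatusCode.HOM_CARRIER if n_hom_q > 0 else CarrierStatusCode.AMBIGUOUS


def _query_columns(panel: GenotypePanel, query: HaplotypeQuery):
    """Panel column indices and query-homozygote codes for a query."""
    marker_pos = {m.id: i for i, m in enumerate(panel.markers)}
    idx, hom_q = [], []
    for m, allele in zip(query.markers, query.alleles):
        if m.id not in marker_pos:
            raise KeyError(f"query marker {m.id} absent from panel")
        idx.append(marker_pos[m.id])
        hom_q.append(HOM_A if allele == m.allele_a else HOM_B)
    return np.asarray(idx, dtype=np.intp), np.asarray(hom_q, dtype=np.int8)


def _classify_row(g: np.ndarray, hom_q: np.ndarray, max_mismatch: int) -> CarrierStatusCode:
    n_missing = int((g == MISSING).sum())
    n_het_q = int((g == HET).sum())
    n_hom_q = int((g == hom_q).sum())
    n_lack = g.size - n_missing - n_het_q - n_hom_q
    optimistic = _status_from_counts(n_hom_q + n_missing, n_het_q, n_lack, max_mismatch)
    pessimistic = _status_from_counts(n_hom_q, n_het_q, n_lack + n_missing, max_mismatch)
    return optimistic if optimistic == pessimistic else CarrierStatusCode.AMBIGUOUS


def classify_carrier(
    panel: GenotypePanel,
    query: HaplotypeQuery,
    sample: str,
    max_mismatch: int = 0,
) -> CarrierStatus:
    """Unphased compatibility classification of one sample against a query.

    hom_carrier: homozygous for the query allele at every marker (up to
    ``max_mismatch`` exceptions); het_carrier: every genotype contains the
    query allele and at least one is heterozygous; non_carrier: the query
    allele is absent at more than ``max_mismatch`` markers. Missing calls
    make the call ambiguous whenever resolving them either way (all query
    homozygous vs. all lacking) would change the verdict.
    """
    idx, hom_q = _query_columns(panel, query)
    g = panel.genotypes[panel.sample_index(sample), idx]
    return CarrierStatus(sample=sample, status=_classify_row(g, hom_q, max_mismatch))


def classify_carriers(
    panel: GenotypePanel,
    query: HaplotypeQuery,
    samples: Sequence[str] | None = None,
    max_mismatch: int = 0,
) -> list[CarrierStatus]:
    samples = list(samples or panel.samples)
    idx, hom_q = _query_columns(panel, query)
    rows = np.asarray([panel.sample_index(s) for s in samples], dtype=np.intp)
    sub = panel.genotypes[np.ix_(rows, idx)]
    return [
        CarrierStatus(sample=s, status=_classify_row(sub[k], hom_q, max_mismatch))
        for k, s in enumerate(samples)
    ]


def haplotype_frequency(statuses: Iterable[CarrierStatus]) -> CarrierFrequency:
    """Haplotype frequency (n_het + 2 n_hom) / (2 n_unambiguous)."""
    n_het = n_hom = n_non = n_amb = 0
    for s in statuses:
        if s.status is CarrierStatusCode.HET_CARRIER:
            n_het += 1
        elif s.status is CarrierStatusCode.HOM_CARRIER:
            n_hom += 1
        elif s.status is CarrierStatusCode.NON_CARRIER:
            n_non += 1
        else:
            n_amb += 1
    n_unamb = n_het + n_hom + n_non
    if n_unamb == 0:
        raise ValueError("all statuses ambiguous; frequency undefined")
    freq = (n_het + 2 * n_hom) / (2 * n_unamb)
    return CarrierFrequency(
        n_het=n_het, n_hom=n_hom, n_non=n_non, n_ambiguous=n_amb, frequency=freq
    )


@dataclass
class ConcordanceResult:
    n_compared: int
    n_concordant: int
    discordant_samples: list[str] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        if self.n_compared == 0:
            raise ValueError("no samples compared")
        return self.n_concordant / self.n_compared


_STATUS_TO_VARIANT_CODE = {
    CarrierStatusCode.HOM_CARRIER: 2,
    CarrierStatusCode.HET_CARRIER: 1,
    CarrierStatusCode.NON_CARRIER: 0,
}


def concordance_check(
    statuses: Sequence[CarrierStatus], variant: VariantRecord
) -> ConcordanceResult:
    """Agreement between haplotype status classes and variant genotype classes.

    Ambiguous statuses and missing variant genotypes are excluded from the
    comparison; discordant samples are listed.
    """
    shared = [s for s in statuses if s.sample in variant.genotypes]
    if not shared:
        raise ValueError("status and variant sample sets are disjoint")
    n_comp = n_conc = 0
    discordant: list[str] = []
    for s in shared:
        expected = _STATUS_TO_VARIANT_CODE.get(s.status)
        observed = variant.genotypes[s.sample]
        if expected is None or observed == MISSING:
            continue
        n_comp += 1
        if observed == expected:
            n_conc += 1
        else:
            discordant.append(s.sample)
    return ConcordanceResult(
        n_compared=n_comp, n_concordant=n_conc, discordant_samples=discordant
    )
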