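"""Germline-specific read identification: three marker channels + expansion.

The classifier flags high-confidence germline (GRC-derived) reads through
three independent channels, then recruits everything sharing a linked-read
barcode with a flagged read:

(a) *region*: reads overlapping (by >= 10 bp) regions of the germline
    assembly >= 500 bp long that are fully covered by testis reads and
    untouched by kidney reads;
(b) *snp_kmer*: reads containing a diagnostic k-mer built around a SNP
    present in every testis sample and absent from every kidney sample,
    after removing any k-mer seen in the kidney read set;
(c) *repeat*: reads matching a germline-restricted repeat consensus with
    >= 100 bp and > 90% identity.

Variant calling is a deliberately naive pileup (>= 2 alt-supporting reads
per sample, no quality weighting): at realistic depths the real gate is the
all-testis / no-kidney tissue filter, not the caller.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Union

import numpy as np

from .io import AlignmentRecord, CoverageTrack, GenomicInterval, ReadRecord
from .seqs import encode, revcomp

__all__ = [
    "VariantCall",
    "BarcodeSelection",
    "germline_specific_regions",
    "reads_overlapping",
    "call_variants_pileup",
    "germline_specific_snps",
    "snp_to_kmers",
    "filter_kmers_against_soma",
    "match_kmers",
    "repeat_reads",
    "expand_barcodes",
]

ReadAlignment = tuple[ReadRecord, AlignmentRecord]


@dataclass
class VariantCall:
    """One candidate SNP site with per-(sample, tissue) support."""

    scaffold: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    # (sample, tissue) -> (alt-supporting reads, total depth)
    support: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class BarcodeSelection:
    """Selected barcodes with the channel(s) that selected each."""

    barcodes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def add(self, barcode: str, channel: str) -> None:
        self.barcodes.add(barcode)
        self.provenance.setdefault(barcode, set()).add(channel)

    def merge(self, other: "BarcodeSelection") -> "BarcodeSelection":
        out = BarcodeSelection(set(self.barcodes), {b: set(c) for b, c in self.provenance.items()})
        for b, chans in other.provenance.items():
            for c in chans:
                out.add(b, c)
        return out

    def __len__(self) -> int:
        return len(self.barcodes)


# ---------------------------------------------------------------------------
# Channel (a): germline-specific regions
# ---------------------------------------------------------------------------

def germline_specific_regions(
    testis_cov: CoverageTrack, kidney_cov: CoverageTrack, min_len: int = 500
) -> list[GenomicInterval]:
    """Maximal runs with testis depth >= 1 and kidney depth = 0, length >= min_len."""
    if testis_cov.scaffold != kidney_cov.scaffold:
        raise ValueError("coverage tracks are on different scaffolds")
    t = np.asarray(testis_cov.depth)
    k = np.asarray(kidney_cov.depth)
    if len(t) != len(k):
        raise ValueError(
            f"track length mismatch on {testis_cov.scaffold}: {len(t)} vs {len(k)}"
        )
    mask = (t >= 1) & (k == 0)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= min_len
    return [
        GenomicInterval(testis_cov.scaffold, int(s), int(e))
        for s, e in zip(starts[keep], ends[keep])
    ]


def _iter_pairs(
    alignments: Iterable[Union[AlignmentRecord, ReadAlignment]],
    barcodes: Optional[Mapping[str, Optional[str]]] = None,
) -> Iterator[tuple[Optional[str], AlignmentRecord]]:
    """Normalise (read, alignment) pairs or bare alignments to (barcode, alignment)."""
    for item in alignments:
        if isinstance(item, AlignmentRecord):
            bc = barcodes.get(item.query_id) if barcodes else None
            yield bc, item
        else:
            read, aln = item
            yield read.barcode, aln


def reads_overlapping(
    regions: list[GenomicInterval],
    alignments: Iterable[Union[AlignmentRecord, ReadAlignment]],
    min_overlap: int = 10,
    barcodes: Optional[Mapping[str, Optional[str]]] = None,
) -> BarcodeSelection:
    """Barcodes of reads whose alignment overlaps any region by >= min_overlap.

    Reads without a barcode can satisfy the overlap rule but contribute no
    barcode (they cannot recruit companions).
    """
    by_scaffold: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
    for r in sorted(regions):
        starts, ivs = by_scaffold.setdefault(r.scaffold, ([], []))
        starts.append(r.start)
        ivs.append(r)
    selection = BarcodeSelection()
    for bc, aln in _iter_pairs(alignments, barcodes):
        if bc is None:
            continue
        entry = by_scaffold.get(aln.target.scaffold)
        if entry is None:
            continue
        starts, ivs = entry
        # regions are disjoint & sorted: candidates are the region starting
        # at or before the alignment plus any region starting inside it
        j = max(0, bisect_left(starts, aln.target.start + 1) - 1)
        while j < len(ivs) and ivs[j].start < aln.target.end:
            if ivs[j].overlap(aln.target) >= min_overlap:
                selection.add(bc, "region")
                break
            j += 1
    return selection


# ---------------------------------------------------------------------------
# Channel (b): germline-specific SNPs and diagnostic k-mers
# ---------------------------------------------------------------------------

def call_variants_pileup(
    alignments_by_sample: Mapping[tuple[str, str], Iterable[ReadAlignment]],
    reference: Mapping[str, str],
    min_alt_reads: int = 2,
) -> list[VariantCall]:
    """Naive pileup SNP caller over ungapped alignments.

    A site is called when at least one sample shows >= ``min_alt_reads``
    reads supporting the same alternative allele; support (alt count, total
    depth) is then recorded for every sample at that site.  Sites where the
    reference base is N are skipped.  Alignments must be ungapped with
    per-base query/target correspondence (minus-strand reads are compared
    after reverse complementing).
    """
    ref_enc = {name: encode(seq) for name, seq in reference.items()}
    # per sample: scaffold -> depth diff array; and alt counts per site
    depth_diffs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    alt_counts: dict[tuple[str, str], dict[tuple[str, int, int], int]] = {}
    for key, pairs in alignments_by_sample.items():
        diffs: dict[str, np.ndarray] = {
            name: np.zeros(len(seq) + 1, dtype=np.int32) for name, seq in reference.items()
        }
        counts: dict[tuple[str, int, int], int] = {}
        for read, aln in pairs:
            scaf = aln.target.scaffold
            ref_arr = ref_enc.get(scaf)
            if ref_arr is None:
                continue
            start, end = aln.target.start, aln.target.end
            seq = read.sequence
            if aln.target.strand == "-":
                seq = revcomp(seq)
            q = encode(seq[aln.query_start : aln.query_end])
            r = ref_arr[start:end]
            if len(q) != len(r):
                raise ValueError(f"{aln.query_id}: alignment is not ungapped per-base")
            diffs[scaf][start] += 1
            diffs[scaf][end] -= 1
            for off in np.flatnonzero(q != r):
                base = q[off]
                if base > 3 or r[off] > 3:  # read N or reference N
                    continue
                site = (scaf, start + int(off), int(base))
                counts[site] = counts.get(site, 0) + 1
        depth_diffs[key] = diffs
        alt_counts[key] = counts

    depths = {
        key: {name: np.cumsum(d[:-1]) for name, d in diffs.items()}
        for key, diffs in depth_diffs.items()
    }

    # candidate sites: any sample with >= min_alt_reads on one allele
    candidates: dict[tuple[str, int], int] = {}
    tally: dict[tuple[str, int, int], int] = {}
    for counts in alt_counts.values():
        for site, n in counts.items():
            tally[site] = tally.get(site, 0) + n
    for key, counts in alt_counts.items():
        for (scaf, pos, base), n in counts.items():
            if n >= min_alt_reads:
                prev = candidates.get((scaf, pos))
                if prev is None or (
                    tally[(scaf, pos, base)],
                    -base,
                ) > (tally[(scaf, pos, prev)], -prev):
                    candidates[(scaf, pos)] = base

    bases = "ACGTN"
    calls = []
    for (scaf, pos), alt in sorted(candidates.items()):
        ref_base = reference[scaf][pos].upper()
        if ref_base == "N":
            continue
        support = {}
        for key in alignments_by_sample:
            n_alt = alt_counts[key].get((scaf, pos, alt), 0)
            depth = int(depths[key][scaf][pos])
            support[key] = (n_alt, depth)
        calls.append(VariantCall(scaf, pos, ref_base, bases[alt], support))
    return calls


def germline_specific_snps(
    calls: list[VariantCall], min_alt_reads: int = 2
) -> list[VariantCall]:
    """Keep calls supported in every testis sample and in no kidney sample."""
    out = []
    for call in calls:
        testis = [(n, d) for (s, t), (n, d) in call.support.items() if t == "testis"]
        kidney = [(n, d) for (s, t), (n, d) in call.support.items() if t == "kidney"]
        if not testis:
            continue
        if all(n >= min_alt_reads for n, _ in testis) and all(n == 0 for n, _ in kidney):
            out.append(call)
    return out


def snp_to_kmers(call: VariantCall, reference: Mapping[str, str], k: int = 29) -> set[str]:
    """All k-length windows of the alt-substituted reference containing the site.

    An interior variant yields exactly ``k`` k-mers; a variant within
    ``k - 1`` bp of a contig end yields fewer (the signal is kept rather
    than discarded).
    """
    seq = reference[call.scaffold]
    pos = call.position
    mutated = seq[:pos] + call.alt_allele + seq[pos + 1 :]
    lo = max(0, pos - k + 1)
    hi = min(pos, len(seq) - k)
    return {mutated[i : i + k] for i in range(lo, hi + 1)}


def _kmer_lookup(kmers: Iterable[str]) -> tuple[dict[str, str], int]:
    """Map every k-mer and its reverse complement to the original k-mer."""
    lookup: dict[str, str] = {}
    k = None
    for kmer in kmers:
        if k is None:
            k = len(kmer)
        elif len(kmer) != k:
            raise ValueError("k-mers of mixed length")
        lookup[kmer] = kmer
        lookup[revcomp(kmer)] = kmer
    return lookup, (k or 0)


def _read_sequences(reads: Iterable[Union[ReadRecord, str]]) -> Iterator[tuple[Optional[ReadRecord], str]]:
    for r in reads:
        if isinstance(r, str):
            yield None, r
        else:
            yield r, r.sequence


def filter_kmers_against_soma(
    kmers: set[str], kidney_reads: Iterable[Union[ReadRecord, str]]
) -> set[str]:
    """Remove every k-mer occurring (either strand) in any kidney read."""
    if not kmers:
        return set()
    lookup, k = _kmer_lookup(kmers)
    seen: set[str] = set()
    for _, seq in _read_sequences(kidney_reads):
        for i in range(len(seq) - k + 1):
            hit = lookup.get(seq[i : i + k])
            if hit is not None:
                seen.add(hit)
    return set(kmers) - seen


def match_kmers(
    kmers: set[str], testis_reads: Iterable[ReadRecord]
) -> BarcodeSelection:
    """Barcodes of testis reads containing any surviving k-mer (either strand)."""
    selection = BarcodeSelection()
    if not kmers:
        return selection
    lookup, k = _kmer_lookup(kmers)
    for read in testis_reads:
        if read.barcode is None:
            continue
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in lookup:
                selection.add(read.barcode, "snp_kmer")
                break
    return selection


# ---------------------------------------------------------------------------
# Channel (c): germline-restricted repeat
# ---------------------------------------------------------------------------

def repeat_reads(
    repeat_consensus: str,
    alignments: Iterable[Union[AlignmentRecord, ReadAlignment]],
    min_len: int = 100,
    min_identity: float = 0.90,
    barcodes: Optional[Mapping[str, Optional[str]]] = None,
) -> BarcodeSelection:
    """Barcodes of reads matching the repeat with >= min_len bp and > min_identity.

    ``alignments`` are read-vs-consensus alignments (from the built-in
    mapper or an external aligner).  The identity threshold is strict
    (greater than), the length threshold inclusive (at least).
    """
    if not repeat_consensus:
        raise ValueError("empty repeat consensus")
    selection = BarcodeSelection()
    for bc, aln in _iter_pairs(alignments, barcodes):
        if bc is None:
            continue
        if aln.block_len >= min_len and aln.identity > min_identity:
            selection.add(bc, "repeat")
    return selection


# ---------------------------------------------------------------------------
# Barcode expansion
# ---------------------------------------------------------------------------

def expand_barcodes(
    selection: BarcodeSelection, all_reads: Iterable[ReadRecord]
) -> list[ReadRecord]:
    """All reads whose barcode was selected by any channel.

    Reads without barcodes are never recruited.
    """
    return [r for r in all_reads if r.barcode is not None and r.barcode in selection.barcodes]
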