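"""A minimal exact-seed, ungapped-extension mapper for toy genomes.

Because the simulator is substitution-only, every true placement is a
full-length ungapped alignment, so seed-and-extend on exact k-mer seeds
with Hamming scoring recovers it.  Real data should use a production
aligner; its PAF output substitutes for this module at every call site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io import AlignmentRecord, GenomicInterval, ReadRecord
from .seqs import encode, revcomp

__all__ = ["SeedIndex", "build_index", "map_read", "map_sequences"]


@dataclass
class SeedIndex:
    """Canonical k-mer -> [(scaffold, position, strand)] over all scaffolds.

    ``strand`` is '+' when the forward genomic k-mer at that position equals
    the canonical form, '-' when its reverse complement does.  Palindromic
    seeds are stored once per position (strand '+').
    """

    k: int
    seeds: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    _encoded: dict[str, np.ndarray] = field(default_factory=dict)


def build_index(sequences: dict[str, str], k: int) -> SeedIndex:
    """Index every k-mer of every scaffold in canonical form."""
    if not sequences:
        raise ValueError("no sequences to index")
    shortest = min(len(s) for s in sequences.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest scaffold length {shortest}")
    index = SeedIndex(k=k)
    for name, seq in sequences.items():
        index.lengths[name] = len(seq)
        index._encoded[name] = encode(seq)
        for i in range(len(seq) - k + 1):
            fwd = seq[i : i + k]
            rc = revcomp(fwd)
            canon, strand = (fwd, "+") if fwd <= rc else (rc, "-")
            index.seeds.setdefault(canon, []).append((name, i, strand))
    return index


def map_read(read: ReadRecord, index: SeedIndex) -> list[AlignmentRecord]:
    """Map one read (or an arbitrary query sequence) against the index.

    Seeds are chained per (scaffold, strand, diagonal); each candidate
    diagonal is scored by full-length Hamming comparison.  Records are
    sorted by ascending mismatches, ties broken by (scaffold, position);
    ``unique`` is True iff the best placement strictly beats all others.
    """
    seq = read.sequence
    k = index.k
    if len(seq) < k:
        return []
    fwd_enc = encode(seq)
    rev_seq = revcomp(seq)
    rev_enc = encode(rev_seq)
    rl = len(seq)

    candidates: set[tuple[str, int, str]] = set()
    for j in range(rl - k + 1):
        kmer = seq[j : j + k]
        rc = revcomp(kmer)
        canon = kmer if kmer <= rc else rc
        read_fwd_is_canon = kmer <= rc
        for scaffold, pos, strand in index.seeds.get(canon, ()):
            # read aligns forward iff its forward k-mer equals the genomic one
            forward = read_fwd_is_canon == (strand == "+")
            if forward:
                start = pos - j
            else:
                # reverse-complemented read laid forward on the genome
                start = pos - (rl - k - j)
            if 0 <= start and start + rl <= index.lengths[scaffold]:
                candidates.add((scaffold, start, "+" if forward else "-"))

    records = []
    for scaffold, start, strand in candidates:
        target = index._encoded[scaffold][start : start + rl]
        query = fwd_enc if strand == "+" else rev_enc
        mm = int(np.count_nonzero(query != target))
        records.append((mm, scaffold, start, strand))
    records.sort(key=lambda t: (t[0], t[1], t[2]))
    if not records:
        return []
    best_mm = records[0][0]
    n_best = sum(1 for r in records if r[0] == best_mm)
    unique = n_best == 1
    out = []
    for mm, scaffold, start, strand in records:
        out.append(
            AlignmentRecord(
                query_id=read.read_id,
                query_start=0,
                query_end=rl,
                target=GenomicInterval(scaffold, start, start + rl, strand),
                matches=rl - mm,
                block_len=rl,
                mapq=60 if unique else 0,
                unique=unique and mm == best_mm,
            )
        )
    return out


def map_sequences(
    queries: dict[str, str], index: SeedIndex, best_only: bool = True
) -> list[AlignmentRecord]:
    """Map named sequences (e.g. GRC scaffolds) against the index."""
    out: list[AlignmentRecord] = []
    for name, seq in queries.items():
        recs = map_read(ReadRecord(read_id=name, sequence=seq), index)
        if best_only and recs:
            best = recs[0].mismatches
            recs = [r for r in recs if r.mismatches == best]
        out.extend(recs)
    return out
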