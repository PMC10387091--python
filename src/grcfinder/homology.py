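"""Cross-species GRC homology classes, A-chromosome origin, divergence polarity.

Every base of each species' GRC assembly gets exactly one label:

* ``homologous`` — covered by a direct alignment to the other species' GRC;
* ``potentially_homologous`` — not directly shared, but originating from an
  A-chromosome region whose merged footprint (alignments within 10 kbp
  merged) also seeded the other species' GRC, so absence from the other
  assembly may be an assembly gap rather than a real difference;
* ``species_specific`` — everything else.

Copy-number weighting is applied only when reporting proportions, so that
collapsed duplications count with their physical weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .io import AlignmentRecord, GenomicInterval

__all__ = [
    "HomologyClass",
    "OriginAttribution",
    "RegionDivergence",
    "merge_within_gap",
    "classify_homology",
    "class_totals",
    "origin_attribution",
    "divergence_polarity",
]

LABELS = ("species_specific", "potentially_homologous", "homologous")


@dataclass(frozen=True)
class HomologyClass:
    interval: GenomicInterval
    label: str


@dataclass(frozen=True)
class OriginAttribution:
    interval: GenomicInterval  # on the GRC assembly
    chromosome: str
    contribution_bp: float  # copy-weighted


@dataclass(frozen=True)
class RegionDivergence:
    query_id: str
    mismatch_prop_1: float
    mismatch_prop_2: float

    @property
    def d(self) -> float:
        """Signed difference; negative = closer to species 1."""
        return self.mismatch_prop_1 - self.mismatch_prop_2


def merge_within_gap(
    intervals: Iterable[GenomicInterval], gap: int = 10_000
) -> list[GenomicInterval]:
    """Merge intervals separated by at most ``gap`` bp (transitive closure).

    Input order is irrelevant; the operation is idempotent.  Intervals on
    different scaffolds are merged independently.
    """
    by_scaffold: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_scaffold.setdefault(iv.scaffold, []).append(iv)
    out: list[GenomicInterval] = []
    for scaffold in sorted(by_scaffold):
        ivs = sorted(by_scaffold[scaffold], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(scaffold, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(scaffold, cur_start, cur_end))
    return out


def _interval_mask(length: int, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s) : min(length, e)] = True
    return mask


def _mask_to_intervals(scaffold: str, codes: np.ndarray) -> list[HomologyClass]:
    edges = np.flatnonzero(np.diff(codes)) + 1
    bounds = np.concatenate(([0], edges, [len(codes)]))
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        out.append(HomologyClass(GenomicInterval(scaffold, int(s), int(e)),
                                 LABELS[codes[s]]))
    return out


def _filter(alignments, min_len, min_identity):
    return [a for a in alignments if a.block_len >= min_len and a.identity >= min_identity]


def classify_homology(
    grc_lengths_1: Mapping[str, int],
    grc_lengths_2: Mapping[str, int],
    cross_alignments: Iterable[AlignmentRecord],
    to_genome_1: Iterable[AlignmentRecord],
    to_genome_2: Iterable[AlignmentRecord],
    gap: int = 10_000,
    min_len: int = 500,
    min_identity: float = 0.90,
) -> dict[int, list[HomologyClass]]:
    """Label every base of both GRC assemblies.

    ``cross_alignments`` place species-1 GRC scaffolds (query) on the
    species-2 GRC assembly (target); ``to_genome_N`` place species N's GRC
    scaffolds on one shared reference genome.  Returns ``{1: [...], 2: [...]}``
    with labels partitioning each assembly exactly.
    """
    cross = _filter(cross_alignments, min_len, min_identity)
    g1 = _filter(to_genome_1, min_len, min_identity)
    g2 = _filter(to_genome_2, min_len, min_identity)

    # merged A-chromosome footprints per species, and their intersection
    fp1 = merge_within_gap((a.target for a in g1), gap)
    fp2 = merge_within_gap((a.target for a in g2), gap)
    shared: dict[str, list[tuple[int, int]]] = {}
    for iv1 in fp1:
        for iv2 in fp2:
            ov = iv1.overlap(iv2)
            if ov > 0:
                s = max(iv1.start, iv2.start)
                shared.setdefault(iv1.scaffold, []).append((s, s + ov))

    result: dict[int, list[HomologyClass]] = {}
    for species, lengths, genome_alns in ((1, grc_lengths_1, g1), (2, grc_lengths_2, g2)):
        codes: dict[str, np.ndarray] = {
            name: np.zeros(L, dtype=np.int8) for name, L in lengths.items()
        }
        # direct cross-GRC homology: query side for species 1, target side for 2
        for a in cross:
            if species == 1 and a.query_id in codes:
                codes[a.query_id][a.query_start : a.query_end] = 2
            elif species == 2 and a.target.scaffold in codes:
                codes[a.target.scaffold][a.target.start : a.target.end] = 2
        # potentially homologous: project shared genome footprint back
        for a in genome_alns:
            arr = codes.get(a.query_id)
            if arr is None:
                continue
            for s, e in shared.get(a.target.scaffold, ()):
                ov_s = max(s, a.target.start)
                ov_e = min(e, a.target.end)
                if ov_s >= ov_e:
                    continue
                if a.target.strand == "-":
                    q_s = a.query_start + (a.target.end - ov_e)
                    q_e = a.query_start + (a.target.end - ov_s)
                else:
                    q_s = a.query_start + (ov_s - a.target.start)
                    q_e = a.query_start + (ov_e - a.target.start)
                seg = arr[q_s:q_e]
                seg[seg == 0] = 1
        result[species] = [
            hc for name in sorted(codes) for hc in _mask_to_intervals(name, codes[name])
        ]
    return result


def class_totals(
    classes: list[HomologyClass],
    copy_number: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Total bp per label, optionally copy-number weighted per scaffold."""
    totals = {label: 0.0 for label in LABELS}
    for hc in classes:
        w = 1.0 if copy_number is None else copy_number.get(hc.interval.scaffold, 1.0)
        totals[hc.label] += len(hc.interval) * w
    return totals


def origin_attribution(
    grc_to_genome: Iterable[AlignmentRecord],
    chromosome_of: Mapping[str, str],
    chromosome_lengths: Mapping[str, int],
    copy_number: Optional[Mapping[str, float]] = None,
) -> tuple[list[OriginAttribution], dict[str, float], dict[str, float]]:
    """Attribute GRC sequence to source chromosomes; report proportions.

    Each query is attributed to the chromosome of its top hit (most
    matches; ties broken by longest block, then lexicographic chromosome
    name).  Observed proportions are copy-number weighted; expected
    proportions are chromosome length over genome length.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for a in grc_to_genome:
        by_query.setdefault(a.query_id, []).append(a)

    attributions: list[OriginAttribution] = []
    observed: dict[str, float] = {}
    for qid in sorted(by_query):
        alns = by_query[qid]
        top = min(
            alns,
            key=lambda a: (
                -a.matches,
                -a.block_len,
                chromosome_of.get(a.target.scaffold, "~"),
            ),
        )
        chrom = chromosome_of.get(top.target.scaffold)
        if chrom is None:
            continue
        w = 1.0 if copy_number is None else copy_number.get(qid, 1.0)
        bp = (top.query_end - top.query_start) * w
        attributions.append(
            OriginAttribution(
                GenomicInterval(qid, top.query_start, top.query_end), chrom, bp
            )
        )
        observed[chrom] = observed.get(chrom, 0.0) + bp

    total_obs = sum(observed.values())
    observed_prop = {c: v / total_obs for c, v in observed.items()} if total_obs else {}
    genome_len = sum(chromosome_lengths.values())
    expected_prop = {c: L / genome_len for c, L in chromosome_lengths.items()}
    return attributions, observed_prop, expected_prop


def divergence_polarity(
    alignments_genome_1: Iterable[AlignmentRecord],
    alignments_genome_2: Iterable[AlignmentRecord],
) -> tuple[list[RegionDivergence], int]:
    """Per-region signed mismatch-proportion difference between two genomes.

    For each query region, the best (fewest-mismatch-proportion) alignment
    to each genome is taken; ``d = mp1 - mp2``.  Regions equally divergent
    from both genomes (d == 0) are removed; regions aligning to only one
    genome are excluded and counted in the second return value.
    """
    def best(alignments):
        out: dict[str, float] = {}
        for a in alignments:
            mp = 1.0 - a.identity
            if a.query_id not in out or mp < out[a.query_id]:
                out[a.query_id] = mp
        return out

    mp1 = best(alignments_genome_1)
    mp2 = best(alignments_genome_2)
    excluded = len(set(mp1) ^ set(mp2))
    results = []
    for qid in sorted(set(mp1) & set(mp2)):
        rd = RegionDivergence(qid, mp1[qid], mp2[qid])
        if rd.d != 0.0:
            results.append(rd)
    return results, excluded
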