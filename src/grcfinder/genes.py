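"""Gene annotation on the GRC: completeness, pseudogenization, expression.

Genes are annotated from translated-search hits of reference coding
sequences against the GRC assembly.  Because the GRC accumulates partial,
duplicated gene copies, each gene is scored by:

* **completeness** — the fraction of its coding region found on the GRC,
  normalised by the fraction found in the reference A-genome (so poor
  cross-species conservation is not mistaken for GRC truncation), with the
  denominator floored at 0.75 and the result capped at 1;
* **premature stops** — an exon is pseudogenic if no reading frame on its
  annotated strand contains an open (stop-free) stretch spanning at least
  95% of the exon;
* **copy number** — exon-length-weighted mean of the harbouring scaffolds'
  normalised coverage;
* **sharing** — found unambiguously in both species, potentially shared
  (single-species but inside a potentially-homologous region), or
  species-specific;
* **expression** — unique-mapping FPKM, and an OLS fit of log2(FPKM)
  against completeness.

A naive translated scan (six-frame translation, exact peptide seeds,
ungapped extension) is bundled for toy genomes; real data should supply an
external translated-search hit table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import GenomicInterval, HitRecord
from .seqs import revcomp, translate

__all__ = [
    "AnnotatedExon",
    "GeneHit",
    "ExpressionRecord",
    "CompletenessExpressionFit",
    "annotate_exons",
    "completeness",
    "include_gene",
    "premature_stop",
    "gene_copy_number",
    "sharing_category",
    "completeness_band",
    "fpkm",
    "completeness_expression_fit",
    "translated_search",
]

BANDS = (0.95, 0.75, 0.50, 0.0)
_BAND_NAMES = {0.95: ">95%", 0.75: ">75%", 0.50: ">50%", 0.0: ">0%"}


@dataclass
class AnnotatedExon:
    """A merged translated-search region assigned to its best gene."""

    region: GenomicInterval  # on the GRC assembly
    gene_id: str
    strand: str
    frame: int
    cds_interval: tuple[int, int]  # covered interval on the gene CDS
    bitscore: float


@dataclass
class GeneHit:
    gene_id: str
    exons: list[AnnotatedExon] = field(default_factory=list)
    raw_prop_grc: float = 0.0
    prop_genome: float = 1.0
    norm_completeness: float = 0.0
    premature_stop_exons: int = 0
    copy_number: float = 1.0
    sharing: str = ""


@dataclass
class ExpressionRecord:
    gene_id: str
    tissue: str
    unique_fragment_count: int
    exon_kbp: float
    library_mapped_millions: float

    @property
    def fpkm(self) -> float:
        return fpkm(self.unique_fragment_count, self.exon_kbp, self.library_mapped_millions)


@dataclass
class CompletenessExpressionFit:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    n: int


# ---------------------------------------------------------------------------
# Exon annotation from hit tables
# ---------------------------------------------------------------------------

def annotate_exons(
    hits: Iterable[HitRecord], evalue_max: float = 1e-6
) -> list[AnnotatedExon]:
    """Merge overlapping same-strand hits and assign each region to a gene.

    Hits above the e-value cut-off are dropped.  Overlapping hits on the
    same strand of the same GRC scaffold are merged into one region; the
    region is assigned to the gene of its highest-bitscore constituent hit,
    and the covered CDS interval is the union over that gene's hits in the
    region.
    """
    kept = [h for h in hits if h.evalue <= evalue_max]
    by_group: dict[tuple[str, str], list[HitRecord]] = {}
    for h in kept:
        by_group.setdefault((h.query_id, h.strand), []).append(h)

    out: list[AnnotatedExon] = []
    for (scaffold, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: (h.query_start, h.query_end))
        cluster: list[HitRecord] = []
        cluster_end = -1
        for h in group + [None]:  # sentinel flush
            if h is not None and (not cluster or h.query_start < cluster_end):
                cluster.append(h)
                cluster_end = max(cluster_end, h.query_end)
                continue
            if cluster:
                top = max(cluster, key=lambda x: (x.bitscore, -x.evalue, x.gene_id))
                gene_hits = [x for x in cluster if x.gene_id == top.gene_id]
                cds_lo = min(x.target_start for x in gene_hits)
                cds_hi = max(x.target_end for x in gene_hits)
                out.append(
                    AnnotatedExon(
                        region=GenomicInterval(
                            scaffold,
                            min(x.query_start for x in cluster),
                            cluster_end,
                            strand,
                        ),
                        gene_id=top.gene_id,
                        strand=strand,
                        frame=top.frame,
                        cds_interval=(cds_lo, cds_hi),
                        bitscore=top.bitscore,
                    )
                )
            if h is not None:
                cluster = [h]
                cluster_end = h.query_end
    return out


# ---------------------------------------------------------------------------
# Completeness scoring
# ---------------------------------------------------------------------------

def completeness(raw_prop_grc: float, prop_genome: float, floor: float = 0.75) -> float:
    """Floored, capped completeness normalisation.

    raw_prop_grc / max(prop_genome, floor), capped at 1, so weak
    cross-species conservation (small denominator) cannot inflate a tiny
    GRC fragment into a complete gene.
    """
    if not (0.0 <= raw_prop_grc <= 1.0 and 0.0 <= prop_genome <= 1.0):
        raise ValueError("proportions must be in [0,1]")
    return min(1.0, raw_prop_grc / max(prop_genome, floor))


def include_gene(*completeness_per_species: Optional[float], threshold: float = 0.25) -> bool:
    """Keep a gene if at least one species shows >= threshold of its CDS."""
    values = [c for c in completeness_per_species if c is not None]
    return bool(values) and max(values) >= threshold


def completeness_band(value: float) -> Optional[str]:
    """Highest completeness threshold strictly exceeded (Table-2 style)."""
    for threshold in BANDS:
        if value > threshold:
            return _BAND_NAMES[threshold]
    return None


# ---------------------------------------------------------------------------
# Premature stops
# ---------------------------------------------------------------------------

def premature_stop(exon_sequence: str, strand: str = "+") -> bool:
    """True iff no reading frame has an open stretch >= 95% of the exon.

    All three frames on the annotated strand are considered; an open
    stretch is a run of bases uninterrupted by an in-frame stop codon
    (bases before the first stop and after the last count).  The 95%
    boundary is inclusive: an open stretch of exactly 0.95 x length does
    not flag.  Integer arithmetic avoids floating-point edge effects.
    """
    L = len(exon_sequence)
    if L < 3:
        raise ValueError("exon shorter than one codon")
    seq = exon_sequence if strand == "+" else revcomp(exon_sequence)
    for frame in range(3):
        aa = translate(seq, frame)
        longest = 0
        run_start = 0  # in bp, start of current open stretch
        for i, res in enumerate(aa):
            if res == "*":
                stop_bp = frame + 3 * i
                longest = max(longest, stop_bp - run_start)
                run_start = stop_bp + 3
        longest = max(longest, L - run_start)
        if 20 * longest >= 19 * L:  # longest >= 0.95 * L, exactly
            return False
    return True


# ---------------------------------------------------------------------------
# Copy number and sharing
# ---------------------------------------------------------------------------

def gene_copy_number(
    exons: Sequence[AnnotatedExon], scaffold_copy_number: Mapping[str, float]
) -> float:
    """Exon-length-weighted mean copy number of the harbouring scaffolds."""
    if not exons:
        raise ValueError("gene has no annotated exons")
    weights = np.array([len(e.region) for e in exons], dtype=float)
    values = np.array(
        [scaffold_copy_number.get(e.region.scaffold, 1.0) for e in exons], dtype=float
    )
    return float(np.average(values, weights=weights))


def sharing_category(
    present: Mapping[str, bool], locus_labels: Mapping[str, str]
) -> str:
    """Classify a gene's sharing between two species.

    ``present`` maps species -> annotated-on-its-GRC; ``locus_labels`` maps
    the species where the gene *is* annotated to the homology label of its
    locus.  A gene annotated in both species is ``both_unambiguous``; in
    one species within a potentially-homologous region ``potentially_shared``;
    otherwise ``species_specific``.
    """
    n = sum(bool(v) for v in present.values())
    if n == 0:
        raise ValueError("gene not annotated in any species")
    if n >= 2:
        return "both_unambiguous"
    species = next(s for s, v in present.items() if v)
    if locus_labels.get(species) == "potentially_homologous":
        return "potentially_shared"
    return "species_specific"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def fpkm(
    unique_fragment_count: int, exon_kbp: float, library_mapped_millions: float
) -> float:
    """Fragments per kbp of exon per million mapped fragments."""
    if exon_kbp <= 0:
        raise ValueError("exon_kbp must be > 0")
    if library_mapped_millions <= 0:
        raise ValueError("library_mapped_millions must be > 0")
    return unique_fragment_count / (exon_kbp * library_mapped_millions)


def completeness_expression_fit(
    records: Iterable[tuple[float, float]]
) -> CompletenessExpressionFit:
    """OLS of log2(FPKM) on completeness over genes with FPKM > 0."""
    import statsmodels.api as sm

    pairs = [(c, f) for c, f in records if f > 0]
    if len(pairs) < 3:
        raise ValueError("need >= 3 expressed genes to fit")
    x = np.array([c for c, _ in pairs])
    y = np.log2([f for _, f in pairs])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return CompletenessExpressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_stderr=float(model.bse[1]),
        n=len(pairs),
    )


# ---------------------------------------------------------------------------
# Naive translated scan (toy-data stand-in for an external translated search)
# ---------------------------------------------------------------------------

def translated_search(
    cds_sequences: Mapping[str, str],
    grc_sequences: Mapping[str, str],
    word: int = 5,
    min_score: int = 40,
    match: int = 2,
    mismatch: int = -3,
    x_drop: int = 20,
) -> list[HitRecord]:
    """Exact-peptide-seed, ungapped-extension search of CDS vs GRC.

    Each GRC scaffold is translated in six frames; exact ``word``-length
    peptide seeds against the frame-0 translation of each CDS are extended
    without gaps under a simple identity score with X-drop termination.
    Scores are reported as the bitscore field; e-values are set to 0 (this
    scan has no extreme-value statistics and is intended for synthetic
    data where hits are unambiguous).
    """
    cds_prot = {g: translate(s, 0) for g, s in cds_sequences.items()}
    seed_index: dict[str, list[tuple[str, int]]] = {}
    for gene, prot in cds_prot.items():
        for i in range(len(prot) - word + 1):
            seed_index.setdefault(prot[i : i + word], []).append((gene, i))

    hits: list[HitRecord] = []
    for scaffold, seq in grc_sequences.items():
        L = len(seq)
        for strand, s_seq in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                prot = translate(s_seq, frame)
                seen_spans: set[tuple[str, int, int]] = set()
                for i in range(len(prot) - word + 1):
                    for gene, j in seed_index.get(prot[i : i + word], ()):
                        target = cds_prot[gene]
                        # ungapped extension in protein space
                        score = word * match
                        best_score = score
                        lo_q, lo_t = i, j
                        hi_q, hi_t = i + word, j + word
                        bl, bt = lo_q, lo_t
                        q, t = i - 1, j - 1
                        while q >= 0 and t >= 0:
                            score += match if prot[q] == target[t] else mismatch
                            if score > best_score:
                                best_score, bl, bt = score, q, t
                            if best_score - score > x_drop:
                                break
                            q, t = q - 1, t - 1
                        lo_q, lo_t = bl, bt
                        score = best_score
                        q, t = hi_q, hi_t
                        bh_q, bh_t = hi_q, hi_t
                        while q < len(prot) and t < len(target):
                            score += match if prot[q] == target[t] else mismatch
                            if score > best_score:
                                best_score, bh_q, bh_t = score + 0, q + 1, t + 1
                            if best_score - score > x_drop:
                                break
                            q, t = q + 1, t + 1
                        hi_q, hi_t = bh_q, bh_t
                        if best_score < min_score:
                            continue
                        span = (gene, lo_q, lo_t)
                        if span in seen_spans:
                            continue
                        seen_spans.add(span)
                        ident = sum(
                            1 for a, b in zip(prot[lo_q:hi_q], target[lo_t:hi_t]) if a == b
                        )
                        alen = hi_q - lo_q
                        # protein coords -> nucleotide coords on the forward strand
                        nt_lo = frame + 3 * lo_q
                        nt_hi = frame + 3 * hi_q
                        if strand == "-":
                            nt_lo, nt_hi = L - nt_hi, L - nt_lo
                        hits.append(
                            HitRecord(
                                query_id=scaffold,
                                gene_id=gene,
                                pident=100.0 * ident / alen,
                                length=alen,
                                query_start=nt_lo,
                                query_end=nt_hi,
                                target_start=3 * lo_t,
                                target_end=3 * hi_t,
                                evalue=0.0,
                                bitscore=float(best_score),
                                strand=strand,
                                frame=(frame + 1) if strand == "+" else -(frame + 1),
                            )
                        )
    return hits
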