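"""Synthetic genomes and linked reads with planted GRC structure.

The generator emulates the data situation the pipeline is built for:

* an "A genome" of ordinary somatic chromosomes, present in both tissues;
* a germline-restricted chromosome (GRC) assembled from A-chromosome
  segments carrying 0.1--2% substitution divergence;
* recent within-GRC duplications that are byte-identical and therefore
  collapse into one assembly scaffold (visible only as elevated coverage),
  and older duplications that have diverged and assemble separately;
* a GRC-restricted tandem repeat;
* partially retained gene copies, optionally with a planted premature stop;
* germline (testis) and somatic (kidney) read sets in which single-copy GRC
  coverage is a configurable fraction (~15--25%) of A-chromosome coverage,
  and every read carries the barcode of a molecule confined to one source
  sequence.

Divergence is substitution-only (no indels), so coordinates map one-to-one
between a GRC copy and its A-chromosome source and mismatch arithmetic
downstream is exact.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .io import AlignmentRecord, GenomicInterval, ReadRecord
from .seqs import decode, encode, mutate_substitutions, random_sequence, revcomp

__all__ = [
    "GrcSegment",
    "GeneModel",
    "SimConfig",
    "SimTruth",
    "TrueCopy",
    "Molecule",
    "GeneTruth",
    "SimReads",
    "simulate_genome",
    "plant_gene_fragments",
    "simulate_reads",
]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class ConfigError(ValueError):
    """A simulation configuration violates its own constraints."""


@dataclass(frozen=True)
class GrcSegment:
    """One A-chromosome segment copied onto the GRC.

    ``divergence`` is the substitution rate applied when the segment moved
    to the GRC (shared by all its copies).  ``copy_number`` > 1 with
    ``copy_divergence`` = 0 plants a recent duplication whose copies are
    byte-identical and collapse into a single assembly scaffold;
    ``copy_divergence`` > 0 plants older duplications that each receive
    private substitutions and assemble as separate scaffolds.
    """

    source_scaffold: str
    start: int
    end: int
    divergence: float = 0.01
    copy_number: int = 1
    copy_divergence: float = 0.0


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on the A genome, partially retained on the GRC.

    Exon lengths must be multiples of 3 (each exon is written as in-frame
    sense codons) and exons must not overlap.
    """

    gene_id: str
    scaffold: str
    exons: tuple[tuple[int, int], ...]
    fraction_retained: float = 1.0
    premature_stop: bool = False


@dataclass
class SimConfig:
    seed: int = 0
    a_genome: dict[str, int] = field(default_factory=lambda: {"A1": 200_000, "A2": 100_000})
    grc_segments: Sequence[GrcSegment] = ()
    repeat_monomer: Optional[str] = None
    repeat_array_length: int = 0
    gene_models: Sequence[GeneModel] = ()
    read_len: int = 150
    soma_depth: float = 20.0
    germline_a_depth: float = 30.0
    grc_singlecopy_ratio: float = 0.2
    molecule_len: int = 1500
    reads_per_molecule: int = 4
    error_rate: float = 0.001
    n_samples: int = 3

    def validate(self) -> None:
        if not (0.0 < self.grc_singlecopy_ratio < 1.0):
            raise ConfigError("grc_singlecopy_ratio must be in (0,1)")
        if self.soma_depth <= 0 or self.germline_a_depth <= 0:
            raise ConfigError("depths must be > 0")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ConfigError("error_rate must be in [0,1]")
        if self.molecule_len < self.read_len:
            raise ConfigError("molecule_len must be >= read_len")
        for seg in self.grc_segments:
            if seg.source_scaffold not in self.a_genome:
                raise ConfigError(f"segment source {seg.source_scaffold!r} not in a_genome")
            if not (0 <= seg.start < seg.end <= self.a_genome[seg.source_scaffold]):
                raise ConfigError(f"segment {seg} outside its source scaffold")
            if not (0.0 <= seg.divergence <= 1.0 and 0.0 <= seg.copy_divergence <= 1.0):
                raise ConfigError("divergence fractions must be in [0,1]")
            if seg.copy_number < 1:
                raise ConfigError("copy_number must be >= 1")
        for gene in self.gene_models:
            if gene.scaffold not in self.a_genome:
                raise ConfigError(f"gene {gene.gene_id}: scaffold not in a_genome")
            if not (0.0 <= gene.fraction_retained <= 1.0):
                raise ConfigError(f"gene {gene.gene_id}: fraction_retained outside [0,1]")
            last_end = -1
            for start, end in sorted(gene.exons):
                if (end - start) % 3 != 0:
                    raise ConfigError(f"gene {gene.gene_id}: exon length not a codon multiple")
                if start < last_end:
                    raise ConfigError(f"gene {gene.gene_id}: overlapping exons")
                if end > self.a_genome[gene.scaffold]:
                    raise ConfigError(f"gene {gene.gene_id}: exon outside scaffold")
                last_end = end


@dataclass
class TrueCopy:
    """One physical GRC copy reads are drawn from.

    ``assembly_scaffold`` names the scaffold the copy is represented by in
    the GRC assembly; collapsed duplicates share one scaffold.  For copies
    with an A-chromosome source, position ``p`` on the copy corresponds to
    ``source_start + p`` on ``source_scaffold`` (substitution-only model).
    """

    name: str
    kind: str  # {"segment", "repeat", "gene"}
    assembly_scaffold: str
    sequence: str
    source_scaffold: Optional[str] = None
    source_start: int = 0


@dataclass
class Molecule:
    barcode: str
    tissue: str
    sample: str
    source: str  # A scaffold name or TrueCopy name
    start: int
    end: int


@dataclass
class GeneTruth:
    gene_id: str
    scaffold: str  # GRC assembly scaffold carrying the fragment
    retained_exons: list[tuple[int, int]]  # intervals on the GRC scaffold
    stop_positions: list[int]  # 0-based positions of planted stop codons
    cds_len: int
    retained_len: int


@dataclass
class SimTruth:
    a_sequences: dict[str, str] = field(default_factory=dict)
    grc_sequences: dict[str, str] = field(default_factory=dict)
    copies: list[TrueCopy] = field(default_factory=list)
    snp_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    genes: list[GeneTruth] = field(default_factory=list)
    molecules: list[Molecule] = field(default_factory=list)

    def scaffold_copy_number(self, scaffold: str) -> int:
        """True copy number of a GRC assembly scaffold."""
        return sum(1 for c in self.copies if c.assembly_scaffold == scaffold)

    def copy_weighted_length(self) -> int:
        """Total physical GRC length: every planted copy counted once."""
        return sum(len(c.sequence) for c in self.copies)

    def assembly_length(self) -> int:
        return sum(len(s) for s in self.grc_sequences.values())

    def combined_sequences(self) -> dict[str, str]:
        """A genome + GRC assembly, the reference channel (a) aligns to."""
        return {**self.a_sequences, **self.grc_sequences}


@dataclass
class SimReads:
    """Reads per (tissue, sample) plus compact per-read origin arrays."""

    reads: dict[tuple[str, str], list[ReadRecord]] = field(default_factory=dict)
    # per (tissue, sample): (copy index into _sources, position, strand, n_errors)
    origins: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    sources: list[tuple[str, str]] = field(default_factory=list)  # (name, kind)

    def samples(self, tissue: Optional[str] = None) -> list[tuple[str, str]]:
        return [k for k in self.reads if tissue is None or k[0] == tissue]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[dict[str, str], dict[str, str], SimTruth]:
    """Build the A genome and GRC assembly with planted truth.

    Returns ``(a_sequences, grc_sequences, truth)``.  Collapsed duplicates
    (``copy_divergence`` = 0) appear once in ``grc_sequences`` but
    ``copy_number`` times in ``truth.copies``; diverged duplicates appear as
    separate scaffolds named ``<segment>_copy<i>``.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    truth = SimTruth()

    for name, length in config.a_genome.items():
        truth.a_sequences[name] = random_sequence(rng, length)

    # gene exon regions must be real (stop-free) coding sequence
    for gene in config.gene_models:
        seq = truth.a_sequences[gene.scaffold]
        arr = bytearray(seq, "ascii")
        for start, end in gene.exons:
            codons = rng.integers(0, len(_SENSE_CODONS), size=(end - start) // 3)
            coding = "".join(_SENSE_CODONS[i] for i in codons)
            arr[start:end] = coding.encode("ascii")
        truth.a_sequences[gene.scaffold] = arr.decode("ascii")

    for si, seg in enumerate(config.grc_segments):
        source = truth.a_sequences[seg.source_scaffold][seg.start : seg.end]
        base, subs = mutate_substitutions(rng, source, seg.divergence)
        for pos in subs:
            truth.snp_sites.append(
                (seg.source_scaffold, seg.start + int(pos), source[pos], base[pos])
            )
        seg_name = f"GRC_seg{si}"
        if seg.copy_divergence == 0.0:
            # recent duplication: copies byte-identical, collapse to one scaffold
            truth.grc_sequences[seg_name] = base
            for ci in range(seg.copy_number):
                truth.copies.append(
                    TrueCopy(
                        name=f"{seg_name}.{ci}",
                        kind="segment",
                        assembly_scaffold=seg_name,
                        sequence=base,
                        source_scaffold=seg.source_scaffold,
                        source_start=seg.start,
                    )
                )
        else:
            for ci in range(seg.copy_number):
                copy_seq, _ = mutate_substitutions(rng, base, seg.copy_divergence)
                scaf = f"{seg_name}_copy{ci}" if seg.copy_number > 1 else seg_name
                truth.grc_sequences[scaf] = copy_seq
                truth.copies.append(
                    TrueCopy(
                        name=f"{scaf}.0",
                        kind="segment",
                        assembly_scaffold=scaf,
                        sequence=copy_seq,
                        source_scaffold=seg.source_scaffold,
                        source_start=seg.start,
                    )
                )

    if config.repeat_monomer:
        if config.repeat_array_length < len(config.repeat_monomer):
            raise ConfigError("repeat_array_length shorter than the monomer")
        n = -(-config.repeat_array_length // len(config.repeat_monomer))
        array = (config.repeat_monomer * n)[: config.repeat_array_length]
        truth.grc_sequences["GRC_repeat"] = array
        truth.copies.append(
            TrueCopy(name="GRC_repeat.0", kind="repeat",
                     assembly_scaffold="GRC_repeat", sequence=array)
        )

    if config.gene_models:
        plant_gene_fragments(config, truth)

    return truth.a_sequences, truth.grc_sequences, truth


def plant_gene_fragments(config: SimConfig, truth: SimTruth) -> SimTruth:
    """Place partially retained gene copies on the GRC.

    Each gene contributes one GRC scaffold holding exactly
    ``round(fraction_retained * CDS length)`` of its coding sequence,
    taken from the 5' end (whole leading exons plus a truncated next exon,
    truncated at a codon boundary).  ``premature_stop`` converts the middle
    codon of the largest retained exon to TAA.
    """
    rng = np.random.default_rng([2, config.seed])
    for gene in config.gene_models:
        exons = sorted(gene.exons)
        cds_len = sum(e - s for s, e in exons)
        target = int(round(gene.fraction_retained * cds_len))
        target -= target % 3
        if gene.fraction_retained > 0 and target == 0:
            raise ConfigError(f"gene {gene.gene_id}: no exon fits the retained fraction")
        if target == 0:
            truth.genes.append(GeneTruth(gene.gene_id, "", [], [], cds_len, 0))
            continue
        pieces: list[str] = []
        retained_exons: list[tuple[int, int]] = []
        remaining = target
        offset = 0
        for start, end in exons:
            if remaining <= 0:
                break
            take = min(end - start, remaining)
            pieces.append(truth.a_sequences[gene.scaffold][start : start + take])
            retained_exons.append((offset, offset + take))
            offset += take
            remaining -= take
        frag = "".join(pieces)
        stop_positions: list[int] = []
        if gene.premature_stop:
            # middle codon of the largest retained exon
            es, ee = max(retained_exons, key=lambda iv: iv[1] - iv[0])
            codon = es + 3 * (((ee - es) // 3) // 2)
            frag = frag[:codon] + "TAA" + frag[codon + 3 :]
            stop_positions.append(codon)
        scaf = f"GRC_gene_{gene.gene_id}"
        truth.grc_sequences[scaf] = frag
        truth.copies.append(
            TrueCopy(name=f"{scaf}.0", kind="gene", assembly_scaffold=scaf, sequence=frag)
        )
        truth.genes.append(
            GeneTruth(gene.gene_id, scaf, retained_exons, stop_positions, cds_len, len(frag))
        )
    return truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _simulate_sample(
    rng: np.random.Generator,
    tissue: str,
    sample: str,
    sources: list[tuple[str, str, str, float]],  # (name, kind, sequence, depth)
    config: SimConfig,
    barcode_counter: list[int],
) -> tuple[list[ReadRecord], tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray], list[Molecule]]:
    reads: list[ReadRecord] = []
    src_idx: list[int] = []
    positions: list[int] = []
    strands: list[int] = []
    nerrs: list[int] = []
    molecules: list[Molecule] = []
    rl = config.read_len
    rpm = config.reads_per_molecule
    for i, (name, kind, seq, depth) in enumerate(sources):
        L = len(seq)
        if L < rl:
            continue
        mlen = min(config.molecule_len, L)
        n_mol = max(1, int(round(depth * L / (rpm * rl))))
        mol_starts = rng.integers(0, L - mlen + 1, size=n_mol)
        for ms in mol_starts:
            barcode_counter[0] += 1
            bc = f"BX{barcode_counter[0]:07d}"
            molecules.append(Molecule(bc, tissue, sample, name, int(ms), int(ms + mlen)))
            rstarts = rng.integers(ms, ms + mlen - rl + 1, size=rpm)
            rstrands = rng.integers(0, 2, size=rpm)
            for rs, st in zip(rstarts, rstrands):
                rs = int(rs)
                frag = seq[rs : rs + rl]
                n_err = 0
                if config.error_rate > 0:
                    frag, errs = mutate_substitutions(rng, frag, config.error_rate)
                    n_err = len(errs)
                out = revcomp(frag) if st else frag
                rid = f"{sample}.{tissue}.r{len(reads)}"
                reads.append(
                    ReadRecord(read_id=rid, sequence=out, barcode=bc,
                               tissue=tissue, sample=sample)
                )
                src_idx.append(i)
                positions.append(rs)
                strands.append(int(st))
                nerrs.append(n_err)
    origin = (
        np.asarray(src_idx, dtype=np.int32),
        np.asarray(positions, dtype=np.int32),
        np.asarray(strands, dtype=np.int8),
        np.asarray(nerrs, dtype=np.int16),
    )
    return reads, origin, molecules


def simulate_reads(config: SimConfig, truth: SimTruth) -> SimReads:
    """Draw barcoded reads for every sample of both tissues.

    Kidney reads come only from A scaffolds at ``soma_depth``.  Testis reads
    come from A scaffolds at ``germline_a_depth`` and from every GRC true
    copy at ``grc_singlecopy_ratio * germline_a_depth`` (so a collapsed
    duplication accrues proportionally more coverage on its single assembly
    scaffold).  One barcode per molecule; molecules never span sources.
    """
    config.validate()
    if not truth.a_sequences:
        raise ConfigError("genome not simulated")
    rng = np.random.default_rng([3, config.seed])
    sim = SimReads()
    a_sources = [(name, "A", seq) for name, seq in truth.a_sequences.items()]
    grc_sources = [(c.name, c.kind, c.sequence) for c in truth.copies]
    sim.sources = [(n, k) for n, k, _ in a_sources + grc_sources]
    barcode_counter = [0]
    grc_depth = config.grc_singlecopy_ratio * config.germline_a_depth
    for tissue in ("testis", "kidney"):
        for s in range(config.n_samples):
            sample = f"{tissue[0].upper()}{s + 1}"
            if tissue == "kidney":
                sources = [(n, k, q, config.soma_depth) for n, k, q in a_sources]
            else:
                sources = [(n, k, q, config.germline_a_depth) for n, k, q in a_sources]
                sources += [(n, k, q, grc_depth) for n, k, q in grc_sources]
            reads, origin, mols = _simulate_sample(
                rng, tissue, sample, sources, config, barcode_counter
            )
            sim.reads[(tissue, sample)] = reads
            sim.origins[(tissue, sample)] = origin
            truth.molecules.extend(mols)
    return sim


# ---------------------------------------------------------------------------
# Truth alignments (stand in for an external aligner on synthetic data)
# ---------------------------------------------------------------------------

def _copy_lookup(truth: SimTruth) -> dict[str, TrueCopy]:
    return {c.name: c for c in truth.copies}


def assembly_alignments(
    truth: SimTruth, sim: SimReads, tissue: Optional[str] = None
) -> Iterator[tuple[ReadRecord, AlignmentRecord]]:
    """Truth placements of reads on the combined A + GRC assembly.

    Collapsed duplicate copies all project onto their shared assembly
    scaffold, reproducing the coverage pile-up a real aligner would see.
    """
    copies = _copy_lookup(truth)
    rl = None
    for key in sim.samples(tissue):
        reads = sim.reads[key]
        src_idx, positions, strands, nerrs = sim.origins[key]
        for r, si, pos, st, ne in zip(reads, src_idx, positions, strands, nerrs):
            name, kind = sim.sources[si]
            scaffold = name if kind == "A" else copies[name].assembly_scaffold
            rl = len(r.sequence)
            yield r, AlignmentRecord(
                query_id=r.read_id,
                query_start=0,
                query_end=rl,
                target=GenomicInterval(scaffold, int(pos), int(pos) + rl,
                                       "-" if st else "+"),
                matches=rl - int(ne),
                block_len=rl,
            )


def reference_alignments(
    truth: SimTruth, sim: SimReads, tissue: Optional[str] = None
) -> Iterator[tuple[ReadRecord, AlignmentRecord]]:
    """Truth placements of reads on the A-chromosome reference only.

    GRC segment reads project through their source interval (mismatching at
    divergence sites), emulating GRC reads aligned to a somatic reference.
    Reads from sources without an A projection (the GRC-restricted repeat,
    gene-fragment scaffolds) are omitted, as a real aligner would either
    fail or place them non-contiguously.
    """
    copies = _copy_lookup(truth)
    # exact mismatch counts per read, vectorised per scaffold
    for key in sim.samples(tissue):
        reads = sim.reads[key]
        src_idx, positions, strands, _ = sim.origins[key]
        for r, si, pos, st in zip(reads, src_idx, positions, strands):
            name, kind = sim.sources[si]
            if kind == "A":
                scaffold, rpos = name, int(pos)
            elif kind == "segment":
                c = copies[name]
                scaffold, rpos = c.source_scaffold, c.source_start + int(pos)
            else:
                continue
            rl = len(r.sequence)
            ref = truth.a_sequences[scaffold][rpos : rpos + rl]
            query = revcomp(r.sequence) if st else r.sequence
            mm = int(np.count_nonzero(encode(query) != encode(ref)))
            yield r, AlignmentRecord(
                query_id=r.read_id,
                query_start=0,
                query_end=rl,
                target=GenomicInterval(scaffold, rpos, rpos + rl, "-" if st else "+"),
                matches=rl - mm,
                block_len=rl,
            )
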