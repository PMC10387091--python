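"""Coverage normalisation, per-window copy number and corrected GRC size.

The GRC occurs in a subset of gonadal cells (one copy per male germ cell),
so single-copy GRC regions sit at a fraction (~15--25%) of A-chromosome
depth in germline libraries.  Normalisation anchors on that fraction:

* ``single_copy_grc_depth`` — the modal testis depth over GRC bases with
  zero kidney coverage (bases that cannot be A-chromosomal contamination);
* the testis ratio (single-copy GRC depth / modal A depth) serves as the
  expected GRC fraction for the kidney track too, so both tracks are in
  single-copy-GRC units before the soma signal is subtracted to cancel
  misaligned A-chromosomal reads.

Per-base copy number is then averaged over 1-kbp windows (floored at zero),
and the copy-weighted window sum gives a GRC size corrected for
near-identical duplications collapsed by the assembler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from .io import AlignmentRecord, GenomicInterval, ReadRecord

__all__ = [
    "NormalizationConstants",
    "WindowCopyNumber",
    "SizeEstimate",
    "depth_from_alignments",
    "modal_depth",
    "estimate_constants",
    "copy_number_windows",
    "grc_size_estimate",
    "scaffold_copy_number",
]


@dataclass
class NormalizationConstants:
    sample: str
    single_copy_grc_depth: float
    modal_a_depth_testis: float
    modal_a_depth_kidney: float

    @property
    def ratio(self) -> float:
        """Single-copy GRC depth as a fraction of A-chromosome depth."""
        return self.single_copy_grc_depth / self.modal_a_depth_testis


@dataclass
class WindowCopyNumber:
    scaffold: str
    window: GenomicInterval
    copy_number: float
    sample: str = ""
    short: bool = False  # trailing window shorter than the nominal size


@dataclass
class SizeEstimate:
    sample: str
    size_bp: float
    assembly_bp: int

    @property
    def inflation(self) -> float:
        """Corrected size relative to the raw assembly length."""
        return self.size_bp / self.assembly_bp if self.assembly_bp else float("nan")


def depth_from_alignments(
    alignments: Iterable[Union[AlignmentRecord, tuple[ReadRecord, AlignmentRecord]]],
    lengths: Mapping[str, int],
) -> dict[str, np.ndarray]:
    """Per-base depth arrays from ungapped alignment placements."""
    starts: dict[str, list[int]] = {name: [] for name in lengths}
    ends: dict[str, list[int]] = {name: [] for name in lengths}
    for item in alignments:
        aln = item if isinstance(item, AlignmentRecord) else item[1]
        t = aln.target
        if t.scaffold not in starts:
            continue
        starts[t.scaffold].append(t.start)
        ends[t.scaffold].append(min(t.end, lengths[t.scaffold]))
    out = {}
    for name, length in lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        if starts[name]:
            np.add.at(diff, np.asarray(starts[name]), 1)
            np.add.at(diff, np.asarray(ends[name]), -1)
        out[name] = np.cumsum(diff[:-1]).astype(np.int32)
    return out


def modal_depth(depths: np.ndarray) -> int:
    """Mode of an integer depth array (binwidth 1, ties toward smaller depth)."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty depth array")
    counts = np.bincount(depths.astype(np.int64))
    return int(counts.argmax())  # argmax returns the first (smallest) tie


def estimate_constants(
    grc_cov_testis: Mapping[str, np.ndarray],
    grc_cov_kidney: Mapping[str, np.ndarray],
    genome_cov_testis: Mapping[str, np.ndarray],
    genome_cov_kidney: Mapping[str, np.ndarray],
    sample: str = "",
) -> NormalizationConstants:
    """Estimate per-sample normalisation constants.

    ``single_copy_grc_depth`` is the modal testis depth over GRC bases with
    kidney depth zero; modal A depths are modes over the A-chromosome
    scaffolds.  Raises if no zero-kidney GRC base exists (nothing anchors
    the normalisation).
    """
    zero_kidney = []
    for name, t in grc_cov_testis.items():
        k = np.asarray(grc_cov_kidney[name])
        t = np.asarray(t)
        if len(t) != len(k):
            raise ValueError(f"track length mismatch on {name}")
        zero_kidney.append(t[k == 0])
    pool = np.concatenate(zero_kidney) if zero_kidney else np.empty(0, dtype=int)
    if pool.size == 0:
        raise ValueError("no zero-kidney GRC base: cannot estimate single-copy depth")
    single = modal_depth(pool)
    if single == 0:
        raise ValueError("modal testis depth on zero-kidney GRC bases is zero")
    modal_t = modal_depth(np.concatenate([np.asarray(v) for v in genome_cov_testis.values()]))
    modal_k = modal_depth(np.concatenate([np.asarray(v) for v in genome_cov_kidney.values()]))
    if modal_t == 0 or modal_k == 0:
        raise ValueError("modal A-chromosome depth is zero")
    return NormalizationConstants(
        sample=sample,
        single_copy_grc_depth=float(single),
        modal_a_depth_testis=float(modal_t),
        modal_a_depth_kidney=float(modal_k),
    )


def copy_number_windows(
    grc_cov_testis: Mapping[str, np.ndarray],
    grc_cov_kidney: Mapping[str, np.ndarray],
    constants: NormalizationConstants,
    window: int = 1000,
) -> list[WindowCopyNumber]:
    """Windowed copy number: normalise both tracks, subtract, average, floor.

    Per base ``cn(b) = testis(b)/single_copy_depth -
    kidney(b)/(ratio * modal_a_depth_kidney)``; window values are means over
    their bases, floored at zero.  A short trailing window is kept, flagged,
    and weighted by its true length downstream.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kidney_unit = constants.ratio * constants.modal_a_depth_kidney
    out: list[WindowCopyNumber] = []
    for name in grc_cov_testis:
        t = np.asarray(grc_cov_testis[name], dtype=np.float64)
        k = np.asarray(grc_cov_kidney[name], dtype=np.float64)
        if len(t) != len(k):
            raise ValueError(f"track length mismatch on {name}")
        cn = t / constants.single_copy_grc_depth - k / kidney_unit
        for start in range(0, len(cn), window):
            end = min(start + window, len(cn))
            value = max(0.0, float(cn[start:end].mean()))
            out.append(
                WindowCopyNumber(
                    scaffold=name,
                    window=GenomicInterval(name, start, end),
                    copy_number=value,
                    sample=constants.sample,
                    short=(end - start) < window,
                )
            )
    return out


def grc_size_estimate(
    windows: list[WindowCopyNumber], sample: Optional[str] = None
) -> SizeEstimate:
    """Copy-weighted GRC size: sum of window copy number x window length."""
    if sample is not None:
        windows = [w for w in windows if w.sample == sample]
    size = sum(w.copy_number * len(w.window) for w in windows)
    assembly = sum(len(w.window) for w in windows)
    return SizeEstimate(sample=sample or (windows[0].sample if windows else ""),
                        size_bp=size, assembly_bp=assembly)


def scaffold_copy_number(
    windows: list[WindowCopyNumber], scaffold: str
) -> dict[str, float]:
    """Per-sample mean of window copy numbers over one scaffold."""
    by_sample: dict[str, list[float]] = {}
    for w in windows:
        if w.scaffold == scaffold:
            by_sample.setdefault(w.sample, []).append(w.copy_number)
    if not by_sample:
        raise ValueError(f"no windows for scaffold {scaffold!r}")
    return {s: float(np.mean(v)) for s, v in by_sample.items()}
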