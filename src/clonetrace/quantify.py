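"""Barcode quantification: raw reads -> per-sample barcode-pair count matrix.

The expected read layout is 40 bp: an 18 bp half-barcode, the 4 bp spacer
TTCG at positions 19-22, and a second 18 bp half-barcode at positions 23-40.
All coordinates in this module are 1-based inclusive, matching the layout
description above.

Pipeline: (1) keep reads whose spacer matches TTCG within Hamming distance 1;
(2) split into the two 18-mers; (3) match each half against the reference
half-library, accepting an exact match or a single mismatch at the first or
last base of the half-barcode (end-anchored tolerance; ``mismatch_anywhere``
relaxes the position restriction), requiring a unique best hit; (4) count
reads whose halves both matched uniquely, preserving the pairing; (5)
normalize each sample to counts per million, CPM_i = Counts_i / sum(Counts) * 1e6.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .synth import SPACER, HalfLibrary

READ_LENGTH = 40
SPACER_START = 18   # 0-based slice start for 1-based positions 19-22
SPACER_END = 22

__all__ = ["ReadRecord", "CountMatrix", "FilterLog", "spacer_filter",
           "split_read", "HalfAligner", "align_half", "count_pairs",
           "read_fastq_dir", "quantify_run"]


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: str = ""


@dataclass
class FilterLog:
    """Per-stage tallies; kept + dropped always equals the input read count."""

    input_reads: int = 0
    kept: int = 0
    too_short: int = 0
    bad_spacer: int = 0
    half_unmatched: int = 0
    half_ambiguous: int = 0
    counted: int = 0
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("input_reads", "kept", "too_short", "bad_spacer",
                 "half_unmatched", "half_ambiguous", "counted")} | {
                "warnings": list(self.warnings)}


@dataclass
class CountMatrix:
    """Raw and CPM-normalized barcode-pair counts per sample."""

    counts: pd.DataFrame   # index "h1:h2", columns samples, int
    cpm: pd.DataFrame      # same shape
    logs: dict[str, FilterLog]

    @property
    def barcodes(self) -> list[tuple[str, str]]:
        return [tuple(b.split(":")) for b in self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, counts_path, cpm_path) -> None:
        self.counts.rename_axis("barcode").to_csv(counts_path, sep="\t")
        self.cpm.rename_axis("barcode").to_csv(cpm_path, sep="\t")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def spacer_filter(reads, max_mismatch: int = 1, log: FilterLog | None = None):
    """Yield reads with an intact TTCG spacer at positions 19-22.

    A read passes iff it is at least 40 bp long and its spacer is within
    ``max_mismatch`` Hamming distance of TTCG.  N bases count as mismatches.
    """
    log = log if log is not None else FilterLog()
    kept = []
    for read in reads:
        log.input_reads += 1
        seq = read.sequence
        if len(seq) < READ_LENGTH:
            log.too_short += 1
            continue
        if _hamming(seq[SPACER_START:SPACER_END], SPACER) > max_mismatch:
            log.bad_spacer += 1
            continue
        log.kept += 1
        kept.append(read)
    return kept, log


def split_read(read: ReadRecord) -> tuple[str, str]:
    """Split a spacer-validated read into its two 18-mers (positions 1-18, 23-40).

    Reads longer than 40 bp keep only the first 40 bases (adapter remnants).
    """
    seq = read.sequence
    if len(seq) < READ_LENGTH:
        raise ValueError(f"read {read.id} shorter than {READ_LENGTH} bp")
    return seq[0:18], seq[22:40]


class HalfAligner:
    """Hash-based matcher for half-barcodes against a reference library.

    Accepts an exact match, or a Hamming-distance-1 match whose single
    mismatch sits at the first or last base (``mismatch_anywhere=True``
    permits the mismatch at any position).  A hit is returned only when
    exactly one library member attains the minimal distance; otherwise the
    half is 'ambiguous' (>1 candidate) or 'unmatched' (none).
    """

    AMBIGUOUS = "ambiguous"
    UNMATCHED = "unmatched"

    def __init__(self, library: HalfLibrary, mismatch_anywhere: bool = False):
        self.library = library
        self.mismatch_anywhere = mismatch_anywhere
        self.length = library.length
        self._exact: dict[str, str] = dict(zip(library.sequences, library.ids))

    def _neighbors(self, half: str):
        positions = (range(self.length) if self.mismatch_anywhere
                     else (0, self.length - 1))
        for pos in positions:
            for base in "ACGT":
                if base != half[pos]:
                    yield half[:pos] + base + half[pos + 1:]

    def __call__(self, half: str) -> str:
        if len(half) != self.length:
            raise ValueError(
                f"half length {len(half)} != library length {self.length}")
        hit = self._exact.get(half)
        if hit is not None:
            return hit  # distance 0 is unique by library uniqueness
        hits = {self._exact[n] for n in self._neighbors(half)
                if n in self._exact}
        if not hits:
            return self.UNMATCHED
        if len(hits) > 1:
            return self.AMBIGUOUS
        return next(iter(hits))


def align_half(half: str, library: HalfLibrary,
               mismatch_anywhere: bool = False) -> str:
    """One-shot convenience wrapper around :class:`HalfAligner`."""
    return HalfAligner(library, mismatch_anywhere)(half)


def count_pairs(sample_reads: dict[str, list[ReadRecord]],
                library: HalfLibrary, library2: HalfLibrary | None = None,
                mismatch_anywhere: bool = False,
                spacer_mismatch: int = 1) -> CountMatrix:
    """Run the full spacer -> split -> align -> paired-count pipeline.

    Reads where both halves align uniquely are counted as the barcode pair
    (half1_id, half2_id); everything else is dropped and tallied in the
    per-sample :class:`FilterLog`.  CPM columns sum to 1e6 for samples with
    at least one surviving read; a sample with zero surviving reads gets an
    all-zero CPM column and a warning flag.
    """
    lib2 = library2 if library2 is not None else library
    align1 = HalfAligner(library, mismatch_anywhere)
    align2 = (align1 if lib2 is library
              else HalfAligner(lib2, mismatch_anywhere))
    all_counts: dict[str, dict[str, int]] = {}
    logs: dict[str, FilterLog] = {}
    for sample, reads in sample_reads.items():
        log = FilterLog()
        kept, log = spacer_filter(reads, max_mismatch=spacer_mismatch,
                                  log=log)
        counts: dict[str, int] = {}
        for read in kept:
            h1, h2 = split_read(read)
            id1 = align1(h1)
            id2 = align2(h2)
            statuses = (id1, id2)
            if HalfAligner.UNMATCHED in statuses:
                log.half_unmatched += 1
                continue
            if HalfAligner.AMBIGUOUS in statuses:
                log.half_ambiguous += 1
                continue
            key = f"{id1}:{id2}"
            counts[key] = counts.get(key, 0) + 1
            log.counted += 1
        if log.counted == 0:
            log.warnings.append("no reads survived; CPM column is all zeros")
        all_counts[sample] = counts
        logs[sample] = log

    barcodes = sorted(set().union(*[set(c) for c in all_counts.values()])
                      if all_counts else set())
    counts_df = pd.DataFrame(
        {s: [all_counts[s].get(b, 0) for b in barcodes]
         for s in all_counts}, index=pd.Index(barcodes, name="barcode"),
        dtype=int)
    totals = counts_df.sum(axis=0)
    cpm = counts_df.astype(float)
    pos = totals > 0
    cpm.loc[:, pos] = cpm.loc[:, pos] / totals[pos] * 1e6
    cpm.loc[:, ~pos] = 0.0
    return CountMatrix(counts=counts_df, cpm=cpm, logs=logs)


# ---------------------------------------------------------------------------
# File-based entry points
# ---------------------------------------------------------------------------

def _read_fastq(path: Path) -> list[ReadRecord]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [ReadRecord(id=rec.id, sequence=str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fastq")]


def read_fastq_dir(fastq_dir: str | Path, sample_sheet: pd.DataFrame,
                   ) -> dict[str, list[ReadRecord]]:
    """Load ``<sample_id>.fastq[.gz]`` for every sample in the sheet."""
    fastq_dir = Path(fastq_dir)
    out = {}
    for sample in sample_sheet["sample_id"]:
        for suffix in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
            path = fastq_dir / f"{sample}{suffix}"
            if path.exists():
                out[sample] = _read_fastq(path)
                break
        else:
            raise FileNotFoundError(
                f"no FASTQ found for sample {sample} in {fastq_dir}")
    return out


def load_library_fasta(path: str | Path, min_dist: int = 0) -> HalfLibrary:
    records = list(SeqIO.parse(str(path), "fasta"))
    return HalfLibrary(sequences=tuple(str(r.seq).upper() for r in records),
                       min_pairwise_distance=min_dist,
                       ids=tuple(r.id for r in records))


def quantify_run(fastq_dir, library_fasta, sample_sheet_csv,
                 mismatch_anywhere: bool = False) -> CountMatrix:
    library = load_library_fasta(library_fasta)
    sheet = pd.read_csv(sample_sheet_csv)
    reads = read_fastq_dir(fastq_dir, sheet)
    return count_pairs(reads, library, mismatch_anywhere=mismatch_anywhere)
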