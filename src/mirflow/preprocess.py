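"""Read filtering and read-to-miRNA assignment for small-RNA FASTQ data.

The filter chain is order-faithful: 3' adapter trimming, then removal of
very low-quality read ends (Phred < 5), then the 85%-at-Q10 rule, then the
16–27 nt length window.  Surviving reads are matched ungapped against the
mature miRNA set and a contaminant set (rRNA/tRNA/snoRNA/snRNA/YRNA); a read
matching a contaminant with strictly fewer mismatches than any miRNA is
excluded.  Ties between equally good miRNA hits are split as 1/k fractional
weights; matrix cells are rounded half-even to integers at the end.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import AnnotatedMiRNA, ContaminantRef
from .diffexpr import CountMatrix

STATUSES = (
    "counted",
    "no_adapter",
    "quality_fail",
    "length_fail",
    "contaminant_excluded",
    "unmatched",
)


@dataclass
class FilterParams:
    adapter: str
    end_trim_phred: int = 5
    min_phred: int = 10
    min_fraction_at_min_phred: float = 0.85
    min_len: int = 16
    max_len: int = 27
    max_mismatches: int = 1
    adapter_max_mismatches: int = 1
    adapter_min_overlap: int = 6

    def __post_init__(self):
        if len(self.adapter) < self.adapter_min_overlap:
            raise ValueError("adapter must be at least the minimum overlap long")
        if not 0 < self.min_fraction_at_min_phred <= 1:
            raise ValueError("min_fraction_at_min_phred must be in (0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")


@dataclass
class ReadRecord:
    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.read_id}: bases/quals length mismatch")


@dataclass
class AssignmentOutcome:
    status: str
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "counted":
            total = sum(self.targets.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("counted weights must sum to 1")


def trim_adapter(read: ReadRecord, params: FilterParams) -> ReadRecord | None:
    """Truncate at the leftmost adapter occurrence (<= 1 mismatch in the
    matched prefix, >= 6 nt overlap).  Returns None when no adapter evidence
    is found (the read is discarded as ``no_adapter``)."""
    bases = read.bases.upper().replace("U", "T")
    adapter = params.adapter.upper().replace("U", "T")
    n, m = len(bases), len(adapter)
    for i in range(0, n - params.adapter_min_overlap + 1):
        overlap = min(m, n - i)
        mismatches = sum(1 for a, b in zip(bases[i : i + overlap], adapter[:overlap]) if a != b)
        if mismatches <= params.adapter_max_mismatches:
            return ReadRecord(read.read_id, read.bases[:i], read.quals[:i])
    return None


def quality_filter(read: ReadRecord, params: FilterParams) -> ReadRecord | str:
    """End-trim Phred < 5 bases, enforce the 85%-at-Q10 rule, then the
    16–27 nt window.  Returns the surviving read or a failure status."""
    quals = read.quals
    lo, hi = 0, len(quals)
    while lo < hi and quals[lo] < params.end_trim_phred:
        lo += 1
    while hi > lo and quals[hi - 1] < params.end_trim_phred:
        hi -= 1
    bases, quals = read.bases[lo:hi], quals[lo:hi]
    if len(bases) == 0:
        return "length_fail"
    frac_ok = sum(q >= params.min_phred for q in quals) / len(quals)
    if frac_ok < params.min_fraction_at_min_phred:
        return "quality_fail"
    if not params.min_len <= len(bases) <= params.max_len:
        return "length_fail"
    return ReadRecord(read.read_id, bases, quals)


_BASE_CODE = {b: i for i, b in enumerate("ACGU")}


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("T", "U")
    return np.array([_BASE_CODE.get(b, 255) for b in seq], dtype=np.uint8)


class ReferenceIndex:
    """Pre-encoded mature and contaminant sequences for fast ungapped
    substring matching (read aligned end-to-end within the reference)."""

    def __init__(self, mirnas: Sequence[AnnotatedMiRNA], contaminants: Sequence[ContaminantRef]):
        # one entry per unique mature name (multi-locus records collapse)
        seen: dict[str, np.ndarray] = {}
        for m in mirnas:
            if m.mirna_id not in seen:
                seen[m.mirna_id] = _encode(m.sequence)
        self.mirna_names = list(seen)
        self.mirna_seqs = list(seen.values())
        self.contaminant_names = [c.ref_id for c in contaminants]
        self.contaminant_seqs = [_encode(c.sequence) for c in contaminants]

    @staticmethod
    def _best_hamming(read: np.ndarray, ref: np.ndarray) -> int:
        """Minimum mismatches of ``read`` against any end-to-end placement
        inside ``ref``; a large sentinel when the read does not fit."""
        n, m = len(read), len(ref)
        if n > m:
            return 10**9
        windows = np.lib.stride_tricks.sliding_window_view(ref, n)
        return int((windows != read).sum(axis=1).min())

    def best_mirna_hits(self, read: np.ndarray) -> tuple[int, list[str]]:
        best, hits = 10**9, []
        for name, ref in zip(self.mirna_names, self.mirna_seqs):
            mm = self._best_hamming(read, ref)
            if mm < best:
                best, hits = mm, [name]
            elif mm == best:
                hits.append(name)
        return best, hits

    def best_contaminant(self, read: np.ndarray) -> int:
        best = 10**9
        for ref in self.contaminant_seqs:
            mm = self._best_hamming(read, ref)
            if mm < best:
                best = mm
                if best == 0:
                    break
        return best


def assign_read(
    read: ReadRecord,
    mirnas: Sequence[AnnotatedMiRNA],
    contaminants: Sequence[ContaminantRef],
    params: FilterParams,
    index: ReferenceIndex | None = None,
    multimap: str = "fractional",
) -> AssignmentOutcome:
    """Match a filtered read against matures and contaminants.

    The read is excluded only when a contaminant matches with *strictly*
    fewer mismatches than the best miRNA; ties stay with the miRNA.  Equally
    good miRNA hits share fractional 1/k weights (``multimap="first"`` keeps
    only the alphabetically first hit).
    """
    if index is None:
        index = ReferenceIndex(mirnas, contaminants)
    enc = _encode(read.bases)
    mirna_mm, hits = index.best_mirna_hits(enc)
    cont_mm = index.best_contaminant(enc) if mirna_mm > 0 else 10**9
    if mirna_mm > params.max_mismatches and cont_mm > params.max_mismatches:
        return AssignmentOutcome("unmatched")
    if cont_mm < mirna_mm:
        return AssignmentOutcome("contaminant_excluded")
    if mirna_mm > params.max_mismatches:
        return AssignmentOutcome("unmatched")
    hits = sorted(hits)
    if multimap == "first":
        return AssignmentOutcome("counted", {hits[0]: 1.0})
    return AssignmentOutcome("counted", {h: 1.0 / len(hits) for h in hits})


def process_read(
    read: ReadRecord,
    index: ReferenceIndex,
    params: FilterParams,
    multimap: str = "fractional",
) -> AssignmentOutcome:
    """Full per-read chain: adapter → end-trim → 85% rule → length → match."""
    trimmed = trim_adapter(read, params)
    if trimmed is None:
        return AssignmentOutcome("no_adapter")
    filtered = quality_filter(trimmed, params)
    if isinstance(filtered, str):
        return AssignmentOutcome(filtered)
    return assign_read(filtered, [], [], params, index=index, multimap=multimap)


def read_fastq(path: str | Path) -> Iterable[ReadRecord]:
    """Stream Phred+33 FASTQ records (plain or gzip).

    Any base quality decoding above Q41 aborts with a Phred+64 diagnosis;
    malformed records raise naming the record index.
    """
    i = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                i += 1
                if entry.quality is None:
                    raise ValueError(f"{path}: record {i} has no quality string")
                quals = [ord(c) - 33 for c in entry.quality]
                if any(q > 41 for q in quals):
                    raise ValueError(
                        f"{path}: record {i} decodes above Q41 — input looks like "
                        "Phred+64, which is not supported"
                    )
                yield ReadRecord(entry.name, entry.sequence, quals)
    except OSError as exc:
        raise ValueError(f"{path}: malformed FASTQ near record {i + 1}: {exc}") from exc


def infer_adapter(path: str | Path, n_reads: int = 10_000, k: int = 12) -> str:
    """Heuristic adapter scan: the most frequent k-mer in the 3' halves of the
    first ``n_reads`` reads.  Intended as a fallback when the library kit's
    adapter is unknown; prefer supplying the adapter explicitly."""
    counter: Counter[str] = Counter()
    for i, rec in enumerate(read_fastq(path)):
        if i >= n_reads:
            break
        half = rec.bases[len(rec.bases) // 2 :]
        for j in range(len(half) - k + 1):
            counter[half[j : j + k]] += 1
    if not counter:
        raise ValueError("no reads to infer an adapter from")
    return counter.most_common(1)[0][0]


def build_count_matrix(
    fastqs: Mapping[str, str | Path],
    sample_sheet: pd.DataFrame,
    mirnas: Sequence[AnnotatedMiRNA],
    contaminants: Sequence[ContaminantRef],
    params: FilterParams,
    multimap: str = "fractional",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Quantify each sample's FASTQ into a miRNA × sample count matrix.

    ``fastqs`` maps sample_id → FASTQ path; every sample must appear in the
    sample sheet.  Returns the rounded (half-even) matrix and a per-sample
    filter report counting reads per assignment status.
    """
    missing = set(fastqs) - set(sample_sheet.index)
    if missing:
        raise ValueError(f"samples not in sample sheet: {sorted(missing)}")
    index = ReferenceIndex(mirnas, contaminants)
    mirna_names = index.mirna_names

    weights = pd.DataFrame(0.0, index=mirna_names, columns=list(fastqs))
    report_rows = []
    for sample_id, path in fastqs.items():
        tally = {s: 0 for s in STATUSES}
        for rec in read_fastq(path):
            outcome = process_read(rec, index, params, multimap=multimap)
            tally[outcome.status] += 1
            for name, w in outcome.targets.items():
                weights.at[name, sample_id] += w
        tally["sample_id"] = sample_id
        tally["total"] = sum(tally[s] for s in STATUSES)
        report_rows.append(tally)

    counts = pd.DataFrame(
        np.rint(weights.to_numpy()).astype(int), index=weights.index, columns=weights.columns
    )
    report = pd.DataFrame(report_rows).set_index("sample_id")
    meta = sample_sheet.loc[list(fastqs)]
    if (report["total"] == report["counted"]).all() and report["total"].sum() == 0:
        warnings.warn("no reads were processed")
    return CountMatrix(counts=counts, sample_meta=meta), report
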