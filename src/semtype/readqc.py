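"""Demultiplexing and read-level quality filtering of paired-end amplicons.

Reads are assigned to samples by their forward-read barcode, the barcode is
trimmed, and each mate is 3'-truncated at the first base whose Phred quality
drops below the threshold (default Q30). A pair is retained only if both
truncated mates are at least ``min_length`` nucleotides (default 100) and
contain no ambiguous characters; otherwise the whole pair is discarded, since
taxonomic assignment downstream requires concordant mates. Phred+33 only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCReport",
    "FastqRecord",
    "demultiplex",
    "filter_pair",
    "run_qc",
    "read_fastq_pairs",
    "write_fastq",
]

# (id, sequence, quality-string) triple; the minimal FASTQ record.
FastqRecord = tuple[str, str, str]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class QCConfig:
    """Quality-filter settings.

    ``mean_quality_mode`` switches the Q30 interpretation from
    truncate-at-first-low-quality-base (default) to a mean-quality >= threshold
    test without truncation.
    """

    min_quality: int = 30
    min_length: int = 100
    allow_ambiguous: bool = False
    barcode_mismatches: int = 0
    mean_quality_mode: bool = False

    def __post_init__(self) -> None:
        if not 2 <= self.min_quality <= 41:
            raise ValueError("min_quality must lie in [2, 41]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class QCReport:
    """Per-sample read-pair accounting; the categories always sum to the input."""

    input_pairs: dict[str, int] = field(default_factory=dict)
    retained: dict[str, int] = field(default_factory=dict)
    discarded_short: dict[str, int] = field(default_factory=dict)
    discarded_ambiguous: dict[str, int] = field(default_factory=dict)
    discarded_quality: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    def check(self) -> None:
        total_in = sum(self.input_pairs.values()) + self.unassigned
        total_out = self.unassigned + sum(
            sum(d.values())
            for d in (
                self.retained,
                self.discarded_short,
                self.discarded_ambiguous,
                self.discarded_quality,
            )
        )
        if total_in != total_out:
            raise AssertionError(
                f"QC accounting violated: {total_in} in vs {total_out} out"
            )

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(self.input_pairs)
        df = pd.DataFrame(
            {
                "input_pairs": [self.input_pairs.get(s, 0) for s in samples],
                "retained": [self.retained.get(s, 0) for s in samples],
                "discarded_short": [self.discarded_short.get(s, 0) for s in samples],
                "discarded_ambiguous": [
                    self.discarded_ambiguous.get(s, 0) for s in samples
                ],
                "discarded_quality": [
                    self.discarded_quality.get(s, 0) for s in samples
                ],
            },
            index=pd.Index(samples, name="sample_id"),
        )
        return df


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    barcode_map: Mapping[str, str],
    cfg: QCConfig | None = None,
) -> tuple[dict[str, list], list]:
    """Split read pairs by forward-read barcode; trim the barcode.

    Barcodes must be unique and equal-length. A read whose leading bases match
    no barcode within ``cfg.barcode_mismatches`` goes to the unassigned bin.
    """
    cfg = cfg or QCConfig()
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    if len(set(map(len, barcodes))) > 1:
        raise ValueError("barcodes must all have the same length")
    blen = len(barcodes[0])
    lookup = {bc: sid for sid, bc in barcode_map.items()}
    by_sample: dict[str, list] = {sid: [] for sid in barcode_map}
    unassigned: list = []
    for r1, r2 in pairs:
        lead = r1[1][:blen]
        sid = lookup.get(lead)
        if sid is None and cfg.barcode_mismatches > 0:
            hits = [
                s for bc, s in lookup.items()
                if _hamming(bc, lead) <= cfg.barcode_mismatches
            ]
            sid = hits[0] if len(hits) == 1 else None
        if sid is None:
            unassigned.append((r1, r2))
        else:
            trimmed = (r1[0], r1[1][blen:], r1[2][blen:])
            by_sample[sid].append((trimmed, r2))
    return by_sample, unassigned


def _filter_mate(rec: FastqRecord, cfg: QCConfig) -> tuple[FastqRecord | None, str | None]:
    rid, seq, qual = rec
    if len(seq) != len(qual):
        raise ValueError(f"malformed FASTQ record {rid!r}: sequence/quality length mismatch")
    q = _phred(qual)
    if cfg.mean_quality_mode:
        if q.mean() < cfg.min_quality:
            return None, "quality"
    else:
        low = np.nonzero(q < cfg.min_quality)[0]
        if low.size:
            cut = int(low[0])
            seq, qual = seq[:cut], qual[:cut]
    if len(seq) < cfg.min_length:
        return None, "short"
    if not cfg.allow_ambiguous and not _ACGT.issuperset(seq):
        return None, "ambiguous"
    return (rid, seq, qual), None


def filter_pair(
    pair: tuple[FastqRecord, FastqRecord], cfg: QCConfig | None = None
):
    """Quality-filter one pair. Returns (pair or None, reason or None).

    Each mate is truncated at its first sub-threshold base; the pair is
    discarded (with the first failing mate's reason) unless both mates pass
    the length and ambiguity checks.
    """
    cfg = cfg or QCConfig()
    out = []
    for rec in pair:
        kept, reason = _filter_mate(rec, cfg)
        if kept is None:
            return None, reason
        out.append(kept)
    return (out[0], out[1]), None


def run_qc(
    by_sample: Mapping[str, Iterable],
    cfg: QCConfig | None = None,
    n_unassigned: int = 0,
) -> tuple[dict[str, list], QCReport]:
    """Apply ``filter_pair`` per sample and assemble the accounting report."""
    cfg = cfg or QCConfig()
    report = QCReport(unassigned=n_unassigned)
    retained: dict[str, list] = {}
    for sid, pairs in by_sample.items():
        pairs = list(pairs)
        report.input_pairs[sid] = len(pairs)
        kept = []
        counts = {"short": 0, "ambiguous": 0, "quality": 0}
        for pair in pairs:
            out, reason = filter_pair(pair, cfg)
            if out is None:
                counts[reason] += 1
            else:
                kept.append(out)
        retained[sid] = kept
        report.retained[sid] = len(kept)
        report.discarded_short[sid] = counts["short"]
        report.discarded_ambiguous[sid] = counts["ambiguous"]
        report.discarded_quality[sid] = counts["quality"]
    report.check()
    return retained, report


def read_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Stream synchronized read pairs from two FASTQ files."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(r1_path) as f1, open(r2_path) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield (id1, s1, q1), (id2, s2, q2)


def write_fastq(records: Iterable[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
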