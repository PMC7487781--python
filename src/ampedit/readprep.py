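"""Adapter trimming and overlap merging of paired-end amplicon reads.

Read pairs from a short amplicon (a few hundred bp) sequenced at 300 bp read
length read through the fragment into the sequencing adapter.  The pipeline
therefore 3'-trims each mate against the expected read-through sequence and
then merges the pair on its overlap, electing the higher-quality base at
discordant overlapped positions (ties go to read 1).

Pairs that fail to merge are excluded from classification and counted in the
reported ``unmerged`` tally.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import revcomp

# TruSeq-style read-through sequences: adapter + index + post-adapter run.
# Used as trimming defaults and by the simulator to pad reads past the
# fragment end.
ADAPTER_READTHROUGH_R1 = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
    "ACAGTGAT"
    "ATCTCGTATGCCGTCTTCTGCTTG"
    + "A" * 60
)
ADAPTER_READTHROUGH_R2 = (
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"
    "AGATCTCG"
    "GTGTAGATCTCGGTGGTCGCCGTATCATT"
    + "A" * 60
)


class ReadPrepError(ValueError):
    """Malformed read input (sequence/quality length mismatch, bad Phred)."""


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read; qualities are Phred+33 strings."""

    id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ReadPrepError(f"pair {self.id!r}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    """A merged amplicon-spanning read (or a recorded merge failure)."""

    id: str
    seq: str
    qual: str
    overlap_len: int
    merge_status: str  # "merged" | "failed"

    @property
    def merged(self) -> bool:
        return self.merge_status == "merged"


def trim_adapter(
    seq: str,
    qual: str,
    adapter: str,
    min_overlap: int = 3,
    max_err_frac: float = 0.1,
) -> tuple[str, str]:
    """Trim the longest read 3' suffix matching a prefix of *adapter*.

    A suffix of length L qualifies when L >= *min_overlap* and its mismatch
    fraction against ``adapter[:L]`` is <= *max_err_frac*.  Quality is trimmed
    in lockstep.  Reads without a qualifying match pass through unchanged.
    """
    if not adapter:
        raise ReadPrepError("adapter must be non-empty")
    if len(seq) != len(qual):
        raise ReadPrepError("sequence/quality length mismatch")
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ad = np.frombuffer(adapter.upper().encode("ascii"), dtype=np.uint8)
    for L in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        mm = int(np.count_nonzero(s[len(seq) - L :] != ad[:L]))
        if mm <= max_err_frac * L:
            return seq[: len(seq) - L], qual[: len(qual) - L]
    return seq, qual


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead:
    """Merge a read pair on the best overlap between r1 and revcomp(r2).

    Among overlap lengths L >= *min_overlap* whose mismatch fraction is
    <= *max_mismatch_frac*, the one maximizing the number of matched bases is
    chosen (ties prefer the longer overlap).  At discordant overlapped
    positions the base with the higher Phred quality wins and its quality is
    kept (quality ties go to r1); at concordant positions the higher quality
    is kept.  If no overlap qualifies the failure is recorded, not raised.
    """
    r2rc = revcomp(pair.r2_seq)
    q2r = pair.r2_qual[::-1]
    n1, n2 = len(pair.r1_seq), len(r2rc)
    a1 = np.frombuffer(pair.r1_seq.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(r2rc.encode("ascii"), dtype=np.uint8)
    best_L, best_matched = 0, -1
    for L in range(min(n1, n2), min_overlap - 1, -1):
        mm = int(np.count_nonzero(a1[n1 - L :] != a2[:L]))
        if mm <= max_mismatch_frac * L:
            matched = L - mm
            if matched > best_matched:
                best_matched, best_L = matched, L
    if best_L == 0:
        return MergedRead(pair.id, "", "", 0, "failed")
    L = best_L
    head_s, head_q = pair.r1_seq[: n1 - L], pair.r1_qual[: n1 - L]
    tail_s, tail_q = r2rc[L:], q2r[L:]
    mid_s = []
    mid_q = []
    for c1, q1, c2, q2 in zip(
        pair.r1_seq[n1 - L :], pair.r1_qual[n1 - L :], r2rc[:L], q2r[:L]
    ):
        if c1 == c2:
            mid_s.append(c1)
            mid_q.append(max(q1, q2))
        elif q2 > q1:
            mid_s.append(c2)
            mid_q.append(q2)
        else:
            mid_s.append(c1)
            mid_q.append(q1)
    return MergedRead(
        pair.id,
        head_s + "".join(mid_s) + tail_s,
        head_q + "".join(mid_q) + tail_q,
        L,
        "merged",
    )


def prepare_pairs(
    pairs: Iterable[ReadPair],
    adapter_r1: str = ADAPTER_READTHROUGH_R1,
    adapter_r2: str = ADAPTER_READTHROUGH_R2,
    adapter_min_overlap: int = 3,
    adapter_max_err_frac: float = 0.1,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], dict[str, int]]:
    """Trim and merge a stream of pairs; returns merged reads and tallies.

    The statistics dictionary has ``pairs_in``, ``merged`` and ``unmerged``
    counts; failed pairs are excluded from the returned list.
    """
    merged: list[MergedRead] = []
    stats = {"pairs_in": 0, "merged": 0, "unmerged": 0}
    for pair in pairs:
        stats["pairs_in"] += 1
        s1, q1 = trim_adapter(
            pair.r1_seq, pair.r1_qual, adapter_r1, adapter_min_overlap, adapter_max_err_frac
        )
        s2, q2 = trim_adapter(
            pair.r2_seq, pair.r2_qual, adapter_r2, adapter_min_overlap, adapter_max_err_frac
        )
        result = merge_pair(
            ReadPair(pair.id, s1, q1, s2, q2), min_overlap, max_mismatch_frac
        )
        if result.merged:
            stats["merged"] += 1
            merged.append(result)
        else:
            stats["unmerged"] += 1
    return merged, stats


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # Fixed mtime so identical runs give byte-identical files.
            import io

            return io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate read pairs from two (optionally gzipped) FASTQ files."""
    with _open_text(r1_path, "r") as h1, _open_text(r2_path, "r") as h2:
        it1 = SeqIO.parse(h1, "fastq")
        it2 = SeqIO.parse(h2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            yield ReadPair(
                rec1.id,
                str(rec1.seq),
                "".join(
                    chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                ),
                str(rec2.seq),
                "".join(
                    chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                ),
            )


def write_fastq(reads: Iterable[MergedRead], path) -> None:
    """Write merged reads to an (optionally gzipped) FASTQ file."""
    with _open_text(path, "w") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.seq), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in read.qual]
            SeqIO.write(rec, handle, "fastq")
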