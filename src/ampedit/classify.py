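"""Per-read HDR/NHEJ classification and per-sample outcome tables.

Each merged read is globally aligned to the reference amplicon and assigned
exactly one category:

* ``NHEJ``       - any insertion or deletion overlaps the cut site or lies
                   within w bp (default 3) of either side of it.  This rule is
                   unconditional: it supersedes donor conversion, so a read
                   carrying both a converted edit site and a window indel is
                   counted once, as NHEJ (its ``primary_converted`` flag is
                   still set for optional recounting).
* ``HDR``        - the main (non-PAM) donor edit site is converted and no
                   indel lies within the cut window.  Auxiliary (PAM-blocking)
                   edits are reported but do not gate HDR.
* ``UNMODIFIED`` - neither of the above.
* ``DISCARD``    - off-amplicon/chimeric reads (gap-excluded identity below
                   ``min_identity``) or reads too short to span the donor
                   footprint; excluded from all rate denominators.

Substitutions never count toward NHEJ (only indel events do), which makes the
call robust to per-base sequencing error.  Rates are fractions of the
classified total (HDR + NHEJ + UNMODIFIED); the HDR/NHEJ ratio is flagged
undefined when no NHEJ reads are present.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .align import DEFAULT_SCHEME, ScoringScheme, extract_events, global_align
from .locus import (
    CutWindow,
    DonorSpec,
    GuideSite,
    LocusError,
    ReferenceAmplicon,
    cut_window,
    derive_edits,
    locate_guide,
)
from .readprep import MergedRead

CATEGORIES = ("HDR", "NHEJ", "UNMODIFIED", "DISCARD")


@dataclass(frozen=True)
class TargetLocus:
    """Bundle of reference, guide site, cut window and donor specification."""

    reference: ReferenceAmplicon
    guide: GuideSite
    window: CutWindow
    donor: DonorSpec

    @classmethod
    def build(
        cls,
        reference: ReferenceAmplicon,
        protospacer: str,
        donor: str,
        w: int = 3,
        pam: str = "NGG",
        primary: Union[int, str] = "nearest-to-cut",
    ) -> "TargetLocus":
        """Locate the guide, derive the window and donor edits in one step."""
        guide = locate_guide(reference, protospacer, pam)
        window = cut_window(guide, w)
        spec = derive_edits(reference, donor, primary, cut_index=guide.cut_index)
        return cls(reference, guide, window, spec)

    def with_window(self, w: int) -> "TargetLocus":
        return TargetLocus(
            self.reference, self.guide, cut_window(self.guide, w), self.donor
        )


@dataclass(frozen=True)
class ReadCall:
    """Classification of a single merged read."""

    read_id: str
    category: str
    primary_converted: bool = False
    aux_converted_count: int = 0
    window_indel: bool = False
    ref_score: float = math.nan
    donor_score: float = math.nan
    identity: float = math.nan
    reason: str = ""


@dataclass(frozen=True)
class OutcomeTable:
    """Per-sample outcome counts, rates and HDR/NHEJ ratio.

    ``n_total`` counts classified reads only (HDR + NHEJ + UNMODIFIED);
    discarded and unmerged reads are excluded from all denominators.
    """

    n_hdr: int
    n_nhej: int
    n_unmodified: int
    n_discard: int = 0
    n_unmerged: int = 0

    @property
    def n_total(self) -> int:
        return self.n_hdr + self.n_nhej + self.n_unmodified

    @property
    def hdr_rate(self) -> float:
        return self.n_hdr / self.n_total

    @property
    def nhej_rate(self) -> float:
        return self.n_nhej / self.n_total

    @property
    def ratio_defined(self) -> bool:
        return self.n_nhej > 0

    @property
    def hdr_nhej_ratio(self) -> float:
        """HDR rate over NHEJ rate; NaN (flagged) when no NHEJ reads exist."""
        if not self.ratio_defined:
            return math.nan
        return self.n_hdr / self.n_nhej

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_hdr": self.n_hdr,
            "n_nhej": self.n_nhej,
            "n_unmodified": self.n_unmodified,
            "n_discard": self.n_discard,
            "n_unmerged": self.n_unmerged,
            "hdr_rate": self.hdr_rate,
            "nhej_rate": self.nhej_rate,
            "hdr_rate_pct": 100.0 * self.hdr_rate,
            "nhej_rate_pct": 100.0 * self.nhej_rate,
            "hdr_nhej_ratio": None if not self.ratio_defined else self.hdr_nhej_ratio,
            "ratio_defined": self.ratio_defined,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "OutcomeTable":
        return cls(
            n_hdr=int(d["n_hdr"]),
            n_nhej=int(d["n_nhej"]),
            n_unmodified=int(d["n_unmodified"]),
            n_discard=int(d.get("n_discard", 0)),
            n_unmerged=int(d.get("n_unmerged", 0)),
        )


def _read_base_at(ref_coord: int, ref_base: str, subs: dict, deleted: set) -> str | None:
    if ref_coord in deleted:
        return None
    return subs.get(ref_coord, ref_base)


def classify_sequence(
    read_id: str,
    seq: str,
    locus: TargetLocus,
    min_identity: float = 0.60,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    align_donor: bool = True,
) -> ReadCall:
    """Classify one merged read sequence against the locus bundle.

    The read is aligned globally to the reference; the read-vs-donor score is
    recorded for diagnostics only (window coordinates are reference-frame).
    """
    ref = locus.reference.sequence
    aln = global_align(ref, seq, scheme)
    identity = aln.identity()
    donor_score = math.nan
    if align_donor:
        donor_score = global_align(
            locus.donor.sequence, seq, scheme, free_end_gaps=True
        ).score
    if identity < min_identity:
        return ReadCall(
            read_id,
            "DISCARD",
            ref_score=aln.score,
            donor_score=donor_score,
            identity=identity,
            reason=f"identity {identity:.3f} < {min_identity}",
        )
    lo, hi = aln.ref_coverage()
    fp = locus.donor.footprint
    if lo > fp.start or hi < fp.stop:
        return ReadCall(
            read_id,
            "DISCARD",
            ref_score=aln.score,
            donor_score=donor_score,
            identity=identity,
            reason="read does not span the donor footprint",
        )
    indels, sub_list = extract_events(aln)
    subs = dict(sub_list)
    deleted: set[int] = set()
    window_indel = False
    for ev in indels:
        if ev.kind == "deletion":
            deleted.update(range(ev.anchor, ev.anchor + ev.length))
            if locus.window.hits_deletion(ev.anchor, ev.length):
                window_indel = True
        else:
            if locus.window.hits_insertion(ev.anchor):
                window_indel = True
    p = locus.donor.primary
    base = _read_base_at(p.ref_coord, p.ref_base, subs, deleted)
    primary_converted = base == p.donor_base
    aux_converted = sum(
        1
        for e in locus.donor.auxiliary
        if _read_base_at(e.ref_coord, e.ref_base, subs, deleted) == e.donor_base
    )
    if window_indel:
        category = "NHEJ"
    elif primary_converted:
        category = "HDR"
    else:
        category = "UNMODIFIED"
    return ReadCall(
        read_id,
        category,
        primary_converted=primary_converted,
        aux_converted_count=aux_converted,
        window_indel=window_indel,
        ref_score=aln.score,
        donor_score=donor_score,
        identity=identity,
    )


def classify_read(
    read: MergedRead,
    locus: TargetLocus,
    min_identity: float = 0.60,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    align_donor: bool = True,
) -> ReadCall:
    """Classify a merged read (see :func:`classify_sequence`)."""
    if not read.merged:
        raise ValueError(f"read {read.id!r} is not merged; exclude failed pairs")
    return classify_sequence(read.id, read.seq, locus, min_identity, scheme, align_donor)


def classify_reads(
    reads: Iterable[MergedRead],
    locus: TargetLocus,
    min_identity: float = 0.60,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    align_donor: bool = True,
) -> list[ReadCall]:
    """Classify many merged reads, caching identical sequences.

    Deep amplicon data is highly redundant (most reads are exact duplicates of
    a few alleles), so calls are memoised on the read sequence; per-pair
    results depend only on the sequence, never on file order.
    """
    cache: dict[str, ReadCall] = {}
    out: list[ReadCall] = []
    for read in reads:
        hit = cache.get(read.seq)
        if hit is None:
            hit = classify_read(read, locus, min_identity, scheme, align_donor)
            cache[read.seq] = hit
        out.append(
            ReadCall(
                read.id,
                hit.category,
                hit.primary_converted,
                hit.aux_converted_count,
                hit.window_indel,
                hit.ref_score,
                hit.donor_score,
                hit.identity,
                hit.reason,
            )
        )
    return out


def quantify(calls: Sequence[ReadCall], n_unmerged: int = 0) -> OutcomeTable:
    """Tally read calls into an :class:`OutcomeTable`.

    Raises
    ------
    ValueError
        If no classifiable (non-discarded) reads exist.
    """
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n_classified = counts["HDR"] + counts["NHEJ"] + counts["UNMODIFIED"]
    if n_classified == 0:
        raise ValueError("zero classifiable reads (all discarded or unmerged)")
    return OutcomeTable(
        n_hdr=counts["HDR"],
        n_nhej=counts["NHEJ"],
        n_unmodified=counts["UNMODIFIED"],
        n_discard=counts["DISCARD"],
        n_unmerged=n_unmerged,
    )
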