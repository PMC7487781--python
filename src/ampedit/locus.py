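"""Target-locus model: reference amplicon, guide placement, cut window, donor edits.

Coordinates are 0-based throughout.  The Cas9 blunt cut is represented as an
*inter-base* index ``cut_index``: the cut lies between reference bases
``cut_index - 1`` and ``cut_index``.  For an SpCas9-class nuclease the cut sits
3 nt 5' of the PAM on the protospacer strand.

The ``CutWindow`` encodes the +-w bp region used to attribute indels to NHEJ:
a deletion is window-positive when it removes any base in
``{cut_index - w, ..., cut_index + w - 1}``; an insertion when its inter-base
anchor lies in ``{cut_index - w, ..., cut_index + w}``.  Independently of ``w``,
an indel that touches the cut itself (a deletion removing base ``cut_index - 1``
or ``cut_index``, or an insertion anchored exactly at ``cut_index``) always
counts as overlapping the cut site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .dna import is_strict_dna, matches_iupac, revcomp


class LocusError(ValueError):
    """Invalid locus construction (bad reference, guide placement, donor)."""


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A reference amplicon sequence with a name; 0-based coordinates."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not is_strict_dna(self.sequence):
            raise LocusError(
                f"reference {self.name!r} must be non-empty uppercase A/C/G/T"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideSite:
    """A protospacer placement on the reference with its derived cut index."""

    protospacer: str
    strand: str  # "+" or "-"
    pam_start: int  # 0-based reference coordinate of the PAM's leftmost base
    cut_index: int  # inter-base index; cut between cut_index-1 and cut_index


@dataclass(frozen=True)
class CutWindow:
    """Symmetric +-w bp indel-attribution window around an inter-base cut."""

    cut_index: int
    w: int = 3

    def __post_init__(self) -> None:
        if self.w < 0:
            raise LocusError("window size w must be >= 0")

    @property
    def deleted_coords(self) -> frozenset[int]:
        """Reference base coordinates whose deletion is window-positive."""
        return frozenset(range(self.cut_index - self.w, self.cut_index + self.w))

    @property
    def insertion_anchors(self) -> frozenset[int]:
        """Inter-base indices at which an insertion is window-positive."""
        return frozenset(range(self.cut_index - self.w, self.cut_index + self.w + 1))

    def hits_deletion(self, start: int, length: int) -> bool:
        """True if deleting ``length`` bases from ``start`` hits the window
        or overlaps the cut itself."""
        span = range(start, start + length)
        if not self.deleted_coords.isdisjoint(span):
            return True
        # Cut-overlap clause, independent of w (only decisive for w == 0).
        return (self.cut_index - 1 in span) or (self.cut_index in span)

    def hits_insertion(self, anchor: int) -> bool:
        """True if an insertion anchored at inter-base ``anchor`` hits the
        window or sits exactly at the cut."""
        return anchor in self.insertion_anchors or anchor == self.cut_index


@dataclass(frozen=True)
class EditPosition:
    """A single donor-programmed substitution relative to the reference."""

    ref_coord: int
    ref_base: str
    donor_base: str
    role: str  # "primary" or "auxiliary"

    def __post_init__(self) -> None:
        if self.ref_base == self.donor_base:
            raise LocusError("edit position must change the base")
        if self.role not in ("primary", "auxiliary"):
            raise LocusError(f"unknown edit role {self.role!r}")


@dataclass(frozen=True)
class DonorSpec:
    """A substitution-only donor mapped onto the reference.

    ``ref_start`` is the reference coordinate of the donor's first base; the
    donor footprint is ``[ref_start, ref_start + len(sequence))``.  Exactly one
    edit is flagged primary (the intended, non-PAM edit); the rest are
    auxiliary (e.g. PAM-blocking silent edits).
    """

    sequence: str
    ref_start: int
    edits: tuple[EditPosition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n_primary = sum(1 for e in self.edits if e.role == "primary")
        if n_primary != 1:
            raise LocusError(f"donor must have exactly 1 primary edit, got {n_primary}")
        lo, hi = self.ref_start, self.ref_start + len(self.sequence)
        for e in self.edits:
            if not lo <= e.ref_coord < hi:
                raise LocusError(f"edit at {e.ref_coord} outside donor footprint [{lo},{hi})")

    @property
    def primary(self) -> EditPosition:
        return next(e for e in self.edits if e.role == "primary")

    @property
    def auxiliary(self) -> tuple[EditPosition, ...]:
        return tuple(e for e in self.edits if e.role == "auxiliary")

    @property
    def footprint(self) -> range:
        return range(self.ref_start, self.ref_start + len(self.sequence))


def locate_guide(
    reference: ReferenceAmplicon, protospacer: str, pam: str = "NGG"
) -> GuideSite:
    """Find the unique PAM-adjacent placement of a 20-nt protospacer.

    Both strands are scanned; the protospacer must be immediately followed
    (3') by a PAM matching the IUPAC pattern *pam*.  The cut index is placed
    3 nt 5' of the PAM on the protospacer strand and converted to reference
    coordinates.

    Raises
    ------
    LocusError
        If the protospacer has zero or more than one qualifying placement
        (the message names the placement count).
    """
    protospacer = protospacer.upper()
    if len(protospacer) != 20:
        raise LocusError(f"protospacer must be 20 nt, got {len(protospacer)}")
    if not is_strict_dna(protospacer):
        raise LocusError("protospacer must be uppercase A/C/G/T")
    ref = reference.sequence
    L = len(ref)
    k, plen = len(protospacer), len(pam)
    hits: list[GuideSite] = []
    for strand, seq in (("+", ref), ("-", revcomp(ref))):
        for i in range(0, L - k - plen + 1):
            if seq[i : i + k] == protospacer and matches_iupac(
                seq[i + k : i + k + plen], pam
            ):
                if strand == "+":
                    hits.append(GuideSite(protospacer, "+", i + k, i + k - 3))
                else:
                    # position p on the reverse strand maps to L-1-p; the
                    # inter-base cut c' maps to inter-base L-c'.
                    hits.append(
                        GuideSite(protospacer, "-", L - (i + k) - plen, L - (i + k - 3))
                    )
    if len(hits) != 1:
        raise LocusError(
            f"{len(hits)} placements found for protospacer adjacent to PAM "
            f"{pam!r}; expected exactly 1"
        )
    return hits[0]


def cut_window(site: Union[GuideSite, int], w: int = 3) -> CutWindow:
    """Build the +-w bp indel window around a guide's cut index."""
    cut = site.cut_index if isinstance(site, GuideSite) else int(site)
    return CutWindow(cut_index=cut, w=w)


def derive_edits(
    reference: ReferenceAmplicon,
    donor: str,
    primary: Union[int, str] = "nearest-to-cut",
    cut_index: int | None = None,
) -> DonorSpec:
    """Map a substitution-only donor onto the reference and list its edits.

    The donor is placed by a global alignment with free end gaps (the donor's
    homology arms anchor it inside the amplicon).  Every mismatch column
    becomes an :class:`EditPosition`; exactly one is flagged primary, chosen
    either by an explicit reference coordinate or, with
    ``primary="nearest-to-cut"``, as the edit closest to ``cut_index``.

    Raises
    ------
    LocusError
        If the donor-reference alignment contains internal gaps (donors with
        indels are unsupported), if no mismatch exists ("no edits found"), or
        if an explicit primary coordinate is not among the mismatches.
    """
    from .align import global_align  # local import to avoid cycle

    donor = donor.upper()
    if not is_strict_dna(donor):
        raise LocusError("donor must be non-empty uppercase A/C/G/T")
    aln = global_align(reference.sequence, donor, free_end_gaps=True)
    a, b = aln.aligned_a, aln.aligned_b
    # Donor footprint = columns between the first and last donor base.
    idx = [i for i, c in enumerate(b) if c != "-"]
    first, last = idx[0], idx[-1]
    inner_a = a[first : last + 1]
    inner_b = b[first : last + 1]
    n_gaps = inner_a.count("-") + inner_b.count("-")
    if n_gaps:
        raise LocusError(
            f"donor-reference alignment contains {n_gaps} gap(s); only "
            "substitution-only donors are supported"
        )
    ref_start = first - a[:first].count("-")  # leading columns are all ref
    mismatches = [
        (ref_start + j, ra, db)
        for j, (ra, db) in enumerate(zip(inner_a, inner_b))
        if ra != db
    ]
    if not mismatches:
        raise LocusError("no edits found: donor equals its reference footprint")
    if isinstance(primary, int):
        coords = [m[0] for m in mismatches]
        if primary not in coords:
            raise LocusError(
                f"primary edit coordinate {primary} not among donor mismatches {coords}"
            )
        primary_coord = primary
    elif primary == "nearest-to-cut":
        if cut_index is None:
            raise LocusError("nearest-to-cut selector requires cut_index")
        # Distance from base p to the inter-base cut is |p + 0.5 - cut|.
        primary_coord = min(mismatches, key=lambda m: (abs(m[0] + 0.5 - cut_index), m[0]))[0]
    else:
        raise LocusError(f"unknown primary selector {primary!r}")
    edits = tuple(
        EditPosition(c, ra, db, "primary" if c == primary_coord else "auxiliary")
        for c, ra, db in mismatches
    )
    return DonorSpec(sequence=donor, ref_start=ref_start, edits=edits)
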