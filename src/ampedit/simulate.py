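"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Two generators:

* :func:`simulate_amplicon_reads` emulates a MiSeq amplicon run: 300 bp
  paired-end reads to a default depth of 10,000 pairs from a few-hundred-bp
  amplicon, as a mixture of unmodified molecules, molecules with a single
  indel concentrated at the Cas9 cut site, and molecules carrying the
  donor-programmed substitutions, with per-base substitution sequencing error
  and Phred qualities.  Reads shorter than the read length are padded with a
  fixed TruSeq-like read-through sequence so adapter trimming is exercised.

* :func:`simulate_sc_counts` emulates the statistical structure cell-cycle
  scoring assumes: phase-labelled cells over-express their phase's marker
  module by a configurable fold over a gamma-Poisson (negative-binomial-like)
  background with log-normal library sizes and a mitochondrial count
  component.

Category counts are drawn once from a multinomial and every molecule gets a
truth record, including the classification expected under the cut-window
rules; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .classify import TargetLocus
from .dna import revcomp
from .locus import ReferenceAmplicon
from .readprep import (
    ADAPTER_READTHROUGH_R1,
    ADAPTER_READTHROUGH_R2,
    ReadPair,
)
from .resources import default_cell_cycle_genes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


def example_locus(seed: int = 0, length: int = 240) -> TargetLocus:
    """A fully synthetic toy target locus (reference, guide, donor).

    The reference is a random amplicon with a protospacer + NGG PAM embedded
    at a fixed position; the donor is a 120-nt substitution-only template with
    a primary edit 4 bp 5' of the cut and an auxiliary PAM-disrupting edit.
    Candidate sequences are redrawn (deterministically from *seed*) until the
    +-35 bp neighbourhood of the cut contains no homopolymer run of length 4
    or more, so that simulated indel coordinates have a unique optimal
    placement under alignment.
    """
    rng = np.random.default_rng(seed)
    proto_start, proto_len = 100, 20
    pam_start = proto_start + proto_len
    cut = pam_start - 3
    for _ in range(1000):
        seq = rng.choice(_BASES, size=length)
        seq[pam_start + 1] = ord("G")
        seq[pam_start + 2] = ord("G")
        ref_seq = seq.tobytes().decode("ascii")
        lo, hi = cut - 35, cut + 35
        if _max_run(ref_seq[lo:hi]) < 4:
            break
    else:  # pragma: no cover
        raise SimulationError("could not draw a run-free toy locus")
    reference = ReferenceAmplicon("toy_amplicon", ref_seq)
    protospacer = ref_seq[proto_start:pam_start]
    donor_start, donor_len = 60, 120
    donor = list(ref_seq[donor_start : donor_start + donor_len])

    def _substitute(coord: int) -> None:
        old = donor[coord - donor_start]
        donor[coord - donor_start] = "ACGT"[("ACGT".index(old) + 1) % 4]

    _substitute(cut - 4)  # primary (intended) edit, outside the +-3 window
    _substitute(pam_start + 2)  # auxiliary PAM-blocking edit
    return TargetLocus.build(
        reference, protospacer, "".join(donor), w=3, primary="nearest-to-cut"
    )


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class AmpliconSimConfig:
    """Mixture and error model for the amplicon read simulator.

    Fractions must sum to 1.  Indel sizes are geometric(p) truncated at
    ``max_indel_len``; deletions outnumber insertions ``deletion_prob`` :
    ``1 - deletion_prob``; indels are anchored uniformly over the cut window
    (strict-inside mode), with an optional ``outside_window_frac`` contaminant
    class placed strictly outside the window.
    """

    n_reads: int = 10_000
    hdr_fraction: float = 0.25
    nhej_fraction: float = 0.40
    unmodified_fraction: float = 0.35
    error_rate: float = 0.001
    read_length: int = 300
    deletion_prob: float = 2.0 / 3.0
    indel_geom_p: float = 0.3
    max_indel_len: int = 25
    aux_conversion_prob: float = 1.0
    outside_window_frac: float = 0.0
    outside_margin: int = 10
    q_high: int = 37
    q_low: int = 12
    low_q_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.hdr_fraction + self.nhej_fraction + self.unmodified_fraction
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"category fractions sum to {total}, expected 1")
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        for name in ("error_rate", "deletion_prob", "aux_conversion_prob",
                     "outside_window_frac", "low_q_prob", "indel_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SimulatedReads:
    """Paired reads plus the per-molecule truth table."""

    pairs: list[ReadPair]
    truth: pd.DataFrame


def _sample_indel(rng: np.random.Generator, locus: TargetLocus, cfg: AmpliconSimConfig,
                  inside: bool) -> tuple[str, int, int]:
    """(kind, anchor/start, length) for one NHEJ molecule."""
    ref_len = len(locus.reference)
    window = locus.window
    kind = "deletion" if rng.random() < cfg.deletion_prob else "insertion"
    length = int(min(rng.geometric(cfg.indel_geom_p), cfg.max_indel_len))
    cut = window.cut_index
    if inside:
        if kind == "deletion":
            covered = int(rng.choice(sorted(window.deleted_coords)))
            start = int(rng.integers(covered - length + 1, covered + 1))
            start = max(10, min(start, ref_len - length - 10))
            return kind, start, length
        anchor = int(rng.choice(sorted(window.insertion_anchors)))
        return kind, anchor, length
    # Contaminant mode: strictly outside the window with a safety margin so
    # alignment-equivalent placements cannot drift into it.
    offset = window.w + cfg.outside_margin + length
    side = -1 if rng.random() < 0.5 else 1
    if kind == "deletion":
        start = cut + side * offset if side > 0 else cut - offset - length
        start = max(10, min(start, ref_len - length - 10))
        return kind, start, length
    anchor = cut + side * offset
    anchor = max(10, min(anchor, ref_len - 10))
    return kind, anchor, length


def _left_normalize(ref: str, kind: str, pos: int, length: int,
                    ins: str) -> tuple[int, str]:
    """Left-align an indel to its canonical placement.

    Indels inside repeats have several alignment-equivalent placements that
    yield the same molecule; truth coordinates are recorded left-aligned, the
    same convention the aligner's tie-breaking produces.
    """
    if kind == "deletion":
        while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
            pos -= 1
        return pos, ins
    while pos > 0 and ins[-1] == ref[pos - 1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def _apply_indel(seq: str, kind: str, pos: int, length: int, ins: str) -> str:
    if kind == "deletion":
        return seq[:pos] + seq[pos + length :]
    return seq[:pos] + ins + seq[pos:]


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _qual_string(n: int, cfg: AmpliconSimConfig, rng: np.random.Generator) -> str:
    qs = np.where(rng.random(n) < cfg.low_q_prob, cfg.q_low, cfg.q_high) + 33
    return qs.astype(np.uint8).tobytes().decode("ascii")


def simulate_amplicon_reads(
    cfg: AmpliconSimConfig, locus: TargetLocus | None = None
) -> SimulatedReads:
    """Simulate paired-end reads and a truth table from a locus bundle.

    Every pair derives from one molecule: the reference, the reference with
    donor conversions, or the reference with one sampled indel.  The truth
    table records the molecule class, its indel/conversion details and
    ``expected_call`` - the category the cut-window rules imply for an
    error-free read (an outside-window contaminant indel is expected to be
    called UNMODIFIED).
    """
    if locus is None:
        locus = example_locus()
    rng = np.random.default_rng(cfg.seed)
    ref = locus.reference.sequence
    if cfg.read_length < len(locus.donor.footprint):
        raise SimulationError("read length shorter than the donor footprint")
    counts = rng.multinomial(
        cfg.n_reads, [cfg.hdr_fraction, cfg.nhej_fraction, cfg.unmodified_fraction]
    )
    categories = np.repeat(["HDR", "NHEJ", "UNMODIFIED"], counts)
    rng.shuffle(categories)
    pairs: list[ReadPair] = []
    rows: list[dict] = []
    for i, category in enumerate(categories):
        read_id = f"read{i:06d}"
        row: dict = {
            "read_id": read_id, "category": category,
            "indel_kind": "", "indel_pos": -1, "indel_len": 0,
            "primary_converted": False, "aux_converted": 0,
        }
        if category == "HDR":
            mol = list(ref)
            p = locus.donor.primary
            mol[p.ref_coord] = p.donor_base
            row["primary_converted"] = True
            for e in locus.donor.auxiliary:
                if rng.random() < cfg.aux_conversion_prob:
                    mol[e.ref_coord] = e.donor_base
                    row["aux_converted"] += 1
            molecule = "".join(mol)
            row["expected_call"] = "HDR"
        elif category == "NHEJ":
            inside = rng.random() >= cfg.outside_window_frac
            # Rejection-sample so the *left-normalized* placement respects the
            # requested mode: strict-inside indels must still hit the window
            # after normalization (edge placements inside repeats can shift).
            for _ in range(100):
                kind, pos, length = _sample_indel(rng, locus, cfg, inside)
                ins = ""
                if kind == "insertion":
                    ins = rng.choice(_BASES, size=length).tobytes().decode("ascii")
                pos, ins = _left_normalize(ref, kind, pos, length, ins)
                hits = (
                    locus.window.hits_deletion(pos, length)
                    if kind == "deletion"
                    else locus.window.hits_insertion(pos)
                )
                if hits == inside:
                    break
            molecule = _apply_indel(ref, kind, pos, length, ins)
            row.update(indel_kind=kind, indel_pos=pos, indel_len=length)
            row["expected_call"] = "NHEJ" if hits else "UNMODIFIED"
        else:
            molecule = ref
            row["expected_call"] = "UNMODIFIED"
        row["molecule"] = molecule
        r1 = (molecule + ADAPTER_READTHROUGH_R1)[: cfg.read_length]
        r2 = (revcomp(molecule) + ADAPTER_READTHROUGH_R2)[: cfg.read_length]
        r1 = _sequencing_errors(r1, cfg.error_rate, rng)
        r2 = _sequencing_errors(r2, cfg.error_rate, rng)
        pairs.append(
            ReadPair(
                read_id,
                r1,
                _qual_string(len(r1), cfg, rng),
                r2,
                _qual_string(len(r2), cfg, rng),
            )
        )
        rows.append(row)
    return SimulatedReads(pairs=pairs, truth=pd.DataFrame(rows))


def write_paired_fastq(pairs: list[ReadPair], r1_path, r2_path) -> None:
    """Write simulated pairs as two (optionally gzipped) FASTQ files."""
    from .readprep import MergedRead, write_fastq

    write_fastq(
        (MergedRead(p.id, p.r1_seq, p.r1_qual, 0, "merged") for p in pairs), r1_path
    )
    write_fastq(
        (MergedRead(p.id, p.r2_seq, p.r2_qual, 0, "merged") for p in pairs), r2_path
    )


MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]


@dataclass(frozen=True)
class ScSimConfig:
    """Phase mixture and expression model for the single-cell simulator."""

    n_g0: int = 100
    n_g1s: int = 100
    n_g2m: int = 100
    fold_change: float = 10.0
    # Cell-cycle genes are largely silent outside the cycle (quiescent cells
    # are defined by lacking both marker programs), so the marker baseline is
    # a fraction of a typical gene's expression; phase-specific up-regulation
    # applies fold_change on top of this baseline.
    marker_baseline: float = 0.2
    n_background_genes: int = 2900
    libsize_log_mean: float = np.log(5000.0)
    libsize_log_sd: float = 0.3
    dispersion: float = 0.3
    mito_fraction: float = 0.03
    n_low_quality: int = 0  # extra cells with <= ~200 detected genes
    n_high_mito: int = 0  # extra cells with high mitochondrial fraction
    high_mito_fraction: float = 0.15
    condition: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_g0, self.n_g1s, self.n_g2m) < 1:
            raise SimulationError("need >= 1 cell per phase")
        if self.fold_change <= 0:
            raise SimulationError("fold_change must be > 0")


def simulate_sc_counts(cfg: ScSimConfig) -> tuple[AnnData, pd.Series]:
    """Simulate a sparse cells x genes count matrix with truth phase labels.

    G1S cells over-express the G1/S marker module by ``fold_change``; G2M
    cells the G2/M module; G0 cells neither.  Counts are gamma-Poisson with
    the configured dispersion; library sizes are log-normal.  Optional
    low-complexity and high-mito cells are appended (labelled ``LOWQ`` /
    ``HIMITO``) to exercise QC filtering.
    """
    g1s_markers, g2m_markers = default_cell_cycle_genes()
    if not g1s_markers or not g2m_markers:
        raise SimulationError("empty marker list")
    rng = np.random.default_rng(cfg.seed)
    background = [f"GENE{i:05d}" for i in range(cfg.n_background_genes)]
    genes = g1s_markers + g2m_markers + background + MITO_GENES
    n_genes = len(genes)
    g1s_idx = np.arange(len(g1s_markers))
    g2m_idx = np.arange(len(g1s_markers), len(g1s_markers) + len(g2m_markers))
    mito_idx = np.arange(n_genes - len(MITO_GENES), n_genes)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[g1s_idx] *= cfg.marker_baseline
    base[g2m_idx] *= cfg.marker_baseline
    base[mito_idx] = 0.0  # mito handled as a fixed fraction below

    labels = ["G0"] * cfg.n_g0 + ["G1S"] * cfg.n_g1s + ["G2M"] * cfg.n_g2m
    labels += ["LOWQ"] * cfg.n_low_quality + ["HIMITO"] * cfg.n_high_mito
    rows = []
    for label in labels:
        w = base.copy()
        if label == "G1S":
            w[g1s_idx] *= cfg.fold_change
        elif label == "G2M":
            w[g2m_idx] *= cfg.fold_change
        mito_frac = cfg.high_mito_fraction if label == "HIMITO" else cfg.mito_fraction
        w = w / w.sum() * (1.0 - mito_frac)
        w[mito_idx] = mito_frac / len(mito_idx)
        lib = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd)
        if label == "LOWQ":
            lib = 150.0  # far below the detected-genes QC threshold
        mean = w * lib
        lam = rng.gamma(1.0 / cfg.dispersion, mean * cfg.dispersion)
        rows.append(rng.poisson(lam))
    X = sparse.csr_matrix(np.vstack(rows).astype(np.int64))
    barcodes = [f"CELL{i:05d}" for i in range(len(labels))]
    adata = AnnData(
        X=X,
        obs=pd.DataFrame({"condition": cfg.condition}, index=barcodes),
        var=pd.DataFrame(index=genes),
    )
    return adata, pd.Series(labels, index=barcodes, name="true_phase")
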