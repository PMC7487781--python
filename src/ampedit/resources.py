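"""Packaged reference data: study oligonucleotides and cell-cycle marker lists."""

from __future__ import annotations

import logging
from importlib import resources

log = logging.getLogger(__name__)


def load_hbb_oligos() -> dict[str, str]:
    """The published HBB assay oligos (two primer sets and the ssODN donor).

    The sequences are stored verbatim.  Note that FP2 and RP1 are listed with
    the identical sequence in the source table (almost certainly a typo in the
    original); both entries are kept as printed and a warning is emitted
    rather than guessing the intended primer.
    """
    oligos: dict[str, str] = {}
    text = (
        resources.files("ampedit").joinpath("data/hbb_oligos.fasta").read_text()
    )
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                oligos[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        oligos[name] = "".join(chunks)
    if oligos.get("FP2", "").lower() == oligos.get("RP1", "").lower():
        log.warning(
            "FP2 and RP1 share the identical sequence %r (stored verbatim from "
            "the source table; likely a typo there)",
            oligos.get("FP2"),
        )
    return oligos


def default_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """Default (43 G1/S, 55 G2/M) human marker gene symbols.

    A reconstruction of the standard cell-cycle module lists (the published
    analysis prints only the counts and a few example genes); override with
    your own lists where exact reproduction matters.
    """
    text = (
        resources.files("ampedit").joinpath("data/cell_cycle_genes.tsv").read_text()
    )
    g1s: list[str] = []
    g2m: list[str] = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        gene, phase = line.split("\t")
        (g1s if phase == "G1S" else g2m).append(gene)
    return g1s, g2m
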