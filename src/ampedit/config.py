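"""YAML run configuration: locus bundle, stage parameters, validation.

A single config file drives all subcommands; command-line flags override
config keys.  Paths inside the config are resolved relative to the config
file's directory.
"""

from __future__ import annotations

import os
from typing import Any, Mapping

import yaml
from Bio import SeqIO

from .classify import TargetLocus
from .locus import LocusError, ReferenceAmplicon


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    cfg["_base_dir"] = os.path.dirname(os.path.abspath(str(path)))
    return cfg


def _read_single_fasta(path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ConfigError(f"{path}: expected exactly 1 FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def _resolve(base_dir: str, value: str) -> str:
    return value if os.path.isabs(value) else os.path.join(base_dir, value)


def load_locus(cfg: Mapping[str, Any]) -> TargetLocus:
    """Build a :class:`TargetLocus` from the ``locus`` section of a config.

    ``reference`` and ``donor`` accept either an inline sequence string or a
    FASTA path; ``primary_edit`` is a reference coordinate or
    ``nearest-to-cut``.
    """
    base = cfg.get("_base_dir", ".")
    section = cfg.get("locus")
    if not section:
        raise ConfigError("config is missing the 'locus' section")
    for key in ("reference", "protospacer", "donor"):
        if key not in section:
            raise ConfigError(f"locus config is missing {key!r}")
    ref_value = section["reference"]
    if isinstance(ref_value, str) and set(ref_value.upper()) <= set("ACGT"):
        reference = ReferenceAmplicon("amplicon", ref_value.upper())
    else:
        name, seq = _read_single_fasta(_resolve(base, str(ref_value)))
        reference = ReferenceAmplicon(name, seq)
    donor_value = str(section["donor"])
    if set(donor_value.upper()) <= set("ACGT"):
        donor = donor_value.upper()
    else:
        _, donor = _read_single_fasta(_resolve(base, donor_value))
    primary = section.get("primary_edit", "nearest-to-cut")
    if isinstance(primary, str) and primary != "nearest-to-cut":
        raise ConfigError(f"primary_edit must be an integer or 'nearest-to-cut', got {primary!r}")
    try:
        return TargetLocus.build(
            reference,
            str(section["protospacer"]).upper(),
            donor,
            w=int(section.get("window", 3)),
            pam=str(section.get("pam", "NGG")),
            primary=primary,
        )
    except LocusError as exc:
        raise ConfigError(f"invalid locus: {exc}") from exc


def stage_params(cfg: Mapping[str, Any], stage: str, defaults: Mapping[str, Any]) -> dict:
    """Merge a config section over stage defaults, rejecting unknown keys."""
    out = dict(defaults)
    section = cfg.get(stage) or {}
    unknown = set(section) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown {stage} parameter(s): {sorted(unknown)}")
    out.update(section)
    return out
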