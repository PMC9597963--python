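"""File formats, run configuration and provenance.

Canonical tabular dialect: TSV, UTF-8, '.' decimal, header row; CSV is
accepted on input.  FASTA is accepted for plain sequence lists.  Every
table written by the pipeline carries a provenance header of '#'
comment lines (config hash, seeds, package version); the timestamp-free
content is what the config hash covers, so identical configs reproduce
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .features import SCHEMA

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_guides", "write_table", "read_table", "write_schema"]

CANONICAL_COLUMNS = ("sequence30", "efficiency", "reads")


@dataclass
class RunConfig:
    """Validated run settings, serialized into every output's provenance."""

    column_map: dict = field(default_factory=dict)
    tm: dict = field(default_factory=dict)
    scaffold_sequence: str | None = None
    fold_engine: str = "RNAfold"
    read_threshold: int = 200
    fold_seed: int = 2022
    train_seed: int = 1
    bo_seed: int = 7
    threads: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_guides(
    path: str | Path,
    fmt: str | None = None,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read guide records from TSV, CSV or FASTA into canonical columns.

    ``column_map`` maps canonical names (sequence30, efficiency, reads)
    to the file's column names.  Rows whose sequence field is missing
    are dropped with their line numbers logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".csv": "csv", ".fa": "fasta", ".fasta": "fasta", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
    if fmt == "fasta":
        records = [
            {"sequence30": str(rec.seq).upper()} for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not records:
            logger.warning("no sequences found in %s", path)
        return pd.DataFrame(records, columns=["sequence30"])
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r} for {path}")
    sep = "\t" if fmt == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in frame.columns]
        if missing:
            raise ValueError(f"mapped columns absent from {path}: {missing}")
        frame = frame.rename(columns=rename)
    if frame.shape[1] == 1 and "sequence30" not in frame.columns:
        frame.columns = ["sequence30"]
    if "sequence30" not in frame.columns:
        raise ValueError(
            f"{path} lacks a 'sequence30' column; provide a column mapping"
        )
    bad = frame["sequence30"].isna()
    if bad.any():
        for line_no in (frame.index[bad] + 2).tolist():
            logger.warning("%s line %d: missing sequence; row dropped", path, line_no)
        frame = frame[~bad]
    keep = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    keep += [c for c in frame.columns if c not in keep]
    if frame.empty:
        logger.warning("%s contained no usable records", path)
    return frame[keep].reset_index(drop=True)


def _provenance_lines(config: RunConfig | None, extra: dict | None = None) -> list[str]:
    info = {"version": __version__}
    if config is not None:
        info["config_hash"] = config.config_hash()
        info["seeds"] = {
            "fold": config.fold_seed,
            "train": config.train_seed,
            "bo": config.bo_seed,
        }
    if extra:
        info.update(extra)
    return [f"# {k}: {json.dumps(v, sort_keys=True, default=str)}" for k, v in info.items()]


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    extra_provenance: dict | None = None,
) -> None:
    """Write a TSV with a '#'-commented provenance header."""
    path = Path(path)
    header = "\n".join(_provenance_lines(config, extra_provenance))
    body = frame.to_csv(sep="\t", index=False)
    path.write_text(header + "\n" + body)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_schema(path: str | Path) -> None:
    """Write the machine-readable 149-feature schema next to a feature table."""
    Path(path).write_text(SCHEMA.to_json())
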