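"""Study configuration, tabular I/O and structured logging.

A *study* is one authorized linkage: its configuration names the field
schema (which columns are identifiers, how each is normalized before
hashing), the hashing-key references, the encryption parameters, the EM
settings, the thresholds and the blocking plan. The configuration is
validated strictly — unknown keys are rejected — before anything runs, and
every source of randomness flows from the declared seed.
"""

from __future__ import annotations

import csv
import json
import logging
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .normalize import TRANSFORMS

__all__ = [
    "StudyConfig", "FieldSpec", "EMSettings", "ConfigError", "DataIntegrityError",
    "load_study_config", "read_records", "write_records",
    "get_logger", "register_secret",
]


class ConfigError(ValueError):
    """Invalid study configuration."""


class DataIntegrityError(ValueError):
    """Input data violates its declared schema (missing column, duplicate id)."""


# --- configuration schema ----------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FieldSpec(_Strict):
    role: Literal["identifier", "payload"] = "payload"
    normalize: list[str] = Field(default_factory=list)
    date_dialect: str = "dmy"

    @field_validator("normalize")
    @classmethod
    def _known_transforms(cls, v: list[str]) -> list[str]:
        unknown = [t for t in v if t not in TRANSFORMS]
        if unknown:
            raise ValueError(f"unknown normalization transform(s): {unknown}")
        return v


class EMSettings(_Strict):
    init_m: float = 0.9
    init_u: float = 0.1
    init_p: float = 0.01
    tol: float = 1e-6
    max_iter: int = 500


class StudyConfig(_Strict):
    """Declarative description of one linkage study."""

    study_id: str
    fields: dict[str, FieldSpec] = Field(default_factory=dict)
    id_field: Optional[str] = None            # linkage identifier column
    key_files: dict[str, str] = Field(default_factory=dict)  # HK1/HK2 -> path
    random_chain_len: int = 16
    rsa_bits: int = 2048
    log_base: float = 2.0
    em: EMSettings = Field(default_factory=EMSettings)
    lower_threshold: float = 0.0
    upper_threshold: float = 0.0
    blocking: list[list[str]] = Field(default_factory=list)
    missing_is_disagreement: bool = False
    minimal_transfer: bool = False
    seed: Optional[int] = None

    @property
    def identifier_fields(self) -> tuple[str, ...]:
        return tuple(n for n, s in self.fields.items() if s.role == "identifier")

    @property
    def compare_fields(self) -> tuple[str, ...]:
        return self.identifier_fields


def load_study_config(path: str) -> StudyConfig:
    """Load and validate a YAML/JSON study configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    try:
        return StudyConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(f"{path}: {exc}") from exc


# --- tabular I/O -------------------------------------------------------------

def read_records(path: str, required_columns: list[str] | None = None,
                 id_column: str | None = None,
                 ) -> tuple[pd.DataFrame, list[int]]:
    """Read a CSV record file, quarantining malformed rows.

    Returns ``(records, quarantined_line_numbers)``. Rows whose field count
    differs from the header are quarantined with their 1-based line number
    rather than aborting the read. Missing declared columns and duplicate
    neutral identifiers raise :class:`DataIntegrityError`.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataIntegrityError(f"{path}: empty file, no header") from None
        rows, quarantined = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                quarantined.append(lineno)
            else:
                rows.append(row)
    frame = pd.DataFrame(rows, columns=header)
    for col in header:  # fully numeric columns come back typed, strings stay strings
        if len(frame):
            converted = pd.to_numeric(frame[col], errors="coerce")
            if converted.notna().all():
                frame[col] = converted
    if required_columns:
        missing = [c for c in required_columns if c not in frame.columns]
        if missing:
            raise DataIntegrityError(f"{path}: missing declared column(s) {missing}")
    if id_column and id_column in frame.columns:
        dupes = frame[id_column][frame[id_column].duplicated()]
        if not dupes.empty:
            raise DataIntegrityError(
                f"{path}: duplicate neutral identifier(s) in {id_column!r}: "
                f"{dupes.unique()[:5].tolist()}")
    return frame, quarantined


def write_records(records: pd.DataFrame, path: str,
                  sort_by: str | list[str] | None = None) -> None:
    """Write records as UTF-8 CSV with deterministic row and column order."""
    out = records
    if sort_by:
        out = records.sort_values(sort_by, kind="stable")
    out.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


# --- logging -----------------------------------------------------------------

_SECRETS: list[str] = []


def register_secret(secret: bytes | str) -> None:
    """Register secret material so the log filter can redact it."""
    text = secret.hex() if isinstance(secret, (bytes, bytearray)) else str(secret)
    if text and text not in _SECRETS:
        _SECRETS.append(text)
        if isinstance(secret, (bytes, bytearray)):
            try:
                _SECRETS.append(secret.decode("utf-8"))
            except UnicodeDecodeError:
                pass


class _RedactionFilter(logging.Filter):
    def filter(self, record: logging.LogRecord) -> bool:
        msg = record.getMessage()
        for s in _SECRETS:
            if s in msg:
                msg = msg.replace(s, "[REDACTED]")
        record.msg, record.args = msg, ()
        return True


class _JsonLinesFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        return json.dumps({"level": record.levelname, "logger": record.name,
                           "message": record.getMessage()})


def get_logger(name: str = "securelink") -> logging.Logger:
    """Structured JSON-lines logger with secret redaction."""
    logger = logging.getLogger(name)
    if not any(isinstance(f, _RedactionFilter) for f in logger.filters):
        logger.addFilter(_RedactionFilter())
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(_JsonLinesFormatter())
        logger.addHandler(handler)
    return logger
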