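"""Readers, writers and run manifests.

Response tables are delimited text (CSV/TSV with a header) or JSON-lines
with the same keys; both render the columns ``response_id, clip_id,
subject_id, condition, text``.  Corpora are plain text, one document per
line.  All files are UTF-8.

Every CLI run emits a JSON *manifest* recording the subcommand, SHA-256
digests of its inputs, the configuration snapshot, the master seed and the
package version — enough to re-run the command and reproduce its outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DuplicateResponseIdError, MissingColumnError, ValidationError
from .preprocessing import RawResponse

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSE_COLUMNS",
    "read_responses",
    "write_responses",
    "read_corpus",
    "read_scores",
    "write_scores",
    "read_curve",
    "write_curve",
    "read_errors",
    "write_errors",
    "read_trials",
    "write_trials",
    "RunManifest",
    "write_manifest",
]

RESPONSE_COLUMNS = ["response_id", "clip_id", "subject_id", "condition", "text"]
_REQUIRED = ["response_id", "clip_id", "subject_id", "text"]


def _infer_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def read_responses(
    path: str | Path, format_hint: Optional[str] = None
) -> list[RawResponse]:
    """Read a response table (CSV, TSV or JSON-lines) into RawResponses.

    Validates that the required columns are present, ``response_id`` values
    are unique and ``clip_id`` is never empty.  The ``condition`` column is
    optional (defaults to empty); empty ``text`` is allowed and logged.
    """
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "jsonl":
        df = pd.read_json(path, lines=True, dtype=str)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(
            path, sep="\t" if fmt == "tsv" else ",", dtype=str, keep_default_na=False
        )
    else:
        raise ValidationError(f"unknown response format {fmt!r}")
    if fmt == "jsonl":
        df = df.fillna("")

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if "condition" not in df.columns:
        df["condition"] = ""

    dupes = df.loc[df["response_id"].duplicated(), "response_id"].tolist()
    if dupes:
        raise DuplicateResponseIdError(
            f"{path}: duplicate response_id values: {sorted(set(dupes))}"
        )
    blank_clip = df.index[df["clip_id"].astype(str).str.strip() == ""].tolist()
    if blank_clip:
        rows = [i + 2 for i in blank_clip]  # 1-based, after the header
        raise ValidationError(f"{path}: empty clip_id on data line(s) {rows}")

    n_empty = int((df["text"].astype(str).str.strip() == "").sum())
    if n_empty:
        logger.warning("%s: %d responses have empty text", path, n_empty)

    return [
        RawResponse(
            response_id=str(r.response_id),
            clip_id=str(r.clip_id),
            subject_id=str(r.subject_id),
            condition=str(r.condition),
            text=str(r.text),
        )
        for r in df.itertuples(index=False)
    ]


def write_responses(
    responses: Iterable[RawResponse], path: str | Path, format_hint: Optional[str] = None
) -> None:
    """Write responses in the standard column order; round-trips losslessly."""
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    df = pd.DataFrame(
        [dataclasses.asdict(r) for r in responses], columns=RESPONSE_COLUMNS
    )
    if fmt == "jsonl":
        df.to_json(path, orient="records", lines=True, force_ascii=False)
    else:
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)


def read_corpus(path: str | Path) -> list[str]:
    """Plain-text corpus: one document per line; blank lines are skipped."""
    docs = [
        line for line in Path(path).read_text(encoding="utf-8").splitlines() if line.strip()
    ]
    if not docs:
        raise ValidationError(f"{path}: corpus contains no documents")
    return docs


def _write_table(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"table missing columns {missing}")
    df.loc[:, list(columns)].to_csv(Path(path), index=False)


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


SCORE_COLUMNS = ["response_id", "clip_id", "method", "score"]
CURVE_COLUMNS = ["n", "replicate", "fraction_correct"]
ERROR_COLUMNS = ["response_id", "n", "replicate", "error"]
TRIAL_COLUMNS = ["subject_id", "clip_id", "condition", "rank", "score"]


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path, SCORE_COLUMNS)


def read_scores(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SCORE_COLUMNS)


def write_curve(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path, CURVE_COLUMNS)


def read_curve(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CURVE_COLUMNS)


def write_errors(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path, ERROR_COLUMNS)


def read_errors(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ERROR_COLUMNS)


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path, TRIAL_COLUMNS)


def read_trials(path: str | Path) -> pd.DataFrame:
    return _read_table(path, TRIAL_COLUMNS)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one CLI run."""

    subcommand: str
    inputs: dict[str, str]  # logical name -> "path:sha256"
    config: dict
    seed: Optional[int]
    version: str
    timestamp: str


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    subcommand: str,
    inputs: dict[str, str | Path],
    config: dict,
    seed: Optional[int],
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        subcommand=subcommand,
        inputs={
            name: f"{p}:{_digest(p)}"
            for name, p in inputs.items()
            if str(p) and Path(p).is_file()
        },
        config=config,
        seed=seed,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    Path(path).write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return manifest
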