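"""MedDRA preferred-term dictionary for drug resistance and ineffectiveness.

Spontaneous adverse-event databases code each reported reaction as a MedDRA
Preferred Term (PT).  Lack-of-efficacy reporting is spread over a small set
of PTs — two describing acquired drug resistance and eleven describing
ineffectiveness (treatment failure, non-response, incomplete effect, ...).
This module ships that fixed 13-term dictionary as packaged data and
classifies arbitrary PTs against it.

The dictionary is data, not code: ``data/meddra_pt_dictionary.csv`` can be
replaced or extended (via :func:`load_dictionary`) to screen other medical
conditions without touching the classifier.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "PTEntry",
    "builtin_dictionary",
    "load_dictionary",
    "classify_pt",
    "dictionary_checksum",
]


class Condition(str, Enum):
    """Medical-condition label attached to a PT.

    ``OTHER`` is not a dictionary entry: it is the label assigned to any PT
    absent from the dictionary.
    """

    RESISTANCE = "resistance"
    INEFFECTIVENESS = "ineffectiveness"
    OTHER = "other"


#: The two conditions that carry dictionary entries.
DICTIONARY_CONDITIONS = (Condition.RESISTANCE, Condition.INEFFECTIVENESS)


@dataclass(frozen=True)
class PTEntry:
    """One MedDRA preferred term with its condition assignment.

    Attributes
    ----------
    code : int
        Eight-digit numeric MedDRA PT identifier.
    name : str
        Canonical PT string as it appears in line listings.
    condition : Condition
        Either ``RESISTANCE`` or ``INEFFECTIVENESS``; never ``OTHER``.
    """

    code: int
    name: str
    condition: Condition


def _parse_dictionary(rows: Iterable[dict], source: str) -> tuple[PTEntry, ...]:
    entries: list[PTEntry] = []
    seen_codes: set[int] = set()
    for i, row in enumerate(rows, start=2):  # header is line 1
        try:
            code = int(row["code"])
            name = row["pt_name"].strip()
            condition = Condition(row["condition"].strip().lower())
        except (KeyError, TypeError) as exc:
            raise FormatError(
                f"{source}: line {i}: missing column {exc}"
            ) from exc
        except ValueError as exc:
            raise FormatError(f"{source}: line {i}: {exc}") from exc
        if condition is Condition.OTHER:
            raise FormatError(
                f"{source}: line {i}: 'other' is not a valid dictionary condition"
            )
        if not name:
            raise FormatError(f"{source}: line {i}: empty PT name")
        if code in seen_codes:
            raise FormatError(f"{source}: line {i}: duplicate PT code {code}")
        seen_codes.add(code)
        entries.append(PTEntry(code=code, name=name, condition=condition))
    return tuple(entries)


def load_dictionary(path: Union[str, Path]) -> tuple[PTEntry, ...]:
    """Load a PT dictionary from a ``code,pt_name,condition`` CSV file."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != {
            "code",
            "pt_name",
            "condition",
        }:
            raise FormatError(
                f"{path}: expected header 'code,pt_name,condition', "
                f"got {reader.fieldnames}"
            )
        return _parse_dictionary(reader, str(path))


_BUILTIN: Optional[tuple[PTEntry, ...]] = None


def builtin_dictionary() -> tuple[PTEntry, ...]:
    """Return the packaged 13-entry dictionary (2 resistance, 11 ineffectiveness).

    The tuple is immutable and cached; entries preserve file order.
    """
    global _BUILTIN
    if _BUILTIN is None:
        ref = resources.files("pvdispro").joinpath("data/meddra_pt_dictionary.csv")
        with ref.open(newline="", encoding="utf-8") as fh:
            _BUILTIN = _parse_dictionary(csv.DictReader(fh), str(ref))
    return _BUILTIN


def classify_pt(
    code: Optional[Union[int, str]] = None,
    name: Optional[str] = None,
    dictionary: Optional[Iterable[PTEntry]] = None,
) -> Condition:
    """Classify a PT by code and/or name against a dictionary.

    Matching is by code first; a name, when given, is matched by
    case-insensitive exact comparison after whitespace trimming.  If both
    code and name are supplied and disagree, the code wins and a warning is
    logged.  Any PT absent from the dictionary classifies as
    ``Condition.OTHER``.

    Parameters
    ----------
    code : int or str, optional
        Numeric MedDRA PT code.
    name : str, optional
        PT name.
    dictionary : iterable of PTEntry, optional
        Defaults to :func:`builtin_dictionary`.

    Raises
    ------
    InputError
        If neither a code nor a non-empty name is supplied.
    """
    entries = tuple(dictionary) if dictionary is not None else builtin_dictionary()

    code_int: Optional[int] = None
    if code is not None and str(code).strip():
        try:
            code_int = int(str(code).strip())
        except ValueError as exc:
            raise InputError(f"PT code is not numeric: {code!r}") from exc
    name_norm = name.strip().lower() if name is not None else ""

    if code_int is None and not name_norm:
        raise InputError("classify_pt needs a PT code or a non-empty PT name")

    by_code = {e.code: e for e in entries}
    by_name = {e.name.strip().lower(): e for e in entries}

    code_hit = by_code.get(code_int) if code_int is not None else None
    name_hit = by_name.get(name_norm) if name_norm else None

    if code_hit is not None:
        if name_hit is not None and name_hit.condition is not code_hit.condition:
            logger.warning(
                "PT code %d (%s) and name %r disagree; using the code",
                code_hit.code,
                code_hit.condition.value,
                name,
            )
        return code_hit.condition
    if code_int is not None:
        # An explicit code that is not in the dictionary is authoritative,
        # even if the name would have matched.
        if name_hit is not None:
            logger.warning(
                "PT code %s not in dictionary but name %r matches; using the code",
                code_int,
                name,
            )
        return Condition.OTHER
    if name_hit is not None:
        return name_hit.condition
    return Condition.OTHER


def dictionary_checksum(dictionary: Optional[Iterable[PTEntry]] = None) -> str:
    """SHA-256 over the sorted (code, name, condition) triples.

    Recorded in run manifests so a changed term set is visible in outputs.
    """
    import hashlib

    entries = tuple(dictionary) if dictionary is not None else builtin_dictionary()
    payload = "\n".join(
        f"{e.code}\t{e.name}\t{e.condition.value}"
        for e in sorted(entries, key=lambda e: e.code)
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
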