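"""Readers/writers for formulation records (YAML 1.2 subset or JSON).

JSON is a subset of YAML, so a single ``yaml.safe_load`` front end accepts
both dialects.  Serialisation drops fields that equal their defaults and
empty sections, producing documents that read like hand-written records and
round-trip to an identical :class:`~pqtpp.model.FormulationProduct`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import yaml
from pydantic import ValidationError

from .model import FormulationProduct

__all__ = [
    "FormulationError",
    "FormulationParseError",
    "FormulationValidationError",
    "read_formulation",
    "reads_formulation",
    "write_formulation",
]


class FormulationError(Exception):
    """Base class for record-level input errors."""


class FormulationParseError(FormulationError):
    """The document is not well-formed YAML/JSON."""


class FormulationValidationError(FormulationError):
    """The document parses but violates the record schema.

    ``errors`` holds one ``"path.to.field: message"`` line per violation.
    """

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid formulation record:\n  " + "\n  ".join(errors))


def _format_errors(exc: ValidationError) -> list[str]:
    lines = []
    for err in exc.errors():
        path = ".".join(str(part) for part in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return lines


def reads_formulation(text: str) -> FormulationProduct:
    """Parse and validate a record from a YAML/JSON string."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormulationParseError(f"cannot parse document: {exc}") from exc
    if not isinstance(data, dict):
        raise FormulationParseError("document root must be a mapping")
    try:
        return FormulationProduct.model_validate(data)
    except ValidationError as exc:
        raise FormulationValidationError(_format_errors(exc)) from exc


def read_formulation(source: Union[str, Path]) -> FormulationProduct:
    """Read and validate a formulation record file (YAML or JSON)."""
    return reads_formulation(Path(source).read_text(encoding="utf-8"))


def _prune(value):
    """Drop ``None`` values and empty containers, recursively."""
    if isinstance(value, dict):
        pruned = {k: _prune(v) for k, v in value.items()}
        return {k: v for k, v in pruned.items() if v is not None and v != {} and v != []}
    if isinstance(value, list):
        return [_prune(v) for v in value]
    return value


def product_to_dict(product: FormulationProduct) -> dict:
    """Canonical plain-dict form of a product (defaults and empties omitted)."""
    return _prune(product.model_dump(mode="json", exclude_defaults=True))


def write_formulation(
    product: FormulationProduct,
    path: Union[str, Path, None] = None,
    fmt: str = "yaml",
) -> str:
    """Serialise a product to YAML (default) or canonical JSON.

    Returns the document text; also writes it to ``path`` when given.
    """
    data = product_to_dict(product)
    if fmt == "yaml":
        text = yaml.safe_dump(data, sort_keys=False, allow_unicode=True)
    elif fmt == "json":
        text = json.dumps(data, indent=2, sort_keys=True) + "\n"
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
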