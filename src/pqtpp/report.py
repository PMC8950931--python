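"""Heat-map and tabular reports for assessment profiles.

Rows are the eight attributes in fixed rubric order, columns are products;
each cell is a score with its traffic-light colour.  CSV and JSON output is
byte-stable for a fixed input; HTML is a single self-contained document with
inline styles and a colour legend.
"""

from __future__ import annotations

import csv
import io
import json
from html import escape
from typing import Sequence

from .scoring import ATTRIBUTE_LABELS, ATTRIBUTE_ORDER, SCORE_COLOURS, PQTPPProfile

__all__ = ["render", "FORMATS"]

FORMATS = ("csv", "json", "html")

_CELL_STYLE = {
    "green": "background:#2e9e4f;color:#fff",
    "yellow": "background:#f2c744;color:#222",
    "red": "background:#d1452c;color:#fff",
    "grey": "background:#9b9b9b;color:#fff",
}


def render(profiles: Sequence[PQTPPProfile], fmt: str = "csv") -> str:
    """Render one or more profiles as ``csv``, ``json`` or ``html``."""
    if not profiles:
        raise ValueError("need at least one profile to render")
    if fmt == "csv":
        return _render_csv(profiles)
    if fmt == "json":
        return _render_json(profiles)
    if fmt == "html":
        return _render_html(profiles)
    raise ValueError(f"unknown report format {fmt!r}; choose from {FORMATS}")


def _render_csv(profiles: Sequence[PQTPPProfile]) -> str:
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(["attribute", *(p.product_label for p in profiles)])
    for idx, attribute in enumerate(ATTRIBUTE_ORDER):
        writer.writerow(
            [ATTRIBUTE_LABELS[attribute], *(p.scores[idx].score for p in profiles)]
        )
    return buffer.getvalue()


def _render_json(profiles: Sequence[PQTPPProfile]) -> str:
    return json.dumps([p.to_dict() for p in profiles], indent=2, sort_keys=True) + "\n"


def _render_html(profiles: Sequence[PQTPPProfile]) -> str:
    head = "".join(
        f'<th style="padding:6px 10px">{escape(p.product_label)}</th>' for p in profiles
    )
    rows = []
    for idx, attribute in enumerate(ATTRIBUTE_ORDER):
        cells = []
        for profile in profiles:
            score = profile.scores[idx]
            cells.append(
                f'<td style="{_CELL_STYLE[score.colour]};text-align:center;'
                f'padding:6px 10px" title="{escape(score.rationale)}">{score.score}</td>'
            )
        rows.append(
            f'<tr><td style="padding:6px 10px">{ATTRIBUTE_LABELS[attribute]}</td>'
            + "".join(cells)
            + "</tr>"
        )
    legend = " ".join(
        f'<span style="{_CELL_STYLE[colour]};padding:2px 8px">{score} = {colour}</span>'
        for score, colour in sorted(SCORE_COLOURS.items(), reverse=True)
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>pQTPP heat map</title></head><body>"
        "<h1>Paediatric formulation appropriateness heat map</h1>"
        f"<p>Legend: {legend}</p>"
        "<table style='border-collapse:collapse;font-family:sans-serif'>"
        f"<thead><tr><th style='padding:6px 10px'>Attribute</th>{head}</tr></thead>"
        f"<tbody>{''.join(rows)}</tbody></table></body></html>\n"
    )
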