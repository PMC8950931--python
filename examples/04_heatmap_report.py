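"""Render a multi-product heat-map report.

Scores the three paracetamol dosage forms and writes the 8x3 matrix as CSV
(printed below) and as a self-contained HTML heat map.  No single dosage
form is green across the board: tablets fail young children, the liquid
fails on excipients, the suppository has limited dose flexibility - which
is exactly why several forms are listed side by side.
"""

from pathlib import Path

from pqtpp import assemble_profile, load_fixture, render

profiles = [
    assemble_profile(load_fixture(name))
    for name in ("paracetamol_tablet", "paracetamol_oral_liquid",
                 "paracetamol_suppository_100mg")
]

csv_doc = render(profiles, "csv")
print(csv_doc)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
html_path = out / "paracetamol_heatmap.html"
html_path.write_text(render(profiles, "html"), encoding="utf-8")
print(f"HTML heat map written to {html_path}")
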