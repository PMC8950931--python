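"""Screen a formulation's excipients against the concern registry.

The paracetamol oral liquid lists a benzoate preservative, a polyol
sweetener, sucrose and an azo colourant.  Because the product is indicated
from birth, the benzoate is a known concern (neonatal accumulation risk);
together the findings push the excipient-safety attribute to red.
Quantities are not public, so findings are presence-based.
"""

from pqtpp import evaluate_excipients, load_fixture
from pqtpp.scoring import score_excipient_safety

liquid = load_fixture("paracetamol_oral_liquid")
findings = evaluate_excipients(liquid)

for finding in findings:
    print(f"  {finding.excipient:<22} {finding.concern_level:<10} {finding.rationale}")

score = score_excipient_safety(findings, liquid)
print(f"\nExcipient-safety score: {score.score} ({score.colour}) - {score.rationale}")
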