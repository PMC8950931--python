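"""Score one formulation record and print its traffic-light profile.

Loads the bundled clofazimine soft-gel capsule record and runs the full
eight-attribute assessment.  Each line prints the attribute, its score
(3 green = meets target, 2 yellow = partially, 1 red = does not meet,
0 grey = insufficient information) and the rationale the engine recorded.
"""

from pqtpp import ATTRIBUTE_LABELS, assemble_profile, load_fixture

product = load_fixture("clofazimine_capsule_50_100")
profile = assemble_profile(product)

print(f"{profile.product_label}\n")
for score in profile.scores:
    label = ATTRIBUTE_LABELS[score.attribute]
    print(f"  {label:<34} {score.score} ({score.colour:<6}) {score.rationale}")
print(f"\nScore vector: {profile.vector()}")
print("A 1 (red) on acceptability 0-5 years flags the formulation gap for "
      "young children who cannot swallow capsules.")
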