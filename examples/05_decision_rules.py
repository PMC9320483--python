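"""The section-level decision cascade and the relative-area rule.

Shows how measured BD/SK areas turn into a diagnosis.  In cascade mode a
section is BD as soon as its BD area reaches delta1 = 0.0256 mm^2; the
relative-area mode additionally requires r = 100*BD/(BD+SK) >= 20%, which
re-labels sections with a small BD fraction (the irritated-SK pattern)
as SK.
"""

from skinseg import DecisionParams, classify_section

cascade = DecisionParams()  # thresholds 0.5/0.6, delta1/delta2 per Table defaults
relative = DecisionParams(mode="relative_area")

cases = [
    ("dominant BD lesion", 0.20, 0.095),
    ("small BD focus in a large SK lesion", 0.03, 0.50),
    ("no lesion above the minimum areas", 0.01, 0.02),
]
for name, bd, sk in cases:
    a = classify_section(bd, sk, cascade)
    b = classify_section(bd, sk, relative)
    print(f"{name}: BD={bd} mm^2 SK={sk} mm^2 r={b.r_percent:5.1f}% "
          f"-> cascade: {a.label:6s} relative-area: {b.label}")
# The second case flips from BD to SK under the relative-area rule:
# its r is far below the 20% cutoff even though the BD area passes delta1.
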