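"""Combine curated ACMG-AMP evidence codes into classifications.

Three evidence sets for germline candidates in a two-affected-sibling
family: a truncating variant with very-strong + strong evidence, an
initiator-codon variant with two strong criteria, and a missense variant
with only moderate/supporting (and contradictory computational) evidence.
"""

from quartetprio import combine_evidence, parse_evidence

EVIDENCE_SETS = {
    "stop-gain, APC-like": "PVS1, PS1, PP1-S, PM2, PP3, BP1",
    "start-loss, WAS-like": "PS1, PS3, PM2, PM4, PP3",
    "missense, RAD54L-like": "PM2, PP3, BP4, PM5",
}

for label, tokens in EVIDENCE_SETS.items():
    result = combine_evidence(parse_evidence(tokens))
    print(f"{label:24s} [{tokens}] -> {result.label()}")

# The first two reach Pathogenic (clause Ia: very-strong + strong; clause
# II: two strong). The third satisfies no combining clause and stays a
# variant of uncertain significance. Note BP1 next to PVS1+PS1 does NOT
# trigger the conflict rule: a single benign-supporting criterion never
# reaches a benign classification on its own.
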