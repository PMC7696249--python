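"""Roll screen hits up to annotated drug targets and apply the >=3-drug filter.

Plants two driver targets in a 2100-compound annotated library — 9 of 11
proteasome inhibitors and 3 of 4 CRM1 (XPO1, nuclear export) inhibitors
killing more than 50% in both cell lines — and shows the roll-up selecting
exactly those two targets out of 200.
"""

import crosskill as ck

annotation, truth = ck.generate_compound_library(
    n_targets=200,
    driver_spec=[("proteasome", 11, 9), ("CRM1", 4, 3)],
    seed=0, n_compounds=2100, noise_sd=8.0)
lines = [("D418", "dog"), ("17-3X", "human")]
wells = ck.generate_screen(truth, lines, seed=1)
matrix = ck.aggregate_replicates(ck.normalize_plates(wells))
hits = ck.call_hits(matrix, threshold=50.0)

result = ck.rollup(hits, annotation, level="target", min_drugs=3,
                   threshold=50.0, require_lines="all", strict=True)
print("top of the target roll-up (drugs killing >50% in BOTH lines):")
print(result.table.head(6).to_string(index=False))
print(f"\ntargets passing the >=3-drug filter: {result.passing}")
print("(the two planted drivers; all 198 background targets are rejected)")
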