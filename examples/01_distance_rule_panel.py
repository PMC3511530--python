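"""Apply the 200 bp distance rule to the characterized regulator panel.

Builds context calls from the packaged nine-pair panel (regulators from
S. coelicolor and S. griseus whose regulation was settled experimentally)
and predicts which divergent neighbors are direct regulatory targets.
"""
from tfrctx import Thresholds, predict_targets
from tfrctx.reference import load_reference_pairs, reference_context_calls

pairs = load_reference_pairs().set_index("tfr_locus")
preds = predict_targets(reference_context_calls(), Thresholds())

print(f"{'regulator':<10} {'target':<9} {'separation':>10}  predicted  observed")
for p in sorted(preds, key=lambda p: p.separation_bp):
    row = pairs.loc[p.tfr_locus]
    print(
        f"{row.tfr_name:<10} {p.target_locus:<9} {p.separation_bp:>7} bp  "
        f"{str(p.predicted):<9}  {row.regulation}"
    )

n = sum(p.predicted for p in preds)
print(f"\n{n} of {len(preds)} divergent pairs fall within 200 bp.")
print("Every predicted pair is a confirmed repressor/target pair; the")
print("regulators beyond 200 bp either do not regulate the neighbor or,")
print("in one case (AtrA), activate it — the rule flags direct repression.")
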