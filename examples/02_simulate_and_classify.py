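"""Generate a synthetic replicon and recover the planted genome contexts.

A 30-regulator replicon is generated with the survey-like group mix
(67% divergent / 15% operonic / 18% other), classified, and scored
against the planted ground truth.
"""
from tfrctx import FixtureSpec, Thresholds, classify_context, evaluate_recovery, generate_fixture, predict_targets, tfr_loci

spec = FixtureSpec(n_tfr=30, seed=2024)
bundle, truth = generate_fixture(spec)
rep = bundle.replicons[0]
print(f"replicon {rep.replicon_id}: {rep.length:,} bp, {len(rep.genes)} genes, "
      f"{spec.n_tfr} regulators planted")

calls = classify_context(bundle, tfr_loci(truth), Thresholds())
for group in ("DIVERGENT", "OPERONIC", "OTHER"):
    n = sum(1 for c in calls if c.group.value == group)
    print(f"  {group:<9} {n}")

preds = predict_targets(calls)
print(f"predicted targets at <=200 bp: {sum(p.predicted for p in preds)} "
      f"of {len(preds)} divergent pairs")

report = evaluate_recovery(truth, calls)
print(f"group recovery {report.group_accuracy:.0%}, "
      f"separation match {report.separation_match_rate:.0%}")
print("Recovery of 100% means classification reproduced every planted")
print("orientation group and every start-to-start separation exactly.")
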