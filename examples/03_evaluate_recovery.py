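"""Score an inferred network against the simulator's ground truth.

Precision/recall/f1 are computed at a chosen existence-weight threshold;
AUPR sweeps all observed weights.  Sign accuracy is the fraction of true
positive edges whose consensus sign matches the true coefficient's sign.
"""

from causnet import (
    evaluate_recovery,
    run_perturbation_analysis,
    sample_network,
    simulate_dataset,
    summarize_replicates,
)

gt = sample_network(G=10, k_true=2, seed=1, process_sd=0.05, measurement_sd=0.2)
ds = simulate_dataset(gt, C=10, T=3, R=3, seed=2)

net = run_perturbation_analysis(
    summarize_replicates(ds), ds.gene_ids, ds.condition_ids, ds.time_labels,
    n_perturbations=100, seed=42, k=2, virtual_shift=False,
)

for threshold in (0.1, 0.5, 0.9):
    m = evaluate_recovery(gt, net, threshold=threshold)
    print(f"threshold {threshold:.1f}: precision={m.precision:.3f} "
          f"recall={m.recall:.3f} f1={m.f1:.3f} sign_acc={m.sign_accuracy:.3f}")
m = evaluate_recovery(gt, net, threshold=0.5)
print(f"AUPR over all weights: {m.aupr:.3f} "
      f"({m.n_true} true edges in a {len(gt.gene_ids)}-gene universe)")
# Raising the threshold trades recall for precision; AUPR summarizes the
# whole trade-off curve in one number (1.0 = perfect ranking).
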