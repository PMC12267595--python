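"""Design single-residue mutants and scan a protein for inducing regions.

The design module enumerates all 19L single-point substitutions of a
peptide and ranks them by hybrid score; the scan module slides a
fixed-length window along a protein and scores every fragment.
"""

from il2kit import descriptors, io, models
from il2kit.apps import design, scan
from il2kit.motifs import mine_motifs
from il2kit.synth import SyntheticConfig, generate

data = generate(SyntheticConfig(seed=1))
split = io.split_dataset(data, ratio=0.2, seed=1)
train_fm = descriptors.compute_feature_set(split.train, "DPC_LEN")
predictor = models.train(
    train_fm, split.train.labels(),
    models.ModelSpec("ET", grid={"n_estimators": [250]}, seed=1),
)
motifs = mine_motifs(split.train.positives(), split.train.negatives(), "NONE", fp=0)[:10]

parent = "KWFYMHNPACDEF"
ranked = design(parent, predictor, motifs)
print(f"{len(ranked)} variants of {parent} (19*13 mutants + parent); top 3:")
print(ranked.head(3)[["mutant", "sequence", "final_score", "call"]].to_string(index=False))

protein = "MKT" + "ALEGSLQ" + "WFYMHNPACDEFGHIKLMNPQRS"
windows = scan(protein, predictor, window=15, step=1, pos_motifs=motifs)
best = windows.loc[windows["final_score"].idxmax()]
print(f"\n{len(windows)} windows scanned; best region "
      f"{int(best['start_1based'])}-{int(best['end_1based'])}: "
      f"{best['sequence']} (score {best['final_score']:.3f})")
# Windows overlapping the planted motif should score highest.
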