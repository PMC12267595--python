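"""Compute the descriptor families for a handful of peptides.

Shows amino-acid composition, dipeptide composition with length, and the
composition/transition/distribution descriptor, and prints the matrix
shapes a classifier would consume.
"""

from il2kit import compute_aac, compute_feature_set
from il2kit.io import PeptideDataset, PeptideRecord

peptides = PeptideDataset([
    PeptideRecord("p1", "ALEGSLQKWFYMHNP"),
    PeptideRecord("p2", "CCDDTTCCDDTTCCD"),
    PeptideRecord("p3", "ACDEFGHIKLMNPQR"),
])

aac = compute_aac("ALEGSLQ")
print("AAC of ALEGSLQ (% per residue, A..Y):")
print(aac.round(1))  # sums to 100; L appears twice -> 28.6%

for tag in ("AAC", "DPC_LEN", "CTD", "AAB"):
    fm = compute_feature_set(peptides, tag)
    print(f"{tag}: {fm.frame.shape[0]} peptides x {fm.frame.shape[1]} features")
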