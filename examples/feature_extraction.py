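"""Extract k-mer pair features from sequences and a positive-pair list.

Generates a small synthetic motif dataset (FASTA + pair list), featurizes
both sequence classes, samples negatives, and assembles the labelled
pair-feature matrix that the selection loop consumes.
"""

import tempfile

from rbfs import (
    AMINO_ACID,
    NUCLEOTIDE,
    FeatureSpec,
    InteractionMatrix,
    MotifSpec,
    build_pair_dataset,
    featurize_sequences,
    generate_motif_dataset,
    read_fasta,
    read_pair_list,
    sample_negatives,
)

with tempfile.TemporaryDirectory() as tmp:
    info = generate_motif_dataset(MotifSpec(n_lnc=20, n_prot=12, seed=7), tmp)
    lncs = read_fasta(info["lnc_fasta"], NUCLEOTIDE)
    prots = read_fasta(info["prot_fasta"], AMINO_ACID)
    positives = read_pair_list(info["pairs"])

spec = FeatureSpec()  # nucleotide k=1..4 (340), amino acid k=1..2 (420)
lnc_feats, lnc_names = featurize_sequences(lncs, spec, prefix="lnc:")
prot_feats, prot_names = featurize_sequences(prots, spec, prefix="prot:")

interactions = InteractionMatrix.from_pairs(
    positives, [r.id for r in lncs], [r.id for r in prots]
)
negatives = sample_negatives(interactions, ratio=1.0, seed=7)
data = build_pair_dataset(
    lnc_feats, prot_feats, positives, negatives, lnc_names, prot_names
)

print(f"{len(lncs)} lncRNAs x {len(prots)} proteins, {len(positives)} known interactions")
print(f"pair dataset: {data.n_samples} pairs x {data.n_features} features")
print(f"positives {int(data.labels.sum())}, negatives {int((1 - data.labels).sum())}")
print("first features:", data.feature_names[:3], "...", data.feature_names[-2:])
# Each row concatenates one lncRNA's k-mer composition (340 values) with one
# protein's (420 values); label 1 marks a known interacting pair.
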