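"""Score gene-phenotype associations with the five-feature random forest.

For a phenotype's modules, every member gene gets five features: module
enrichment for the phenotype's known genes G_p (-log hypergeometric p),
PPI edge count to module partners in G_p, and one GO term-sharing score
per subtree (BP/CC/MF).  Genes already annotated with the phenotype are
positives, genes annotated only in disjoint ontology branches are
negatives, and everything else is held out and scored by the fraction of
trees voting "associated" (out-of-bag votes for training genes).

This demo builds a feature table directly with a planted signal so the
classifier's behavior is visible without a full discovery run.
"""

import numpy as np

from phenomod import FeatureVector, TrainingSplit, precision_recall_curve, train_and_predict

rng = np.random.default_rng(0)


def make_features(n, shift, offset=0):
    out = []
    for i in range(n):
        e, p, bp, cc, mf = np.abs(rng.standard_normal(5)) + shift
        out.append(
            FeatureVector(
                gene=f"g{offset + i}",
                phenotype="PH1",
                enrichment_neglogp=e,
                ppi_score=p,
                go_bp_score=bp,
                go_cc_score=cc,
                go_mf_score=mf,
                n_modules=1,
            )
        )
    return out


positives = make_features(25, shift=3.0)
negatives = make_features(60, shift=0.0, offset=25)
held_out = make_features(10, shift=3.0, offset=85)  # unannotated true members

split = TrainingSplit(
    positives={f.gene for f in positives},
    negatives={f.gene for f in negatives},
    excluded_for_prediction={f.gene for f in held_out},
)
features = positives + negatives + held_out

predictions, oob = train_and_predict(features, split, n_trees=500, seed=0)

held_hits = [p for p in predictions if p.gene in split.excluded_for_prediction]
print(f"positive predictions           : {len(predictions)}")
print(f"held-out genes predicted +     : {len(held_hits)}/10")
print("top votes:", [(p.gene, round(p.vote_fraction, 2)) for p in predictions[:5]])

labels = {f.gene: f.gene in split.positives for f in positives + negatives}
curve = precision_recall_curve(oob, labels, cutoffs=[0.3, 0.5, 0.7, 0.9])
print(f"{'cutoff':>7}{'precision':>11}{'recall':>8}")
for c, prec, rec in curve:
    print(f"{c:>7.2f}{prec:>11.2f}{rec:>8.2f}")
print()
print("Held-out genes drawn from the positive feature distribution are the")
print("analog of unannotated module members: high vote fractions on them are")
print("the novel association calls; precision rises with the vote cutoff.")
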