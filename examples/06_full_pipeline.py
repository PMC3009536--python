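"""Run the whole workflow end to end and score it against planted truth.

simulate -> discover -> classify -> pleiotropy -> chip, all seeded from
one master seed.  The run directory receives per-stage outputs, logs, a
manifest with content hashes, and a scorecard comparing the results to
the simulation's ground truth.
"""

import shutil
from pathlib import Path

from phenomod import run_pipeline

out = Path("scratch/example_run")
shutil.rmtree(out, ignore_errors=True)

manifest, results = run_pipeline(out, seed=1)

print(f"stages run          : {sorted(manifest.outputs)}")
print(f"modules discovered  : {len(results.modules)}")
for m in results.modules:
    print(f"  {m.module_id}: {m.size} genes, density {m.mean_density:.2f}, "
          f"BH p {m.fdr_p:.3g}")
print(f"predictions         : {len(results.predictions)}")
print(f"fraction pleiotropic: {results.pleiotropy_report.fraction_pleiotropic:.3f}")
print(f"concordant phenos   : "
      f"{[r.chip_phenotype for r in results.concordance if r.significant]}")
print()
print((out / "scorecard.tsv").read_text())
print("The scorecard's module_jaccard_mean of 1.0 means every planted module")
print("was recovered exactly. At this desk scale the recovered modules are")
print("so clean that no negative training genes exist inside them, so the")
print("classify stage skips (see logs/classify.log) — exactly as the")
print("corpus-scale study could only train classifiers for a subset of")
print("phenotypes — and with one module per phenotype the concordance")
print("Mann-Whitney test cannot reach significance (examples/05 shows the")
print("powered version). Re-running with the same seed reproduces every")
print("output byte for byte (hashes in manifest.json).")
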