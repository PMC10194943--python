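"""Run the complete pipeline on the demo cohort and read its phenotypes.

Simulates six rats (45 min each), filters and delineates every segment,
fits the clustering grid, selects a model, and writes phenotype tables,
the group-scaled heatmap matrix and glucose-interval correlations. Takes a
couple of minutes on one CPU.
"""

import json
from pathlib import Path

import pandas as pd

from beatshape.pipeline import load_run_config, run_pipeline

cfg = load_run_config(Path(__file__).resolve().parents[1] / "configs" / "demo.yaml")
cfg.outdir = "demo_output"
report = run_pipeline(cfg)
print(json.dumps(report, indent=2))

out = Path(cfg.outdir)
pheno = pd.read_csv(out / "phenotype_table.csv")
cols = ["cluster", "n", "pct_diabetic", "pct_severe", "pct_qt_increased",
        "median_qt_ms", "median_qrs_ms"]
print("\nper-cluster phenotypes:")
print(pheno[cols].round(2).to_string(index=False))
print("\nheatmap leaf order (Ward on group profiles):",
      json.loads((out / "heatmap_leaf_order.json").read_text()))
print("\nglucose-interval correlations by experimental group:")
print(pd.read_csv(out / "spearman.csv").round(3).to_string(index=False))

# Interpretation: clusters separate by glycemic state and diabetes status -
# severe-hypoglycemia clusters carry high QT/QRS-prolongation percentages,
# and the Ward ordering groups severe-hypoglycemia experimental groups
# together, mirroring the analysis the pipeline implements.
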