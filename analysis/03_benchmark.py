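"""Score the classification against the simulation ground truth.

Confronts the labels from 02_classify.py with the generating classes from
01_simulate.py: confusion matrix, per-class sensitivity/precision, overall
model-class accuracy and the rejected-class sensitivity on the decoys
(the genes no constant-parameter variant can explain).
"""

import json
import sys
from pathlib import Path

import pandas as pd

from protdyn import benchmark_report


def main(sim_dir="results/synthetic", cls_dir="results/classification",
         out_dir="results/benchmark"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = pd.read_csv(Path(sim_dir) / "truth.tsv", sep="\t", index_col=0)
    table = pd.read_csv(Path(cls_dir) / "classification.tsv", sep="\t", index_col=0)

    rep = benchmark_report(truth, table)
    rep["confusion"].to_csv(out / "confusion.tsv", sep="\t")
    summary = {k: v for k, v in rep.items() if k != "confusion"}
    (out / "benchmark.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(rep["confusion"].to_string())
    print(f"\nmodel-class accuracy:       {rep['model_class_accuracy']:.3f}")
    print(f"decoy rejected sensitivity: {rep['decoy_rejected_sensitivity']:.3f}")
    for c, m in rep["per_class"].items():
        print(f"  {c:22s} sens={m['sensitivity']:.2f} prec={m['precision']:.2f}")


if __name__ == "__main__":
    main(*sys.argv[1:])
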