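#!/usr/bin/env python
"""Dissect LD-confounded association signals and run the gene-based test.

Two experiments on purpose-built genotypes (n=2,000): stepwise selection in a
block holding two causal variants (r2=0.5 between them) and a pure r2=0.9
proxy of the stronger one, and the LD-aware gene-based test on a null
phenotype (checking its calibration) and on the causal block.
"""

import logging
from pathlib import Path

from scipy import stats

from pdprog import experiments, io

logging.basicConfig(level=logging.WARNING)
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# stepwise independent-signal selection over 10 replicates
trials = [experiments.signal_dissection_trial(seed) for seed in range(10)]
n_correct = sum(t["correct"] for t in trials)
print(f"stepwise selection: exactly the two causal variants in {n_correct}/10 replicates")
joint = trials[0]["joint"]
io.write_table(joint, OUT / "signals_joint_model.tsv")
print("replicate 0 joint model (truth: snp_00000 beta 0.5, snp_00001 beta 0.4):")
print(joint.to_string(index=False))

# gene-based test calibration under intra-gene LD
calib = experiments.gene_test_null_calibration(seed=20, n_genes=100)
ks = stats.kstest(calib["P"], "uniform")
io.write_table(calib, OUT / "gene_test_null.tsv")
print(f"\ngene-based null calibration over {len(calib)} genes: KS P = {ks.pvalue:.3f}")
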