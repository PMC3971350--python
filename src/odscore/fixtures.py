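"""Deterministic small synthetic datasets for demos and tests.

``make_fixtures`` writes a 50-gene x 12-sample cohort — the scale of a
small clinical expression study — with planted structure echoing the three
analysis use cases: single-sample outliers at effect sizes 3/4/5, a
gender-shifted gene block for covariate adjustment, and a gene dysregulated
in two samples for the shared-outlier comparison. Truth is written
alongside as JSON. All data are synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_expression
from .scores import outlying_degree
from .significance import rank_genes

__all__ = ["make_fixtures"]

N_GENES = 50
N_SAMPLES = 12


def make_fixtures(out_dir, seed: int = 0, verify: bool = True) -> dict:
    """Generate the fixture bundle under ``out_dir``; returns the truth dict.

    Files written: ``expression.tsv`` (50 x 12, Normal(7, 0.35) baseline),
    ``covariates.tsv`` (gender, 6 F / 6 M), ``truth.json``. Planted:

    * three single-sample outliers at effects +3, +4, +5 (distinct genes
      and samples);
    * a +1.5 gender shift on 5 genes (females), removable by OLS residuals;
    * one gene raised ~ +3 in two samples (the shared-dysregulation pair).

    With ``verify`` (default) the generator asserts that each planted
    outlier gene ranks in the top 5 by OD (k=6) for its sample.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genes = [f"g{i + 1:02d}" for i in range(N_GENES)]
    samples = [f"s{j + 1:02d}" for j in range(N_SAMPLES)]
    # tight baseline so the planted effects dominate the gene-level ranking
    x = rng.normal(7.0, 0.35, size=(N_GENES, N_SAMPLES))
    expr = pd.DataFrame(x, index=genes, columns=samples)

    outliers = [  # gene, sample, effect — the simulation effect-size grades
        {"gene": "g05", "sample": "s03", "effect": 3.0},
        {"gene": "g17", "sample": "s07", "effect": 4.0},
        {"gene": "g29", "sample": "s11", "effect": 5.0},
    ]
    for o in outliers:
        expr.loc[o["gene"], o["sample"]] += o["effect"]

    gender = ["F"] * 6 + ["M"] * 6
    gender_genes = ["g40", "g41", "g42", "g43", "g44"]
    female = [s for s, g in zip(samples, gender) if g == "F"]
    expr.loc[gender_genes, female] += 1.5

    shared = {"gene": "g33", "samples": ["s02", "s09"], "effect": 3.0}
    expr.loc[shared["gene"], shared["samples"]] += shared["effect"] + rng.normal(0, 0.1, 2)

    truth = {
        "seed": seed,
        "outliers": outliers,
        "gender_shift": {"genes": gender_genes, "level": "F", "shift": 1.5},
        "shared": shared,
    }

    if verify:
        od = outlying_degree(expr, k=6)
        for o in outliers:
            table = rank_genes(od, o["sample"], top=5)
            assert o["gene"] in set(table["gene_id"]), (
                f"fixture self-check failed: {o['gene']} not in top 5 for {o['sample']}"
            )

    write_expression(expr, out_dir / "expression.tsv")
    pd.DataFrame({"sample_id": samples, "gender": gender}).to_csv(
        out_dir / "covariates.tsv", sep="\t", index=False
    )
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
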