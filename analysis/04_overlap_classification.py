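#!/usr/bin/env python
"""Directional overlap between the hypoxia and progression axes.

For each stage, intersects the stage's hypoxia DEG set with the DEG set
of the following progression step and classifies shared genes as co- or
anti-regulated; also summarizes consecutive hypoxia-set overlaps and the
regressions of paired fold changes. Compares the recovered co-regulated
fractions against the constructed planted values.
"""

import json
from pathlib import Path

import pandas as pd

from hypro import call_degs, export_summaries, intersect_and_classify
from hypro.compare import round_half_up
from hypro.simulate import ModelDesign

BASE = Path(__file__).resolve().parent.parent / "results"


def load_set(label: str):
    tab = pd.read_csv(BASE / "de" / f"{label}.tsv", sep="\t", index_col="gene")
    tab.attrs["label"] = label
    return call_degs(tab)


def main() -> None:
    (BASE / "xcompare").mkdir(parents=True, exist_ok=True)
    design = ModelDesign()
    truth_pairs = pd.read_csv(BASE / "data" / "truth_pairs.tsv", sep="\t")
    truth_eff = pd.read_csv(BASE / "data" / "truth_effects.tsv", sep="\t")

    summaries = []
    for i, trans in enumerate(design.transitions()):
        stage = design.stages[i]
        a = load_set(f"{stage}_hypoxia_vs_atm")
        b = load_set(f"{trans}_atm")
        summary, table = intersect_and_classify(a, b)
        table.to_csv(BASE / "xcompare" / f"{stage}__{trans}.tsv", sep="\t", index=False)
        # realized planted fraction from the truth tables
        h = truth_eff.query("set == 'hdeg' and contrast == @stage").set_index("gene")["log2fc"]
        d = truth_eff.query("set == 'deg' and contrast == @trans").set_index("gene")["log2fc"]
        shared = h.index.intersection(d.index)
        co = int(((h.loc[shared] > 0) == (d.loc[shared] > 0)).sum())
        planted_pct = round_half_up(100 * co / len(shared)) if len(shared) else None
        rec = summary.to_dict() | {"planted_co_pct": planted_pct}
        summaries.append(rec)
        print(
            f"{stage} hypoxia vs {trans}: shared {summary.shared}, "
            f"co {summary.co_pct}% (planted {planted_pct}%)"
        )

    hyp_sets = [load_set(f"{s}_hypoxia_vs_atm") for s in design.stages]
    extras = export_summaries(hyp_sets, outdir=BASE / "xcompare")
    (BASE / "xcompare" / "summary.json").write_text(
        json.dumps({"pairs": summaries, **extras}, indent=2)
    )
    for reg in extras["regressions"]:
        r = reg["regression"]
        if r:
            print(
                f"log2FC regression {reg['set_a']} vs {reg['set_b']}: "
                f"slope {r['slope']:.2f} over {r['n']} shared genes"
            )


if __name__ == "__main__":
    main()
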