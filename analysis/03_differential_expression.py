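#!/usr/bin/env python
"""Differential expression for all seven contrasts.

Four hypoxia contrasts (hypoxia vs atmospheric within each stage) and
three progression contrasts (consecutive stages at atmospheric oxygen),
each tested with the NB exact test on TMM-normalized counts and called
at adjusted p < 0.01, |log2FC| > 1, max TPM > 1. Writes one DE table per
contrast plus the up/down count summary under results/de/.
"""

from pathlib import Path

import pandas as pd

from hypro import CountMatrix, counts_to_tpm, de_contrast
from hypro.simulate import ModelDesign

BASE = Path(__file__).resolve().parent.parent / "results"


def contrasts(cm: CountMatrix, design: ModelDesign) -> dict:
    out = {}
    for stage in design.stages:
        out[f"{stage}_hypoxia_vs_atm"] = (
            cm.samples_for(stage=stage, condition="atm"),
            cm.samples_for(stage=stage, condition="hypoxia"),
        )
    for i, trans in enumerate(design.transitions()):
        out[f"{trans}_atm"] = (
            cm.samples_for(stage=design.stages[i], condition="atm"),
            cm.samples_for(stage=design.stages[i + 1], condition="atm"),
        )
    return out


def main() -> None:
    cm = CountMatrix.from_tsv(BASE / "data" / "counts.tsv", BASE / "data" / "samples.tsv")
    (BASE / "de").mkdir(parents=True, exist_ok=True)
    tpm = counts_to_tpm(cm).tpm
    design = ModelDesign()
    rows = []
    for label, (ga, gb) in contrasts(cm, design).items():
        table = de_contrast(cm, ga, gb, label=label, tpm=tpm)
        table.to_csv(BASE / "de" / f"{label}.tsv", sep="\t")
        up = int(((table["called"]) & (table["direction"] > 0)).sum())
        down = int(((table["called"]) & (table["direction"] < 0)).sum())
        rows.append({"contrast": label, "up": up, "down": down, "total": up + down})
        print(f"{label}: {up} up, {down} down ({up + down} called)")
    pd.DataFrame(rows).to_csv(BASE / "de" / "deg_counts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
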