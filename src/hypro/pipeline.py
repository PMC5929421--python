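"""End-to-end orchestration: simulate -> TPM/QC -> DE -> overlap -> KO -> survival.

A single YAML-able config drives the whole run. Contrasts follow the
two-block layout of the design: per stage, hypoxia vs atmospheric
("{stage}_hypoxia_vs_atm"); per consecutive stage pair, the atmospheric
progression contrast ("{a}_to_{b}_atm"). Every run writes a manifest with
the seed, a config hash, per-stage row counts and a hash over all outputs
so reruns can be verified byte-identical; completed stages are skipped on
rerun unless forced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import export_summaries, intersect_and_classify, round_half_up
from .de import call_degs, de_contrast
from .ko import aggregate_profile, export_circular_table, load_hierarchy
from .matrix import CountMatrix, correlation_cluster, counts_to_tpm, filter_expressed
from .simulate import (
    ModelDesign,
    SurvivalTruth,
    default_truth,
    simulate_counts,
    simulate_survival,
    synthetic_hierarchy,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "hypro_run"
    seed: int = 1
    n_genes: int = 2000
    replicates: int = 2
    alpha: float = 0.01
    min_l2fc: float = 1.0
    min_tpm: float = 1.0
    effect: float = 3.0
    dispersion: float = 0.05
    n_hdeg: int = 150
    n_deg: int = 200
    n_shared: int = 100
    co_fractions: tuple[float, ...] = (0.70, 0.40, 0.92)
    survival: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ("simulate", "qc", "de", "xcompare", "ko", "survscan")

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.min_l2fc < 0 or self.min_tpm < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "co_fractions" in data:
            data["co_fractions"] = tuple(data["co_fractions"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, force: bool = False) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    Deterministic given the config seed. A failing stage raises
    PipelineError naming the stage; outputs of completed stages are kept.
    Completed stages are skipped on rerun (same config hash) unless
    ``force``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "row_counts": {},
    }
    prev: dict = {}
    if manifest_path.exists() and not force:
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == manifest["config_hash"]:
            manifest["stages"] = prev.get("stages", {})
            manifest["row_counts"] = prev.get("row_counts", {})

    design = ModelDesign(n_genes=config.n_genes, replicates_per_cell=config.replicates)
    truth = default_truth(
        design,
        seed=config.seed,
        n_hdeg=config.n_hdeg,
        n_deg=config.n_deg,
        n_shared=config.n_shared,
        effect=config.effect,
        co_fractions=config.co_fractions,
        dispersion=config.dispersion,
    )

    written: list[Path] = []

    def record(stage: str, paths: list[Path]) -> None:
        written.extend(paths)
        manifest["stages"][stage] = {
            "completed": True,
            "outputs": [p.name for p in paths],
            "wall_s": round(time.time() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def done(stage: str) -> bool:
        info = manifest["stages"].get(stage, {})
        if force or not info.get("completed"):
            return False
        paths = [out / name for name in info.get("outputs", [])]
        if all(p.exists() for p in paths):
            written.extend(paths)
            return True
        return False

    t0 = time.time()
    active = set(config.stages)

    # --- simulate -----------------------------------------------------
    try:
        if "simulate" in active and not done("simulate"):
            cm, truth = simulate_counts(design, truth, seed=config.seed)
            cm.to_tsv(out / "counts.tsv", out / "samples.tsv")
            truth.write_tsv(out)
            manifest["row_counts"]["counts"] = int(cm.counts.shape[0])
            record(
                "simulate",
                [out / "counts.tsv", out / "samples.tsv", out / "truth_effects.tsv",
                 out / "truth_pairs.tsv", out / "truth_genes.tsv"],
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    cm = CountMatrix.from_tsv(out / "counts.tsv", out / "samples.tsv")

    # --- QC: TPM + correlation ---------------------------------------
    try:
        if "qc" in active and not done("qc"):
            expr = counts_to_tpm(cm)
            expr.to_tsv(out / "tpm.tsv")
            kept = filter_expressed(expr)
            corr, order = correlation_cluster(kept)
            corr.to_csv(out / "correlation.tsv", sep="\t")
            (out / "dendrogram_order.json").write_text(json.dumps(order))
            manifest["row_counts"]["expressed_genes"] = int(kept.tpm.shape[0])
            record("qc", [out / "tpm.tsv", out / "correlation.tsv",
                          out / "dendrogram_order.json"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", exc) from exc

    # --- DE: 4 hypoxia contrasts + 3 progression transitions ----------
    contrasts: dict[str, tuple[list[str], list[str]]] = {}
    for stage in design.stages:
        contrasts[f"{stage}_hypoxia_vs_atm"] = (
            cm.samples_for(stage=stage, condition=design.conditions[0]),
            cm.samples_for(stage=stage, condition=design.conditions[1]),
        )
    for i, trans in enumerate(design.transitions()):
        contrasts[f"{trans}_atm"] = (
            cm.samples_for(stage=design.stages[i], condition=design.conditions[0]),
            cm.samples_for(stage=design.stages[i + 1], condition=design.conditions[0]),
        )
    de_paths = {label: out / f"de_{label}.tsv" for label in contrasts}
    try:
        if "de" in active and not done("de"):
            tpm = counts_to_tpm(cm).tpm
            table_counts = []
            for label, (ga, gb) in contrasts.items():
                tab = de_contrast(
                    cm, ga, gb, label=label,
                    alpha=config.alpha, min_l2fc=config.min_l2fc,
                    min_tpm=config.min_tpm, tpm=tpm,
                )
                tab.to_csv(de_paths[label], sep="\t")
                up = int(((tab["called"]) & (tab["direction"] > 0)).sum())
                down = int(((tab["called"]) & (tab["direction"] < 0)).sum())
                table_counts.append(
                    {"contrast": label, "up": up, "down": down, "total": up + down}
                )
                manifest["row_counts"][label] = up + down
            pd.DataFrame(table_counts).to_csv(
                out / "deg_counts.tsv", sep="\t", index=False
            )
            record("de", list(de_paths.values()) + [out / "deg_counts.tsv"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", exc) from exc

    def load_set(label: str):
        tab = pd.read_csv(de_paths[label], sep="\t", index_col="gene")
        tab.attrs["label"] = label
        return call_degs(tab)

    # --- xcompare ------------------------------------------------------
    try:
        if "xcompare" in active and not done("xcompare"):
            hyp_sets = {s: load_set(f"{s}_hypoxia_vs_atm") for s in design.stages}
            summaries = []
            paths = []
            for i, trans in enumerate(design.transitions()):
                stage = design.stages[i]
                a = hyp_sets[stage]
                b = load_set(f"{trans}_atm")
                summary, table = intersect_and_classify(a, b)
                d = summary.to_dict()
                d["nominal_co_fraction"] = config.co_fractions[
                    i % len(config.co_fractions)
                ]
                # the constructed truth realizes the nominal fraction up to
                # one gene of rounding; compare against what was built
                realized = truth.realized_co_fraction(stage, trans)
                d["planted_co_fraction"] = realized
                d["planted_co_pct"] = (
                    None if realized is None else round_half_up(100 * realized)
                )
                summaries.append(d)
                p = out / f"xcompare_{stage}__{trans}.tsv"
                table.to_csv(p, sep="\t", index=False)
                paths.append(p)
            extras = export_summaries(
                [hyp_sets[s] for s in design.stages], outdir=out
            )
            (out / "xcompare_summary.json").write_text(
                json.dumps({"pairs": summaries, **extras}, indent=2)
            )
            paths += [out / "xcompare_summary.json", out / "arc_counts.tsv",
                      out / "venn_counts.tsv", out / "regressions.json"]
            record("xcompare", paths)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("xcompare", exc) from exc

    # --- KO profile -----------------------------------------------------
    try:
        if "ko" in active and not done("ko"):
            hier_tab = synthetic_hierarchy(list(cm.genes), seed=config.seed)
            hier_tab.to_csv(out / "ko_hierarchy.tsv", sep="\t", index=False)
            h = load_hierarchy(out / "ko_hierarchy.tsv")
            paths = [out / "ko_hierarchy.tsv"]
            for stage in design.stages:
                label = f"{stage}_hypoxia_vs_atm"
                tab = pd.read_csv(de_paths[label], sep="\t", index_col="gene")
                fc = tab["log2FC"].dropna().to_dict()
                changed = set(tab.index[tab["called"]])
                profile = aggregate_profile(h, fc, changed & set(fc))
                circ = export_circular_table(profile, h)
                p = out / f"ko_profile_{stage}.tsv"
                circ.to_csv(p, sep="\t", index=False)
                paths.append(p)
            record("ko", paths)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ko", exc) from exc

    # --- survival scan ---------------------------------------------------
    try:
        if "survscan" in active and not done("survscan"):
            struth = SurvivalTruth(**config.survival)
            cohort = simulate_survival(struth, seed=config.seed)
            cohort.to_csv(out / "survival_cohort.tsv", sep="\t", index=False)
            from .surv import scan_cutoff

            res = scan_cutoff(cohort)
            res.to_tsv(out / "cutpoint_scan.tsv")
            (out / "cutpoint_result.json").write_text(
                json.dumps(
                    {
                        "cutoff": res.cutoff,
                        "cutoff_percentile": res.cutoff_percentile,
                        "logrank_p": res.p,
                        "hr": res.hr,
                        "coef": res.coef,
                        "n_low": res.n_low,
                        "n_high": res.n_high,
                        "planted_cutoff": struth.cutoff_expression,
                        "planted_hr": struth.true_hr,
                    },
                    indent=2,
                )
            )
            record("survscan", [out / "survival_cohort.tsv",
                                out / "cutpoint_scan.tsv",
                                out / "cutpoint_result.json"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("survscan", exc) from exc

    manifest["outputs_hash"] = _hash_files(list(dict.fromkeys(written)))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
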