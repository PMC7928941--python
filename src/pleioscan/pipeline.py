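"""End-to-end orchestration: simulate fixtures, run every stage, report.

The stage graph is fixed: ``simulate`` feeds ``bivar`` and the five
variant-to-function stages (``pmca``, ``imbalance``, ``cnn``,
``annotation``, ``igr``); ``report`` consolidates whatever ran. A stage
failure halts its dependents only. All randomness flows from the single
global seed through the SimulationConfig substreams and per-stage offsets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, bivariate, cnn, igr, imbalance, pmca
from .synthetic_data import (
    DEMO_MOTIF_CONSENSI,
    SimulationConfig,
    gen_allele_counts,
    gen_epigenome_fixture,
    gen_ortholog_sets,
    gen_peak_dataset,
    gen_summary_stats,
)

log = logging.getLogger("pleioscan")

STAGES = ("simulate", "bivar", "pmca", "imbalance", "cnn", "annotation", "igr")
_DEPENDS = {s: ("simulate",) for s in STAGES if s != "simulate"}
_DEPENDS["simulate"] = ()

_KNOWN_KEYS = {"seed", "out_dir", "stages", "simulate", "bivar", "pmca",
               "imbalance", "cnn", "annotation", "igr"}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (YAML-loadable)."""

    seed: int = 0
    out_dir: str = "pleioscan_out"
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    bivar: dict = field(default_factory=dict)
    pmca: dict = field(default_factory=dict)
    imbalance: dict = field(default_factory=dict)
    cnn: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)
    igr: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = set(raw.get("stages", ())) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        raw["stages"] = tuple(raw.get("stages", STAGES))
        return cls(**raw)


def run(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "pleioscan.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.info("pleioscan %s seed=%d stages=%s",
             __version__, config.seed, ",".join(config.stages))

    sim = SimulationConfig(seed=config.seed, **config.simulate)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    done: set[str] = set()

    def stage(name: str, fn) -> None:
        if name not in config.stages:
            log.info("stage %s disabled", name)
            summary["stages"][name] = {"status": "disabled"}
            return
        missing = [d for d in _DEPENDS[name] if d not in done]
        if missing:
            log.warning("stage %s skipped: dependencies failed: %s",
                        name, missing)
            summary["stages"][name] = {"status": "skipped",
                                       "missing_dependencies": missing}
            return
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # halt dependents, keep siblings running
            log.exception("stage %s failed", name)
            summary["stages"][name] = {"status": "failed", "error": str(exc)}
            return
        summary["stages"][name] = {"status": "ok",
                                   "seconds": round(time.time() - t0, 2),
                                   **(result or {})}
        done.add(name)

    ctx: dict = {}

    def do_simulate():
        ctx["stats_a"], ctx["stats_b"] = gen_summary_stats(sim)
        ctx["case"], ctx["background"] = gen_ortholog_sets(sim)
        ctx["counts"] = gen_allele_counts(sim)
        ctx["peaks"] = gen_peak_dataset(sim)
        ctx["epi"] = gen_epigenome_fixture(sim)
        ctx["stats_a"].to_csv(out / "stats_a.tsv", sep="\t", index=False)
        ctx["stats_b"].to_csv(out / "stats_b.tsv", sep="\t", index=False)
        ctx["counts"].to_csv(out / "counts.tsv", sep="\t", index=False)
        return {"n_snps": sim.n_snps}

    def do_bivar():
        paired = bivariate.harmonize(ctx["stats_a"], ctx["stats_b"])
        bivariate.estimate_null_correlation(paired)
        res = bivariate.bivariate_scan(paired, **config.bivar)
        res.to_csv(out / "bivariate.tsv", sep="\t", index=False)
        n_loci = int(res.loc[res["PASS"], "LOCUS"].nunique())
        return {"n_pass": int(res["PASS"].sum()), "n_loci": n_loci,
                "null_correlation": float(paired.R[0, 1])}

    def do_pmca():
        lib = pmca.MotifLibrary(
            [pmca.pwm_from_consensus(k, v)
             for k, v in DEMO_MOTIF_CONSENSI.items()],
            {k: k for k in DEMO_MOTIF_CONSENSI})
        params = dict(config.pmca)
        n_perm = params.pop("n_perm", max(100, len(ctx["background"])))
        score = pmca.pmca_score(ctx["case"], lib, **params)
        bg_scores = [pmca.pmca_score(b, lib, **params).score
                     for b in ctx["background"]]
        score.perm_p = pmca.permutation_pvalue(score.score, bg_scores,
                                               n_perm=n_perm)
        pd.DataFrame([{"set_id": "case", "score": score.score,
                       "perm_p": score.perm_p}]).to_csv(
            out / "pmca.tsv", sep="\t", index=False)
        return {"score": score.score, "perm_p": score.perm_p}

    def do_imbalance():
        tbl = imbalance.imbalance_table(ctx["counts"], **config.imbalance)
        tbl.to_csv(out / "imbalance.tsv", sep="\t", index=False)
        top = tbl.iloc[0]
        return {"fold": float(top["FOLD"]), "p": float(top["P"])}

    def do_cnn():
        seqs, labels, offsets, variants = ctx["peaks"]
        ds = cnn.dataset_from_sequences(seqs, labels, seed=config.seed)
        cfg = cnn.ModelConfig(seed=config.seed, **config.cnn)
        model = cnn.train(ds, cfg)
        rows = []
        for v in variants:
            s = seqs[v.seq_index]
            alt = s[:v.pos] + v.alt + s[v.pos + 1:]
            rows.append({"seq": v.seq_index, "pos": v.pos, "ref": v.ref,
                         "alt": v.alt, "disrupting": v.disrupting,
                         "sad": cnn.sad(model, s, alt).summary})
        sad_df = pd.DataFrame(rows)
        sad_df.to_csv(out / "sad.tsv", sep="\t", index=False)
        model.save(out / "model")
        val_acc = max(h["val_accuracy"] for h in model.history)
        return {"best_val_accuracy": val_acc,
                "n_variants_scored": len(rows)}

    def do_annotation():
        epi = ctx["epi"]
        clusters = annotation.merge_repressed(epi.segmentation,
                                              **config.annotation)
        annotation.clusters_to_frame(clusters).to_csv(
            out / "repressor_clusters.tsv", sep="\t", index=False)
        ratios = annotation.clade_enrichment(epi.newick, epi.leaf_signals)
        annotation.clade_table(ratios).to_csv(
            out / "clade_ratios.tsv", sep="\t", index=False)
        return {"n_clusters": len(clusters),
                "top_clade_ratio": float(ratios[0].ratio)}

    def do_igr():
        epi = ctx["epi"]
        sim_cfg = sim
        anchors_ref = igr.find_anchors(epi.genome, sim_cfg.kmer)
        anchors_alt = igr.find_anchors(epi.genome, sim_cfg.kmer_alt)
        # center windows on the k-mer and keep them inside the elevated span
        igr_params = {"window": 50,
                      "anchor_offset": len(sim_cfg.kmer) // 2,
                      **config.igr}
        res = igr.allele_affinity(epi.track, anchors_ref, anchors_alt,
                                  **igr_params)
        pd.DataFrame({"offset": np.arange(len(res.profile_ref.profile))
                      - len(res.profile_ref.profile) // 2,
                      "ref": res.profile_ref.profile,
                      "alt": res.profile_alt.profile}).to_csv(
            out / "igr_profile.tsv", sep="\t", index=False)
        return {"fold": res.fold, "p": res.p,
                "n_anchors_ref": len(res.profile_ref.anchor_means),
                "n_anchors_alt": len(res.profile_alt.anchor_means)}

    stage("simulate", do_simulate)
    stage("bivar", do_bivar)
    stage("pmca", do_pmca)
    stage("imbalance", do_imbalance)
    stage("cnn", do_cnn)
    stage("annotation", do_annotation)
    stage("igr", do_igr)

    with open(out / "summary.json", "w") as fhj:
        json.dump(summary, fhj, indent=1, sort_keys=True)
    log.removeHandler(fh)
    fh.close()
    return summary


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

# published schema shipped with the package
with open(Path(__file__).parent / "report_schema.json") as _fh:
    REPORT_SCHEMA = json.load(_fh)


def validate_report(doc: dict, schema: dict = REPORT_SCHEMA) -> None:
    """Minimal structural validation against the shipped JSON schema."""
    types = {"object": dict, "string": str, "integer": int}
    if not isinstance(doc, types[schema["type"]]):
        raise ValueError("report root must be an object")
    for key in schema.get("required", ()):
        if key not in doc:
            raise ValueError(f"report missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in doc and not isinstance(doc[key], types[sub["type"]]):
            raise ValueError(f"report key {key!r} has wrong type")


def report(out_dir) -> tuple[str, dict]:
    """Render the run summary as markdown + validated JSON."""
    out = Path(out_dir)
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {out_dir}")
    with open(summary_path) as fhj:
        summary = json.load(fhj)
    validate_report(summary)
    lines = [f"# pleioscan report (v{summary['version']}, "
             f"seed {summary['seed']})", ""]
    for name, info in summary["stages"].items():
        lines.append(f"## {name}: {info['status']}")
        for k, v in sorted(info.items()):
            if k != "status":
                lines.append(f"- {k}: {v}")
        lines.append("")
    md = "\n".join(lines)
    with open(out / "report.md", "w") as fhm:
        fhm.write(md)
    return md, summary
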