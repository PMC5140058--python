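"""End-to-end orchestration over a cohort directory.

Stages run in order: simulate (optional) -> consensus -> cna -> signatures
-> clonal -> cohort. Each stage's outputs are written under the run
directory and recorded, with SHA-256 digests, in a single reproducibility
manifest (``manifest.json``) written last. A stage failure stops the
pipeline, names the failing stage, and leaves the manifest marked
incomplete.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clonal as clonal_mod
from . import cohort as cohort_mod
from . import copy_number as cna_mod
from . import signatures as sig_mod
from . import synthdata
from . import variant_consensus as vc
from .errors import IbcpipeError

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "out": "ibcpipe_run",
    "simulate": {"n_patients": 6, "seed": 1},
    "consensus": {"min_callers": 2, "min_vaf": 0.05},
    "cna": {"n_simulations": 2000, "alpha": 0.05, "seed": 1},
    "signatures": {"weight_floor": 0.06, "error_tolerance": 1e-3},
    "clonal": {"iterations": 1200, "burn_in": 600, "concentration": 1.0, "seed": 7},
}


class StageFailure(IbcpipeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_all(config_path) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    cfg = load_config(config_path)
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": cfg,
        "stages": {},
        "warnings": {},
        "status": "incomplete",
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("consensus", _stage_consensus),
        ("cna", _stage_cna),
        ("signatures", _stage_signatures),
        ("clonal", _stage_clonal),
        ("cohort", _stage_cohort),
    ]
    try:
        for name, fn in stages:
            t0 = time.monotonic()
            outputs = fn(cfg, out, state)
            elapsed = time.monotonic() - t0
            manifest["stages"][name] = {
                "seconds": round(elapsed, 3),
                "outputs": {
                    (str(p.relative_to(out)) if p.is_relative_to(out) else str(p)):
                    _sha256(p) for p in outputs
                },
            }
            logger.info("stage %s done in %.1fs", name, elapsed)
    except Exception as exc:
        failing = name
        manifest["failed_stage"] = failing
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise StageFailure(failing, exc) from exc
    manifest["status"] = "complete"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg, out, state):
    if "simulate" in cfg and cfg["simulate"] is not None:
        sim_cfg = synthdata.SimulationConfig.from_dict(cfg["simulate"])
        bundle = synthdata.simulate_cohort(sim_cfg)
        fixture_dir = out / "fixture"
        synthdata.write_fixture(bundle, fixture_dir)
        state["fixture_dir"] = fixture_dir
        state["genome"] = sim_cfg.genome
    else:
        fixture_dir = Path(cfg["inputs"]["fixture_dir"])
        state["fixture_dir"] = fixture_dir
        with open(fixture_dir / "manifest.json") as fh:
            fx = json.load(fh)
        state["genome"] = [tuple(g) for g in fx["config"]["genome"]]
    with open(state["fixture_dir"] / "manifest.json") as fh:
        state["fixture_manifest"] = json.load(fh)
    return [state["fixture_dir"] / "manifest.json"]


def _stage_consensus(cfg, out, state):
    ccfg = cfg["consensus"]
    fixture_dir = state["fixture_dir"]
    truth_ctx = {}
    truth_path = fixture_dir / "truth" / "truth_mutations.tsv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t", dtype={"chrom": str})
        for r in tdf.itertuples(index=False):
            truth_ctx[(str(r.chrom), int(r.pos), r.ref, r.alt)] = (
                None if r.substitution == "." else r.substitution,
                None if r.context == "." else r.context,
            )
    state["variants"] = {}
    outputs = []
    vdir = out / "variants"
    vdir.mkdir(exist_ok=True)
    for entry in state["fixture_manifest"]["samples"]:
        sample = entry["sample"]
        callsets = {
            caller: vc.read_caller_vcf(fixture_dir / rel, caller, sample=sample)
            for caller, rel in entry["vcfs"].items()
        }
        snv_sets = [cs for name, cs in callsets.items() if name in synthdata.SNV_CALLERS]
        snvs = vc.consensus_snvs(snv_sets, min_callers=ccfg["min_callers"],
                                 min_vaf=ccfg["min_vaf"])
        indel_sets = []
        for name in synthdata.INDEL_CALLERS:
            cs = callsets[name]
            indels = [v for v in cs.variants if v.variant_class != "SNV"]
            indel_sets.append(vc.CallSet(name, cs.sample, indels))
        indels = vc.consensus_indels(indel_sets[0], indel_sets[1],
                                     min_vaf=ccfg["min_vaf"])
        variants = snvs + indels
        if truth_ctx:
            from dataclasses import replace
            variants = [
                replace(v, substitution=truth_ctx.get(v.key, (None, None))[0],
                        context=truth_ctx.get(v.key, (None, None))[1])
                if v.key in truth_ctx else v
                for v in variants
            ]
        state["variants"][sample] = variants
        path = vdir / f"{sample}.tsv"
        vc.write_variant_table(variants, path, sample)
        outputs.append(path)
    return outputs


def _stage_cna(cfg, out, state):
    ncfg = cfg["cna"]
    fixture_dir = state["fixture_dir"]
    segments = cna_mod.read_segments(fixture_dir / "segments.tsv")
    pp = cna_mod.read_purity_ploidy(fixture_dir / "purity_ploidy.tsv")
    state["segments"] = segments
    state["purity_ploidy"] = pp
    arm_table = cna_mod.arm_table_for_genome(state["genome"])
    rows = []
    scna_rows = []
    state["wgd_calls"] = {}
    rng = np.random.default_rng(ncfg.get("seed", 0))
    for sample in sorted(segments):
        segs = segments[sample]
        sp = pp[sample]
        for call in cna_mod.classify_segments(segs, sp):
            scna_rows.append({
                "sample": sample, "chrom": call.segment.chromosome,
                "start": call.segment.start, "end": call.segment.end,
                "nMajor": call.segment.major, "nMinor": call.segment.minor,
                "log2_ratio": round(call.log2_ratio, 4), "class": call.scna_class,
            })
        score = cna_mod.wgii(segs, sp)
        profile = cna_mod.arm_profile(segs, arm_table)
        wgd = cna_mod.genome_doubling_test(
            profile, n_simulations=ncfg["n_simulations"],
            seed=int(rng.integers(0, 2**31 - 1)), alpha=ncfg["alpha"])
        state["wgd_calls"][sample] = wgd
        rows.append({
            "sample": sample, "wGII": round(score, 4), "ploidy": round(sp.ploidy, 4),
            "observed_fraction": round(wgd.observed_fraction, 4),
            "wgd_p": wgd.p_value, "doubled": wgd.doubled,
        })
    cna_dir = out / "cna"
    cna_dir.mkdir(exist_ok=True)
    scna_path = cna_dir / "scna_calls.tsv"
    pd.DataFrame(scna_rows).to_csv(scna_path, sep="\t", index=False)
    metrics_path = cna_dir / "sample_metrics.tsv"
    pd.DataFrame(rows).to_csv(metrics_path, sep="\t", index=False)
    state["cna_metrics"] = pd.DataFrame(rows).set_index("sample")
    return [scna_path, metrics_path]


def _stage_signatures(cfg, out, state):
    scfg = cfg["signatures"]
    catalog = sig_mod.synthetic_catalog()
    rows = []
    for sample, variants in sorted(state["variants"].items()):
        with_ctx = [v for v in variants if v.context is not None]
        if not with_ctx:
            logger.warning("sample %s has no context-annotated SNVs; skipped", sample)
            continue
        spectrum = sig_mod.build_spectrum(with_ctx)
        fit = sig_mod.refit(spectrum, catalog, weight_floor=scfg["weight_floor"],
                            error_tolerance=scfg["error_tolerance"])
        groups = sig_mod.aggregate_exposures(fit)
        row = {"sample": sample, "n_mutations": fit.n_mutations,
               "reconstruction_error": round(fit.reconstruction_error, 6)}
        row.update({f"group_{g}": round(w, 4) for g, w in groups.items()})
        row.update({f"sig_{s}": round(w, 4) for s, w in fit.weights.items() if w > 0})
        rows.append(row)
    path = out / "signature_exposures.tsv"
    pd.DataFrame(rows).fillna(0.0).to_csv(path, sep="\t", index=False)
    return [path]


def _stage_clonal(cfg, out, state):
    lcfg = cfg["clonal"]
    patients = {}
    for entry in state["fixture_manifest"]["samples"]:
        patients.setdefault(entry["patient"], {})[entry["timepoint"]] = entry["sample"]
    cluster_rows, evo_rows = [], []
    rng = np.random.default_rng(lcfg.get("seed", 0))
    for patient in sorted(patients):
        pair = patients[patient]
        if "pre" not in pair or "post" not in pair:
            logger.warning("patient %s lacks a paired biopsy; skipped", patient)
            continue
        pre_s, post_s = pair["pre"], pair["post"]
        pre_snvs = [v for v in state["variants"][pre_s] if v.variant_class == "SNV"]
        post_snvs = [v for v in state["variants"][post_s] if v.variant_class == "SNV"]
        shared = clonal_mod.shared_mutation_fraction(pre_snvs, post_snvs)
        records = clonal_mod.records_for_pair(
            pre_snvs, post_snvs,
            state["segments"][pre_s], state["segments"][post_s],
            state["purity_ploidy"][pre_s].purity,
            state["purity_ploidy"][post_s].purity,
        )
        retained, excluded = clonal_mod.dp_cluster(
            records, concentration=lcfg["concentration"],
            iterations=lcfg["iterations"], burn_in=lcfg["burn_in"],
            seed=int(rng.integers(0, 2**31 - 1)))
        for cl in retained + excluded:
            cluster_rows.append({
                "patient": patient, "cluster": cl.cluster_id, "size": cl.size,
                "phi_pre": round(cl.mean_ccf["pre"], 4),
                "phi_post": round(cl.mean_ccf["post"], 4),
                "excluded": cl.size < clonal_mod.MIN_CLUSTER_SIZE,
            })
        call = clonal_mod.classify_evolution(retained, patient=patient)
        evo_rows.append({
            "patient": patient, "pattern": call.pattern,
            "shared_fraction": round(shared, 4),
            "n_clusters": len(retained),
            "events": ";".join(f"{cid}:{ev}" for cid, _, _, ev in call.evidence),
        })
    clusters_path = out / "clusters.tsv"
    pd.DataFrame(cluster_rows).to_csv(clusters_path, sep="\t", index=False)
    evo_path = out / "evolution_calls.tsv"
    pd.DataFrame(evo_rows).to_csv(evo_path, sep="\t", index=False)
    state["evolution"] = evo_rows
    return [clusters_path, evo_path]


def _stage_cohort(cfg, out, state):
    # demo grouping: genome-doubled versus near-diploid pre-treatment samples
    summaries = {"doubled": [], "diploid": []}
    metrics = state["cna_metrics"]
    for entry in state["fixture_manifest"]["samples"]:
        if entry["timepoint"] != "pre":
            continue
        sample = entry["sample"]
        wgd = state["wgd_calls"][sample]
        summary = cohort_mod.SampleSummary(
            sample=sample, group="doubled" if wgd.doubled else "diploid",
            burden=len(state["variants"][sample]),
            wgii=float(metrics.loc[sample, "wGII"]),
            wgd_status=wgd.doubled,
        )
        summaries[summary.group].append(summary)
    path = out / "cohort_comparison.tsv"
    if summaries["doubled"] and summaries["diploid"]:
        report = cohort_mod.burden_table(
            summaries["doubled"], summaries["diploid"], traits=())
        report.to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame([{"note": "only one group present; no comparison"}]).to_csv(
            path, sep="\t", index=False)
    return [path]
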