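"""End-to-end orchestration from a single YAML config.

``run_all`` executes preprocess -> annotate -> composition -> novel ->
diffexpr -> targets -> qpcr over either user-supplied input files or a
self-generated synthetic experiment, writes every stage output as TSV under
a run directory, and records a manifest (config snapshot, seeds, input
checksums, output paths) that makes a run byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import pandas as pd
import yaml

from . import annotate as ann
from . import composition as comp
from . import diffexpr as de
from . import novel_mirna as novel
from . import preprocess as pp
from . import qpcr as qp
from . import synthetic as syn
from . import target_prediction as tp
from .config import DiffexprConfig, NovelConfig, PreprocessConfig, QpcrConfig, TargetConfig

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "annotate", "composition", "novel", "diffexpr",
          "targets", "qpcr")

DEFAULT_CONFIG = {
    "seed": 1,
    "out_dir": "tubemir_run",
    "stages": {s: True for s in STAGES},
    "synthetic": {
        "n_reads": 5000,
        "focus": "tube_foot",
        "others": ["haemocyte", "intestine"],
        "bundle": {},
        "ct_noise_sd": 0.2,
    },
    "thresholds": {},
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: Optional[str] = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config must be a YAML mapping")
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages in config: {sorted(unknown)}")
    return cfg


def _write(df: pd.DataFrame, out_dir: str, name: str, outputs: dict) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False)
    outputs[name] = path
    return path


def run_all(config_path: Optional[str] = None,
            config: Optional[dict] = None) -> dict:
    """Run the configured stages; returns the manifest (also written to disk)."""
    cfg = config if config is not None else load_config(config_path)
    seed = int(cfg["seed"])
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    stages = cfg["stages"]
    th = cfg.get("thresholds") or {}
    pre_cfg = PreprocessConfig(**th.get("preprocess", {}))
    novel_cfg = NovelConfig(**th.get("novel", {}))
    target_cfg = TargetConfig(**th.get("targets", {}))
    de_cfg = DiffexprConfig(**th.get("diffexpr", {}))
    qp_cfg = QpcrConfig(**th.get("qpcr", {}))

    outputs: dict[str, str] = {}
    checksums: dict[str, str] = {}

    # --- inputs: synthetic experiment (default) -----------------------------
    s = cfg["synthetic"]
    bundle = syn.make_reference_bundle(
        syn.BundleConfig(**s.get("bundle", {})), seed=seed)
    profiles = syn.make_tissue_profiles(
        bundle, focus=s["focus"], others=s["others"])
    libraries = {}
    for k, tissue in enumerate([s["focus"], *s["others"]]):
        reads, truth = syn.simulate_library(
            bundle, profiles[tissue], int(s["n_reads"]), seed=seed * 1000 + k)
        fq = os.path.join(out_dir, f"{tissue}.fastq")
        syn.write_fastq(reads, fq)
        checksums[f"{tissue}.fastq"] = _sha256(fq)
        _write(truth, out_dir, f"{tissue}.truth.tsv", outputs)
        libraries[tissue] = reads

    mirna_index = ann.build_exact_index(bundle.mature_mirnas)
    ncrna_indices = {
        cls: ann.build_exact_index(
            {n: sq for n, (c, sq) in bundle.ncrna_fragments.items() if c == cls})
        for cls in syn.NCRNA_CLASSES
    }

    clean_by_tissue, profile_by_tissue, unannotated = {}, {}, {}
    for tissue, reads in libraries.items():
        if not stages.get("preprocess", True):
            break
        clean, report = pp.run_cascade(reads, pre_cfg)
        clean_by_tissue[tissue] = clean
        _write(report.to_frame(), out_dir, f"{tissue}.filter_report.tsv", outputs)
        _write(pp.length_distribution(clean), out_dir,
               f"{tissue}.length_distribution.tsv", outputs)
        if stages.get("annotate", True):
            table, profile, un = ann.annotate_reads(
                clean, mirna_index, ncrna_indices, tissue=tissue)
            profile_by_tissue[tissue] = profile
            unannotated[tissue] = un
            _write(table.to_frame(), out_dir, f"{tissue}.annotation.tsv", outputs)
            _write(profile.to_frame(), out_dir, f"{tissue}.mirna_counts.tsv",
                   outputs)

    focus = s["focus"]
    if stages.get("composition", True) and focus in profile_by_tissue:
        mirna_reads = [r for r in clean_by_tissue[focus]
                       if mirna_index.lookup(r.insert)]
        _write(comp.first_nucleotide_bias(mirna_reads).reset_index(), out_dir,
               f"{focus}.first_nt_bias.tsv", outputs)
        reads22 = [r for r in mirna_reads if len(r.insert) == 22]
        if reads22:
            _write(comp.positional_composition(reads22).reset_index(), out_dir,
                   f"{focus}.positional_composition.tsv", outputs)

    if stages.get("novel", True) and focus in unannotated:
        candidates = novel.screen_scaffolds(
            bundle.scaffolds, unannotated[focus], novel_cfg)
        _write(novel.candidates_to_frame(candidates), out_dir,
               "novel_candidates.tsv", outputs)

    calls = []
    if stages.get("diffexpr", True) and len(profile_by_tissue) > 1:
        calls = de.call_specific(
            profile_by_tissue[focus],
            [profile_by_tissue[t] for t in s["others"]],
            threshold=de_cfg.threshold, pseudo_reads=de_cfg.pseudo_reads)
        _write(de.calls_to_frame(calls), out_dir, "fold_change_calls.tsv",
               outputs)

    if stages.get("targets", True):
        specific = [c.mirna for c in calls if c.significant] or \
            list(bundle.target_mirnas)
        mirnas = {m: bundle.mature_mirnas[m] for m in specific}
        sites = tp.predict_targets(mirnas, bundle.transcripts, target_cfg,
                                   utr_intervals=bundle.utr_intervals)
        both = tp.intersect(sites["A"], sites["B"])
        _write(tp.sites_to_frame(sites["A"] + sites["B"]), out_dir,
               "target_sites.tsv", outputs)
        _write(pd.DataFrame({"transcript": both}), out_dir,
               "potential_targets.tsv", outputs)

    if stages.get("qpcr", True):
        up = {c.mirna: c for c in calls if c.direction == "up"}
        genes = {m: {s["focus"]: 8.0, **{t: 1.0 for t in s["others"]}}
                 for m in (up or dict.fromkeys(bundle.target_mirnas))}
        # folds are relative to the calibrator tissue
        genes = {g: {t: f / folds[qp_cfg.calibrator_tissue]
                     for t, f in folds.items()}
                 for g, folds in genes.items()}
        ct = syn.simulate_ct_table(genes, ct_noise_sd=float(s["ct_noise_sd"]),
                                   seed=seed + 7,
                                   calibrator_tissue=qp_cfg.calibrator_tissue)
        ct_path = os.path.join(out_dir, "ct_table.csv")
        ct.to_csv(ct_path, index=False)
        outputs["ct_table.csv"] = ct_path
        rel = qp.summarize(ct, qp_cfg.calibrator_tissue, qp_cfg.reference_gene,
                           qp_cfg.alpha)
        _write(qp.results_to_frame(rel), out_dir, "relative_expression.tsv",
               outputs)

    for name, path in outputs.items():
        checksums[name] = _sha256(path)
    from importlib.metadata import version
    try:
        pkg_version = version("tubemir")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {
        "config": cfg,
        "seed": seed,
        "outputs": {k: os.path.abspath(v) for k, v in outputs.items()},
        "checksums": checksums,
        "version": pkg_version,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
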