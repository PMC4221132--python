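"""Synthetic multi-tissue small-RNA experiment with ground truth.

Generates everything the pipeline consumes — mature-miRNA and ncRNA
reference sets, genomic scaffolds with planted hairpin precursors,
transcripts with planted target sites, adapter-ligated FASTQ libraries with
a per-read truth table, and qPCR Ct tables — so every downstream stage is
testable without external data.

Every planted feature is validated at generation time against the detector
it is planted for (hairpins against ``evaluate_hairpin``, target sites
against both target-prediction scorers, reads against the filter cascade),
regenerating until it passes, so ground truth and detector semantics agree
by construction.

Study conditions emulated: read-length mode at 22 nt, uracil bias at the
first position, a library dominated by adapter products and miRNA reads,
and a handful of tissue-enriched miRNAs planted at a known multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (DEFAULT_ADAPTER_3P, DEFAULT_ADAPTER_5P, PreprocessConfig,
                     RNA_BASES, revcomp, to_dna, to_rna)
from .novel_mirna import NovelConfig, ReadCluster, evaluate_hairpin
from .preprocess import RawRead, classify_and_trim
from .target_prediction import TargetConfig, accessibility, duplex_align, duplex_energy

NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")

#: origin classes a library mixes, and the filter category each must land in
EXPECTED_CATEGORY = {
    "miRNA": "clean", "rRNA": "clean", "tRNA": "clean", "snRNA": "clean",
    "snoRNA": "clean", "novel_hairpin": "clean", "other": "clean",
    "low_quality": "low_quality",
    "adapter_dimer": "adapter3_null_or_insert_null",
    "poly_nt": "poly_nt",
    "high_N": "high_N",
}

#: read-length mix of mature miRNAs (mode at 22 nt, as in miRNA-rich
#: libraries; the remaining mass spreads over the flanking lengths)
MIRNA_LENGTH_WEIGHTS = {
    18: 0.02, 19: 0.02, 20: 0.09, 21: 0.14, 22: 0.63, 23: 0.05,
    24: 0.03, 25: 0.02,
}
FIRST_U_PROB = 0.6


@dataclass
class BundleConfig:
    n_mirnas: int = 100
    n_ncrna_per_class: int = 5
    n_scaffolds: int = 3
    scaffold_len: int = 2000
    n_hairpins: int = 6
    n_transcripts: int = 12
    transcript_len: int = 600
    utr5_len: int = 100
    utr3_len: int = 200
    n_target_sites: int = 8
    n_target_mirnas: int = 4
    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P

    def validate(self) -> None:
        for name in ("n_mirnas", "n_ncrna_per_class", "n_scaffolds",
                     "scaffold_len", "n_transcripts", "transcript_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_hairpins < 0 or self.n_target_sites < 0:
            raise ValueError("planted feature counts must be >= 0")


@dataclass
class ReferenceBundle:
    mature_mirnas: dict = field(default_factory=dict)   # name -> RNA seq
    ncrna_fragments: dict = field(default_factory=dict)  # name -> (class, seq)
    scaffolds: dict = field(default_factory=dict)       # name -> seq
    #: scaffold -> list of (start, end, hairpin_name, mature) 1-based inclusive
    hairpin_intervals: dict = field(default_factory=dict)
    hairpin_matures: dict = field(default_factory=dict)  # hairpin name -> mature
    transcripts: dict = field(default_factory=dict)     # name -> seq
    utr_intervals: dict = field(default_factory=dict)   # name -> [(s, e, label)]
    #: transcript -> list of (mirna_name, start, end) 1-based inclusive
    target_sites: dict = field(default_factory=dict)
    target_mirnas: tuple = ()
    config: Optional[BundleConfig] = None


@dataclass
class TissueProfile:
    tissue: str
    mirna_proportions: dict
    category_mix: dict

    def validate(self) -> None:
        for group in (self.mirna_proportions, self.category_mix):
            for k, v in group.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"fraction {k}={v} outside [0, 1]")
            if abs(sum(group.values()) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")
        unknown = set(self.category_mix) - set(EXPECTED_CATEGORY)
        if unknown:
            raise ValueError(f"unknown origin classes: {sorted(unknown)}")


DEFAULT_CATEGORY_MIX = {
    "miRNA": 0.45, "rRNA": 0.006, "tRNA": 0.002, "snRNA": 0.0005,
    "snoRNA": 0.0005, "novel_hairpin": 0.002, "other": 0.222,
    "low_quality": 0.01, "adapter_dimer": 0.30, "poly_nt": 0.005,
    "high_N": 0.002,
}


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _random_rna(rng: np.random.Generator, length: int,
                weights=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length, p=list(weights)))


def _random_mirna(rng: np.random.Generator) -> str:
    lengths = list(MIRNA_LENGTH_WEIGHTS)
    L = int(rng.choice(lengths, p=list(MIRNA_LENGTH_WEIGHTS.values())))
    seq = _random_rna(rng, L)
    if rng.random() < FIRST_U_PROB:
        seq = "U" + seq[1:]
    return seq


def _insert_ok(insert: str, cfg: PreprocessConfig) -> bool:
    """Would this insert survive the filter cascade as a clean read?"""
    read = RawRead(id="probe", sequence=to_dna(insert) + cfg.adapter_3p,
                   quality="I" * (len(insert) + len(cfg.adapter_3p)))
    category, _ = classify_and_trim(read, cfg.adapter_3p, cfg.adapter_5p, cfg)
    return category == "clean"


def _draw_clean_insert(rng: np.random.Generator, cfg: PreprocessConfig,
                       lo: int = 18, hi: int = 40) -> str:
    for _ in range(100):
        L = int(rng.integers(lo, hi + 1))
        seq = _random_rna(rng, L)
        if _insert_ok(seq, cfg):
            return seq
    raise RuntimeError("could not draw a clean insert")  # pragma: no cover


# ---------------------------------------------------------------------------
# reference bundle
# ---------------------------------------------------------------------------


def _plant_hairpin(rng: np.random.Generator, novel_cfg: NovelConfig,
                   pre_cfg: PreprocessConfig, context_len: int = 10,
                   ) -> tuple[str, str]:
    """(mature, precursor) passing evaluate_hairpin even with trailing context."""
    for _ in range(200):
        mature = "U" + _random_rna(rng, 21, weights=(0.22, 0.28, 0.28, 0.22))
        if not _insert_ok(mature, pre_cfg):
            continue
        loop = _random_rna(rng, int(rng.integers(8, 21)))
        star = list(revcomp(mature[:20]))
        # 1-4 interior mismatches: 80-95% star complementarity, emulating the
        # bulged duplexes of real precursors
        n_mut = int(rng.integers(1, 5))
        for pos in rng.choice(range(2, 18), size=n_mut, replace=False):
            star[pos] = str(rng.choice(list(RNA_BASES)))
        precursor = mature + loop + "".join(star) + _random_rna(rng, 2)
        window = precursor + _random_rna(rng, context_len)
        cluster = ReadCluster(start=0, end=len(mature), mature=mature,
                              read_count=10, reads=[(mature, 10, 0)])
        cand, _reason = evaluate_hairpin(window, cluster, novel_cfg)
        if cand is not None and evaluate_hairpin(precursor, cluster,
                                                 novel_cfg)[0] is not None:
            return mature, precursor
    raise RuntimeError("could not plant a hairpin precursor")  # pragma: no cover


def _plant_target_site(rng: np.random.Generator, mirna: str,
                       target_cfg: TargetConfig, flank: int = 14) -> str:
    """Site cassette (flank + perfect complement + flank) passing both methods."""
    for _ in range(100):
        flanks = [
            "".join(rng.choice(["A", "C"], size=flank, p=[0.7, 0.3]))
            for _ in range(2)
        ]
        cassette = flanks[0] + revcomp(mirna) + flanks[1]
        _, score = duplex_align(mirna, revcomp(mirna), target_cfg)
        dg = duplex_energy(mirna, revcomp(mirna))
        ddg = accessibility(mirna, cassette, flank + 1, flank + len(mirna),
                            target_cfg.fold_window)
        if (score >= target_cfg.s_min and dg <= target_cfg.dg_max
                and ddg <= target_cfg.ddg_max):
            return cassette
    raise RuntimeError("could not plant a target site")  # pragma: no cover


def make_reference_bundle(config: Optional[BundleConfig] = None,
                          seed: int = 0) -> ReferenceBundle:
    """Deterministic reference bundle for a given (config, seed)."""
    cfg = config or BundleConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    pre_cfg = PreprocessConfig(adapter_3p=cfg.adapter_3p, adapter_5p=cfg.adapter_5p)
    novel_cfg = NovelConfig()
    target_cfg = TargetConfig()
    bundle = ReferenceBundle(config=cfg)

    # mature miRNAs, unique and clean-classifiable.  The tissue-specific /
    # target miRNAs are the LAST n_target_mirnas ranks: abundance ranks map
    # to insertion order, and planting the enrichment on low-abundance
    # miRNAs keeps the renormalisation distortion of all other proportions
    # well below the fold-change threshold.  Those miRNAs are kept >= 21 nt
    # so a perfect planted site clears the alignment-score threshold.
    seen = set()
    i = 0
    first_target = cfg.n_mirnas - cfg.n_target_mirnas
    while len(bundle.mature_mirnas) < cfg.n_mirnas:
        seq = _random_mirna(rng)
        if len(bundle.mature_mirnas) >= first_target and len(seq) < 21:
            continue
        if seq in seen or not _insert_ok(seq, pre_cfg):
            continue
        seen.add(seq)
        i += 1
        bundle.mature_mirnas[f"mir-{i}"] = seq
    bundle.target_mirnas = tuple(list(bundle.mature_mirnas)[first_target:])

    # ncRNA fragments, 18-40 nt so they can appear as clean reads
    for cls in NCRNA_CLASSES:
        for k in range(cfg.n_ncrna_per_class):
            while True:
                seq = _draw_clean_insert(rng, pre_cfg, 20, 40)
                if seq not in seen:
                    break
            seen.add(seq)
            bundle.ncrna_fragments[f"{cls}-{k + 1}"] = (cls, seq)

    # scaffolds with planted hairpins
    hairpins_left = cfg.n_hairpins
    per_scaffold = -(-cfg.n_hairpins // cfg.n_scaffolds)  # ceil
    for s in range(cfg.n_scaffolds):
        name = f"Scaffold{s + 1}"
        seq = _random_rna(rng, cfg.scaffold_len)
        intervals = []
        n_here = min(per_scaffold, hairpins_left)
        hairpins_left -= n_here
        slot = cfg.scaffold_len // max(n_here, 1)
        for h in range(n_here):
            mature, precursor = _plant_hairpin(rng, novel_cfg, pre_cfg)
            pos = h * slot + int(rng.integers(0, max(1, slot - len(precursor) - 90)))
            seq = seq[:pos] + precursor + seq[pos + len(precursor):]
            hp_name = f"{name}_{pos + 1}"
            intervals.append((pos + 1, pos + len(precursor), hp_name, mature))
            bundle.hairpin_matures[hp_name] = mature
            seen.add(mature)
        # re-validate in scaffold context; re-plant if the neighbourhood broke it
        for idx, (start, end, hp_name, mature) in enumerate(intervals):
            for _ in range(50):
                window = seq[start - 1:start - 1 + novel_cfg.window_flank]
                cluster = ReadCluster(start=0, end=len(mature), mature=mature,
                                      read_count=10, reads=[(mature, 10, 0)])
                if evaluate_hairpin(window, cluster, novel_cfg)[0] is not None:
                    break
                mature, precursor = _plant_hairpin(rng, novel_cfg, pre_cfg)
                pos = start - 1
                seq = seq[:pos] + precursor + seq[pos + len(precursor):]
                del bundle.hairpin_matures[hp_name]
                intervals[idx] = (pos + 1, pos + len(precursor), hp_name, mature)
                bundle.hairpin_matures[hp_name] = mature
            else:  # pragma: no cover
                raise RuntimeError("hairpin failed validation in context")
        bundle.scaffolds[name] = seq
        bundle.hairpin_intervals[name] = intervals

    # transcripts with UTRs and planted target sites
    sites_left = cfg.n_target_sites
    t_with_sites = min(cfg.n_target_sites, max(1, cfg.n_transcripts // 2))
    for t in range(cfg.n_transcripts):
        name = f"transcript{t + 1}"
        seq = _random_rna(rng, cfg.transcript_len)
        L = len(seq)
        utr5 = (1, cfg.utr5_len, "5'UTR")
        utr3 = (L - cfg.utr3_len + 1, L, "3'UTR")
        sites = []
        if t < t_with_sites and sites_left > 0:
            n_here = -(-sites_left // (t_with_sites - t))  # spread evenly
            offset = utr3[0] - 1
            slot = cfg.utr3_len // n_here
            for s in range(n_here):
                mirna_name = bundle.target_mirnas[
                    (sites_left - 1) % len(bundle.target_mirnas)]
                mirna = bundle.mature_mirnas[mirna_name]
                cassette = _plant_target_site(rng, mirna, target_cfg)
                pos = offset + s * slot
                if pos + len(cassette) > L:
                    break
                seq = seq[:pos] + cassette + seq[pos + len(cassette):]
                site_start = pos + 14 + 1  # 1-based, past the 5' flank
                sites.append((mirna_name, site_start,
                              site_start + len(mirna) - 1))
                sites_left -= 1
        bundle.transcripts[name] = seq
        bundle.utr_intervals[name] = [utr5, utr3]
        bundle.target_sites[name] = sites
    return bundle


# ---------------------------------------------------------------------------
# tissue profiles
# ---------------------------------------------------------------------------


def base_mirna_proportions(names: Sequence[str]) -> dict[str, float]:
    """Rank-skewed proportions p_i proportional to 1/(rank + 25).

    The offset floors the least-abundant miRNA at a workable read count so
    that proportion ratios between tissues are estimable at library sizes
    of a few tens of thousands of reads.
    """
    raw = {n: 1.0 / (i + 25.0) for i, n in enumerate(names)}
    total = sum(raw.values())
    return {n: v / total for n, v in raw.items()}


def make_tissue_profiles(bundle: ReferenceBundle,
                         enriched: Optional[Sequence[str]] = None,
                         multiplier: float = 8.0,
                         focus: str = "tube_foot",
                         others: Sequence[str] = ("haemocyte", "intestine"),
                         category_mix: Optional[Mapping[str, float]] = None,
                         ) -> dict[str, TissueProfile]:
    """Focus tissue with planted enrichment vs. flat comparison tissues.

    ``enriched`` miRNAs get ``multiplier`` times their base proportion in
    the focus tissue (then renormalised); default: the bundle's target
    miRNAs, mirroring a four-miRNA tissue-specific design.
    """
    names = list(bundle.mature_mirnas)
    enriched = list(enriched if enriched is not None else bundle.target_mirnas)
    missing = [m for m in enriched if m not in names]
    if missing:
        raise ValueError(f"enriched miRNAs not in bundle: {missing}")
    base = base_mirna_proportions(names)
    boosted = {n: v * (multiplier if n in enriched else 1.0)
               for n, v in base.items()}
    total = sum(boosted.values())
    boosted = {n: v / total for n, v in boosted.items()}
    mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    profiles = {focus: TissueProfile(focus, boosted, mix)}
    for tissue in others:
        profiles[tissue] = TissueProfile(tissue, dict(base), mix)
    for p in profiles.values():
        p.validate()
    return profiles


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def _quality(rng: np.random.Generator, length: int, good: bool) -> str:
    lo, hi = (30, 41) if good else (3, 13)
    return "".join(chr(int(q) + 33) for q in rng.integers(lo, hi, size=length))


def simulate_library(bundle: ReferenceBundle, profile: TissueProfile,
                     n_reads: int, adapter_3p: Optional[str] = None,
                     adapter_5p: Optional[str] = None, seed: int = 0,
                     read_len: int = 50,
                     ) -> tuple[list[RawRead], pd.DataFrame]:
    """Simulate an adapter-ligated single-end library with per-read truth.

    Returns the reads and a truth table with one row per read (read id,
    origin class, source name, tissue, expected filter category).  Every
    read is verified against the filter cascade at generation time, so
    truth and cascade agree exactly.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    profile.validate()
    a3 = adapter_3p or (bundle.config.adapter_3p if bundle.config else DEFAULT_ADAPTER_3P)
    a5 = adapter_5p or (bundle.config.adapter_5p if bundle.config else DEFAULT_ADAPTER_5P)
    if not a3 or not a5:
        raise ValueError("adapters must be non-empty")
    missing = [m for m in profile.mirna_proportions if m not in bundle.mature_mirnas]
    if missing:
        raise ValueError(f"profile miRNAs absent from bundle: {missing}")
    pre_cfg = PreprocessConfig(adapter_3p=a3, adapter_5p=a5)
    rng = np.random.default_rng(seed)

    classes = sorted(profile.category_mix)
    class_draw = rng.choice(classes, size=n_reads,
                            p=[profile.category_mix[c] for c in classes])
    mirna_names = sorted(profile.mirna_proportions)
    mirna_p = [profile.mirna_proportions[m] for m in mirna_names]
    ncrna_by_class = {cls: sorted(n for n, (c, _) in bundle.ncrna_fragments.items()
                                  if c == cls) for cls in NCRNA_CLASSES}
    hairpin_names = sorted(bundle.hairpin_matures)

    reads: list[RawRead] = []
    truth_rows = []
    for r, origin in enumerate(class_draw):
        rid = f"{profile.tissue}_read{r + 1}"
        expected = EXPECTED_CATEGORY[origin]
        for _attempt in range(50):
            source = ""
            good_q = origin != "low_quality"
            if origin == "miRNA":
                source = str(rng.choice(mirna_names, p=mirna_p))
                insert = bundle.mature_mirnas[source]
            elif origin in NCRNA_CLASSES:
                if not ncrna_by_class[origin]:
                    raise ValueError(f"no {origin} fragments in bundle")
                source = str(rng.choice(ncrna_by_class[origin]))
                insert = bundle.ncrna_fragments[source][1]
            elif origin == "novel_hairpin":
                if not hairpin_names:
                    raise ValueError("no planted hairpins in bundle")
                source = str(rng.choice(hairpin_names))
                insert = bundle.hairpin_matures[source]
            elif origin in ("other", "low_quality"):
                insert = _draw_clean_insert(rng, pre_cfg)
            elif origin == "adapter_dimer":
                insert = ""
            elif origin == "poly_nt":
                base = str(rng.choice(list("ACGU")))
                insert = base * int(rng.integers(20, 25))
            elif origin == "high_N":
                raw = list(_draw_clean_insert(rng, pre_cfg, 20, 30))
                n_n = max(3, int(0.15 * len(raw)) + 1)
                for pos in rng.choice(len(raw), size=n_n, replace=False):
                    raw[pos] = "N"
                insert = "".join(raw)
            else:  # pragma: no cover
                raise AssertionError(origin)
            body = to_dna(insert) + a3
            if len(body) < read_len:
                body += "".join(rng.choice(list("ACGT"), size=read_len - len(body)))
            body = body[:read_len]
            read = RawRead(id=rid, sequence=body,
                           quality=_quality(rng, read_len, good_q))
            category, _ = classify_and_trim(read, a3, a5, pre_cfg)
            if category == expected:
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not realise a {origin} read")
        reads.append(read)
        truth_rows.append((rid, origin, source, profile.tissue, expected))

    truth = pd.DataFrame(truth_rows, columns=[
        "read_id", "origin_class", "source_name", "tissue", "expected_category"])
    return reads, truth


def expected_filter_counts(truth: pd.DataFrame) -> dict[str, int]:
    return truth["expected_category"].value_counts().to_dict()


def expected_class_counts(truth: pd.DataFrame) -> dict[str, int]:
    """Clean reads per annotation class implied by the truth table."""
    clean = truth[truth["expected_category"] == "clean"]
    mapping = {"miRNA": "miRNA", "rRNA": "rRNA", "tRNA": "tRNA",
               "snRNA": "snRNA", "snoRNA": "snoRNA",
               "novel_hairpin": "others", "other": "others"}
    out: dict[str, int] = {}
    for origin, n in clean["origin_class"].value_counts().items():
        cls = mapping[origin]
        out[cls] = out.get(cls, 0) + int(n)
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(true_rel_expression: Mapping[str, Mapping[str, float]],
                      ct_noise_sd: float = 0.0, seed: int = 0,
                      reference_genes: Sequence[str] = ("b-actin", "Cytb"),
                      n_replicates: int = 3,
                      calibrator_tissue: str = "tube_foot") -> pd.DataFrame:
    """Ct table for gene -> tissue -> fold (relative to the calibrator).

    Ct_target = Ct_reference + base_delta - log2(fold) + N(0, sd); reference
    genes are noise-free and mutually proportional, so the recovered
    2^-ddCt inverts the planted folds exactly at sd = 0.
    """
    if ct_noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    tissues = sorted({t for folds in true_rel_expression.values() for t in folds})
    ref_base = {g: 15.0 + 2.0 * i for i, g in enumerate(reference_genes)}
    tissue_offset = {t: float(rng.uniform(-1.5, 1.5)) for t in tissues}
    rows = []
    for gene, folds in sorted(true_rel_expression.items()):
        for tissue in tissues:
            fold = folds.get(tissue)
            if fold is None:
                continue
            if fold <= 0:
                raise ValueError(f"fold must be positive ({gene}/{tissue})")
            for rep in range(1, n_replicates + 1):
                ct_ref = ref_base[reference_genes[0]] + tissue_offset[tissue]
                ct = (ct_ref + 6.0 - np.log2(fold)
                      + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0))
                rows.append((gene, tissue, rep, float(ct), False))
    for g in reference_genes:
        for tissue in tissues:
            for rep in range(1, n_replicates + 1):
                rows.append((g, tissue, rep,
                             ref_base[g] + tissue_offset[tissue], True))
    return pd.DataFrame(rows, columns=["gene", "tissue", "replicate", "ct",
                                       "is_reference"])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_fastq(reads: Iterable[RawRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n{to_dna(records[name])}\n")


def bundle_to_files(bundle: ReferenceBundle, out_dir) -> dict[str, str]:
    """Write the bundle as FASTA/TSV files; returns written paths."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["mirnas"] = os.path.join(out_dir, "mature_mirnas.fasta")
    write_fasta(bundle.mature_mirnas, paths["mirnas"])
    for cls in NCRNA_CLASSES:
        frags = {n: s for n, (c, s) in bundle.ncrna_fragments.items() if c == cls}
        paths[cls] = os.path.join(out_dir, f"{cls}.fasta")
        write_fasta(frags, paths[cls])
    paths["scaffolds"] = os.path.join(out_dir, "scaffolds.fasta")
    write_fasta(bundle.scaffolds, paths["scaffolds"])
    paths["transcripts"] = os.path.join(out_dir, "transcripts.fasta")
    write_fasta(bundle.transcripts, paths["transcripts"])
    utr_rows = [(t, s, e, label) for t, iv in bundle.utr_intervals.items()
                for (s, e, label) in iv]
    paths["utrs"] = os.path.join(out_dir, "utr_intervals.tsv")
    pd.DataFrame(utr_rows, columns=["transcript", "start", "end", "label"]) \
        .to_csv(paths["utrs"], sep="\t", index=False)
    site_rows = [(t, m, s, e) for t, sites in bundle.target_sites.items()
                 for (m, s, e) in sites]
    paths["sites"] = os.path.join(out_dir, "planted_target_sites.tsv")
    pd.DataFrame(site_rows, columns=["transcript", "mirna", "start", "end"]) \
        .to_csv(paths["sites"], sep="\t", index=False)
    hp_rows = [(sc, s, e, n, m) for sc, iv in bundle.hairpin_intervals.items()
               for (s, e, n, m) in iv]
    paths["hairpins"] = os.path.join(out_dir, "planted_hairpins.tsv")
    pd.DataFrame(hp_rows, columns=["scaffold", "start", "end", "name", "mature"]) \
        .to_csv(paths["hairpins"], sep="\t", index=False)
    return paths
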