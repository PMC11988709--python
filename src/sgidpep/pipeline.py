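"""Pipeline orchestration: one reproducible run from peptide pools to reports.

``run_pipeline`` chains the stages — load (or simulate) pools, confidence
filtering and deduplication, resistant-peptide matching, terminal-motif
screening and physicochemical profiling — and writes the full report bundle
(resistant FASTA, match/screen/profile TSVs, JSON summary). Every parameter
and seed is echoed into the summary so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import yaml

from .core import PeptidePool, Source, deduplicate, filter_by_alc
from .io import read_pool, write_fasta
from .matcher import find_resistant, write_match_tsv
from .motifs import (
    DEFAULT_AMYLASE_CRITERIA,
    CriteriaSet,
    bin_distribution,
    select_candidates,
    write_screen_tsv,
)
from .physchem import length_class, write_profile_tsv
from .simulate import DigestionSpec, NoiseSpec, generate_parent_proteins, simulate_sgid

logger = logging.getLogger("sgidpep")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Defaults follow the standard screening workflow: ALC ≥ 85 confidence
    filter, cosine similarity threshold 0.95 with strict comparison, maximum
    length difference 8 residues, length bins 2–5 / 6–10 / >10.
    """

    id_pool_path: Optional[str] = None
    spc_pool_path: Optional[str] = None
    out_dir: str = "sgidpep_out"
    threshold: float = 0.95
    max_len_diff: int = 8
    min_alc: float = 85.0
    merge_il: bool = False
    criteria_path: Optional[str] = None
    seed: int = 0
    # simulation fallback (used when no input pools are given)
    n_proteins: int = 20
    substitution_rate: float = 0.02
    n_resistant: Optional[int] = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def summarize_pools(pools: Mapping[str, PeptidePool]) -> Dict[str, Dict[str, int]]:
    """Per-pool counts of short / medium / long peptides (the digest-profile
    histogram). Counts always sum to the pool size."""
    out: Dict[str, Dict[str, int]] = {}
    for name, pool in pools.items():
        counts = {"short": 0, "medium": 0, "long": 0}
        for p in pool:
            counts[length_class(p).value] += 1
        out[name] = counts
    return out


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute the full screen and write the report bundle into ``cfg.out_dir``.

    Stages: load or simulate the ID and SPC pools → ALC filter → deduplicate
    → resistant matching → motif screen of the resistant pool → candidate
    selection → physicochemical profiles. Returns the summary dict (also
    written as ``summary.json``).
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    stage = "load"
    try:
        if cfg.id_pool_path and cfg.spc_pool_path:
            id_pool = read_pool(cfg.id_pool_path, name="ID", source=Source.ID)
            spc_pool = read_pool(cfg.spc_pool_path, name="SPC", source=Source.SPC)
            truth = None
        else:
            stage = "simulate"
            proteins = generate_parent_proteins(cfg.n_proteins, seed=cfg.seed)
            sim = simulate_sgid(
                proteins,
                DigestionSpec(seed=cfg.seed),
                NoiseSpec(substitution_rate=cfg.substitution_rate, seed=cfg.seed + 1),
                n_resistant=cfg.n_resistant,
            )
            id_pool, spc_pool = sim.pools["ID"], sim.pools["SPC"]
            truth = sim.truth

        stage = "filter"
        id_f = deduplicate(filter_by_alc(id_pool, cfg.min_alc), cfg.merge_il)
        spc_f = deduplicate(filter_by_alc(spc_pool, cfg.min_alc), cfg.merge_il)
        logger.info("pools after ALC>=%s + dedup: ID %d, SPC %d",
                    cfg.min_alc, len(id_f), len(spc_f))

        stage = "match"
        records, resistant = find_resistant(
            id_f, spc_f, threshold=cfg.threshold,
            max_len_diff=cfg.max_len_diff, merge_il=cfg.merge_il,
        )
        write_match_tsv(records, os.path.join(cfg.out_dir, "matches.tsv"))
        if len(resistant):
            write_fasta(resistant, os.path.join(cfg.out_dir, "resistant.fasta"))

        stage = "screen"
        criteria = (CriteriaSet.from_file(cfg.criteria_path)
                    if cfg.criteria_path else DEFAULT_AMYLASE_CRITERIA)
        screen_target = resistant if len(resistant) else id_f
        write_screen_tsv(screen_target, criteria,
                         os.path.join(cfg.out_dir, "screen.tsv"))
        bins = {b.value: round(v, 1)
                for b, v in bin_distribution(screen_target, criteria).items()}
        candidates = select_candidates(screen_target, criteria)

        stage = "profile"
        profile_pool = candidates if len(candidates) else screen_target
        write_profile_tsv(profile_pool, os.path.join(cfg.out_dir, "physchem.tsv"))

        stage = "summarize"
        summary = {
            "config": cfg.to_dict(),
            "criteria_set": criteria.name,
            "pool_sizes": {"ID": len(id_f), "SPC": len(spc_f)},
            "n_resistant": len(resistant),
            "n_candidates": len(candidates),
            "criteria_bins_pct": bins,
            "length_classes": summarize_pools(
                {"ID": id_f, "SPC": spc_f, "resistant": resistant}
            ),
        }
        if truth is not None:
            from .simulate import evaluate_recovery

            precision, recall = evaluate_recovery(resistant, truth)
            summary["ground_truth"] = {
                "n_true_resistant": len(truth.resistant_set),
                "precision": round(precision, 4),
                "recall": round(recall, 4),
            }
        with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
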