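"""Configuration, fixtures, file formats and the end-to-end pipeline.

The pipeline chains the five analysis stages — reference-community
simulation, clone-library simulation, chimera detection, composition and
divergence statistics, and the dataset I/II phylogenetic contrast — into
one reproducible run directory.  A single integer seed is fanned out to
fixed per-stage child seeds, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .amplicon import (
    CloneRead,
    SampleConfig,
    simulate_clone_library,
    simulate_direct_sequencing,
)
from .community import (
    DEFAULT_CONSERVED_RATE,
    DEFAULT_MAX_PRIMARY_P,
    DEFAULT_SECONDARY_SPEC,
    Community,
    RegionMap,
    build_region_map,
    simulate_references,
)
from .detector import ChimeraDetector
from .phylo import chimera_contrast, write_newick
from .stats import (
    categorize_calls,
    direct_seq_rate,
    group_divergence,
    summarize_library,
)

logger = logging.getLogger("chimeraseg")

_STAGE_OFFSETS = {
    "community": 11,
    "amplicon": 23,
    "detector": 37,
    "stats": 41,
    "phylo": 53,
}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed, kept below 2**31."""
    return (int(base_seed) * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Flat, fully serialisable configuration of one pipeline run."""

    seed: int = 0
    # community
    total_length: int = 1500
    n_conserved: int = 10
    conserved_len: int = 50
    n_hosts: int = 12
    conserved_rate: float = DEFAULT_CONSERVED_RATE
    max_primary_p: float = DEFAULT_MAX_PRIMARY_P
    secondary_spec: tuple[tuple[str, float], ...] = DEFAULT_SECONDARY_SPEC
    # amplicon
    n_clones: int = 20
    chimera_rate: float = 0.0649
    max_breakpoints: int = 2
    single_template_prob: float = 1.0 / 6.0
    dominance_threshold: float = 0.9
    # detector
    identity_min: float = 0.80
    margin_min: float = 0.02
    anchor_mismatch_limit: int = 3
    # phylo
    n_substituted: int = 6
    n_rell: int = 1000

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["secondary_spec"] = tuple(
            (str(n), float(p)) for n, p in raw.get("secondary_spec", DEFAULT_SECONDARY_SPEC)
        )
        return cls(**raw)


# ---------------------------------------------------------------------------
# Sample composition
# ---------------------------------------------------------------------------


def draw_sample_configs(
    community: Community, config: PipelineConfig, seed: int
) -> list[SampleConfig]:
    """Template compositions for one sample per primary-symbiont host.

    Each sample carries its host's primary symbiont and, with
    probability ``1 - single_template_prob``, one or two secondary
    symbionts at a substantial relative abundance (the regime in which
    direct sequencing shows miscellaneous peaks).
    """
    rng = np.random.default_rng(seed)
    samples = []
    secondaries = [r.taxon for r in community.secondary]
    for i, primary in enumerate(community.primary, start=1):
        if not secondaries or rng.random() < config.single_template_prob:
            complement = ((primary.taxon, 1.0),)
        else:
            k = int(rng.integers(1, min(2, len(secondaries)) + 1))
            picks = rng.choice(len(secondaries), size=k, replace=False)
            primary_ab = float(rng.uniform(0.3, 0.85))
            rest = np.asarray(rng.dirichlet(np.ones(k)) * (1.0 - primary_ab))
            complement = (
                (primary.taxon, primary_ab),
                *((secondaries[j], float(a)) for j, a in zip(picks, rest)),
            )
            total = sum(a for _, a in complement)
            complement = tuple((t, a / total) for t, a in complement)
        samples.append(
            SampleConfig(
                sample_id=f"sample_{i:02d}",
                complement=complement,
                n_clones=config.n_clones,
                chimera_rate=config.chimera_rate,
                max_breakpoints=config.max_breakpoints,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_clones(clones: list[CloneRead], fasta_path, provenance_path) -> None:
    write_fasta({c.clone_id: c.sequence for c in clones}, fasta_path)
    rows = [
        {"clone_id": c.clone_id, "sample_id": c.sample_id, "start": s, "end": e, "parent": p}
        for c in clones
        for s, e, p in c.provenance
    ]
    pd.DataFrame(rows).to_csv(provenance_path, sep="\t", index=False)


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for call in calls:
        rows.append(
            {
                "clone_id": call.clone_id,
                "is_chimera": call.is_chimera,
                "undetermined": call.undetermined,
                "structure": call.structure,
                "blocks": ";".join(f"{s}-{e}:{g}" for s, e, g in call.blocks),
                "breakpoints": ";".join(str(b) for b in call.breakpoints),
                "identities": ";".join(
                    f"{a.identity:.4f}" for a in call.assignments
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def load_fixtures() -> dict[str, pd.DataFrame]:
    """Packaged reference tables from the published 12-sample survey.

    Returns ``clone_counts`` (clone-library category counts, 185 clones),
    ``direct_sequencing`` (per-sample effectiveness flags, 2/12), and
    ``dataset1_inventory`` (record inventory of the chimera-free
    alignment: 45 database + 12 study + 4 outgroup records).
    """
    out = {}
    base = importlib.resources.files("chimeraseg") / "data"
    for name in ("clone_counts", "direct_sequencing", "dataset1_inventory"):
        with (base / f"{name}.tsv").open() as fh:
            out[name] = pd.read_csv(fh, sep="\t", comment="#")
    out["direct_sequencing"]["effective"] = (
        out["direct_sequencing"]["effective"].astype(str).str.lower() == "true"
    )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Objects and paths produced by one full run."""

    out_dir: Path
    community: Community
    sample_configs: list[SampleConfig]
    clones: list[CloneRead]
    calls: list
    summary: object  # CloneLibrarySummary
    chimera_frequency: float
    direct_rate: float
    divergence: pd.DataFrame
    contrast: object


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute community -> amplicon -> detector -> stats -> phylo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    log_lines = [f"chimeraseg {__version__} seed={config.seed}"]

    def _log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    try:
        # -- community -----------------------------------------------------
        stage = "community"
        region_map = build_region_map(
            config.total_length, config.n_conserved, config.conserved_len
        )
        from .community import default_host_tree

        host_tree = default_host_tree(config.n_hosts, seed=stage_seed(config.seed, stage))
        community = simulate_references(
            host_tree=host_tree,
            region_map=region_map,
            secondary_spec=config.secondary_spec,
            seed=stage_seed(config.seed, stage),
            conserved_rate=config.conserved_rate,
            max_primary_p=config.max_primary_p,
        )
        region_map.to_tsv(out_dir / "regions.tsv")
        write_fasta({r.taxon: r.sequence for r in community.refs}, out_dir / "community.fasta")
        write_fasta({"primary_root": community.root_sequence}, out_dir / "root.fasta")
        _log(stage, f"{len(community.primary)} primary + {len(community.secondary)} secondary refs")

        # -- amplicon ------------------------------------------------------
        stage = "amplicon"
        rng = np.random.default_rng(stage_seed(config.seed, stage))
        sample_configs = draw_sample_configs(community, config, stage_seed(config.seed, stage))
        clones: list[CloneRead] = []
        for sc in sample_configs:
            clones.extend(simulate_clone_library(sc, community, seed=rng))
        write_clones(clones, out_dir / "clones.fasta", out_dir / "provenance.tsv")
        pd.DataFrame(
            [
                {"sample_id": sc.sample_id, "taxon": t, "abundance": a}
                for sc in sample_configs
                for t, a in sc.complement
            ]
        ).to_csv(out_dir / "sample_configs.tsv", sep="\t", index=False)
        _log(stage, f"{len(clones)} clones from {len(sample_configs)} samples")

        # -- detector ------------------------------------------------------
        stage = "detector"
        detector = ChimeraDetector(
            community,
            identity_min=config.identity_min,
            margin_min=config.margin_min,
            anchor_mismatch_limit=config.anchor_mismatch_limit,
        )
        calls = detector.call_many(clones)
        calls_to_frame(calls).to_csv(out_dir / "calls.tsv", sep="\t", index=False)
        _log(stage, f"{sum(c.is_chimera for c in calls)} chimera calls")

        # -- stats ---------------------------------------------------------
        stage = "stats"
        summary = summarize_library(categorize_calls(calls))
        summary.to_frame().to_csv(out_dir / "library_summary.tsv", sep="\t", index=False)
        flags = [
            simulate_direct_sequencing(sc, config.dominance_threshold)
            for sc in sample_configs
        ]
        rate = direct_seq_rate(flags)
        pd.DataFrame(
            {"sample_id": [sc.sample_id for sc in sample_configs], "effective": flags}
        ).to_csv(out_dir / "direct_sequencing.tsv", sep="\t", index=False)
        divergence = group_divergence(
            {r.taxon: r.sequence for r in community.refs}, community.groups()
        )
        divergence.to_csv(out_dir / "divergence.tsv", sep="\t", index=False)
        _log(
            stage,
            f"chimera_frequency={summary.chimera_frequency}% direct_rate={rate}%",
        )

        # -- phylo ---------------------------------------------------------
        stage = "phylo"
        # substitute the authentic chimeras detected in the libraries:
        # one chimeric clone per host species that yielded one
        call_by_id = {c.clone_id: c for c in calls}
        sample_primary = {sc.sample_id: sc.complement[0][0] for sc in sample_configs}
        chimera_map: dict[str, str] = {}
        for clone in clones:
            primary_taxon = sample_primary[clone.sample_id]
            call = call_by_id[clone.clone_id]
            if call.is_chimera and primary_taxon not in chimera_map:
                chimera_map[primary_taxon] = clone.sequence
        contrast = chimera_contrast(
            community,
            chimeras=chimera_map,
            n_rell=config.n_rell,
            seed=stage_seed(config.seed, stage),
        )
        _log(stage, f"substituted chimeras for {len(chimera_map)} species")
        contrast.dataset_i.to_fasta(out_dir / "dataset1.fasta")
        contrast.dataset_ii.to_fasta(out_dir / "dataset2.fasta")
        write_newick(contrast.tree_i, out_dir / "tree1.nwk")
        write_newick(contrast.tree_ii, out_dir / "tree2.nwk")
        pd.DataFrame(
            [
                {
                    "delta_lnL": contrast.sh.delta_lnL,
                    "p_value": contrast.sh.p_value,
                    "n_rell": contrast.sh.n_replicates,
                    "seed": contrast.sh.seed,
                    "rf_distance": contrast.rf,
                }
            ]
        ).to_csv(out_dir / "sh_test.tsv", sep="\t", index=False)
        _log(stage, f"SH p={contrast.sh.p_value:.4g} RF={contrast.rf}")
    except Exception as exc:  # fail fast with a stage-labelled error
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    config.to_json(out_dir / "config.json")
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        out_dir=out_dir,
        community=community,
        sample_configs=sample_configs,
        clones=clones,
        calls=calls,
        summary=summary,
        chimera_frequency=summary.chimera_frequency,
        direct_rate=rate,
        divergence=divergence,
        contrast=contrast,
    )
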