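"""End-to-end orchestration: curation → loops → statistics → reconstruction.

One declarative :class:`PipelineConfig` (YAML-loadable) drives all stages and
:func:`run_pipeline` writes every artifact plus a machine-readable report
with per-stage counts and a provenance block (config hash, seed, version).
:func:`reproduce_from_alignment` is the reproduction mode for a deposited
family alignment: it recomputes the headline dataset statistics (tip-residue
shares and P32 co-occurrence) directly from an aligned FASTA.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .ancestral import MISSING, MkAncestral
from .curation import curate, read_annotations, read_domain_hits, read_fasta, write_fasta
from .loops import (
    DEFAULT_WINDOW,
    classify_loop,
    extract_loops_msa,
    extract_loops_pairwise,
    loops_to_frame,
    read_msa,
)
from .simulate import BACKBONE, TIP_STATES
from .stats import column_frequencies, cooccurrence_table, information_content
from .trees import make_ultrametric, midpoint_root, read_newick, serialize_newick, write_newick

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "reproduce_from_alignment"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    fasta: str = None
    hits: str = None
    hits_dialect: str = "simple_tsv"
    annotations: Optional[str] = None
    tree: str = None
    msa: Optional[str] = None
    reference_id: Optional[str] = None  # row id in the MSA / record in the FASTA
    window: tuple = DEFAULT_WINDOW
    evalue_cutoff: float = 1e-3
    character: str = "minus2_P"  # or "tip"
    model_form: str = "ER"
    seed: int = 0
    outdir: str = "efp_loopscape_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    def digest(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("fasta", "hits", "tree"):
            path = getattr(self, name)
            if path is None:
                raise ConfigError(f"config is missing required input {name!r}")
            if not os.path.exists(path):
                raise ConfigError(f"{name} file not found: {path}")
        for name in ("annotations", "msa"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name} file not found: {path}")
        if self.character not in ("minus2_P", "tip"):
            raise ConfigError(f"unknown character {self.character!r}")
        if self.evalue_cutoff <= 0:
            raise ConfigError("evalue_cutoff must be > 0")


@dataclass
class ReportBundle:
    """All pipeline outputs plus the counts that reconcile the stages."""

    counts: dict
    loop_table: pd.DataFrame
    frequency_matrix: object
    logo_matrix: object
    cooccurrence: dict
    reconstruction: object
    provenance: dict
    paths: dict = field(default_factory=dict)

    def report_dict(self) -> dict:
        rec = self.reconstruction
        out = {
            "counts": self.counts,
            "cooccurrence": {
                key: df.drop(columns=["pct_P32_unrounded"], errors="ignore").to_dict(orient="records")
                for key, df in self.cooccurrence.items()
            },
            "provenance": self.provenance,
        }
        if rec is not None:
            out["reconstruction"] = {
                "form": rec.mk_model.form,
                "states": list(rec.states),
                "rates": [float(r) for r in rec.rates],
                "log_likelihood": rec.llf,
                "root": rec.summarize_root(),
            }
        return out


def _character_states(loop_frame: pd.DataFrame, genome_of: dict, character: str):
    """Per-genome character map for the reconstruction stage."""
    ok = loop_frame[loop_frame["status"] == "ok"]
    per_genome: dict = {}
    for _, row in ok.sort_values("protein_id", kind="stable").iterrows():
        genome = genome_of.get(row["protein_id"])
        if genome is None or genome in per_genome:
            continue  # one character observation per genome (first curated copy)
        if character == "minus2_P":
            per_genome[genome] = "P" if row["minus2"] == "P" else "not-P"
        else:
            tip = row["tip"]
            per_genome[genome] = tip if tip in TIP_STATES else MISSING
    return per_genome


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute curation, loop extraction, statistics, and reconstruction."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    paths = {}

    records = read_fasta(config.fasta)
    hits = read_domain_hits(config.hits, dialect=config.hits_dialect)
    annotations = read_annotations(config.annotations) if config.annotations else None
    tree = read_newick(config.tree)

    # stage 1: curation
    kept, paralog_counts, enzyme_table, stage_counts = curate(hits, records, config.evalue_cutoff)
    paths["curated_fasta"] = os.path.join(config.outdir, "curated.fasta")
    write_fasta(kept, paths["curated_fasta"])
    paths["paralog_counts"] = os.path.join(config.outdir, "paralog_counts.tsv")
    paralog_counts.to_csv(paths["paralog_counts"], sep="\t", index=False)
    paths["enzyme_table"] = os.path.join(config.outdir, "genome_annotations.tsv")
    enzyme_table.to_csv(paths["enzyme_table"], sep="\t", index=False)

    # stage 2: loop extraction
    if config.msa:
        msa = read_msa(config.msa)
        if config.reference_id is None or config.reference_id not in msa:
            raise ConfigError("msa mode requires reference_id naming an alignment row")
        keep_ids = {r.protein_id for r in kept}
        assignments, rejections = extract_loops_msa(
            msa, config.reference_id, config.window, ids=keep_ids
        )
    else:
        reference = BACKBONE
        if config.reference_id is not None:
            by_id = {r.protein_id: r.sequence for r in records}
            if config.reference_id not in by_id:
                raise ConfigError(f"reference_id {config.reference_id!r} not in FASTA")
            reference = by_id[config.reference_id]
        assignments, rejections = extract_loops_pairwise(kept, reference, config.window)
    loop_frame = loops_to_frame(assignments, rejections)
    paths["loops"] = os.path.join(config.outdir, "loops.tsv")
    loop_frame.to_csv(paths["loops"], sep="\t", index=False)
    stage_counts["loops_accepted"] = len(assignments)
    stage_counts["loops_rejected_gap"] = len(rejections)

    # stage 3: conservation statistics
    freq = logo = None
    cooc: dict = {}
    genome_of = {r.protein_id: r.genome_id for r in kept}
    if assignments:
        freq = column_frequencies(assignments)
        logo = information_content(freq)
        paths["frequencies"] = os.path.join(config.outdir, "frequencies.tsv")
        freq.frequencies.to_csv(paths["frequencies"], sep="\t")
        paths["logo"] = os.path.join(config.outdir, "logo.tsv")
        logo.heights.to_csv(paths["logo"], sep="\t")
        classes = [classify_loop(a) for a in assignments]
        ann_for_stats = enzyme_table.rename(columns=str) if annotations is None else annotations
        cooc["tip_residue"] = cooccurrence_table(
            classes, annotations=ann_for_stats, group_by="tip_residue", genome_of=genome_of
        )
        cooc["loop_type"] = cooccurrence_table(classes, group_by="loop_type")
        cooc["enzyme"] = cooccurrence_table(
            classes, annotations=ann_for_stats, group_by="enzyme", genome_of=genome_of
        )
        for key, df in cooc.items():
            paths[f"cooccurrence_{key}"] = os.path.join(config.outdir, f"cooccurrence_{key}.tsv")
            df.to_csv(paths[f"cooccurrence_{key}"], sep="\t", index=False)

    # stage 4: ancestral reconstruction (midpoint root + ultrametric first)
    reconstruction = None
    leaf_states = _character_states(loop_frame, genome_of, config.character)
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if leaf_states and n_leaves >= 2:
        rooted = make_ultrametric(midpoint_root(tree))
        full_states = {
            leaf.taxon.label: leaf_states.get(leaf.taxon.label, MISSING)
            for leaf in rooted.leaf_node_iter()
        }
        alphabet = ("P", "not-P") if config.character == "minus2_P" else TIP_STATES
        model = MkAncestral(rooted, full_states, states=alphabet, form=config.model_form)
        reconstruction = model.fit()
        paths["rooted_tree"] = os.path.join(config.outdir, "rooted_ultrametric.nwk")
        write_newick(rooted, paths["rooted_tree"])
        paths["posteriors"] = os.path.join(config.outdir, "ancestral_posteriors.tsv")
        reconstruction.to_frame().to_csv(paths["posteriors"], sep="\t", index=False)
        paths["fitted_model"] = os.path.join(config.outdir, "fitted_model.json")
        with open(paths["fitted_model"], "w") as fh:
            json.dump(
                {
                    "form": reconstruction.mk_model.form,
                    "states": list(reconstruction.states),
                    "rates": [float(r) for r in reconstruction.rates],
                    "log_likelihood": reconstruction.llf,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    bundle = ReportBundle(
        counts=stage_counts,
        loop_table=loop_frame,
        frequency_matrix=freq,
        logo_matrix=logo,
        cooccurrence=cooc,
        reconstruction=reconstruction,
        provenance=provenance,
        paths=paths,
    )
    paths["report"] = os.path.join(config.outdir, "report.json")
    with open(paths["report"], "w") as fh:
        json.dump(bundle.report_dict(), fh, indent=2, sort_keys=True)
    return bundle


def reproduce_from_alignment(msa_path, reference_id: str, window=DEFAULT_WINDOW) -> dict:
    """Recompute the headline dataset statistics from a family alignment.

    Reads an aligned FASTA with the reference as a named row, extracts the
    loop window of every other row, and reports the final set size, the
    tip-residue shares, and the per-tip P32 co-occurrence percentages (2
    decimals, half-up).
    """
    msa = read_msa(msa_path)
    assignments, rejections = extract_loops_msa(msa, reference_id, window)
    if not assignments:
        raise ValueError("no loop could be extracted from the alignment")
    classes = [classify_loop(a) for a in assignments]
    table = cooccurrence_table(classes, group_by="tip_residue")
    n = len(assignments)
    shares = {
        row["group"]: round(100.0 * row["count"] / n, 2) for _, row in table.iterrows()
    }
    cooc = {row["group"]: row["pct_P32"] for _, row in table.iterrows()}
    other_share = round(sum(v for k, v in shares.items() if k not in ("K", "R")), 2)
    return {
        "final_set_size": n,
        "rejected_gap_in_window": len(rejections),
        "tip_share_pct": shares,
        "tip_share_other_pct": other_share,
        "p32_cooccurrence_pct": cooc,
        "table": table,
    }
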