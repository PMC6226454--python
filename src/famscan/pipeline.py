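"""End-to-end orchestration: simulate -> identify -> props -> phylo ->
structure/motifs -> duplication -> expression -> qPCR, with one seeded
configuration and a consolidated, reproducible run report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import duplication, expression, identify, io, phylo, props, qpcr, structure
from .models import GenomeBundle, ParalogPair
from .reference import MOTIFS
from .simulate import GeneratorConfig, generate, simulate_ct, simulate_expression

log = logging.getLogger("famscan")


@dataclass
class RunConfig:
    """All thresholds of a pipeline run; serialized verbatim into the run
    report so any run can be reproduced from its report alone."""

    seed: int = 42
    outdir: str = "famscan_run"
    stages: tuple[str, ...] = (
        "simulate", "identify", "props", "phylo", "structure", "dup", "expr", "qpcr",
    )
    evalue_threshold: float = identify.EVALUE_THRESHOLD
    presence_threshold: float = identify.PRESENCE_THRESHOLD
    n_shuffles: int = identify.DEFAULT_SHUFFLES
    distance_model: str = "p-distance"
    bootstrap_reps: int = 100
    k_subfamilies: int = 5
    identity_min: float = 0.95
    tandem_window_bp: int = duplication.TANDEM_WINDOW_BP
    tandem_max_intervening: int = duplication.TANDEM_MAX_INTERVENING
    fpkm_threshold: float = 1.0
    pseudocount: float = 0.01
    alpha: float = qpcr.ALPHA
    fold_min: float = qpcr.FOLD_MIN
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if self.generator.seed != self.seed:
            self.generator = dataclasses.replace(self.generator, seed=self.seed)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["stages"] = list(self.stages)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        gen = payload.pop("generator", {})
        if gen:
            for key in ("linker_length_range", "motif_order"):
                if key in gen and gen[key] is not None:
                    gen[key] = tuple(gen[key])
            payload["generator"] = GeneratorConfig(**gen)
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


@dataclass
class RunReport:
    config: dict
    headline: dict
    files: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "headline": self.headline, "files": self.files},
            indent=2,
            sort_keys=True,
        )


def run_all(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Downstream stages consume in-memory results of upstream ones; a
    disabled prerequisite makes the dependent stage fail fast with the
    stage name in the error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    headline: dict = {}
    files: dict[str, str] = {}
    state: dict = {}

    def record(name: str, path: Path) -> None:
        files[name] = str(path)

    def require(stage: str, key: str):
        if key not in state:
            raise RuntimeError(
                f"stage {stage!r} requires output of a disabled stage ({key} missing)"
            )
        return state[key]

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            log.info("stage %s disabled", name)
            return
        log.info("running stage %s", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def stage_simulate() -> None:
        bundle = generate(config.generator)
        state["bundle"] = bundle
        state["fpkm"] = simulate_expression(bundle, config.generator)
        state["ct"] = simulate_ct(bundle, config.generator)
        io.write_fasta(bundle.proteins, outdir / "proteome.fasta")
        io.write_cds_fasta(bundle.cds, outdir / "cds.fasta")
        io.write_gff3(bundle.genes, outdir / "genes.gff3")
        io.write_motifs_tsv(MOTIFS, outdir / "motifs.tsv")
        io.write_expression_tsv(state["fpkm"], outdir / "expression.tsv")
        io.write_ct_tsv(state["ct"], outdir / "ct.tsv")
        io.write_truth_json(bundle.truth, outdir / "truth.json")
        for name in ("proteome.fasta", "cds.fasta", "genes.gff3", "motifs.tsv",
                     "expression.tsv", "ct.tsv", "truth.json"):
            record(name, outdir / name)
        headline["proteome_size"] = len(bundle.proteins)

    def stage_identify() -> None:
        bundle: GenomeBundle = require("identify", "bundle")
        reports = identify.scan_proteome(
            bundle.proteins, MOTIFS,
            n_shuffles=config.n_shuffles,
            seed=config.seed,
            presence_threshold=config.presence_threshold,
        )
        gene_index = {g.id: g for g in bundle.genes}
        accepted = identify.filter_candidates(
            reports, bundle.proteins, gene_index,
            evalue_threshold=config.evalue_threshold,
        )
        state["reports"] = reports
        state["accepted"] = accepted
        frame = pd.DataFrame(
            {
                "id": [r.protein_id for r in reports],
                "score": [r.score for r in reports],
                "evalue": [r.evalue for r in reports],
                "redundant": [r.redundant for r in reports],
                "incomplete": [r.incomplete for r in reports],
                "verdict": [r.verdict for r in reports],
            }
        ).sort_values("id")
        frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        record("candidates.tsv", outdir / "candidates.tsv")
        headline["raw_candidates"] = int(
            sum(r.evalue < config.evalue_threshold for r in reports)
        )
        headline["accepted"] = len(accepted)

    def accepted_proteins():
        bundle: GenomeBundle = state["bundle"]
        ids = {r.protein_id for r in state["accepted"]}
        return [p for p in bundle.proteins if p.id in ids]

    def stage_props() -> None:
        require("props", "accepted")
        table = props.properties_table(accepted_proteins())
        table.to_csv(outdir / "properties.tsv", sep="\t", index=False)
        record("properties.tsv", outdir / "properties.tsv")
        headline["length_range_aa"] = [
            int(table["length_aa"].min()), int(table["length_aa"].max()),
        ]

    def stage_phylo() -> None:
        require("phylo", "accepted")
        proteins = accepted_proteins()
        tree = phylo.bootstrap_supports(
            proteins, n_reps=config.bootstrap_reps, seed=config.seed,
            model=config.distance_model,
        )
        state["tree"] = tree
        state["proteins"] = proteins
        labels = phylo.cut_subfamilies(tree, config.k_subfamilies)
        state["subfamilies"] = labels
        pairs = phylo.sister_pairs(tree, proteins, config.identity_min)
        state["pairs"] = pairs
        (outdir / "tree.nwk").write_text(tree.newick() + "\n")
        pd.DataFrame(sorted(labels.items()), columns=["gene", "subfamily"]).to_csv(
            outdir / "subfamilies.tsv", sep="\t", index=False
        )
        record("tree.nwk", outdir / "tree.nwk")
        record("subfamilies.tsv", outdir / "subfamilies.tsv")
        sizes = sorted(
            pd.Series(list(labels.values())).value_counts().tolist(), reverse=True
        )
        headline["subfamily_sizes"] = sizes
        headline["sister_pairs"] = [[p.gene_a, p.gene_b] for p in pairs]

    def stage_structure() -> None:
        bundle: GenomeBundle = require("structure", "bundle")
        require("structure", "accepted")
        ids = {r.protein_id for r in state["accepted"]}
        family_genes = [g for g in bundle.genes if g.id in ids]
        report = structure.structure_report(family_genes)
        report.to_csv(outdir / "structure.tsv", sep="\t", index=False)
        counts = structure.chromosome_distribution(family_genes)
        counts.rename("n_genes").to_csv(outdir / "chromosome_counts.tsv", sep="\t")
        presence = structure.motif_presence_matrix(
            accepted_proteins(), MOTIFS, threshold=config.presence_threshold
        )
        presence.to_csv(outdir / "motif_presence.tsv", sep="\t")
        for name in ("structure.tsv", "chromosome_counts.tsv", "motif_presence.tsv"):
            record(name, outdir / name)
        headline["chromosomes_occupied"] = structure.occupied_chromosomes(counts)
        headline["chromosome_counts"] = counts[counts > 0].to_dict()

    def stage_dup() -> None:
        bundle: GenomeBundle = require("dup", "bundle")
        pairs: list[ParalogPair] = require("dup", "pairs")
        classified = duplication.classify_pairs(
            pairs, bundle.genes,
            tandem_window_bp=config.tandem_window_bp,
            max_intervening=config.tandem_max_intervening,
        )
        frame = pd.DataFrame(
            {
                "gene_a": [p.gene_a for p in classified],
                "gene_b": [p.gene_b for p in classified],
                "identity": [p.identity for p in classified],
                "distance_bp": [p.distance_bp for p in classified],
                "intervening_genes": [p.intervening_genes for p in classified],
                "class": [p.duplication_class for p in classified],
            }
        )
        frame.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        record("pairs.tsv", outdir / "pairs.tsv")
        headline["pair_classes"] = (
            frame["class"].value_counts().sort_index().to_dict()
        )

    def stage_expr() -> None:
        fpkm: pd.DataFrame = require("expr", "fpkm")
        normalized = expression.normalize(fpkm, pseudocount=config.pseudocount)
        dendrogram = expression.hcluster(normalized)
        counts = expression.expressed_tissue_counts(fpkm, config.fpkm_threshold)
        normalized.to_csv(outdir / "expression_log2.tsv", sep="\t", index_label="gene")
        (outdir / "expression_dendrogram.nwk").write_text(dendrogram.newick() + "\n")
        counts.rename("n_tissues").to_csv(
            outdir / "expressed_tissue_counts.tsv", sep="\t", index_label="gene"
        )
        for name in ("expression_log2.tsv", "expression_dendrogram.nwk",
                     "expressed_tissue_counts.tsv"):
            record(name, outdir / name)
        headline["expressed_tissue_counts"] = counts.to_dict()

    def stage_qpcr() -> None:
        ct = require("qpcr", "ct")
        calls = qpcr.regulation_calls(ct, alpha=config.alpha, fold_min=config.fold_min)
        table = qpcr.calls_table(calls)
        table.to_csv(outdir / "regulation_calls.tsv", sep="\t", index=False)
        record("regulation_calls.tsv", outdir / "regulation_calls.tsv")
        headline["changed_per_treatment"] = (
            qpcr.changed_counts(calls).sort_index().to_dict()
        )

    for name, fn in (
        ("simulate", stage_simulate),
        ("identify", stage_identify),
        ("props", stage_props),
        ("phylo", stage_phylo),
        ("structure", stage_structure),
        ("dup", stage_dup),
        ("expr", stage_expr),
        ("qpcr", stage_qpcr),
    ):
        run_stage(name, fn)

    report = RunReport(config=config.to_dict(), headline=headline, files=files)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
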