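"""End-to-end pipeline driver over the synthetic (or user-supplied) inputs.

Stages: simulate -> assign -> aggregate -> enrich -> classify-specialists ->
phylo-assoc -> convergence.  Every run writes a machine-readable manifest
recording inputs, thresholds, seeds and stage status.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assign as assign_mod
from . import convergence as conv_mod
from . import enrichment as enr_mod
from . import io as io_mod
from . import phylo as phylo_mod
from .simulate import (
    MARKERS,
    SimulationConfig,
    make_metadata,
    simulate_asv_tables,
    simulate_gene_pa,
    simulate_marker_alignments,
    simulate_population_tree,
    simulate_rates,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tau: float = 0.80
    alpha: float = 0.05
    abundance_threshold: float = 0.01
    min_og_fraction: float = 0.5
    nmds_k: int = 2
    n_permutations: int = 999
    n_sim: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 <= self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must be in [0,1)")
        if not 0 <= self.min_og_fraction <= 1:
            raise ValueError("min_og_fraction must be in [0,1]")
        self.simulation.validate()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        sim = SimulationConfig(**d.pop("simulation", {}))
        return cls(simulation=sim, **d)


def _specialist_calls_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mc": c.mc,
                "call": c.call,
                "enriched_taxonomic": c.enriched_taxonomic,
                "enriched_functional": c.enriched_functional,
                "mean_western_abundance": c.mean_western_abundance,
            }
            for c in calls
        ]
    ).set_index("mc")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages on a simulated scenario; returns the manifest."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulation.seed == 0:  # master seed drives the simulation stream
        config.simulation.seed = config.seed
    manifest: dict = {
        "version": __version__,
        "numpy": np.__version__,
        "config": json.loads(config.to_json()),
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
                manifest["stages"].append({"name": name, "status": "ok"})
                return result
            except Exception as exc:
                manifest["stages"].append(
                    {"name": name, "status": "failed", "error": str(exc)}
                )
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return deco

    sim = config.simulation

    @stage("simulate")
    def _simulate():
        tree = simulate_population_tree(sim)
        meta = make_metadata(sim)
        alns = simulate_marker_alignments(tree, sim)
        tables = simulate_asv_tables(tree, meta, sim, alns)
        pa = simulate_gene_pa(tree, sim)
        rates = simulate_rates(tree, sim)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        meta.to_csv(out / "metadata.tsv", sep="\t")
        for marker in MARKERS:
            aln = alns[marker]
            io_mod.write_fasta(
                out / f"{marker}.aln.fasta", dict(zip(aln.ids, aln.rows))
            )
            tables[marker].counts.to_csv(out / f"{marker}.counts.tsv", sep="\t")
            io_mod.write_fasta(out / f"{marker}.asv.fasta", tables[marker].sequences)
        pa.table.to_csv(out / "gene_pa.tsv", sep="\t")
        rates.rename("rate").to_csv(out / "rates.tsv", sep="\t")
        truth = pd.DataFrame(
            {"mc": sorted(tree.mcs)}
        )
        truth["specialist"] = truth["mc"].isin(tree.specialist_mcs)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        return tree, meta, alns, tables, pa, rates

    tree, meta, alns, tables, pa, rates = _simulate

    @stage("assign")
    def _assign():
        assignments = {}
        for marker in MARKERS:
            aln = alns[marker]
            ref_ids = [i for i in aln.ids if aln.group_of_row[i] == "ingroup"]
            ref_rows = [r for i, r in zip(aln.ids, aln.rows) if aln.group_of_row[i] == "ingroup"]
            joint = assign_mod.align_queries_to_reference(
                ref_ids, ref_rows, tables[marker].sequences
            )
            jt = assign_mod.build_joint_tree(joint, aln.mc_of_row)
            res = assign_mod.assign_all(jt, tau=config.tau)
            for q in joint.excluded_queries:  # unplaceable ASVs stay unassigned
                res.append(assign_mod.AssignmentResult(q, None, 0.0, 0, -1))
            assignments[marker] = res
            pd.DataFrame(
                [
                    {
                        "asv_id": a.asv_id,
                        "mc": a.assigned_mc or "unassigned",
                        "fraction": a.supporting_fraction,
                        "depth": a.ancestor_depth_used,
                    }
                    for a in res
                ]
            ).to_csv(out / f"{marker}.assignments.tsv", sep="\t", index=False)
        return assignments

    assignments = _assign

    @stage("aggregate")
    def _aggregate():
        abundances = {}
        for marker in MARKERS:
            rel, unassigned, flagged = assign_mod.aggregate_population_abundance(
                tables[marker].counts, assignments[marker]
            )
            abundances[marker] = rel
            rel.to_csv(out / f"{marker}.mc_abundance.tsv", sep="\t")
            if flagged:
                logger.warning("%s: samples with zero assigned reads: %s", marker, flagged)
        return abundances

    abundances = _aggregate

    @stage("enrich")
    def _enrich():
        ords = {}
        envfits = []
        for marker in MARKERS:
            table = abundances[marker].fillna(0.0)
            d = enr_mod.bray_curtis(table.T)
            ordn = enr_mod.nmds(d, k=config.nmds_k, seed=config.seed)
            ords[marker] = ordn
            ordn.scores.to_csv(out / f"{marker}.nmds_scores.tsv", sep="\t")
            for var in ("nitrate", "nitrite", "ammonia", "total_phosphorus"):
                fit = enr_mod.envfit_vector(
                    ordn, meta.loc[ordn.scores.index, var],
                    n_permutations=config.n_permutations, seed=config.seed,
                    variable=f"{marker}:{var}",
                )
                envfits.append(
                    {"marker": marker, "variable": var, "r2": fit.r_squared,
                     "p": fit.p_value}
                )
        pd.DataFrame(envfits).to_csv(out / "envfit.tsv", sep="\t", index=False)
        return ords

    ords = _enrich

    @stage("classify-specialists")
    def _classify():
        calls = enr_mod.classify_specialists(
            abundances,
            meta["site_group"],
            alpha=config.alpha,
            abundance_threshold=config.abundance_threshold,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        _specialist_calls_frame(calls).to_csv(out / "specialist_calls.tsv", sep="\t")
        return calls

    calls = _classify
    called_specialists = {c.mc for c in calls if c.call == "specialist"}

    @stage("phylo-assoc")
    def _phylo():
        spec = pd.Series(
            {t: float(tree.mc_of_tip[t] in called_specialists) for t in tree.mc_of_tip}
        )
        results = phylo_mod.gene_trait_association_workflow(
            tree.tree, pa.table, spec, alpha=config.alpha
        )
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "gene_assoc.tsv", sep="\t", index=False
        )
        groups = pd.Series(
            {t: "specialist" if spec[t] else "non-specialist" for t in spec.index}
        )
        if groups.nunique() == 2 and groups.value_counts().min() >= 2:
            pa_res = phylo_mod.phylanova(
                tree.tree, groups, rates, n_sim=config.n_sim, seed=config.seed
            )
            (out / "phylanova.json").write_text(json.dumps(dataclasses.asdict(pa_res)))
        return results

    _phylo

    @stage("convergence")
    def _convergence():
        retained = conv_mod.filter_ogs(pa.table, min_fraction=config.min_og_fraction)
        calls_c = []
        for og in retained:
            carriers = set(pa.table.index[pa.table[og] > 0])
            if len(carriers) < 2:
                continue
            gt = tree.tree.shear(carriers)
            calls_c.append(
                conv_mod.detect_specialist_convergent_clade(
                    gt, tree.mc_of_tip, called_specialists, og=og
                )
            )
        conv_mod.summarize_convergent_ogs(calls_c).to_csv(
            out / "convergent_ogs.tsv", sep="\t", index=False
        )
        return calls_c

    _convergence

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
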