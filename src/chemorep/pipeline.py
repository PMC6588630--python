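"""End-to-end orchestration of a synthetic repertoire study.

Runs the stages in the order of the underlying analysis — simulate
genomes, mine and classify receptor genes, build the repertoire tree,
reconcile against the species tree, test for gene conversion, run the
repertoire-ecotype statistics, the selection models, and the expression
contrasts — communicating only through on-disk files in the declared
formats so any stage's input can be replaced by real external output.
A manifest records inputs, parameters, seeds, and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as cio
from . import mining, phylogeny, reconcile, geneconv, repstats, phyloglm
from . import selection as sel
from . import simulate as sim
from .io import SequenceRecord


class DependencyError(RuntimeError):
    """A stage was enabled without the stage that produces its input."""


# A receptor-sized seed protein (~310 aa) built deterministically; the
# synthetic study derives every subfamily seed from it.
def _seed_protein(subfamily: int, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    core = "".join(aas[i] for i in rng.integers(0, 20, size=309))
    return "M" + core


def default_config() -> dict[str, object]:
    return {
        "seed": 1,
        "n_fright": 2,
        "n_nofright": 2,
        "n_subfamilies": 2,
        "boosted_subfamily": 1,
        "genes_per_subfamily": 2,
        "boost_copies": 4,
        "divergence": 0.08,
        "contig_len": 4000,
        "flank": 1500,
        "stage_simulate": True,
        "stage_mine": True,
        "stage_tree": True,
        "stage_reconcile": True,
        "stage_geneconv": True,
        "stage_repstats": True,
        "stage_selection": True,
        "stage_expression": True,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunReport:
    outdir: Path
    manifest: dict[str, object]
    status_counts: pd.DataFrame | None = None
    event_table: pd.DataFrame | None = None
    association: dict[str, object] | None = None
    selection_table: pd.DataFrame | None = None


def run_pipeline(config: dict[str, object], outdir: str | Path) -> RunReport:
    cfg = default_config()
    cfg.update(config)
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = cio.get_logger("chemorep.pipeline", run_id=out.name, seed=seed)
    manifest: dict[str, object] = {"config": {k: str(v) for k, v in cfg.items()},
                                   "outputs": {}}
    rng = np.random.default_rng(seed)

    n_f, n_n = int(cfg["n_fright"]), int(cfg["n_nofright"])
    species = [f"SpF{i+1}" for i in range(n_f)] + [f"SpN{i+1}" for i in range(n_n)]
    ecotype = {s: (1 if s.startswith("SpF") else 0) for s in species}
    n_sub = int(cfg["n_subfamilies"])
    seeds_prot = [
        SequenceRecord(f"subfam{j+1}_seed", _seed_protein(j, rng))
        for j in range(n_sub)
    ]

    # ladder species tree over the study species
    def _ladder(tips: list[str]) -> str:
        t = f"{tips[0]}:1"
        for i, s in enumerate(tips[1:], 1):
            t = f"({t},{s}:{i}):1"
        return t + ";"
    species_tree_text = _ladder(species)
    (out / "species_tree.nwk").write_text(species_tree_text)

    # --- simulate ---------------------------------------------------------
    truth_by_species: dict[str, sim.PlantedTruth] = {}
    if cfg["stage_simulate"]:
        for si, sp in enumerate(species):
            contigs_all: list[SequenceRecord] = []
            genes = []
            for j in range(n_sub):
                n_copies = int(cfg["genes_per_subfamily"])
                if j == int(cfg["boosted_subfamily"]) and ecotype[sp]:
                    n_copies = int(cfg["boost_copies"])
                contigs, truth = sim.simulate_receptor_genome(
                    seeds_prot[j], n_intact=n_copies, n_truncated=0,
                    n_pseudo=1, divergence=float(cfg["divergence"]),
                    contig_len=int(cfg["contig_len"]),
                    seed=seed * 1000 + si * 10 + j,
                    subfamily=f"subfam{j+1}",
                )
                for c in contigs:
                    c.id = f"{sp}_{seeds_prot[j].id}_{c.id}"
                for g in truth.genes:
                    g.contig = f"{sp}_{seeds_prot[j].id}_{g.contig}"
                contigs_all.extend(contigs)
                genes.extend(truth.genes)
            truth_by_species[sp] = sim.PlantedTruth(genes)
            cio.write_fasta(contigs_all, out / f"{sp}_genome.fasta")
            feats = [
                cio.GffFeature(g.contig, "simulate", "receptor_gene",
                               g.start, g.end, None, g.strand,
                               {"status": g.status, "subfamily": g.subfamily or "."})
                for g in genes
            ]
            cio.write_gff_lite(feats, out / f"{sp}_truth.gff")
        log.info("simulated %d genomes", len(species))

    # --- mine -------------------------------------------------------------
    counts = None
    proteins: list[SequenceRecord] = []
    subfam_of: dict[str, str] = {}
    if cfg["stage_mine"]:
        if not cfg["stage_simulate"]:
            raise DependencyError("mine requires simulate")
        rows = []
        for sp in species:
            contigs = cio.read_fasta(out / f"{sp}_genome.fasta")
            anns = mining.mine_genome(
                contigs, seeds_prot, flank=int(cfg["flank"]),
            )
            tally = {"intact": 0, "truncated": 0, "pseudogene": 0}
            sub_counts = {f"subfam{j+1}": 0 for j in range(n_sub)}
            feats = []
            for k, a in enumerate(anns):
                tally[a.status] += 1
                subfam = a.model.locus.best_query.replace("_seed", "")
                feats.append(
                    cio.GffFeature(a.model.locus.contig, "chemorep", "receptor_gene",
                                   a.model.cds_start, a.model.cds_end,
                                   a.model.score, a.model.locus.strand,
                                   {"status": a.status, "subfamily": subfam})
                )
                if a.status == "intact":
                    sub_counts[subfam] += 1
                    gid = f"{sp}_{subfam}_m{k}"
                    proteins.append(SequenceRecord(gid, a.model.protein))
                    subfam_of[gid] = subfam
            cio.write_gff_lite(
                feats, out / f"{sp}_annotations.gff",
                header={"flank": cfg["flank"], "completeness": 0.9},
            )
            rows.append({"species": sp, **tally, **sub_counts})
        counts = pd.DataFrame(rows).set_index("species")
        cio.write_matrix(counts, out / "status_counts.tsv")
        if proteins:
            cio.write_fasta(proteins, out / "intact_proteins.fasta")
        log.info("mined %d intact proteins", len(proteins))

    # project every inferred protein onto its subfamily seed so pooled sets
    # have equal aligned lengths (reference-anchored projection)
    aligned_proteins: list[SequenceRecord] = []
    if proteins:
        seed_by_sub = {s.id.replace("_seed", ""): s for s in seeds_prot}
        for p in proteins:
            aligned_proteins.extend(
                phylogeny.project_to_reference([p], seed_by_sub[subfam_of[p.id]])
            )

    # --- tree -------------------------------------------------------------
    gene_tree = None
    if cfg["stage_tree"]:
        if not cfg["stage_mine"]:
            raise DependencyError("tree requires mine")
        if len(proteins) >= 3:
            gene_tree = phylogeny.nj_tree(
                phylogeny.poisson_distance_matrix(aligned_proteins),
                allow_saturated=True,
            )
            (out / "gene_tree.nwk").write_text(cio.write_newick(gene_tree))

    # --- reconcile --------------------------------------------------------
    events = None
    if cfg["stage_reconcile"]:
        if not cfg["stage_tree"]:
            raise DependencyError("reconcile requires tree")
        if gene_tree is not None and len(species) >= 2:
            sp_tree = cio.read_newick(out / "species_tree.nwk")
            try:
                res = reconcile.reconcile_dl(
                    cio.read_newick(out / "gene_tree.nwk"), sp_tree,
                    rooting="minimize",
                )
                events = reconcile.event_table(res, sp_tree)
                cio.write_matrix(events.set_index("branch"), out / "branch_events.tsv")
            except reconcile.PolytomyError:
                log.warning("gene tree not binary; reconciliation skipped")

    # --- geneconv ---------------------------------------------------------
    if cfg["stage_geneconv"]:
        boosted = f"subfam{int(cfg['boosted_subfamily'])+1}"
        fam = [p for p in aligned_proteins if subfam_of.get(p.id) == boosted]
        if len(fam) >= 3:
            gc = geneconv.conversion_test(fam, n_perm=200, seed=seed)
            pd.DataFrame(
                [{"pair": "|".join(p), "p": v} for p, v in gc.pair_p.items()]
                + [{"pair": "GLOBAL", "p": gc.global_p}]
            ).to_csv(out / "geneconv.tsv", sep="\t", index=False)

    # --- repstats ---------------------------------------------------------
    association = None
    if cfg["stage_repstats"]:
        if counts is None:
            raise DependencyError("repstats requires mine")
        sub_cols = [f"subfam{j+1}" for j in range(n_sub)]
        mat = repstats.RepertoireMatrix(
            counts[sub_cols], pd.Series(ecotype).reindex(counts.index)
        )
        an = repstats.anosim(mat.counts.values,
                             mat.ecotype.values, n_perm=999, seed=seed)
        association = {"anosim_R": an.R, "anosim_p": an.p_value}
        if counts.shape[0] >= 3 and n_sub >= 2:
            try:
                pca = repstats.pca_repertoire(mat)
                association["pc1_pct"] = float(pca.variance_explained[0])
            except ValueError:
                pass
        sp_tree = cio.read_newick(out / "species_tree.nwk")
        try:
            glm = phyloglm.phylo_logistic_regression(
                sp_tree, {s: ecotype[s] for s in counts.index},
                {s: float(counts.loc[s, sub_cols].sum()) for s in counts.index},
                n_bootstrap=99, seed=seed,
            )
            association.update(phyloglm_p=glm.p_slope, phyloglm_aic=glm.aic)
        except (ValueError, RuntimeError):
            pass
        pd.Series(association).to_csv(out / "association.tsv", sep="\t")

    # --- selection --------------------------------------------------------
    sel_table = None
    if cfg["stage_selection"]:
        sp_tree = cio.read_newick(out / "species_tree.nwk")
        for nd in sp_tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length = min(nd.edge.length, 1.0) * 0.3
        seqs, _ = sim.simulate_codon_alignment(
            sp_tree, [(0.8, 0.1), (0.2, 1.0)], kappa=2.0,
            n_codons=150, seed=seed + 7,
        )
        eng = sel._Engine(sp_tree, seqs)
        m0 = sel.fit_site_model(sp_tree, seqs, "M0", starts=1, seed=seed, engine=eng)
        m1a = sel.fit_site_model(sp_tree, seqs, "M1a", fixed_scale=m0.scale,
                                 starts=1, seed=seed, engine=eng)
        m2a = sel.fit_site_model(sp_tree, seqs, "M2a", fixed_scale=m0.scale,
                                 starts=1, seed=seed, engine=eng)
        lrt = sel.likelihood_ratio_test(m2a.lnL, m1a.lnL, df=2)
        sel_table = pd.DataFrame(
            [
                {"model": f.model, "lnL": f.lnL, "np": f.n_params}
                for f in (m0, m1a, m2a)
            ]
        )
        sel_table.loc[2, "2dlnL"] = lrt.two_delta
        sel_table.loc[2, "p"] = lrt.p_value
        cio.write_matrix(sel_table.set_index("model"), out / "selection.tsv")

    # --- expression -------------------------------------------------------
    if cfg["stage_expression"]:
        from . import expression as expr
        mat, is_de = sim.simulate_expression_counts(
            n_genes=400, n_per_group=3, dispersion=0.1, de_fraction=0.1,
            log2fc=2.0, seed=seed + 11,
        )
        receptor_like = list(mat.counts.index[is_de])
        summary = expr.expression_change_summary(
            mat, {"receptor": receptor_like}
        )
        summary["contrasts"].to_csv(out / "expression_contrasts.tsv",
                                    sep="\t", index=False)

    for f in sorted(out.iterdir()):
        if f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(out, manifest, counts, events, association, sel_table)
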