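#!/usr/bin/env python
"""Generate the synthetic repertoire study with known ground truth.

Four species — two with the fright-reaction ecotype (SpF1, SpF2), two
without (SpN1, SpN2) — each get receptor genes planted in random-background
contigs: two subfamilies, with subfamily 2 boosted to four intact copies in
the fright species (the planted analogue of a fright-associated subfamily
expansion), plus one pseudogene per subfamily.  Also writes the
13-species-shaped repertoire count matrix (17 subfamilies, subfamily 9
boosted) and a before/after expression count matrix with planted fold
changes.  Everything downstream reads only these files.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from chemorep import io as cio
from chemorep.io import SequenceRecord
from chemorep.simulate import (
    simulate_expression_counts,
    simulate_receptor_genome,
    simulate_repertoire_matrix,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/study")
OUT.mkdir(parents=True, exist_ok=True)

AAS = "ACDEFGHIKLMNPQRSTVWY"
rng = np.random.default_rng(SEED)
seeds_prot = [
    SequenceRecord(f"subfam{j + 1}_seed",
                   "M" + "".join(AAS[i] for i in rng.integers(0, 20, 309)))
    for j in range(2)
]
cio.write_fasta(seeds_prot, OUT / "query_panel.fasta")

species = ["SpF1", "SpF2", "SpN1", "SpN2"]
(OUT / "species_tree.nwk").write_text(
    "((SpF1:1,SpF2:1):1,(SpN1:1,SpN2:1):1);\n"
)

planted = []
for si, sp in enumerate(species):
    contigs_all = []
    feats = []
    for j, seed_prot in enumerate(seeds_prot):
        n_intact = 4 if (j == 1 and sp.startswith("SpF")) else 2
        contigs, truth = simulate_receptor_genome(
            seed_prot, n_intact=n_intact, n_truncated=0, n_pseudo=1,
            divergence=0.08, contig_len=4000, seed=SEED * 1000 + si * 10 + j,
        )
        for c in contigs:
            c.id = f"{sp}_subfam{j + 1}_{c.id}"
        for g in truth.genes:
            g.contig = f"{sp}_subfam{j + 1}_{g.contig}"
            planted.append({"species": sp, "subfamily": f"subfam{j + 1}",
                            "contig": g.contig, "status": g.status})
            feats.append(cio.GffFeature(
                g.contig, "simulate", "receptor_gene", g.start, g.end, None,
                g.strand, {"status": g.status, "subfamily": f"subfam{j + 1}"},
            ))
        contigs_all.extend(contigs)
    cio.write_fasta(contigs_all, OUT / f"{sp}_genome.fasta")
    cio.write_gff_lite(feats, OUT / f"{sp}_truth.gff", header={"seed": SEED})

pd.DataFrame(planted).to_csv(OUT / "planted_truth.tsv", sep="\t", index=False)

# 13-species repertoire matrix shaped like the comparative study
mat = simulate_repertoire_matrix(5, 8, 17, base_mean=3.0,
                                 boosted_subfamily=8, boost=6.0,
                                 seed=SEED + 19)
df = mat.counts.copy()
df["ecotype"] = mat.ecotype
cio.write_matrix(df, OUT / "repertoire_matrix.tsv")

# expression counts with planted fold changes (3 vs 3 replicates)
emat, is_de = simulate_expression_counts(400, 3, dispersion=0.1,
                                         de_fraction=0.1, log2fc=2.0,
                                         seed=SEED + 11)
cio.write_matrix(emat.counts, OUT / "expression_counts.tsv")
emat.lengths.to_csv(OUT / "expression_lengths.tsv", sep="\t",
                    header=["length"])
pd.Series(is_de, index=emat.counts.index, name="is_de").to_csv(
    OUT / "expression_truth.tsv", sep="\t")

n_genes = len(planted)
print(f"planted {n_genes} receptor genes across {len(species)} genomes "
      f"({sum(p['status'] == 'intact' for p in planted)} intact, "
      f"{sum(p['status'] == 'pseudogene' for p in planted)} pseudogenes)")
print(f"repertoire matrix: {mat.counts.shape[0]} species x "
      f"{mat.counts.shape[1]} subfamilies; expression: 400 genes, 10% DE")
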