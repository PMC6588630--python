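"""Receptor-gene mining: find gene loci in a genome and classify each as
intact, truncated, or pseudogene.

The stages mirror a classical homology-mining pipeline: (1) a six-frame
translated search of the genome with protein queries (exact 4-mer seeds,
gapped local extension under BLOSUM62, Karlin-Altschul e-values);
(2) merging of redundant hits on the same genomic region into loci, with
sub-200-nt loci discarded; (3) a frame-aware protein-to-DNA alignment over
the flank-extended locus that records in-frame stop codons (nonsense) and
frame switches (frameshifts); (4) classification by disruptions, query
coverage, and contig-edge evidence; (5) verification that the inferred
protein's best reference match belongs to the target family.

Gene models are intronless; users with spliced real-genome gene models can
import external hit tables and annotations instead.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import codon as C
from .io import HitRow, SequenceRecord

# Gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_TO_I = {a: i for i, a in enumerate(_AA_ORDER)}
_SUB = np.zeros((len(_AA_ORDER), len(_AA_ORDER)))
for _a in _AA_ORDER:
    for _b in _AA_ORDER:
        _SUB[_AA_TO_I[_a], _AA_TO_I[_b]] = _BLOSUM[_a][_b]

STOP_SCORE = -10.0      # aligning a query residue over an in-frame stop
FRAMESHIFT_PENALTY = 15.0
GAP_PENALTY = 11.0      # per residue/codon indel in the frame-aware DP


def _protein_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _BLOSUM
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp.get(c, "N") for c in reversed(seq))


def _sanitize_protein(seq: str) -> str:
    return "".join(c if c in _AA_TO_I else "X" for c in seq.upper())


def six_frame_translations(contig: str) -> list[tuple[str, int, str]]:
    """(protein, frame offset, strand) for all six frames."""
    out = []
    fwd = contig.upper()
    rev = _revcomp(fwd)
    for strand, seq in (("+", fwd), ("-", rev)):
        for f in range(3):
            out.append((C.translate_cds(seq[f:]), f, strand))
    return out


def _frame_to_forward(aa_start: int, aa_end: int, frame: int, strand: str,
                      contig_len: int) -> tuple[int, int]:
    """Map an aa interval in a translated frame to forward-strand nt
    coordinates (0-based half-open)."""
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return contig_len - nt_end, contig_len - nt_start


def search_homologs(contigs: Sequence[SequenceRecord],
                    queries: Sequence[SequenceRecord],
                    e_cutoff: float = 1e-10,
                    mode: str = "internal",
                    imported_hits: Sequence[HitRow] | None = None,
                    seed_k: int = 4) -> list[HitRow]:
    """Translated homology search of a genome with a protein query panel.

    'internal' mode runs the built-in seeded search; 'imported' mode
    filters externally produced tabular hits at the same cutoff.
    """
    if mode == "imported":
        if imported_hits is None:
            raise ValueError("imported mode needs imported_hits")
        return [h for h in imported_hits if h.evalue <= e_cutoff]
    if mode != "internal":
        raise ValueError("mode must be 'internal' or 'imported'")
    if not queries:
        raise ValueError("query panel is empty")
    if not contigs:
        return []
    aligner = _protein_aligner()
    total_aa = sum(2 * len(c.residues) for c in contigs)  # six frames
    hits: list[HitRow] = []
    for query in queries:
        q = _sanitize_protein(query.residues)
        m = len(q)
        if m < seed_k:
            continue
        kmers: dict[str, list[int]] = {}
        for i in range(m - seed_k + 1):
            kmers.setdefault(q[i:i + seed_k], []).append(i)
        for contig in contigs:
            L = len(contig.residues)
            for prot, frame, strand in six_frame_translations(contig.residues):
                seeds = []  # (diag, spos, qpos)
                for spos in range(len(prot) - seed_k + 1):
                    for qpos in kmers.get(prot[spos:spos + seed_k], ()):
                        seeds.append((spos - qpos, spos, qpos))
                if not seeds:
                    continue
                seeds.sort()
                clusters: list[list[tuple[int, int, int]]] = []
                for s in seeds:
                    if clusters and abs(s[0] - clusters[-1][-1][0]) <= 20 and \
                            abs(s[1] - clusters[-1][-1][1]) <= 2 * m:
                        clusters[-1].append(s)
                    else:
                        clusters.append([s])
                for cl in clusters:
                    lo = max(0, min(sp - qp for _, sp, qp in cl) - 25)
                    hi = min(len(prot),
                             max(sp + (m - qp) for _, sp, qp in cl) + 25)
                    window = prot[lo:hi]
                    if not window:
                        continue
                    alns = aligner.align(q, window)
                    if len(alns) == 0 or alns.score <= 0:
                        continue
                    aln = alns[0]
                    score = float(alns.score)
                    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
                    evalue = m * total_aa / (2.0 ** bits)
                    if evalue > e_cutoff:
                        continue
                    qb = aln.aligned[0]
                    sb = aln.aligned[1]
                    qstart, qend = int(qb[0][0]), int(qb[-1][1])
                    ws, we = int(sb[0][0]), int(sb[-1][1])
                    ident = 0
                    alen = 0
                    for (q0, q1), (s0, s1) in zip(qb, sb):
                        alen += q1 - q0
                        ident += sum(
                            1 for a, b in zip(q[q0:q1], window[s0:s1]) if a == b
                        )
                    nt_s, nt_e = _frame_to_forward(lo + ws, lo + we, frame,
                                                   strand, L)
                    hits.append(
                        HitRow(
                            query_id=query.id, subject_id=contig.id,
                            pident=100.0 * ident / max(alen, 1),
                            length=alen, mismatch=alen - ident, gapopen=0,
                            qstart=qstart, qend=qend,
                            sstart=nt_s, send=nt_e, strand=strand,
                            evalue=evalue, bitscore=bits,
                        )
                    )
    # Deduplicate identical envelopes from overlapping clusters.
    best: dict[tuple, HitRow] = {}
    for h in hits:
        key = (h.query_id, h.subject_id, h.strand, h.sstart, h.send)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.subject_id, h.sstart, -h.bitscore))


# ---------------------------------------------------------------------------
# Hit merging


@dataclasses.dataclass
class GeneLocus:
    contig: str
    strand: str
    start: int       # merged hit envelope, forward 0-based half-open
    end: int
    hits: list[HitRow]
    best_query: str

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_hits(hits: Sequence[HitRow], max_gap: int = 5000,
               min_len: int = 200) -> list[GeneLocus]:
    """Merge same-contig, same-strand hits that overlap or lie within
    ``max_gap`` into loci; loci shorter than ``min_len`` nt are discarded."""
    groups: dict[tuple[str, str], list[HitRow]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    loci: list[GeneLocus] = []
    for (contig, strand), rows in groups.items():
        rows = sorted(rows, key=lambda h: h.sstart)
        cur: list[HitRow] = []
        for h in rows:
            if cur and h.sstart <= max(r.send for r in cur) + max_gap:
                cur.append(h)
            else:
                if cur:
                    loci.append(_locus_from(cur, contig, strand))
                cur = [h]
        if cur:
            loci.append(_locus_from(cur, contig, strand))
    return sorted(
        (l for l in loci if l.length >= min_len),
        key=lambda l: (l.contig, l.start),
    )


def _locus_from(rows: list[HitRow], contig: str, strand: str) -> GeneLocus:
    best = max(rows, key=lambda h: h.bitscore)
    return GeneLocus(
        contig=contig, strand=strand,
        start=min(r.sstart for r in rows), end=max(r.send for r in rows),
        hits=list(rows), best_query=best.query_id,
    )


# ---------------------------------------------------------------------------
# Frame-aware gene model


@dataclasses.dataclass
class GeneModel:
    locus: GeneLocus
    cds_start: int          # forward-strand coordinates of the aligned CDS
    cds_end: int
    protein: str            # inferred protein (query-aligned residues)
    coverage: float         # aligned fraction of the query
    disruptions: list[tuple[str, int]]   # (kind, CDS nt position)
    contig_edge: bool
    clipped: bool           # flank extension hit a contig boundary
    score: float


def _frame_dp(query: str, dna: str) -> tuple[float, int, int, int, int,
                                             list[tuple[str, int]], str]:
    """Local frame-aware alignment of a protein to DNA.

    Moves per query residue: consume 3 nt (codon match; stops score
    STOP_SCORE and are recorded as nonsense), 2 or 4 nt (frameshift,
    penalized and recorded), or 0 nt (query deletion).  Extra codons in
    the DNA cost GAP_PENALTY each.  Returns (score, qstart, qend,
    dna_start, dna_end, disruptions, inferred protein).
    """
    m, n = len(query), len(dna)
    if n < 3:
        return 0.0, 0, 0, 0, 0, [], ""
    qi = np.array([_AA_TO_I.get(a, _AA_TO_I["X"]) for a in query])
    # aa index of the codon ending at dna position j (1-based end j)
    aa_idx = np.full(n + 1, _AA_TO_I["X"])
    stop_end = np.zeros(n + 1, dtype=bool)
    for j in range(3, n + 1):
        cod = dna[j - 3:j]
        aa = C.translate_codon(cod)
        stop_end[j] = aa == "*"
        aa_idx[j] = _AA_TO_I.get(aa if aa != "*" else "X", _AA_TO_I["X"])
    sub_of_end = _SUB[:, aa_idx]  # residue x (n+1)
    sub_of_end[:, stop_end] = STOP_SCORE

    NEG = -1e9
    S = np.full((m + 1, n + 1), 0.0, dtype=np.float64)
    for i in range(1, m + 1):
        prev = S[i - 1]
        subs = sub_of_end[qi[i - 1]]
        c_diag = np.full(n + 1, NEG)
        c_diag[3:] = prev[:-3] + subs[3:]
        c_fs2 = np.full(n + 1, NEG)
        c_fs2[2:] = prev[:-2] - FRAMESHIFT_PENALTY + subs[2:]
        c_fs4 = np.full(n + 1, NEG)
        c_fs4[4:] = prev[:-4] - FRAMESHIFT_PENALTY + subs[4:]
        c_del = prev - GAP_PENALTY
        row = np.maximum.reduce([c_diag, c_fs2, c_fs4, c_del])
        np.maximum(row, 0.0, out=row)
        # extra-codon (DNA insertion) chain within the row, stride 3
        for r in range(3):
            idx = np.arange(r, n + 1, 3)
            vals = row[idx] + GAP_PENALTY * np.arange(len(idx))
            np.maximum.accumulate(vals, out=vals)
            row[idx] = np.maximum(
                row[idx], vals - GAP_PENALTY * np.arange(len(idx))
            )
        S[i] = row

    best_flat = int(np.argmax(S))
    bi, bj = divmod(best_flat, n + 1)
    score = float(S[bi, bj])
    if score <= 0:
        return 0.0, 0, 0, 0, 0, [], ""

    # Traceback by recomputation.
    i, j = bi, bj
    disruptions: list[tuple[str, int]] = []
    protein: list[str] = []
    qend, dend = i, j
    tol = 1e-6
    while i > 0 and S[i, j] > tol:
        v = S[i, j]
        subs = sub_of_end[qi[i - 1], j] if j >= 2 else NEG
        if j >= 3 and abs(S[i - 1, j - 3] + subs - v) < tol:
            if stop_end[j]:
                disruptions.append(("nonsense", 3 * (i - 1)))
                protein.append("*")
            else:
                protein.append(_AA_ORDER[aa_idx[j]])
            i, j = i - 1, j - 3
        elif j >= 2 and abs(S[i - 1, j - 2] - FRAMESHIFT_PENALTY + subs - v) < tol:
            disruptions.append(("frameshift", 3 * (i - 1)))
            protein.append(_AA_ORDER[aa_idx[j]])
            i, j = i - 1, j - 2
        elif j >= 4 and abs(S[i - 1, j - 4] - FRAMESHIFT_PENALTY + subs - v) < tol:
            disruptions.append(("frameshift", 3 * (i - 1)))
            protein.append(_AA_ORDER[aa_idx[j]])
            i, j = i - 1, j - 4
        elif abs(S[i - 1, j] - GAP_PENALTY - v) < tol:
            i = i - 1
        elif j >= 3 and abs(S[i, j - 3] - GAP_PENALTY - v) < tol:
            j = j - 3
        else:
            break
    qstart, dstart = i, j
    disruptions.reverse()
    # Merge frameshift events closer than 3 codons into one.
    merged: list[tuple[str, int]] = []
    for kind, pos in disruptions:
        if (merged and kind == "frameshift" and merged[-1][0] == "frameshift"
                and pos - merged[-1][1] < 9):
            continue
        merged.append((kind, pos))
    return score, qstart, qend, dstart, dend, merged, "".join(reversed(protein))


def build_gene_model(locus: GeneLocus, contigs: dict[str, str],
                     query: SequenceRecord, flank: int = 10000,
                     score_floor: float = 25.0) -> GeneModel | None:
    """Extend the locus by ``flank`` on both sides (clipped at contig ends)
    and align the query protein to the oriented DNA frame-aware; returns
    None when no alignment clears ``score_floor``."""
    contig_seq = contigs[locus.contig]
    L = len(contig_seq)
    ext_start = max(0, locus.start - flank)
    ext_end = min(L, locus.end + flank)
    clipped = ext_start == 0 or ext_end == L
    dna = contig_seq[ext_start:ext_end].upper()
    if locus.strand == "-":
        dna = _revcomp(dna)
    q = _sanitize_protein(query.residues)
    score, qs, qe, ds, de, disr, prot = _frame_dp(q, dna)
    if score < score_floor:
        return None
    # Map oriented-DNA coordinates back to forward contig coordinates.
    if locus.strand == "+":
        cds_start, cds_end = ext_start + ds, ext_start + de
    else:
        cds_start, cds_end = ext_end - de, ext_end - ds
    coverage = (qe - qs) / len(q)
    # the aligned CDS abutting a contig boundary (within two codons) is
    # evidence the gene runs off the assembly edge
    edge = (cds_start <= 6 and ext_start == 0) or (cds_end >= L - 6 and ext_end == L)
    return GeneModel(
        locus=locus, cds_start=cds_start, cds_end=cds_end, protein=prot,
        coverage=coverage, disruptions=disr, contig_edge=edge,
        clipped=clipped, score=score,
    )


# ---------------------------------------------------------------------------
# Classification and family verification


def classify_gene(model: GeneModel, completeness: float = 0.9) -> str:
    """'pseudogene' on any ORF disruption; else 'intact' when the query is
    covered to the completeness threshold with no contig-edge evidence;
    else 'truncated'."""
    if model.disruptions:
        return "pseudogene"
    if model.coverage >= completeness and not model.contig_edge:
        return "intact"
    return "truncated"


def verify_family_membership(protein: str,
                             references: Sequence[SequenceRecord],
                             family_of: dict[str, str],
                             target_family: str = "target") -> bool:
    """Accept iff the best-scoring reference under gapped local alignment
    belongs to the target family; score ties are rejected (conservative)."""
    if not references:
        raise ValueError("reference panel is empty")
    missing = [r.id for r in references if r.id not in family_of]
    if missing:
        raise ValueError(f"references without family labels: {missing}")
    fams = set(family_of.values())
    if target_family not in fams or fams == {target_family}:
        raise ValueError("panel must contain the target family and decoys")
    aligner = _protein_aligner()
    p = _sanitize_protein(protein.replace("*", "X"))
    scores = [(float(aligner.score(p, _sanitize_protein(r.residues))), r.id)
              for r in references]
    best_score = max(s for s, _ in scores)
    best_fams = {family_of[rid] for s, rid in scores if s >= best_score - 1e-9}
    return best_fams == {target_family}


# ---------------------------------------------------------------------------
# End-to-end mining


@dataclasses.dataclass
class ReceptorAnnotation:
    model: GeneModel
    status: str
    family_accepted: bool
    subfamily: str | None = None


def mine_genome(contigs: Sequence[SequenceRecord],
                queries: Sequence[SequenceRecord],
                e_cutoff: float = 1e-10, max_gap: int = 5000,
                min_len: int = 200, flank: int = 10000,
                completeness: float = 0.9,
                verify_panel: Sequence[SequenceRecord] | None = None,
                family_of: dict[str, str] | None = None
                ) -> list[ReceptorAnnotation]:
    """Search, merge, model, classify, and (optionally) verify."""
    hits = search_homologs(contigs, queries, e_cutoff=e_cutoff)
    loci = merge_hits(hits, max_gap=max_gap, min_len=min_len)
    contig_map = {c.id: c.residues for c in contigs}
    query_map = {q.id: q for q in queries}
    out: list[ReceptorAnnotation] = []
    for locus in loci:
        model = build_gene_model(locus, contig_map, query_map[locus.best_query],
                                 flank=flank)
        if model is None:
            continue
        status = classify_gene(model, completeness=completeness)
        accepted = True
        if verify_panel is not None and family_of is not None:
            accepted = verify_family_membership(
                model.protein, verify_panel, family_of
            )
        out.append(ReceptorAnnotation(model, status, accepted))
    return out
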