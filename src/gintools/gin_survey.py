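"""Permissive homology survey for three-integrase (gin) operons.

Protein comparison is explicit local alignment (BLOSUM62, affine gaps
11/1) with Karlin-Altschul expectation statistics, so the survey needs no
external aligner binary. A genome is considered to carry a gin operon when
three consecutive same-strand CDSs match the GinA, GinB and GinC
references at E <= 0.1 (GinD is never required: it is small and often
unannotated).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import AnnotatedGenome, extract_cds_protein

__all__ = [
    "GinReferenceSet",
    "AlignmentResult",
    "OperonHit",
    "MotifReport",
    "ScoringParams",
    "local_align",
    "find_gin_operons",
    "pairwise_identity_matrix",
    "check_catalytic_motif",
    "read_reference_fasta",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def _blosum62_x_neutral():
    # X (unknown residue) is scored 0 against everything, as the survey
    # treats non-standard residues as uninformative rather than penalized.
    mat = substitution_matrices.load("BLOSUM62").copy()
    xi = mat.alphabet.index("X")
    mat[xi, :] = 0.0
    mat[:, xi] = 0.0
    return mat

_MATRIX = _blosum62_x_neutral()


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring: substitution matrix name plus affine-gap costs.

    ``gap_open`` is the cost of opening a gap (a gap of length k costs
    ``gap_open + k * gap_extend``, the BLAST convention).
    """

    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_k: float = DEFAULT_K


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    identity: float
    aligned_length: int
    evalue: float


@dataclass(frozen=True)
class GinReferenceSet:
    """Reference Gin proteins; A/B/C are required, D is optional."""

    ginA: str
    ginB: str
    ginC: str
    ginD: str | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        for name in ("ginA", "ginB", "ginC"):
            if not getattr(self, name):
                raise ValueError(f"reference set requires a non-empty {name}")

    def required(self) -> dict[str, str]:
        return {"ginA": self.ginA, "ginB": self.ginB, "ginC": self.ginC}


@dataclass(frozen=True)
class OperonHit:
    cds_triplet: tuple[str, ...]
    per_gene: dict[str, AlignmentResult]
    strand: str
    span: tuple[int, int]
    max_intergenic_gap: int
    gind_present: bool = False

    def __post_init__(self) -> None:
        if len(self.cds_triplet) not in (3, 4):
            raise ValueError("operon hit must list 3 CDSs (4 with ginD)")


@dataclass(frozen=True)
class MotifReport:
    residues_found: dict[int, tuple[str, int]]
    complete: bool


def _sanitize(seq: str, role: str) -> str:
    if not seq:
        raise ValueError(f"empty {role} sequence")
    seq = seq.upper()
    if set(seq) - _PROTEIN_ALPHABET:
        bad = sorted(set(seq) - _PROTEIN_ALPHABET)
        warnings.warn(
            f"non-standard residues {bad} in {role}; substituted by X (score 0)",
            stacklevel=3,
        )
        seq = "".join(c if c in _PROTEIN_ALPHABET else "X" for c in seq)
    return seq


def _make_aligner(params: ScoringParams, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        aligner.end_gap_score = 0
    return aligner


def evalue_from_score(score: float, m: int, n: int,
                      params: ScoringParams = ScoringParams()) -> float:
    """Karlin-Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


def local_align(query: str, target: str,
                params: ScoringParams = ScoringParams(),
                search_space: int | None = None) -> AlignmentResult:
    """Optimal local alignment of two proteins under affine gaps.

    ``search_space`` is the effective database residue count used for the
    expectation value; it defaults to the target length (single-pair
    comparison).
    """
    query = _sanitize(query, "query")
    target = _sanitize(target, "target")
    aligner = _make_aligner(params, "local")
    alignments = aligner.align(query, target)
    aln = alignments[0]
    score = int(aln.score)
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    n = search_space if search_space is not None else len(target)
    return AlignmentResult(
        score=score,
        identity=identity,
        aligned_length=columns,
        evalue=evalue_from_score(score, len(query), n, params),
    )


def pairwise_identity_matrix(proteins: Sequence[str],
                             params: ScoringParams = ScoringParams()) -> np.ndarray:
    """Symmetric identity matrix from end-gap-free global alignments.

    Identity is the number of identical aligned residues divided by the
    longer sequence length, which is invariant under co-optimal end-gap
    placements.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two sequences")
    proteins = [_sanitize(p, f"protein {i}") for i, p in enumerate(proteins)]
    aligner = _make_aligner(params, "global")
    n = len(proteins)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(proteins[i], proteins[j])[0]
            ident = aln.counts().identities
            frac = ident / max(len(proteins[i]), len(proteins[j]))
            mat[i, j] = mat[j, i] = frac
    return mat


def find_gin_operons(genome: AnnotatedGenome, refs: GinReferenceSet,
                     evalue_max: float = 0.1, max_gap: int = 1000,
                     enforce_order: bool = True,
                     params: ScoringParams = ScoringParams()) -> list[OperonHit]:
    """Scan a genome for runs of three consecutive CDSs matching GinA/B/C.

    Consecutive means adjacent in annotation order on the same strand with
    intergenic gaps <= ``max_gap``. On the minus strand the genomic order
    of matches is reversed (C, B, A). When a fourth consecutive CDS
    matches GinD it is appended to the hit but never required. Overlapping
    triplets are all reported.
    """
    if not isinstance(refs, GinReferenceSet):
        raise TypeError("refs must be a GinReferenceSet")
    feats = genome.features
    if len(feats) < 3:
        return []

    proteome = {f.feature_id: extract_cds_protein(genome, f.feature_id)
                for f in feats}
    total_residues = sum(len(p) for p in proteome.values())

    gene_refs = dict(refs.required())
    if refs.ginD:
        gene_refs["ginD"] = refs.ginD

    # per-CDS alignment vs each reference, E-value against the whole proteome
    scores: dict[tuple[str, str], AlignmentResult] = {}
    for gene, ref in gene_refs.items():
        for fid, prot in proteome.items():
            if not prot:
                continue
            scores[(gene, fid)] = local_align(
                ref, prot, params=params, search_space=total_residues)

    def matches(gene: str, fid: str) -> AlignmentResult | None:
        res = scores.get((gene, fid))
        if res is not None and res.evalue <= evalue_max:
            return res
        return None

    hits: list[OperonHit] = []
    for i in range(len(feats) - 2):
        trio = feats[i:i + 3]
        strand = trio[0].strand
        if any(f.strand != strand for f in trio):
            continue
        gaps = [trio[k + 1].start - trio[k].end for k in range(2)]
        if max(gaps) > max_gap:
            continue
        # translation order: genomic order on +, reversed on -
        ordered = trio if strand == "+" else trio[::-1]
        assignments: list[dict[str, AlignmentResult]] = []
        if enforce_order:
            per_gene = {}
            for gene, feat in zip(("ginA", "ginB", "ginC"), ordered):
                res = matches(gene, feat.feature_id)
                if res is None:
                    break
                per_gene[gene] = res
            if len(per_gene) == 3:
                assignments.append(per_gene)
        else:
            for perm in itertools.permutations(("ginA", "ginB", "ginC")):
                per_gene = {}
                for gene, feat in zip(perm, ordered):
                    res = matches(gene, feat.feature_id)
                    if res is None:
                        break
                    per_gene[gene] = res
                if len(per_gene) == 3:
                    assignments.append(per_gene)
                    break
        if not assignments:
            continue
        per_gene = assignments[0]

        cds_ids = tuple(f.feature_id for f in trio)
        span = (trio[0].start, trio[-1].end)
        max_intergenic = max(gaps)
        gind_present = False
        if refs.ginD:
            # the ginD CDS extends the run downstream in translation order
            next_idx = i + 3 if strand == "+" else i - 1
            if 0 <= next_idx < len(feats):
                nxt = feats[next_idx]
                adjacent_gap = (nxt.start - trio[-1].end if strand == "+"
                                else trio[0].start - nxt.end)
                if (nxt.strand == strand and 0 <= adjacent_gap <= max_gap
                        and matches("ginD", nxt.feature_id) is not None):
                    gind_present = True
                    per_gene = dict(per_gene)
                    per_gene["ginD"] = scores[("ginD", nxt.feature_id)]
                    if strand == "+":
                        cds_ids = cds_ids + (nxt.feature_id,)
                        span = (span[0], max(span[1], nxt.end))
                    else:
                        cds_ids = (nxt.feature_id,) + cds_ids
                        span = (min(span[0], nxt.start), span[1])
                    max_intergenic = max(max_intergenic, adjacent_gap)
        hits.append(OperonHit(
            cds_triplet=cds_ids, per_gene=per_gene, strand=strand,
            span=span, max_intergenic_gap=max_intergenic,
            gind_present=gind_present,
        ))
    return hits


DEFAULT_MOTIF = tuple(zip("RHRHY", [(0, 10000)] * 5))


def check_catalytic_motif(protein: str,
                          spec: Sequence[tuple[str, tuple[int, int]]] = DEFAULT_MOTIF,
                          ) -> MotifReport:
    """Locate the tyrosine-recombinase catalytic residues (R-H-R-H-Y).

    ``spec`` lists (residue, (min_spacing, max_spacing)) entries; spacing
    is measured from the previously assigned residue (ignored for the
    first). The lexicographically smallest feasible assignment is
    returned; when no full assignment exists, a maximal prefix assigned
    greedily is reported with ``complete=False``.
    """
    if not spec:
        raise ValueError("empty motif spec")
    for entry in spec:
        if (len(entry) != 2 or len(entry[0]) != 1
                or entry[1][0] < 0 or entry[1][1] < entry[1][0]):
            raise ValueError(f"malformed motif spec entry: {entry!r}")
    protein = protein.upper()

    def assign(idx: int, min_pos: int, max_pos: int) -> list[int] | None:
        if idx == len(spec):
            return []
        residue, (lo, hi) = spec[idx]
        for pos in range(min_pos, min(max_pos, len(protein))):
            if protein[pos] != residue:
                continue
            rest = assign(idx + 1, pos + 1 + lo, pos + 1 + hi + 1)
            if rest is not None:
                return [pos] + rest
        return None

    full = assign(0, 0, len(protein))
    if full is not None:
        found = {i: (spec[i][0], pos) for i, pos in enumerate(full)}
        return MotifReport(residues_found=found, complete=True)

    # Partial report: maximize the number of motif positions assigned in
    # order (spacing applies between consecutively assigned residues), so
    # a protein missing one catalytic residue still reports the others.
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(idx: int, pos: int) -> tuple[int, tuple[tuple[int, int], ...]]:
        if idx == len(spec):
            return 0, ()
        skip = best(idx + 1, pos)
        residue, (lo, hi) = spec[idx]
        start = pos + 1 + lo if pos >= 0 else 0
        end = min(len(protein), pos + 1 + hi + 1) if pos >= 0 else len(protein)
        chosen = skip
        for p in range(start, end):
            if protein[p] != residue:
                continue
            cnt, rest = best(idx + 1, p)
            if cnt + 1 > chosen[0]:
                chosen = (cnt + 1, ((idx, p),) + rest)
        return chosen

    _, picks = best(0, -1)
    found = {i: (spec[i][0], p) for i, p in picks}
    return MotifReport(residues_found=found, complete=False)


def read_reference_fasta(path) -> GinReferenceSet:
    """Load a GinA/B/C(/D) reference set from FASTA (ids ginA..ginD)."""
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    missing = {"ginA", "ginB", "ginC"} - records.keys()
    if missing:
        raise ValueError(f"reference FASTA missing {sorted(missing)}")
    return GinReferenceSet(
        ginA=records["ginA"], ginB=records["ginB"], ginC=records["ginC"],
        ginD=records.get("ginD"), source_label=str(path),
    )
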