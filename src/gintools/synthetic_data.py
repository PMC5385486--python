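"""Synthetic host genomes and planted islands with known ground truth.

Every pipeline stage is testable offline: a host replicon gets a target
gene carrying an attB core; an element with the tripartite structure
(gin operon, cargo, short AT-rich 3' end) is built from mutated copies of
the reference Gin proteins and planted by the integration model, so the
flanking attL/attR repeats arise exactly as the mechanism dictates.
Everything is deterministic per (params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import AnnotatedGenome, CdsFeature
from .gin_survey import GinReferenceSet
from .recombination_model import (
    PARENTAL_INTEGRATION,
    AttCore,
    RecombinationConfig,
    integrate,
)

__all__ = [
    "SynthParams",
    "SyntheticTruth",
    "GintElement",
    "make_reference_set",
    "generate_host",
    "generate_gint",
    "plant_gint",
    "generate_planted_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = unambiguous_dna_by_id[1]
_SENSE: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _SENSE.setdefault(aa, []).append(codon)
_STOPS = tuple(_TABLE.stop_codons)


@dataclass(frozen=True)
class SynthParams:
    host_length: int = 20000
    host_gc: float = 0.5
    n_background_cds: int = 6
    target_gene: Literal["abc_transporter_like", "ssb_like"] = "ssb_like"
    att_placement: Literal["gene_3prime", "gene_5prime"] = "gene_3prime"
    gin_identity: float = 0.6
    cargo_size: int = 3000
    three_prime_length: int = 300
    three_prime_at: float = 0.8
    att_length: int = 17
    att_mismatches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("host_gc", "gin_identity", "three_prime_at"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 10 <= self.att_length <= 17:
            raise ValueError("att_length must lie in [10, 17]")
        if not 200 <= self.three_prime_length <= 400:
            raise ValueError("three_prime_length must lie in [200, 400]")


@dataclass
class SyntheticTruth:
    attB: AttCore
    attB_span: tuple[int, int]
    target_gene_id: str
    insertion_class: str
    element_span: tuple[int, int] | None = None
    operon_span: tuple[int, int] | None = None
    cargo_span: tuple[int, int] | None = None
    three_prime_span: tuple[int, int] | None = None
    attL: AttCore | None = None
    attR: AttCore | None = None
    attI: AttCore | None = None


@dataclass
class GintElement:
    """An un-integrated element: sequence plus element-relative layout."""

    sequence: str
    attI: AttCore
    operon_span: tuple[int, int]
    cargo_span: tuple[int, int]
    three_prime_span: tuple[int, int]
    cds: list[CdsFeature]
    proteins: dict[str, str]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=n, p=p)]).decode()


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons - 2) sense codons drawn at the host composition + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _plant_motif(protein: list[str], rng: np.random.Generator,
                 residues: str) -> None:
    # catalytic residues spaced through the C-terminal half
    L = len(protein)
    span = np.sort(rng.choice(np.arange(L // 2, L - 1), size=len(residues),
                              replace=False))
    for pos, res in zip(span, residues):
        protein[pos] = res


def make_reference_set(seed: int = 0) -> GinReferenceSet:
    """Deterministic reference Gin proteins for tests and simulations.

    GinA and GinB carry a full R-H-R-H-Y catalytic motif; GinC lacks the
    first arginine; GinD is short (no motif).
    """
    rng = np.random.default_rng([seed, 101])
    lengths = {"ginA": 389, "ginB": 377, "ginC": 344, "ginD": 96}
    # background excludes the motif residues so the planted motif is unique
    background = "".join(c for c in _AA20 if c not in "RHY")
    out = {}
    for name, L in lengths.items():
        aa = ["M"] + [background[i]
                      for i in rng.integers(0, len(background), size=L - 1)]
        if name in ("ginA", "ginB"):
            _plant_motif(aa, rng, "RHRHY")
        elif name == "ginC":
            _plant_motif(aa, rng, "HRHY")
        out[name] = "".join(aa)
    return GinReferenceSet(**out, source_label=f"synthetic-refs-seed{seed}")


def _mutate_protein(protein: str, identity: float,
                    rng: np.random.Generator) -> str:
    n_sub = int(round((1 - identity) * len(protein)))
    if identity < 0.25:
        warnings.warn("gin_identity < 0.25 may fall below detectability",
                      stacklevel=3)
    positions = rng.choice(np.arange(1, len(protein)), size=min(n_sub, len(protein) - 1),
                           replace=False)
    aa = list(protein)
    for pos in positions:
        alternatives = _AA20.replace(aa[pos], "")
        aa[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(aa)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    for aa in protein[1:]:
        options = _SENSE[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(codons)


def generate_host(params: SynthParams) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Random annotated host carrying an attB core at the target gene.

    By default the attB overlaps the final bases of the target gene (the
    ssb-like pattern), so integration preserves the gene product.
    """
    rng = np.random.default_rng([params.seed, 1])
    n_genes = params.n_background_cds + 1
    lengths = [int(x) * 3 for x in rng.integers(100, 300, size=n_genes)]
    target_idx = n_genes // 2
    lengths[target_idx] = 600
    min_gap = params.att_length + 30
    needed = sum(lengths) + n_genes * min_gap + 200
    if needed > params.host_length:
        raise ValueError(
            f"host_length {params.host_length} too small for "
            f"{n_genes} CDSs (needs >= {needed})")

    seq = np.frombuffer(_random_seq(rng, params.host_length,
                                    params.host_gc).encode(), np.uint8).copy()
    slack = params.host_length - sum(lengths) - n_genes * min_gap - 100
    gaps = rng.multinomial(slack, np.ones(n_genes) / n_genes) + min_gap
    features = []
    pos = 50
    target_span = None
    for i, (L, gap) in enumerate(zip(lengths, gaps)):
        pos += int(gap)
        cds_seq = _random_cds(rng, L // 3, params.host_gc)
        seq[pos:pos + L] = np.frombuffer(cds_seq.encode(), np.uint8)
        fid = "target_gene" if i == target_idx else f"host_cds_{i}"
        features.append(CdsFeature(feature_id=fid, start=pos, end=pos + L,
                                   strand="+", locus_tag=fid))
        if i == target_idx:
            target_span = (pos, pos + L)
        pos += L

    if params.att_placement == "gene_3prime":
        attb_start = target_span[1] - 5
        insertion_class = "gene_3prime_overlap"
    else:
        attb_start = target_span[0] + 30
        insertion_class = "gene_5prime"
    attb_seq = bytes(seq[attb_start:attb_start + params.att_length]).decode()
    attB = AttCore(attb_seq, role="attB")
    genome = AnnotatedGenome(
        id=f"synthetic_host_{params.seed}",
        sequence=bytes(seq).decode(), features=features)
    truth = SyntheticTruth(
        attB=attB, attB_span=(attb_start, attb_start + params.att_length),
        target_gene_id="target_gene", insertion_class=insertion_class)
    return genome, truth


def generate_gint(params: SynthParams, refs: GinReferenceSet,
                  attB: AttCore) -> GintElement:
    """Build an element with the tripartite structure and a derived attI.

    Gin CDSs are mutated copies of the references at ``gin_identity``;
    the attI differs from the given attB by ``att_mismatches``
    substitutions placed inside the 6-nt overhang.
    """
    rng = np.random.default_rng([params.seed, 2])
    leader = _random_seq(rng, 40, params.host_gc)
    parts = [leader]
    cds: list[CdsFeature] = []
    proteins: dict[str, str] = {}
    pos = len(leader)
    operon_start = pos
    genes = {"ginA": refs.ginA, "ginB": refs.ginB, "ginC": refs.ginC}
    if refs.ginD:
        genes["ginD"] = refs.ginD
    for name, ref in genes.items():
        mutated = _mutate_protein(ref, params.gin_identity, rng)
        nt = _back_translate(mutated, rng)
        parts.append(nt)
        cds.append(CdsFeature(feature_id=f"planted_{name}", start=pos,
                              end=pos + len(nt), strand="+", locus_tag=name))
        proteins[name] = mutated
        pos += len(nt)
        gap = _random_seq(rng, 20, params.host_gc)
        parts.append(gap)
        pos += len(gap)
    operon_end = cds[-1].end
    pos = operon_end + 20  # trailing gap already appended
    cargo = _random_seq(rng, params.cargo_size, params.host_gc)
    parts.append(cargo)
    cargo_span = (pos, pos + len(cargo))
    pos += len(cargo)
    tail = _random_seq(rng, params.three_prime_length,
                       1 - params.three_prime_at)
    parts.append(tail)
    three_prime_span = (pos, pos + len(tail))
    pos += len(tail)

    o = attB.overhang_offset
    mism = rng.choice(6, size=params.att_mismatches, replace=False)
    atti = list(attB.seq)
    for k in mism:
        alternatives = "ACGT".replace(atti[o + k], "")
        atti[o + k] = alternatives[rng.integers(0, 3)]
    attI = AttCore("".join(atti), o, "attI")
    return GintElement(sequence="".join(parts), attI=attI,
                       operon_span=(operon_start, operon_end),
                       cargo_span=cargo_span, three_prime_span=three_prime_span,
                       cds=cds, proteins=proteins)


def plant_gint(host: AnnotatedGenome, element: GintElement,
               truth: SyntheticTruth,
               cfg: RecombinationConfig | None = None,
               ) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Integrate the element at the host attB; returns genome + full truth.

    The attL/attR flanks come from the integration model with parental
    resolutions. Bases just inside the element termini are adjusted so the
    planted repeat pair is maximal (it cannot be extended without extra
    mismatches), which keeps the truth boundaries identifiable.
    """
    cfg = cfg or RecombinationConfig(seed=0)
    b, b_end = truth.attB_span
    L = len(truth.attB)
    if host.sequence[b:b_end] != truth.attB.seq:
        raise ValueError("host does not carry the stated attB at its coordinate")
    integ = integrate(element.attI, truth.attB, cfg,
                      resolution_choices=PARENTAL_INTEGRATION)
    attL, attR = integ.attL, integ.attR

    body = np.frombuffer(element.sequence.encode(), np.uint8).copy()
    hseq = host.sequence
    # enforce maximality of the repeat pair at all four boundaries
    for k in range(3):
        left_host = b - 1 - k
        if left_host >= 0 and hseq[left_host] == chr(body[-1 - k]):
            body[-1 - k] = ord("ACGT"["ACGT".index(hseq[left_host]) - 1])
        right_host = b_end + k
        if right_host < len(hseq) and hseq[right_host] == chr(body[k]):
            body[k] = ord("ACGT"["ACGT".index(hseq[right_host]) - 1])
    body_seq = bytes(body).decode()

    new_seq = hseq[:b] + attL.seq + body_seq + attR.seq + hseq[b_end:]
    ins_len = L + len(body_seq)  # net shift for features right of attB
    elem_offset = b + L

    features = []
    for feat in host.features:
        if feat.end <= b + (5 if truth.insertion_class == "gene_3prime_overlap"
                            else 0) and feat.start < b:
            features.append(feat)
        elif feat.end <= b:
            features.append(feat)
        elif feat.start >= b_end:
            features.append(feat.shifted(ins_len))
        elif feat.feature_id == truth.target_gene_id:
            if truth.insertion_class == "gene_3prime_overlap":
                # gene end lies in the attB left arm, preserved in attL
                features.append(feat)
            else:
                # disrupted gene: annotate the full post-insertion extent
                features.append(replace(feat, end=feat.end + ins_len,
                                        locus_tag="target_gene_disrupted"))
        else:
            features.append(feat)
    for feat in element.cds:
        features.append(feat.shifted(elem_offset))

    genome = AnnotatedGenome(id=host.id + "_gint", sequence=new_seq,
                             features=features)
    shift = elem_offset
    full = SyntheticTruth(
        attB=truth.attB, attB_span=truth.attB_span,
        target_gene_id=truth.target_gene_id,
        insertion_class=truth.insertion_class,
        element_span=(b, b + L + len(body_seq) + L),
        operon_span=(element.operon_span[0] + shift,
                     element.operon_span[1] + shift),
        cargo_span=(element.cargo_span[0] + shift,
                    element.cargo_span[1] + shift),
        three_prime_span=(element.three_prime_span[0] + shift,
                          element.three_prime_span[1] + shift),
        attL=attL, attR=attR, attI=element.attI)
    # consistency assertions: the emitted genome matches the truth ledger
    assert genome.sequence[b:b + L] == attL.seq
    ar0 = full.element_span[1] - L
    assert genome.sequence[ar0:ar0 + L] == attR.seq
    return genome, full


def generate_planted_genome(params: SynthParams,
                            refs: GinReferenceSet | None = None,
                            cfg: RecombinationConfig | None = None,
                            ) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """Host + element + plant in one call (the common test entry point)."""
    refs = refs or make_reference_set()
    host, truth = generate_host(params)
    element = generate_gint(params, refs, truth.attB)
    return plant_gint(host, element, truth, cfg)
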