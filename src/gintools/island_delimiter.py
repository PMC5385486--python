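"""Delimit a candidate island around a detected gin operon.

The element boundaries are the attL/attR pair: imperfect direct repeats of
10-17 nt, attL just upstream of the operon and attR at a distance set by
the cargo-size bounds. Candidate pairs are ranked by
(matches, length, AT-richness of the implied 3' end, compactness); the
terminal 0.2-0.4 kb before attR is scored as the AT-rich 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .genome_io import AnnotatedGenome, at_fraction
from .gin_survey import OperonHit

__all__ = [
    "AttRepeatPair",
    "GIntAnnotation",
    "PositionProfile",
    "DelimiterConfig",
    "InsertionPointResult",
    "find_direct_repeats",
    "delimit_gint",
    "classify_insertion_site",
    "locate_insertion_point",
    "att_logo",
]


@dataclass(frozen=True)
class AttRepeatPair:
    """A located pair of same-orientation imperfect direct repeats."""

    left: tuple[int, int]
    right: tuple[int, int]
    repeat_length: int
    mismatches: int
    mismatch_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.left[1] - self.left[0] != self.repeat_length:
            raise ValueError("left interval length != repeat_length")
        if self.right[1] - self.right[0] != self.repeat_length:
            raise ValueError("right interval length != repeat_length")
        if self.left[1] > self.right[0]:
            raise ValueError("left repeat must precede the right repeat")
        if len(self.mismatch_positions) != self.mismatches:
            raise ValueError("mismatch count disagrees with positions")

    @property
    def matches(self) -> int:
        return self.repeat_length - self.mismatches


@dataclass(frozen=True)
class PositionProfile:
    """Per-position base frequencies and information content of aligned sites."""

    frequencies: np.ndarray  # (L, 4) in A, C, G, T order
    bits: np.ndarray         # (L,)
    n_sequences: int


@dataclass
class DelimiterConfig:
    len_min: int = 10
    len_max: int = 17
    max_mismatch: int = 3
    attl_window: int = 1500
    cargo_min: int = 2500
    cargo_max: int = 76000
    three_prime_min: int = 200
    three_prime_max: int = 400
    # a repeat pair only delimits the element when the expected number of
    # equally good chance pairs in the searched windows is below this
    max_expected_chance: float = 0.5


@dataclass(frozen=True)
class GIntAnnotation:
    operon_span: tuple[int, int]
    cargo_span: tuple[int, int] | None
    three_prime_span: tuple[int, int] | None
    att: AttRepeatPair | None
    element_span: tuple[int, int] | None
    cargo_size: int | None
    three_prime_at_fraction: float | None
    insertion_class: Literal["gene_5prime", "gene_3prime_overlap",
                             "intergenic", "unknown"] = "unknown"
    confidence: Literal["full", "operon_only"] = "operon_only"

    def to_gff3(self, genome_id: str) -> str:
        """GFF3 rows (1-based inclusive) for the island and its parts."""
        rows = []

        def row(ftype, span, attrs):
            rows.append("\t".join([
                genome_id, "gintools", ftype,
                str(span[0] + 1), str(span[1]), ".", "+", ".", attrs]))

        if self.confidence == "full":
            row("genomic_island", self.element_span,
                f"ID=gint;confidence=full;insertion_class={self.insertion_class}")
            row("direct_repeat", self.att.left,
                f"ID=attL;Parent=gint;mismatches={self.att.mismatches}")
            row("gin_operon", self.operon_span, "ID=gin_operon;Parent=gint")
            row("cargo", self.cargo_span, "ID=cargo;Parent=gint")
            row("three_prime_end", self.three_prime_span,
                f"ID=three_prime_end;Parent=gint;"
                f"at_fraction={self.three_prime_at_fraction:.3f}")
            row("direct_repeat", self.att.right,
                f"ID=attR;Parent=gint;mismatches={self.att.mismatches}")
        else:
            row("gin_operon", self.operon_span,
                "ID=gin_operon;confidence=operon_only")
        return "\n".join(rows) + "\n"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_pairs(arr: np.ndarray, left: tuple[int, int], right: tuple[int, int],
                len_range: tuple[int, int], max_mismatch: int,
                best_only: bool = False,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized enumeration of candidate (i, j, L, mismatches) tuples.

    Works per shift d = j - i: equality of arr over the left window against
    its d-shifted copy, cumulative-summed so every repeat length is a
    difference of two prefix sums. With ``best_only`` only candidates tied
    with the best (matches, length) ranking key are returned, which keeps
    large-window scans cheap.
    """
    l0, l1 = left
    r0, r1 = right
    lmin, lmax = len_range
    W = l1 - l0
    d_lo = r0 - (l1 - lmin)
    d_hi = r1 - lmin - l0
    out_i, out_j, out_L, out_mm = [], [], [], []
    best_key = -1
    chunk = 2048
    base = np.arange(l0, l1, dtype=np.int32)
    for dstart in range(d_lo, d_hi + 1, chunk):
        shifts = np.arange(dstart, min(dstart + chunk, d_hi + 1),
                           dtype=np.int32)
        if len(shifts) == 0:
            continue
        idx = base[None, :] + shifts[:, None]
        valid = idx < len(arr)
        np.minimum(idx, len(arr) - 1, out=idx)
        eq = (arr[base][None, :] == arr[idx]) & valid
        cs = np.zeros((len(shifts), W + 1), dtype=np.int32)
        np.cumsum(eq, axis=1, out=cs[:, 1:])
        for L in range(lmin, lmax + 1):
            if L > W:
                continue
            n_start = W - L + 1
            matches = cs[:, L:L + n_start] - cs[:, :n_start]
            i_pos = base[:n_start]
            # j = i + d bounds become per-row bounds on i
            lo_i = np.maximum(l0, r0 - shifts)[:, None]
            hi_i = (r1 - L - shifts)[:, None]
            ok = ((matches >= L - max_mismatch)
                  & (i_pos[None, :] >= lo_i) & (i_pos[None, :] <= hi_i))
            if best_only:
                masked = np.where(ok, matches, -1)
                kmax = int(masked.max(initial=-1)) * 100 + L
                if kmax < best_key or masked.max(initial=-1) < 0:
                    continue
                best_key = max(best_key, kmax)
                ok &= masked * 100 + L == best_key
            si, sj = np.nonzero(ok)
            if len(si):
                out_i.append(i_pos[sj].astype(np.int64))
                out_j.append((i_pos[sj] + shifts[si]).astype(np.int64))
                out_L.append(np.full(len(si), L, dtype=np.int64))
                out_mm.append((L - matches[si, sj]).astype(np.int64))
    if not out_i:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty, empty
    i = np.concatenate(out_i)
    j = np.concatenate(out_j)
    L = np.concatenate(out_L)
    mm = np.concatenate(out_mm)
    if best_only:
        key = (L - mm) * 100 + L
        keep = key == key.max()
        i, j, L, mm = i[keep], j[keep], L[keep], mm[keep]
    return i, j, L, mm


def _materialize(seq: str, i: int, j: int, L: int) -> AttRepeatPair:
    a, b = seq[i:i + L], seq[j:j + L]
    mism = tuple(k for k in range(L) if a[k] != b[k])
    return AttRepeatPair(left=(i, i + L), right=(j, j + L), repeat_length=L,
                         mismatches=len(mism), mismatch_positions=mism)


def find_direct_repeats(seq: str, left_window: tuple[int, int],
                        right_window: tuple[int, int],
                        len_range: tuple[int, int] = (10, 17),
                        max_mismatch: int = 3,
                        top: int | None = None) -> list[AttRepeatPair]:
    """All imperfect direct-repeat pairs between two disjoint windows.

    Every substring pair (one per window) with length in ``len_range`` and
    Hamming mismatches <= ``max_mismatch`` is a candidate; the list is
    ranked by (matches desc, length desc, anchor proximity, position). Set
    ``top`` to truncate the ranked list.
    """
    l0, l1 = left_window
    r0, r1 = right_window
    if not (0 <= l0 < l1 <= len(seq)) or not (0 <= r0 < r1 <= len(seq)):
        raise ValueError("windows must lie inside the sequence")
    if l1 > r0:
        raise ValueError("left and right windows must be disjoint (left first)")
    if min(l1 - l0, r1 - r0) < len_range[0]:
        return []
    arr = _encode(seq)
    i, j, L, mm = _scan_pairs(arr, left_window, right_window,
                              len_range, max_mismatch)
    if len(i) == 0:
        return []
    matches = L - mm
    # anchor proximity: attL expected near the left window's right edge,
    # attR near the right window's left edge
    proximity = (l1 - (i + L)) + (j - r0)
    order = np.lexsort((i, j, proximity, -L, -matches))
    if top is not None:
        order = order[:top]
    return [_materialize(seq, int(i[k]), int(j[k]), int(L[k])) for k in order]


def expected_chance_pairs(left: tuple[int, int], right: tuple[int, int],
                          repeat_length: int, mismatches: int,
                          match_prob: float = 0.25) -> float:
    """Expected count of equally good repeat pairs arising by chance.

    Binomial tail over all start-position pairs in the two windows; used
    to reject delimitations that random sequence would produce anyway.
    """
    import math
    L, q = repeat_length, match_prob
    n_pairs = max(0, left[1] - left[0] - L + 1) * max(0, right[1] - right[0] - L + 1)
    p = sum(math.comb(L, k) * q ** (L - k) * (1 - q) ** k
            for k in range(mismatches + 1))
    return n_pairs * p


def _match_prob(seq: str) -> float:
    # chance that two independent draws from the sequence composition agree
    counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.25
    f = counts / total
    return float((f ** 2).sum())


def _three_prime_pick(seq: str, attr_start: int, cfg: DelimiterConfig,
                      floor: int) -> tuple[int, float]:
    """Choose the 3'-end length in [min, max] maximizing AT fraction."""
    best_len, best_at = cfg.three_prime_min, -1.0
    for tp in range(cfg.three_prime_min, cfg.three_prime_max + 1, 20):
        start = attr_start - tp
        if start < floor:
            break
        frac = at_fraction(seq[start:attr_start])
        if frac > best_at:
            best_len, best_at = tp, frac
    return best_len, best_at


def delimit_gint(genome: AnnotatedGenome, operon: OperonHit,
                 config: DelimiterConfig | None = None) -> GIntAnnotation:
    """Annotate the tripartite island around an operon hit.

    Searches for attL in a window upstream of the operon and attR at
    cargo-bound distances downstream; degrades to ``operon_only`` when no
    acceptable repeat pair exists.
    """
    cfg = config or DelimiterConfig()
    seq = genome.sequence
    op_start, op_end = operon.span

    left = (max(0, op_start - cfg.attl_window), op_start)
    right = (op_end + cfg.cargo_min + cfg.three_prime_min,
             min(len(seq), op_end + cfg.cargo_max + cfg.three_prime_max + cfg.len_max))
    operon_only = GIntAnnotation(
        operon_span=operon.span, cargo_span=None, three_prime_span=None,
        att=None, element_span=None, cargo_size=None,
        three_prime_at_fraction=None, confidence="operon_only")
    if (left[1] - left[0] < cfg.len_min or right[1] - right[0] < cfg.len_min
            or left[1] > right[0]):
        return operon_only

    arr = _encode(seq)
    # best-only scan: every returned candidate ties the top (matches, length)
    i, j, L, mm = _scan_pairs(arr, left, right,
                              (cfg.len_min, cfg.len_max), cfg.max_mismatch,
                              best_only=True)
    if len(i) == 0:
        return operon_only
    chance = expected_chance_pairs(left, right, int(L[0]), int(mm[0]),
                                   _match_prob(seq))
    if chance > cfg.max_expected_chance:
        return operon_only
    at_scores = np.array([
        at_fraction(seq[max(0, jj - 300):jj]) if jj > 0 else 0.0
        for jj in j])
    span = (j + L) - i
    order = np.lexsort((i, span, -at_scores))
    k = order[0]
    att = _materialize(seq, int(i[k]), int(j[k]), int(L[k]))

    attl_end = att.left[1]
    attr_start = att.right[0]
    tp_len, tp_at = _three_prime_pick(seq, attr_start, cfg, op_end)
    # keep the cargo within bounds when the 3'-end length allows it
    cargo_size = attr_start - tp_len - op_end
    if cargo_size < cfg.cargo_min:
        slack = cfg.cargo_min - cargo_size
        if tp_len - slack >= cfg.three_prime_min:
            tp_len -= slack
            tp_at = at_fraction(seq[attr_start - tp_len:attr_start])
            cargo_size = cfg.cargo_min
    three_prime_span = (attr_start - tp_len, attr_start)
    cargo_span = (op_end, three_prime_span[0])
    element_span = (att.left[0], att.right[1])
    annotation = GIntAnnotation(
        operon_span=operon.span, cargo_span=cargo_span,
        three_prime_span=three_prime_span, att=att,
        element_span=element_span, cargo_size=cargo_span[1] - cargo_span[0],
        three_prime_at_fraction=float(tp_at), confidence="full")
    return GIntAnnotation(
        **{**annotation.__dict__,
           "insertion_class": classify_insertion_site(annotation, genome)})


def classify_insertion_site(annotation: GIntAnnotation,
                            genome: AnnotatedGenome) -> str:
    """Classify where attL sits relative to annotated genes."""
    if annotation.att is None:
        return "unknown"
    al, ar = annotation.att.left
    for cds in genome.features:
        if cds.end <= al or cds.start >= ar:
            continue
        if cds.strand == "+":
            third = cds.start + (cds.end - cds.start) // 3
            if al < cds.end <= ar:
                return "gene_3prime_overlap"
            if cds.start <= al and ar <= third:
                return "gene_5prime"
        else:
            third = cds.end - (cds.end - cds.start) // 3
            if al <= cds.start < ar:
                return "gene_3prime_overlap"
            if third <= al and ar <= cds.end:
                return "gene_5prime"
        return "unknown"
    return "intergenic"


@dataclass(frozen=True)
class InsertionPointResult:
    status: Literal["located", "no_insertion", "no_syntenic_anchor"]
    ref_interval: tuple[int, int] | None = None
    query_offset: int | None = None


def locate_insertion_point(query: AnnotatedGenome, reference: AnnotatedGenome,
                           operon: OperonHit, seed_len: int = 40,
                           anchor_offset: int = 2500) -> InsertionPointResult:
    """Find the empty-site coordinate in a reference lacking the element.

    Anchors a seed upstream of the operon and one near the query 3' end in
    the reference, then walks inward from both anchors until the sequences
    diverge. The returned interval brackets the insertion point (exact up
    to the arm sequence shared by attL/attR and the restored attB).
    """
    q, r = query.sequence, reference.sequence
    ql0 = max(0, operon.span[0] - anchor_offset)
    seed = q[ql0:ql0 + seed_len]
    rl = r.find(seed)
    if rl < 0:
        return InsertionPointResult(status="no_syntenic_anchor")
    # right anchor from the query tail
    qr0 = len(q) - seed_len
    rr = r.rfind(q[qr0:qr0 + seed_len])
    if rr < 0:
        return InsertionPointResult(status="no_syntenic_anchor")
    # walk right from the left anchor
    qi, ri = ql0 + seed_len, rl + seed_len
    while qi < len(q) and ri < len(r) and q[qi] == r[ri]:
        qi += 1
        ri += 1
    if qi == len(q) and ri == len(r):
        return InsertionPointResult(status="no_insertion")
    # walk left from the right anchor
    qj, rj = qr0 - 1, rr - 1
    while qj >= 0 and rj >= 0 and q[qj] == r[rj]:
        qj -= 1
        rj -= 1
    lo, hi = min(rj + 1, ri), max(rj + 1, ri)
    return InsertionPointResult(status="located", ref_interval=(lo, hi),
                                query_offset=qi)


_BASES = "ACGT"


def att_logo(att_seqs: Sequence[str], pad: str = "right",
             small_sample_correction: bool = False) -> PositionProfile:
    """Per-position base frequencies and information content (bits).

    Bits are ``2 - H`` with ``H`` the Shannon entropy (log2) of the base
    frequencies at each position; ``pad`` right- or left-pads shorter
    sequences with ``N`` (excluded from the counts).
    """
    if len(att_seqs) < 2:
        raise ValueError("need at least two sequences for a profile")
    L = max(len(s) for s in att_seqs)
    padded = []
    for s in att_seqs:
        s = s.upper()
        fill = "N" * (L - len(s))
        padded.append(s + fill if pad == "right" else fill + s)
    counts = np.zeros((L, 4))
    for s in padded:
        for pos, c in enumerate(s):
            if c in _BASES:
                counts[pos, _BASES.index(c)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.25)
        logf = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1)), 0.0)
    entropy = -(freqs * logf).sum(axis=1)
    bits = 2.0 - entropy
    if small_sample_correction:
        n = totals.ravel()
        bits = np.maximum(0.0, bits - np.where(n > 0, 3 / (2 * np.log(2) * n), 0))
    return PositionProfile(frequencies=freqs, bits=bits,
                           n_sequences=len(att_seqs))
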