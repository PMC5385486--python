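"""Site-specific integration/excision via 6-nt staggered cuts.

The model: recombination between two registered core sites exchanges the
flanking arms around a fixed-length overhang (default 6 nt). Positions
where the two overhangs differ form a heteroduplex that the cell resolves
toward one template or the other — "element" (the attI-derived strand) or
"host" (the attB-derived strand). Whole-overhang resolution (one template
for all mismatched positions) yields exactly two attI variant classes,
parental and attB-like; per-position resolution can produce intermediates.

Conventions for excision, matching integration with parental choices
(attL overhang from the element, attR overhang from the host):
"element" copies the overhang from attL, "host" from attR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AttCore",
    "RecombinationConfig",
    "IntegrationResult",
    "ExcisionResult",
    "RegistrationError",
    "integrate",
    "excise",
    "sample_excision_products",
    "att_identity",
    "rank_by_identity",
    "assemble_minimal_element",
    "circular_junction_seq",
    "PARENTAL_INTEGRATION",
    "PARENTAL_EXCISION",
]

OVERHANG_LENGTH = 6

Role = Literal["attI", "attB", "attL", "attR"]
Template = Literal["element", "host"]

# resolution choices that make excise(integrate(attI, attB)) the identity
PARENTAL_INTEGRATION: tuple[Template, Template] = ("element", "host")
PARENTAL_EXCISION: tuple[Template, Template] = ("element", "host")


class RegistrationError(ValueError):
    """The two att cores cannot be registered (length/offset mismatch)."""


@dataclass(frozen=True)
class AttCore:
    """A core attachment site with its staggered-cut overhang.

    ``overhang_offset`` locates the exchanged region within the core; the
    default centres a 6-nt overhang: ``floor((L - 6) / 2)``.
    """

    seq: str
    overhang_offset: int | None = None
    role: Role = "attB"

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if set(seq) - set("ACGT"):
            raise ValueError(f"att core contains non-ACGT characters: {seq!r}")
        if len(seq) < OVERHANG_LENGTH:
            raise ValueError(
                f"att core shorter than the {OVERHANG_LENGTH}-nt overhang")
        off = self.overhang_offset
        if off is None:
            off = (len(seq) - OVERHANG_LENGTH) // 2
            object.__setattr__(self, "overhang_offset", off)
        if not 0 <= off <= len(seq) - OVERHANG_LENGTH:
            raise ValueError(f"overhang offset {off} outside core of length {len(seq)}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def left_arm(self) -> str:
        return self.seq[: self.overhang_offset]

    @property
    def overhang(self) -> str:
        o = self.overhang_offset
        return self.seq[o: o + OVERHANG_LENGTH]

    @property
    def right_arm(self) -> str:
        return self.seq[self.overhang_offset + OVERHANG_LENGTH:]


@dataclass
class RecombinationConfig:
    overhang_length: int = OVERHANG_LENGTH
    resolution_mode: Literal["whole_overhang", "per_position"] = "whole_overhang"
    p_host: float = 0.5
    seed: int | None = None
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_host <= 1.0:
            raise ValueError("p_host must lie in [0, 1]")
        if self.overhang_length != OVERHANG_LENGTH:
            raise ValueError(
                f"only the {OVERHANG_LENGTH}-nt overhang mechanism is modelled")

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)
        return self._rng


@dataclass(frozen=True)
class IntegrationResult:
    attL: AttCore
    attR: AttCore
    heteroduplex_positions: tuple[int, ...]
    resolution_choices: tuple[Template, Template]


@dataclass(frozen=True)
class ExcisionResult:
    attI_restored: AttCore
    attB_restored: AttCore
    resolution_choices: tuple[Template, Template]
    variant_class: Literal["parental", "attB_like_overhang", "other", "unclassified"]


def _register(a: AttCore, b: AttCore) -> None:
    if len(a) != len(b):
        raise RegistrationError(
            f"att cores differ in length ({len(a)} vs {len(b)}); "
            "register them by end-gap-free alignment first")
    if a.overhang_offset != b.overhang_offset:
        raise RegistrationError("att cores have different overhang offsets")


def register_cores(a: str, b: str, overhang_offset: int | None = None,
                   roles: tuple[Role, Role] = ("attI", "attB")) -> tuple[AttCore, AttCore]:
    """Build a registered pair of equal-length cores from raw sequences.

    Unequal-length pairs are aligned end-gap-free and rejected when the
    optimal alignment needs indels inside the overhang.
    """
    if len(a) == len(b):
        return (AttCore(a, overhang_offset, roles[0]),
                AttCore(b, overhang_offset, roles[1]))
    from Bio.Align import PairwiseAligner
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aligner.end_gap_score = 0
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim to the gap-free registered window
    keep = [i for i in range(len(sa)) if sa[i] != "-" and sb[i] != "-"]
    if not keep:
        raise RegistrationError("sites do not overlap under alignment")
    lo, hi = keep[0], keep[-1] + 1
    if "-" in sa[lo:hi] or "-" in sb[lo:hi]:
        raise RegistrationError("indels inside the registered core are not supported")
    return (AttCore(sa[lo:hi], overhang_offset, roles[0]),
            AttCore(sb[lo:hi], overhang_offset, roles[1]))


def _heteroduplex(x: AttCore, y: AttCore) -> tuple[int, ...]:
    return tuple(i for i, (p, q) in enumerate(zip(x.overhang, y.overhang)) if p != q)


def _resolve_overhang(element_ov: str, host_ov: str, positions: Sequence[int],
                      cfg: RecombinationConfig,
                      choice: Template | Sequence[Template] | None) -> tuple[str, Template]:
    """Resolve one heteroduplex; returns (overhang, dominant template)."""
    if not positions:
        return element_ov, "element"
    if choice is None:
        if cfg.resolution_mode == "whole_overhang":
            choice = "host" if cfg.rng.random() < cfg.p_host else "element"
        else:
            choice = ["host" if cfg.rng.random() < cfg.p_host else "element"
                      for _ in positions]
    if isinstance(choice, str):
        resolved = host_ov if choice == "host" else element_ov
        return resolved, choice
    if len(choice) != len(positions):
        raise ValueError("per-position choices must match heteroduplex size")
    ov = list(element_ov)
    n_host = 0
    for pos, c in zip(positions, choice):
        if c == "host":
            ov[pos] = host_ov[pos]
            n_host += 1
    dominant: Template = "host" if n_host == len(positions) else "element"
    return "".join(ov), dominant


def integrate(attI: AttCore, attB: AttCore,
              cfg: RecombinationConfig | None = None,
              resolution_choices: tuple | None = None) -> IntegrationResult:
    """Integrate: staggered cuts at attI and attB produce hybrid attL/attR.

    ``attL = attB_left_arm + overhang + attI_right_arm`` and
    ``attR = attI_left_arm + overhang' + attB_right_arm``; each site's
    heteroduplex is resolved toward the element (attI) or host (attB)
    template. Explicit ``resolution_choices`` (one per site) override the
    stochastic choice; ``PARENTAL_INTEGRATION`` gives the invertible pair.
    """
    cfg = cfg or RecombinationConfig()
    _register(attI, attB)
    positions = _heteroduplex(attI, attB)
    cL = cR = None
    if resolution_choices is not None:
        cL, cR = resolution_choices
    ovL, chL = _resolve_overhang(attI.overhang, attB.overhang, positions, cfg, cL)
    ovR, chR = _resolve_overhang(attI.overhang, attB.overhang, positions, cfg, cR)
    o = attI.overhang_offset
    attL = AttCore(attB.left_arm + ovL + attI.right_arm, o, "attL")
    attR = AttCore(attI.left_arm + ovR + attB.right_arm, o, "attR")
    return IntegrationResult(attL=attL, attR=attR,
                             heteroduplex_positions=positions,
                             resolution_choices=(chL, chR))


def excise(attL: AttCore, attR: AttCore,
           cfg: RecombinationConfig | None = None,
           resolution_choices: tuple | None = None,
           parental_attI: AttCore | None = None) -> ExcisionResult:
    """Excise: staggered cuts at attL/attR restore attI (circle) and attB.

    ``attI_restored = attR_left_arm + overhang + attL_right_arm`` and
    ``attB_restored = attL_left_arm + overhang' + attR_right_arm``.
    Template "element" copies the overhang from attL (which carries the
    element-derived overhang after a parental integration), "host" from
    attR. ``variant_class`` compares the restored attI to
    ``parental_attI`` when supplied.
    """
    cfg = cfg or RecombinationConfig()
    _register(attL, attR)
    positions = _heteroduplex(attL, attR)
    cI = cB = None
    if resolution_choices is not None:
        cI, cB = resolution_choices
    ovI, chI = _resolve_overhang(attL.overhang, attR.overhang, positions, cfg, cI)
    ovB, chB = _resolve_overhang(attL.overhang, attR.overhang, positions, cfg, cB)
    o = attL.overhang_offset
    attI_restored = AttCore(attR.left_arm + ovI + attL.right_arm, o, "attI")
    attB_restored = AttCore(attL.left_arm + ovB + attR.right_arm, o, "attB")

    if parental_attI is None:
        variant = "unclassified" if positions else "parental"
    elif attI_restored.seq == parental_attI.seq:
        variant = "parental"
    elif ovI == attR.overhang:
        variant = "attB_like_overhang"
    else:
        variant = "other"
    return ExcisionResult(attI_restored=attI_restored, attB_restored=attB_restored,
                          resolution_choices=(chI, chB), variant_class=variant)


def sample_excision_products(attL: AttCore, attR: AttCore, n: int,
                             cfg: RecombinationConfig,
                             parental_attI: AttCore | None = None,
                             ) -> dict[str, int]:
    """Draw ``n`` independent excisions and tally attI variant classes.

    With whole-overhang resolution the parental fraction concentrates at
    ``1 - p_host``. When ``parental_attI`` is omitted the attI restored by
    fully element-templated resolution is used as the parental reference.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if parental_attI is None:
        parental_attI = excise(attL, attR, cfg,
                               resolution_choices=PARENTAL_EXCISION).attI_restored
    counts: dict[str, int] = {"parental": 0, "attB_like_overhang": 0, "other": 0}
    for _ in range(n):
        res = excise(attL, attR, cfg, parental_attI=parental_attI)
        counts[res.variant_class] += 1
    return counts


def att_identity(a: AttCore, b: AttCore) -> float:
    """Fraction of matching positions between two registered cores."""
    _register(a, b)
    return sum(x == y for x, y in zip(a.seq, b.seq)) / len(a)


def rank_by_identity(candidates: Sequence[AttCore], attB: AttCore) -> list[AttCore]:
    """Order candidate attI cores by decreasing identity to a given attB."""
    return sorted(candidates, key=lambda c: att_identity(c, attB), reverse=True)


def assemble_minimal_element(genome_seq: str,
                             three_prime_coords: tuple[int, int],
                             five_prime_coords: tuple[int, int],
                             cargo_stub: str = "") -> tuple[str, dict[str, int]]:
    """Assemble a minimal circular element from two genome segments.

    Coordinates follow the file convention (1-based inclusive). The circle
    is the element 3' terminus joined to the element 5' start, with an
    optional cargo stub closing the circle. Returns the circular sequence
    and a report of each segment's inclusive length.
    """
    segments = []
    for name, (start, end) in (("three_prime", three_prime_coords),
                               ("five_prime", five_prime_coords)):
        if not (1 <= start <= end <= len(genome_seq)):
            raise ValueError(
                f"{name} interval {start}-{end} outside sequence of length "
                f"{len(genome_seq)}")
        segments.append(genome_seq[start - 1: end])
    report = {
        "three_prime_length": three_prime_coords[1] - three_prime_coords[0] + 1,
        "five_prime_length": five_prime_coords[1] - five_prime_coords[0] + 1,
        "cargo_stub_length": len(cargo_stub),
    }
    circle = segments[0] + segments[1] + cargo_stub
    report["circle_length"] = len(circle)
    return circle, report


def circular_junction_seq(element_body: str, attI: AttCore, flank: int = 50) -> str:
    """Sequence across the excised circle's attI junction.

    ``element_body`` is the element interior between the att repeats (in
    genome orientation); the circle is ``attI + body``. The junction reads
    the last ``flank`` nt of the body, the resolved attI, and the first
    ``flank`` nt of the body.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if flank == 0:
        return attI.seq
    return element_body[-flank:] + attI.seq + element_body[:flank]
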