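"""Design of paired-gRNA barcode cassettes and combinatorial libraries.

A barcode cassette is a fixed-flank DNA insert carrying two designed 20-nt
gRNA target sites (the two halves of the barcode) separated by a short
linker, fused in frame between two fluorescent reporter coding sequences::

    five_flank  site_a (N20)  linker  site_b (N20)  three_flank
    CGTCCG      NNNNNNNNN...  GCCACCATGGTCGAC  ...  CGGTAG

The two protospacer-adjacent motifs (PAMs) required by the Cas9 nickase are
supplied by the fixed flanks in PAM-out orientation: the plus-strand NGG at
the start of the 3' flank serves ``site_b`` and the minus-strand NGG
(complement of the CCN at the end of the 5' flank) serves ``site_a``.  A
library of ``n_top x n_bottom`` cassettes is obtained combinatorially from
two synthesized oligo pools that anneal over a complementary region in the
linker.

Candidate target sites are filtered so that the insert never interrupts the
reporter fusion: no stop codon may appear in any in-frame codon overlapping
the candidate (including junction codons shared with the fixed flanks), and
no restriction site used for cloning may be created.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from ._dna import DNA_ALPHABET, STOP_CODONS, is_dna, revcomp, stop_positions

DEFAULT_FIVE_FLANK = "CGTCCG"
DEFAULT_LINKER = "GCCACCATGGTCGAC"
DEFAULT_THREE_FLANK = "CGGTAG"
# Restriction sites used to clone the insert into the backbone (MluI, BamHI).
# SalI (GTCGAC) is deliberately NOT forbidden: the default linker contains it.
DEFAULT_FORBIDDEN_MOTIFS = frozenset({"ACGCGT", "GGATCC"})

PROTOSPACER_LEN = 20

#: canonical -1 programmed-ribosomal-frameshift slippery heptamer
#: X1 X1 X1 X2 X2 X2 N with X2 in {A, T}
DEFAULT_SLIPPERY_PATTERN = r"(.)\1\1([AT])\2\2."


class DesignError(ValueError):
    """Raised when a design precondition is violated."""


@dataclass(frozen=True)
class CassetteSpec:
    """Geometry and constraint parameters of the barcode construct.

    ``frame_phase`` is the codon phase of the first base of ``five_flank``
    within the reporter fusion reading frame (0 means the flank starts a
    codon).  ``offset_bp`` is the distance between the two nick sites and
    must equal the linker length (15 and 9 are the supported geometries).
    """

    five_flank: str = DEFAULT_FIVE_FLANK
    linker: str = DEFAULT_LINKER
    three_flank: str = DEFAULT_THREE_FLANK
    offset_bp: int = 15
    frame_phase: int = 0
    version: str = "v1"
    forbidden_motifs: frozenset[str] = DEFAULT_FORBIDDEN_MOTIFS

    def __post_init__(self) -> None:
        for name in ("five_flank", "linker", "three_flank"):
            if not is_dna(getattr(self, name)):
                raise DesignError(f"{name} must be non-empty uppercase A/C/G/T")
        if len(self.linker) != self.offset_bp:
            raise DesignError(
                f"linker length {len(self.linker)} != offset_bp {self.offset_bp}"
            )
        if self.frame_phase not in (0, 1, 2):
            raise DesignError("frame_phase must be 0, 1 or 2")
        if self.version not in ("v1", "v2"):
            raise DesignError("version must be 'v1' or 'v2'")
        if not self.pam_out_realizable():
            raise DesignError(
                "PAM-out geometry unsatisfiable: three_flank must start with "
                "NGG and five_flank must end with CCN"
            )

    def pam_out_realizable(self) -> bool:
        """Plus-strand NGG at the start of the 3' flank and minus-strand NGG
        (CCN on the plus strand) at the end of the 5' flank."""
        return (
            len(self.three_flank) >= 3
            and self.three_flank[1:3] == "GG"
            and len(self.five_flank) >= 3
            and self.five_flank[-3:-1] == "CC"
        )

    @property
    def motif_length(self) -> int:
        return (
            len(self.five_flank)
            + 2 * PROTOSPACER_LEN
            + len(self.linker)
            + len(self.three_flank)
        )

    def site_offset(self, pool: str) -> int:
        """Cassette-coordinate offset of the N20 occupied by ``pool``."""
        if pool == "top":
            return len(self.five_flank)
        if pool == "bottom":
            return len(self.five_flank) + PROTOSPACER_LEN + len(self.linker)
        raise DesignError(f"unknown pool {pool!r}")


@dataclass(frozen=True)
class GuideSite:
    """One designed 20-nt target site (plus-strand sequence as it appears in
    the cassette) belonging to the top or bottom oligo pool."""

    site_id: str
    protospacer: str
    pool: str
    on_target_score: float | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN or not is_dna(self.protospacer):
            raise DesignError(
                f"protospacer must be {PROTOSPACER_LEN} nt of A/C/G/T"
            )
        if self.pool not in ("top", "bottom"):
            raise DesignError("pool must be 'top' or 'bottom'")


@dataclass(frozen=True)
class BarcodeCassette:
    """An assembled cassette; ``barcode_key`` is site_a + site_b (40 nt)."""

    site_a: GuideSite
    site_b: GuideSite
    full_sequence: str
    barcode_key: str


@dataclass
class DesignReport:
    """Outcome of candidate filtering (one pool, or a combined library)."""

    accepted: list[GuideSite] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    library_complexity: int | None = None


def heuristic_on_target_score(protospacer: str) -> float:
    """Simple built-in targetability heuristic on a 0-100 scale.

    Full marks for GC fraction in [0.3, 0.8] and no homopolymer run of 5 or
    more; each violation costs 50.  This is a documented fallback, not a
    re-implementation of published on-target scoring models — externally
    computed scores can be supplied instead.
    """
    score = 100.0
    gc = (protospacer.count("G") + protospacer.count("C")) / len(protospacer)
    if not 0.3 <= gc <= 0.8:
        score -= 50.0
    if re.search(r"(.)\1{4,}", protospacer):
        score -= 50.0
    return score


def _junction_context(spec: CassetteSpec, pool: str) -> tuple[str, str, int]:
    """Fixed sequence immediately left/right of a pool's N20 and the
    cassette-coordinate offset where the left context starts."""
    if pool == "top":
        return spec.five_flank, spec.linker, 0
    left = spec.linker
    return left, spec.three_flank, spec.site_offset("bottom") - len(left)


def _stop_codon_hit(
    candidate: str, spec: CassetteSpec, pool: str, strict_all_frames: bool
) -> bool:
    """True if placing ``candidate`` creates a stop codon in any in-frame
    codon overlapping it (junction codons included)."""
    left, right, ctx_start = _junction_context(spec, pool)
    context = left + candidate + right
    cand_lo = len(left)
    cand_hi = cand_lo + len(candidate)
    if strict_all_frames:
        offsets = range(3)
    else:
        # codons begin at absolute positions i with (frame_phase + i) % 3 == 0
        offsets = [(-(spec.frame_phase + ctx_start)) % 3]
    for off in offsets:
        for i in range(off, len(context) - 2, 3):
            if i + 3 > cand_lo and i < cand_hi and context[i : i + 3] in STOP_CODONS:
                return True
    return False


def _forbidden_motif_hit(candidate: str, spec: CassetteSpec, pool: str) -> bool:
    left, right, _ = _junction_context(spec, pool)
    for motif in spec.forbidden_motifs:
        pad = len(motif) - 1
        window = left[-pad:] + candidate + right[:pad] if pad else candidate
        if motif in window:
            return True
    return False


def filter_guide_candidates(
    candidates: Sequence[str],
    spec: CassetteSpec,
    pool: str,
    min_score: float | None = None,
    scores: Mapping[str, float] | None = None,
    strict_all_frames: bool = False,
    id_prefix: str | None = None,
) -> DesignReport:
    """Filter candidate 20-mers for use as barcode target sites.

    A candidate is accepted iff it is exactly 20 nt of A/C/G/T, creates no
    stop codon in an in-frame codon overlapping it (frame set by
    ``spec.frame_phase``; ``strict_all_frames`` checks all three forward
    frames), contains no forbidden motif including motifs spanning the
    junctions with the fixed flanks/linker, and — when scoring is enabled —
    scores at least ``min_score``.  Scores come from ``scores`` when given,
    otherwise from the built-in heuristic.
    """
    if not candidates:
        raise DesignError("candidate list is empty")
    if pool not in ("top", "bottom"):
        raise DesignError("pool must be 'top' or 'bottom'")
    prefix = id_prefix if id_prefix is not None else pool
    report = DesignReport()
    for idx, cand in enumerate(candidates):
        cand_u = cand.upper()
        if len(cand_u) != PROTOSPACER_LEN:
            report.rejected.append((cand, "bad_length"))
            continue
        if not set(cand_u) <= DNA_ALPHABET:
            report.rejected.append((cand, "non_ACGT"))
            continue
        if _stop_codon_hit(cand_u, spec, pool, strict_all_frames):
            report.rejected.append((cand, "stop_codon"))
            continue
        if _forbidden_motif_hit(cand_u, spec, pool):
            report.rejected.append((cand, "forbidden_motif"))
            continue
        score: float | None
        if scores is not None:
            if cand not in scores and cand_u not in scores:
                raise DesignError(f"min_score given but no score for {cand!r}")
            score = scores.get(cand, scores.get(cand_u))
        else:
            score = heuristic_on_target_score(cand_u) if min_score is not None else None
        if min_score is not None and score is not None and score < min_score:
            report.rejected.append((cand, "low_score"))
            continue
        report.accepted.append(
            GuideSite(f"{prefix}_{idx:05d}", cand_u, pool, score)
        )
    report.library_complexity = len(report.accepted)
    return report


def assemble_cassette(
    site_a: GuideSite, site_b: GuideSite, spec: CassetteSpec | None = None
) -> BarcodeCassette:
    """Assemble a cassette from a top-pool and a bottom-pool site.

    Validates the PAM-out geometry: a plus-strand NGG immediately 3' of
    ``site_b`` (start of the 3' flank) and a minus-strand NGG immediately
    adjacent to ``site_a`` (CCN at the end of the 5' flank).
    """
    spec = spec or CassetteSpec()
    if site_a.pool != "top" or site_b.pool != "bottom":
        raise DesignError(
            f"pool mismatch: expected top/bottom, got {site_a.pool}/{site_b.pool}"
        )
    full = (
        spec.five_flank
        + site_a.protospacer
        + spec.linker
        + site_b.protospacer
        + spec.three_flank
    )
    return BarcodeCassette(
        site_a=site_a,
        site_b=site_b,
        full_sequence=full,
        barcode_key=site_a.protospacer + site_b.protospacer,
    )


@dataclass
class FrameReport:
    """Stop codons in the design frame and the -1 frame, plus slippery sites."""

    frame0_stops: list[int]
    minus1_stops: list[int]
    slippery_sites: list[int]

    @property
    def passes(self) -> bool:
        return not (self.frame0_stops or self.minus1_stops or self.slippery_sites)


def check_frames_v2(
    region: str,
    spec: CassetteSpec,
    slippery_pattern: str = DEFAULT_SLIPPERY_PATTERN,
) -> FrameReport:
    """Frame-safety report for the v2 polycistronic reporter.

    v2 relies on a -1 frameshift switching the selection marker on, so the
    coding region must contain no stop codon in either the design frame or
    the -1 shifted frame, and no -1 ribosomal-frameshift slippery heptamer.
    The region passes iff all three lists are empty.
    """
    if spec.version != "v2":
        raise DesignError("check_frames_v2 requires a v2 spec")
    region = region.upper()
    frame0 = (-spec.frame_phase) % 3
    minus1 = (-spec.frame_phase - 1) % 3
    if len(region) < 7:
        warnings.warn("region shorter than 7 nt: slippery-site scan skipped")
        slippery: list[int] = []
    else:
        pat = re.compile(slippery_pattern)
        slippery = [i for i in range(len(region) - 6) if pat.match(region, i)]
    return FrameReport(
        frame0_stops=stop_positions(region, frame0),
        minus1_stops=stop_positions(region, minus1),
        slippery_sites=slippery,
    )


def enumerate_library(
    top: Sequence[GuideSite],
    bottom: Sequence[GuideSite],
    spec: CassetteSpec | None = None,
) -> tuple[int, Iterator[BarcodeCassette]]:
    """Combinatorial library: complexity ``|top| * |bottom|`` and a lazy
    iterator over every (site_a, site_b) cassette exactly once."""
    if not top or not bottom:
        raise DesignError("both pools must be non-empty")
    for pool_name, pool in (("top", top), ("bottom", bottom)):
        seqs = [s.protospacer for s in pool]
        if len(seqs) != len(set(seqs)):
            raise DesignError(f"duplicate protospacers in {pool_name} pool")
    spec = spec or CassetteSpec()

    def _iter() -> Iterator[BarcodeCassette]:
        for a in top:
            for b in bottom:
                yield assemble_cassette(a, b, spec)

    return len(top) * len(bottom), _iter()


def emit_oligos(
    top_sites: Sequence[GuideSite],
    bottom_sites: Sequence[GuideSite],
    spec: CassetteSpec | None = None,
    pairing_overlap: int = 15,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Single-strand synthesis oligos for the two pools.

    The top oligo carries ``five_flank + site_a`` plus the 5' part of the
    linker; the bottom oligo is the reverse complement of the rest of the
    linker plus ``site_b + three_flank``; the two share a complementary 3'
    region of exactly ``pairing_overlap`` nt centered in the linker, so that
    annealing any top/bottom pair and extending reconstructs the full
    cassette sequence.  Returns ``(top, bottom)`` lists of (site_id, oligo).
    """
    spec = spec or CassetteSpec()
    L = len(spec.linker)
    if pairing_overlap > L:
        raise DesignError(
            f"pairing_overlap {pairing_overlap} exceeds linker length {L}"
        )
    if pairing_overlap < 1:
        raise DesignError("pairing_overlap must be >= 1")
    top_end = (L + pairing_overlap + 1) // 2  # overlap centered in the linker
    bottom_start = top_end - pairing_overlap
    top_oligos = [
        (s.site_id, spec.five_flank + s.protospacer + spec.linker[:top_end])
        for s in top_sites
    ]
    bottom_oligos = [
        (
            s.site_id,
            revcomp(spec.linker[bottom_start:] + s.protospacer + spec.three_flank),
        )
        for s in bottom_sites
    ]
    return top_oligos, bottom_oligos


def capture_guides_for(cassette: BarcodeCassette) -> tuple[str, str]:
    """The two gRNA spacers that target this cassette.

    ``site_a`` is read by Cas9 on the minus strand (its PAM is the
    complement of the CCN at the end of the 5' flank), so its spacer is the
    reverse complement of the plus-strand site; ``site_b`` is read on the
    plus strand (PAM at the start of the 3' flank), so its spacer is the
    site itself.
    """
    return revcomp(cassette.site_a.protospacer), cassette.site_b.protospacer
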