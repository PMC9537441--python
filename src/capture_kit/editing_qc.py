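"""Editing-outcome classification and capture purity from amplicon reads.

Cas9-nickase targeting of a cassette makes a staggered double-strand break
between the two protospacers; repair leaves indels concentrated in the
inter-nick window.  Each read is globally aligned to its reference cassette,
the net indel length inside a configurable cut window is computed, and the
frame class follows net length mod 3:

* ``in_frame``      net = 0 (mod 3)  — reporter fusion preserved
* ``plus1_class``   net = 1 (mod 3)
* ``minus1_class``  net = 2 (mod 3)  — the "-1" frameshift

The v1 reporter turns eGFP off for any frameshift; the v2 polycistronic
reporter additionally frames the puromycin-resistance marker *in* for the
minus-1 class only, so the three classes are phenotypically distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np

from .amplicon_io import ReadRecord, extract_barcode
from .cassette_design import PROTOSPACER_LEN, BarcodeCassette, CassetteSpec

IN_FRAME = "in_frame"
MINUS1 = "minus1_class"
PLUS1 = "plus1_class"

_FRAME_BY_MOD = {0: IN_FRAME, 1: PLUS1, 2: MINUS1}


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment of a read to a cassette reference.

    ``edits`` is a CIGAR-like list of ``(op, ref_pos, length)`` with op in
    {"X" (mismatch), "I" (insertion, anchored at ref_pos), "D" (deletion)};
    matches are implicit.
    """

    score: float
    aligned_ref: str
    aligned_read: str
    edits: tuple[tuple[str, int, int], ...]


def align_to_cassette(
    read: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch, affine gaps).

    Tie-breaking is deterministic: at equal score, diagonal moves are
    preferred over deletions over insertions, and gaps are subsequently
    left-aligned against the reference, so repeated runs and homopolymer
    placements are reproducible.
    """
    if not read:
        raise ValueError("empty read")
    if not (len(reference) / 2 <= len(read) <= 2 * len(reference)):
        raise ValueError("read length outside 2x of the reference length")
    n, m = len(read), len(reference)
    NEG = -1e18
    # M: read[i] aligned to ref[j]; X: gap in read (deletion); Y: gap in ref
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        Y[i][0] = gap_open + gap_extend * (i - 1)
    for i in range(1, n + 1):
        ri = read[i - 1]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            s = match if ri == reference[j - 1] else mismatch
            jp = j - 1
            Mi[j] = max(Mp[jp], Xp[jp], Yp[jp]) + s
            Xi[j] = max(Mi[jp] + gap_open, Xi[jp] + gap_extend,
                        Yi[jp] + gap_open)
            Yi[j] = max(Mp[j] + gap_open, Yp[j] + gap_extend,
                        Xp[j] + gap_open)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][n][m])
    a_read: list[str] = []
    a_ref: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            a_read.append(read[i - 1])
            a_ref.append(reference[j - 1])
            s = match if read[i - 1] == reference[j - 1] else mismatch
            prev = M[i][j] - s
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if abs(mat[i - 1][j - 1] - prev) < eps:
                    state = st
                    break
            i, j = i - 1, j - 1
        elif state == "X":  # gap in read: consume reference (deletion)
            a_read.append("-")
            a_ref.append(reference[j - 1])
            here = X[i][j]
            if abs(X[i][j - 1] + gap_extend - here) < eps:
                state = "X"
            elif abs(M[i][j - 1] + gap_open - here) < eps:
                state = "M"
            else:
                state = "Y"
            j -= 1
        else:  # Y: gap in reference: consume read (insertion)
            a_read.append(read[i - 1])
            a_ref.append("-")
            here = Y[i][j]
            if abs(Y[i - 1][j] + gap_extend - here) < eps:
                state = "Y"
            elif abs(M[i - 1][j] + gap_open - here) < eps:
                state = "M"
            else:
                state = "X"
            i -= 1
    aligned_read = "".join(reversed(a_read))
    aligned_ref = "".join(reversed(a_ref))
    aligned_read, aligned_ref = _left_align_gaps(aligned_read, aligned_ref)
    score = float(max(M[n][m], X[n][m], Y[n][m]))
    return AlignmentResult(score, aligned_ref, aligned_read,
                           tuple(_edits_from_alignment(aligned_ref, aligned_read)))


def _left_align_gaps(read_row: str, ref_row: str) -> tuple[str, str]:
    """Shift gap runs left while the flanking base matches (deterministic
    placement of indels in repeats)."""
    for target in (0, 1):  # 0: gaps in read row, 1: gaps in ref row
        rows = [list(read_row), list(ref_row)]
        gapped, other = rows[target], rows[1 - target]
        moved = True
        while moved:
            moved = False
            k = 0
            while k < len(gapped):
                if gapped[k] == "-":
                    start = k
                    while k < len(gapped) and gapped[k] == "-":
                        k += 1
                    if (start > 0 and gapped[start - 1] != "-"
                            and other[start - 1] == other[k - 1]
                            and gapped[start - 1] == other[k - 1]):
                        gapped[k - 1] = gapped[start - 1]
                        gapped[start - 1] = "-"
                        moved = True
                else:
                    k += 1
        read_row, ref_row = "".join(rows[0]), "".join(rows[1])
    return read_row, ref_row


def _edits_from_alignment(aligned_ref: str, aligned_read: str):
    edits = []
    ref_pos = 0
    i = 0
    L = len(aligned_ref)
    while i < L:
        r, q = aligned_ref[i], aligned_read[i]
        if r == "-":  # insertion relative to reference
            j = i
            while j < L and aligned_ref[j] == "-":
                j += 1
            edits.append(("I", ref_pos, j - i))
            i = j
        elif q == "-":  # deletion
            j = i
            while j < L and aligned_read[j] == "-":
                j += 1
            edits.append(("D", ref_pos, j - i))
            ref_pos += j - i
            i = j
        else:
            if r != q:
                edits.append(("X", ref_pos, 1))
            ref_pos += 1
            i += 1
    return edits


@dataclass(frozen=True)
class EditingOutcome:
    read_id: str
    assigned_barcode_key: str | None
    net_indel_len: int
    frame_class: str
    edited: bool
    reporter_state: str | None = None


def default_cut_window(spec: CassetteSpec | None = None, pad: int = 3) -> tuple[int, int]:
    """[start, end) reference window where edits count: the inter-nick
    offset plus ``pad`` nt into each protospacer."""
    spec = spec or CassetteSpec()
    a_end = spec.site_offset("top") + PROTOSPACER_LEN
    b_start = spec.site_offset("bottom")
    return a_end - pad, b_start + pad


def classify_edit(
    alignment: AlignmentResult,
    cut_window: tuple[int, int],
    read_id: str = "",
    assigned_barcode_key: str | None = None,
    reference_length: int | None = None,
) -> EditingOutcome:
    """Net indel length within the cut window and the resulting frame class.

    Deletions contribute only the part of their span overlapping the window;
    insertions count when anchored inside it.  A read is ``edited`` iff any
    indel overlaps the window.
    """
    start, end = cut_window
    if start < 0 or end <= start:
        raise ValueError("invalid cut window")
    if reference_length is not None and end > reference_length:
        raise ValueError("cut window outside reference")
    net = 0
    edited = False
    for op, pos, length in alignment.edits:
        if op == "I":
            if start <= pos <= end:
                net += length
                edited = True
        elif op == "D":
            overlap = min(pos + length, end) - max(pos, start)
            if overlap > 0:
                net -= overlap
                edited = True
    return EditingOutcome(
        read_id=read_id,
        assigned_barcode_key=assigned_barcode_key,
        net_indel_len=net,
        frame_class=_FRAME_BY_MOD[net % 3],
        edited=edited,
    )


def reporter_state(frame_class: str, version: str = "v1") -> str:
    """Predicted reporter phenotype for a frame class.

    v1 (RFP-barcode-eGFP fusion): any frameshift silences eGFP.
    v2 (GFP / BSD / +1-shifted PuroR-HA polycistron): only the -1 class
    frames the puromycin marker in.
    """
    if version == "v1":
        return "RFP+/eGFP+" if frame_class == IN_FRAME else "RFP+/eGFP-"
    if version == "v2":
        return {
            IN_FRAME: "GFP+/BSD+",
            MINUS1: "GFP-/PuroR-HA+",
            PLUS1: "GFP-/PuroR-",
        }[frame_class]
    raise ValueError("version must be 'v1' or 'v2'")


@dataclass
class PurityReport:
    """Read-level composition of a captured pool.

    ``composition_purity``: fraction of assignable reads carrying the
    intended barcode.  ``targeted_fraction``: fraction of target-assigned
    reads that are edited in the cut window.
    """

    composition_purity: float
    targeted_fraction: float
    composition: dict[str, float]
    n_reads: int
    n_assignable: int


def _assign_read(
    seq: str,
    library: Mapping[str, str],
    spec: CassetteSpec,
    cut_window: tuple[int, int],
) -> tuple[str | None, AlignmentResult | None]:
    """Assign a read to a library barcode.

    Intact motif -> exact barcode_key match.  Otherwise the read is aligned
    to each library cassette and assigned to the best-scoring one whose two
    N20 remnants outside the cut window match the read without mismatches
    (edited reads keep their flank/linker anchors and the PAM-distal parts
    of both protospacers).
    """
    key, _ = extract_barcode(seq, spec)
    if key is not None:
        return (key, None) if key in library else (None, None)
    seq = _trim_to_motif(seq, spec)
    best: tuple[float, str, AlignmentResult] | None = None
    for cand_key, ref in library.items():
        try:
            aln = align_to_cassette(seq, ref)
        except ValueError:
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, cand_key, aln)
    if best is None:
        return None, None
    _, cand_key, aln = best
    start, end = cut_window
    # N20 remnants outside the cut window must match perfectly
    a_lo = spec.site_offset("top")
    b_hi = spec.site_offset("bottom") + PROTOSPACER_LEN
    ref_pos = 0
    for r, q in zip(aln.aligned_ref, aln.aligned_read):
        if r != "-":
            inside_remnant = (a_lo <= ref_pos < start) or (end <= ref_pos < b_hi)
            if inside_remnant and (q == "-" or q != r):
                return None, aln
            ref_pos += 1
    return cand_key, aln


def purity_report(
    reads: Iterable[ReadRecord | str],
    target_barcode: str,
    reference_library: Mapping[str, str] | Sequence[str],
    spec: CassetteSpec | None = None,
    cut_window: tuple[int, int] | None = None,
) -> PurityReport:
    """Composition purity and targeted (edited) fraction of a read pool."""
    spec = spec or CassetteSpec()
    if not isinstance(reference_library, Mapping):
        from .cassette_design import GuideSite, assemble_cassette

        lib: dict[str, str] = {}
        for key in reference_library:
            a = GuideSite("a", key[:PROTOSPACER_LEN], "top")
            b = GuideSite("b", key[PROTOSPACER_LEN:], "bottom")
            lib[key] = assemble_cassette(a, b, spec).full_sequence
        reference_library = lib
    if target_barcode not in reference_library:
        raise ValueError("target barcode not in reference library")
    window = cut_window or default_cut_window(spec)
    n_reads = 0
    assigned: dict[str, int] = {}
    n_target_edited = 0
    n_target = 0
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        rid = read.read_id if isinstance(read, ReadRecord) else ""
        n_reads += 1
        key, aln = _assign_read(seq, reference_library, spec, window)
        if key is None:
            continue
        assigned[key] = assigned.get(key, 0) + 1
        if key == target_barcode:
            n_target += 1
            if aln is None:
                aln = align_to_cassette(
                    _trim_to_motif(seq, spec), reference_library[key]
                )
            outcome = classify_edit(aln, window, read_id=rid)
            if outcome.edited:
                n_target_edited += 1
    if n_reads == 0:
        raise ValueError("empty read set")
    n_assignable = sum(assigned.values())
    purity = n_target / n_assignable if n_assignable else 0.0
    targeted = n_target_edited / n_target if n_target else 0.0
    composition = {k: v / n_assignable for k, v in assigned.items()} if n_assignable else {}
    return PurityReport(
        composition_purity=purity,
        targeted_fraction=targeted,
        composition=composition,
        n_reads=n_reads,
        n_assignable=n_assignable,
    )


def _trim_to_motif(seq: str, spec: CassetteSpec) -> str:
    """Trim stagger/adapter context so the alignment sees only the cassette."""
    i = seq.find(spec.five_flank)
    if i >= 0:
        return seq[i : i + spec.motif_length]
    return seq


def position_profile(
    alignments: Iterable[AlignmentResult], reference_length: int
) -> np.ndarray:
    """Per-reference-position frequencies of deletion, insertion and
    substitution events (rows: D, I, X)."""
    counts = np.zeros((3, reference_length))
    n = 0
    for aln in alignments:
        n += 1
        for op, pos, length in aln.edits:
            row = {"D": 0, "I": 1, "X": 2}[op]
            if op == "D":
                counts[row, pos : pos + length] += 1
            else:
                counts[row, min(pos, reference_length - 1)] += 1
    return counts / n if n else counts


def expected_frameshift_fraction(
    indel_model: Mapping[int, float] | None = None,
) -> float:
    """Probability that a net indel length is not a multiple of 3.

    The default model is uniform over indel sizes 1..30 (deletions and
    insertions symmetric, so only the magnitude matters), under which
    exactly 20 of 30 sizes shift the frame: 2/3.
    """
    if indel_model is None:
        indel_model = {size: 1.0 / 30.0 for size in range(1, 31)}
    total = sum(indel_model.values())
    if total <= 0:
        raise ValueError("indel model has no mass")
    shifted = sum(p for size, p in indel_model.items() if size % 3 != 0)
    frac = shifted / total
    if frac == 0.0 and indel_model.get(0, 0.0) == total:
        warnings.warn("indel model has all mass at 0: no editing modeled")
    return frac
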