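"""Independent string-level oracle for single-indel editing outcomes.

Given a reference and a planted single indel, computes the left-normalized
placement of that indel (the standard shift-left rule used for variant
normalization) and the expected in-window net indel length, without running
any alignment.  Used to cross-check the dynamic-programming route.
"""

from __future__ import annotations


def normalize_deletion(ref: str, pos: int, size: int) -> int:
    """Left-shift a deletion of ref[pos:pos+size] while equivalent."""
    while pos > 0 and ref[pos - 1] == ref[pos + size - 1]:
        pos -= 1
    return pos


def normalize_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    """Left-shift an insertion anchored before ref[pos] while equivalent."""
    while pos > 0 and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def expected_outcome(
    ref: str,
    kind: str,
    pos: int,
    size: int,
    window: tuple[int, int],
    ins_seq: str | None = None,
) -> tuple[int, bool]:
    """(net_indel_in_window, edited) for a planted single indel."""
    start, end = window
    if kind == "D":
        p = normalize_deletion(ref, pos, size)
        overlap = min(p + size, end) - max(p, start)
        if overlap > 0:
            return -overlap, True
        return 0, False
    p, _ = normalize_insertion(ref, pos, ins_seq or "")
    if start <= p <= end:
        return size, True
    return 0, False


def perturb(ref: str, kind: str, pos: int, size: int, ins_seq: str | None = None) -> str:
    if kind == "D":
        return ref[:pos] + ref[pos + size :]
    return ref[:pos] + (ins_seq or "") + ref[pos:]
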