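"""Barcode extraction and exact-match counting from amplicon reads.

Reads carry the cassette motif ``five_flank (N20) linker (N20) three_flank``
at a variable offset (the sequencing library uses a 0-8 nt stagger to
diversify the flow-cell image).  Extraction locates the motif at any offset
on either strand, pulls out the two N20 segments and concatenates them into
the 40-nt ``barcode_key``; counting then keeps only keys that match a
reference library exactly (optionally rescuing keys within a small Hamming
distance of a unique reference key).
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import DNA_ALPHABET, hamming, revcomp
from .cassette_design import PROTOSPACER_LEN, CassetteSpec

NO_MOTIF = "no_motif"
NO_REFERENCE_MATCH = "no_reference_match"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (qualities optional, Phred-scaled integers)."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must equal sequence length")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a FASTQ or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            fh.readline()  # '+' separator
            qual = fh.readline().strip()
            yield ReadRecord(
                header.strip()[1:].split()[0],
                seq,
                tuple(ord(c) - 33 for c in qual) if qual else None,
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in records:
            qual = (
                "".join(chr(q + 33) for q in rec.qualities)
                if rec.qualities is not None
                else "I" * len(rec.sequence)
            )
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def _motif_regex(spec: CassetteSpec) -> re.Pattern[str]:
    n = PROTOSPACER_LEN
    return re.compile(
        re.escape(spec.five_flank)
        + f"([ACGT]{{{n}}})"
        + re.escape(spec.linker)
        + f"([ACGT]{{{n}}})"
        + re.escape(spec.three_flank)
    )


def _scan_with_mismatches(
    seq: str, spec: CassetteSpec, max_mm: int
) -> str | None:
    """Leftmost motif hit allowing <= max_mm mismatches per fixed segment."""
    n = PROTOSPACER_LEN
    f5, lk, f3 = spec.five_flank, spec.linker, spec.three_flank
    motif_len = spec.motif_length
    for i in range(len(seq) - motif_len + 1):
        p = i
        if hamming(seq[p : p + len(f5)], f5) > max_mm:
            continue
        p += len(f5)
        n20a = seq[p : p + n]
        p += n
        if hamming(seq[p : p + len(lk)], lk) > max_mm:
            continue
        p += len(lk)
        n20b = seq[p : p + n]
        p += n
        if hamming(seq[p : p + len(f3)], f3) > max_mm:
            continue
        if set(n20a) <= DNA_ALPHABET and set(n20b) <= DNA_ALPHABET:
            return n20a + n20b
    return None


def extract_barcode(
    read: ReadRecord | str,
    spec: CassetteSpec | None = None,
    max_flank_mismatch: int = 0,
    search_revcomp: bool = True,
) -> tuple[str | None, str | None]:
    """Extract the 40-nt barcode_key from a read, or (None, reason).

    The motif is searched at every offset on the plus strand (leftmost hit
    wins); if absent and ``search_revcomp`` is on, the reverse complement is
    searched.  ``max_flank_mismatch`` mismatches are tolerated in each fixed
    segment (5' flank, linker, 3' flank counted separately); the N20
    segments must be unambiguous A/C/G/T.
    """
    spec = spec or CassetteSpec()
    seq = (read.sequence if isinstance(read, ReadRecord) else read).upper()
    if len(seq) < spec.motif_length:
        return None, NO_MOTIF
    strands = [seq, revcomp(seq)] if search_revcomp else [seq]
    if max_flank_mismatch == 0:
        pattern = _motif_regex(spec)
        for strand in strands:
            m = pattern.search(strand)
            if m:
                return m.group(1) + m.group(2), None
    else:
        for strand in strands:
            key = _scan_with_mismatches(strand, spec, max_flank_mismatch)
            if key is not None:
                return key, None
    return None, NO_MOTIF


@dataclass
class BarcodeCountTable:
    """Barcodes x samples integer counts plus per-sample accounting.

    ``totals[s]`` is the number of reads assigned to a reference barcode in
    sample ``s``; ``unassigned[s]`` maps a reason (``no_motif``,
    ``no_reference_match``) to a read count.  Conservation holds per sample:
    assigned + unassigned = reads processed.
    """

    counts: pd.DataFrame
    unassigned: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def barcode_keys(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def fractions(self) -> pd.DataFrame:
        totals = self.totals
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=1)

    def summary(self) -> dict:
        return {
            "samples": {
                s: {
                    "assigned": int(self.totals[s]),
                    "unassigned": {
                        k: int(v) for k, v in self.unassigned.get(s, {}).items()
                    },
                }
                for s in self.sample_ids
            },
            "n_barcodes": len(self.counts),
        }


def count_barcodes(
    reads_per_sample: Mapping[str, Iterable[ReadRecord | str]],
    reference: Iterable[str],
    spec: CassetteSpec | None = None,
    exact: bool = True,
    hamming_rescue: int = 0,
    max_flank_mismatch: int = 0,
    search_revcomp: bool = True,
) -> BarcodeCountTable:
    """Count extracted barcode keys against a reference library.

    In exact mode a key is counted iff it equals a reference key.  With
    ``hamming_rescue = d > 0`` a non-matching key is rescued to the unique
    reference key within Hamming distance ``d`` (ties stay unassigned).
    """
    spec = spec or CassetteSpec()
    ref_list = list(reference)
    ref_set = set(ref_list)
    if len(ref_list) != len(ref_set):
        raise ValueError("reference contains duplicate barcode keys")
    if not ref_set:
        raise ValueError("reference is empty")
    if not exact and hamming_rescue == 0:
        hamming_rescue = 1

    samples = list(reads_per_sample)
    counts = {s: {} for s in samples}
    unassigned: dict[str, dict[str, int]] = {
        s: {NO_MOTIF: 0, NO_REFERENCE_MATCH: 0} for s in samples
    }
    for sample, reads in reads_per_sample.items():
        c = counts[sample]
        for read in reads:
            key, reason = extract_barcode(
                read, spec, max_flank_mismatch, search_revcomp
            )
            if key is None:
                unassigned[sample][reason] += 1
                continue
            if key not in ref_set and hamming_rescue > 0:
                near = [r for r in ref_list if hamming(key, r) <= hamming_rescue]
                key = near[0] if len(near) == 1 else key
            if key in ref_set:
                c[key] = c.get(key, 0) + 1
            else:
                unassigned[sample][NO_REFERENCE_MATCH] += 1

    mat = pd.DataFrame(
        {s: [counts[s].get(k, 0) for k in ref_list] for s in samples},
        index=pd.Index(ref_list, name="barcode_key"),
        dtype=np.int64,
    )
    # drop reference barcodes never observed in any sample: the table models
    # *detected* complexity
    mat = mat.loc[mat.sum(axis=1) > 0]
    return BarcodeCountTable(counts=mat, unassigned=unassigned)


def write_count_table(table: BarcodeCountTable, path: str | Path) -> None:
    """Write counts as TSV: first column barcode_key, then one per sample."""
    table.counts.to_csv(path, sep="\t", index=True)


def read_count_table(path: str | Path) -> BarcodeCountTable:
    """Read a count TSV written by :func:`write_count_table`.

    Malformed input (ragged rows, non-integer counts) raises a ValueError
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        samples = cols[1:]
        keys: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            keys.append(parts[0])
            try:
                rows.append([int(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
    mat = pd.DataFrame(
        rows or np.empty((0, len(samples)), dtype=np.int64),
        index=pd.Index(keys, name="barcode_key"),
        columns=samples,
        dtype=np.int64,
    )
    return BarcodeCountTable(counts=mat)


def read_reference(path: str | Path) -> list[str]:
    """Reference barcode keys from FASTA (record ids or sequences) or a
    single-column TSV of keys."""
    path = Path(path)
    keys: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith(">"):
            from Bio import SeqIO

            for rec in SeqIO.parse(fh, "fasta"):
                seq = str(rec.seq).upper()
                keys.append(seq if len(seq) == 2 * PROTOSPACER_LEN else rec.id)
        else:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    keys.append(line.split("\t")[0])
    return keys


def write_run_summary(table: BarcodeCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(table.summary(), fh, indent=2)
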