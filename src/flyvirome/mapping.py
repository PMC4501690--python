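"""Minimal small-read placement onto reference sequences.

Small RNAs (17-29 nt) are placed at every position, on either strand, where
the 5'-anchored prefix of the read matches the reference exactly and only a
short 3'-terminal window is allowed to mismatch.  The tolerant 3' window
exists so that non-templated 3' additions (notably the uridylation seen on
some virus-derived small RNAs) are recorded rather than causing the read to
be dropped.  All candidate locations are reported ("all" policy) or assigned
fractional weight 1/n_locations ("fractional" policy).

Coordinates are 0-based half-open on the forward strand of the reference; a
minus-strand placement means the read, as sequenced, is the reverse
complement of the covered reference window.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

MIN_READ_LEN = 17
MAX_READ_LEN = 29

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_VALID = frozenset("ACGTUN")


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide sequence (U treated as T)."""
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid base(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def normalise(sequence: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid base(s) in sequence: {sorted(bad)}")
    return seq


def to_rna(sequence: str) -> str:
    """Render a sequence in the RNA alphabet (T -> U) for reporting."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class Reference:
    """A reference (contig or virus genome) to place small reads on."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", normalise(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappedSmallRead:
    """One placement of a small RNA read on a reference.

    ``three_prime_mismatches`` lists tolerated terminal mismatches as
    ``(offset_from_3prime, read_base, template_base)`` with offset 0 being
    the 3'-terminal base of the read as sequenced.
    """

    read_sequence: str
    contig_id: str
    start: int
    strand: str
    length: int
    three_prime_mismatches: tuple = ()
    weight: float = 1.0


@dataclass
class MappingResult:
    placements: list = field(default_factory=list)
    n_reads_skipped: int = 0


def _index_prefixes(refs, k_values):
    """k-mer -> [(ref_id, pos)] for every needed anchor length k.

    k-mers containing N are not indexed: N never matches.
    """
    index = {k: defaultdict(list) for k in k_values}
    for ref in refs:
        seq = ref.sequence
        for k in k_values:
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" not in kmer:
                    index[k][kmer].append((ref.id, pos))
    return index


def _tail_mismatches(read, template, anchor_len):
    """Mismatch records in the 3' window, or None if a base is N/N-matched."""
    L = len(read)
    records = []
    for i in range(anchor_len, L):
        rb, tb = read[i], template[i]
        if rb != tb or rb == "N" or tb == "N":
            records.append((L - 1 - i, rb, tb))
    return tuple(records)


def map_reads(reads, refs, max_3prime_mismatch: int = 2, multimap: str = "all") -> MappingResult:
    """Place reads on references, 5'-anchored with a tolerant 3' window.

    Parameters
    ----------
    reads : iterable of str
        Small RNA sequences as sequenced (17-29 nt; U accepted).
    refs : iterable of Reference
    max_3prime_mismatch : int
        Number of 3'-terminal bases allowed to mismatch the template.
    multimap : {"all", "fractional"}
        "all" reports every location at weight 1; "fractional" divides unit
        weight over the locations of each read.

    Reads outside the 17-29 nt range are skipped (counted, with a warning);
    invalid characters raise.
    """
    if multimap not in ("all", "fractional"):
        raise ValueError(f"unknown multimap policy {multimap!r}")
    if max_3prime_mismatch < 0:
        raise ValueError("max_3prime_mismatch must be >= 0")

    refs = list(refs)
    ref_by_id = {r.id: r for r in refs}
    clean = []
    skipped = 0
    for read in reads:
        seq = normalise(read)
        if not (MIN_READ_LEN <= len(seq) <= MAX_READ_LEN):
            skipped += 1
            continue
        clean.append(seq)
    if skipped:
        warnings.warn(f"skipped {skipped} read(s) outside {MIN_READ_LEN}-{MAX_READ_LEN} nt")

    k_values = sorted({max(len(s) - max_3prime_mismatch, 1) for s in clean})
    index = _index_prefixes(refs, k_values) if clean else {}

    result = MappingResult(n_reads_skipped=skipped)
    for seq in clean:
        L = len(seq)
        anchor = max(L - max_3prime_mismatch, 1)
        hits = []
        # + strand: read prefix matches the forward reference directly.
        for ref_id, pos in index[anchor].get(seq[:anchor], ()):
            ref_seq = ref_by_id[ref_id].sequence
            if pos + L > len(ref_seq):
                continue
            template = ref_seq[pos:pos + L]
            mm = _tail_mismatches(seq, template, anchor)
            hits.append((ref_id, pos, "+", mm))
        # - strand: the read is the revcomp of the covered window, so its
        # 5'-anchored prefix matches the revcomp of the window's 3' end.
        rc = revcomp(seq)
        for ref_id, pos in index[anchor].get(rc[-anchor:], ()):
            # rc[-anchor:] sits at forward positions [pos, pos+anchor); the
            # full window is [pos - (L - anchor), pos + anchor).
            start = pos - (L - anchor)
            if start < 0:
                continue
            ref_seq = ref_by_id[ref_id].sequence
            template_fwd = ref_seq[start:start + L]
            template = revcomp(template_fwd)  # template in read orientation
            mm = _tail_mismatches(seq, template, anchor)
            hits.append((ref_id, start, "-", mm))

        if not hits:
            continue
        w = 1.0 if multimap == "all" else 1.0 / len(hits)
        for ref_id, start, strand, mm in hits:
            result.placements.append(MappedSmallRead(
                read_sequence=seq, contig_id=ref_id, start=start,
                strand=strand, length=L, three_prime_mismatches=mm, weight=w))
    return result
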