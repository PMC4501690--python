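"""Per-virus small-RNA summary statistics.

Size/strand spectra, 5' and positional base composition (sequence-logo
information content), non-templated 3'-base detection, dominant-read
statistics and the miRNA-normalised viRNA production ratio.  These are the
quantitative descriptors used to characterise virus-derived small RNA
populations: an antiviral Dicer-2 response shows as a sharp 21 nt peak on
both strands, a piRNA signature as a 25-29 nt single-strand-biased
population, and 3' uridylation as an excess of non-templated terminal U.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import MIN_READ_LEN, MAX_READ_LEN

_RNA_BASES = ("A", "C", "G", "U")


@dataclass
class SizeStrandSpectrum:
    """Read counts by (length 17-29, strand)."""

    counts: pd.DataFrame  # index lengths, columns ["+", "-"]
    total: float

    @classmethod
    def empty(cls):
        idx = range(MIN_READ_LEN, MAX_READ_LEN + 1)
        return cls(pd.DataFrame(0.0, index=idx, columns=["+", "-"]), 0.0)


def size_strand_spectrum(placements, virus_id=None) -> SizeStrandSpectrum:
    """Tally placements by read length and strand.

    Placements are weighted (weight 1 under the "all" multimap policy,
    1/n_locations under "fractional").  ``virus_id=None`` pools all contigs.
    """
    spectrum = SizeStrandSpectrum.empty()
    for p in placements:
        if virus_id is not None and p.contig_id != virus_id:
            continue
        spectrum.counts.loc[p.length, p.strand] += p.weight
        spectrum.total += p.weight
    return spectrum


def strand_bias(spectrum: SizeStrandSpectrum):
    """Fraction of placements on the positive strand; None if empty."""
    if spectrum.total == 0:
        return None
    return float(spectrum.counts["+"].sum() / spectrum.total)


def five_prime_composition(placements, by_length: bool = False):
    """5'-base frequencies of the reads as sequenced (RNA alphabet).

    Returns ``{base: freq}`` pooled over lengths, or ``{length: {base:
    freq}}`` when ``by_length``.  The 5' base of a minus-strand placement is
    the first base of the read itself (already reverse-complemented relative
    to the reference).
    """
    counts: dict = {}
    for p in placements:
        base = p.read_sequence[0].replace("T", "U")
        key = p.length if by_length else None
        counts.setdefault(key, Counter())[base] += p.weight
    out = {}
    for key, ctr in counts.items():
        total = sum(ctr.values())
        out[key] = {b: ctr.get(b, 0.0) / total for b in _RNA_BASES}
    return out if by_length else out.get(None, {})


@dataclass
class BaseCompositionProfile:
    """Per-position base frequencies and information content of one length class.

    ``information_content[i] = 2 - H_i`` bits, where H_i is the Shannon
    entropy (log2) of the base frequencies at position i; the total letter
    height of a sequence-logo column.
    """

    frequencies: pd.DataFrame  # positions 1..L x (A, C, G, U)
    information_content: np.ndarray
    read_length: int


def positional_composition(placements, length: int) -> BaseCompositionProfile:
    """Sequence-logo matrix for all placements of one read length."""
    mat = np.zeros((length, 4))
    n = 0.0
    idx = {b: i for i, b in enumerate(_RNA_BASES)}
    for p in placements:
        if p.length != length:
            continue
        for pos, base in enumerate(p.read_sequence.replace("T", "U")):
            if base in idx:
                mat[pos, idx[base]] += p.weight
        n += p.weight
    if n == 0:
        raise ValueError(f"no placements of length {length} nt")
    freq = mat / mat.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return BaseCompositionProfile(
        frequencies=pd.DataFrame(freq, index=range(1, length + 1), columns=_RNA_BASES),
        information_content=info,
        read_length=length,
    )


@dataclass
class NonTemplatedSummary:
    per_base: pd.DataFrame        # terminal base x (templated, non_templated)
    nontemplated_U_fraction: float  # of 3'-U reads, fraction non-templated
    three_prime_U_fraction: float   # fraction of all reads ending in U


def nontemplated_3prime(placements) -> NonTemplatedSummary:
    """Classify each placement's 3'-terminal base as templated or not.

    A terminal base is non-templated when the mapper recorded a mismatch at
    offset 0 from the 3' end.  The headline number is the fraction of 3'-U
    reads whose terminal U is non-templated (the uridylation signal).
    """
    per_base = {b: [0.0, 0.0] for b in _RNA_BASES}
    total = 0.0
    for p in placements:
        terminal = p.read_sequence[-1].replace("T", "U")
        non_templated = any(off == 0 for off, _, _ in p.three_prime_mismatches)
        per_base.setdefault(terminal, [0.0, 0.0])
        per_base[terminal][1 if non_templated else 0] += p.weight
        total += p.weight
    df = pd.DataFrame(per_base, index=["templated", "non_templated"]).T
    u_total = df.loc["U"].sum() if "U" in df.index else 0.0
    return NonTemplatedSummary(
        per_base=df,
        nontemplated_U_fraction=(df.loc["U", "non_templated"] / u_total) if u_total else 0.0,
        three_prime_U_fraction=(u_total / total) if total else 0.0,
    )


@dataclass
class ViRNARatio:
    virus_id: str
    virna_count_21_23: float
    rnaseq_count: float
    ratio: float | None        # (viRNA/miR-34) / (RNAseq/non-viral RNAseq)
    relative_rate: float | None  # ratio / min defined ratio across viruses


def virna_ratio(per_virus: dict, mir34_count: float, nonviral_rnaseq_count: float):
    """Relative viRNA production per virus.

    ``per_virus`` maps virus -> (21-23 nt viRNA count, RNAseq count).  Each
    virus's viRNA count is normalised by the count of the abundant host
    miRNA miR-34-5p, its RNAseq count by the non-viral RNAseq total, and the
    quotient of the two rates is rescaled so the lowest-producing virus has
    relative rate 1.  Viruses with zero RNAseq reads are flagged undefined
    and excluded from the minimum.
    """
    if mir34_count <= 0 or nonviral_rnaseq_count <= 0:
        raise ValueError("miR-34 and non-viral RNAseq counts must be positive")
    out = {}
    for virus, (virna, rnaseq) in per_virus.items():
        ratio = None
        if rnaseq > 0:
            ratio = (virna / mir34_count) / (rnaseq / nonviral_rnaseq_count)
        out[virus] = ViRNARatio(virus, virna, rnaseq, ratio, None)
    defined = [r.ratio for r in out.values() if r.ratio is not None and r.ratio > 0]
    if defined:
        floor = min(defined)
        for r in out.values():
            if r.ratio is not None:
                r.relative_rate = r.ratio / floor
    return out


@dataclass
class DominantReadStats:
    top_sequence: str
    share: float
    n_unique: int
    n_seen_more_than_once: int


def dominant_read_stats(placements) -> DominantReadStats:
    """Share of the single most abundant unique read sequence.

    A very large share of one exact sequence marks a miRNA-like species
    rather than a diverse Dicer-processed population.  Counts each distinct
    sequence once per placement (weighted); multimapped reads under the
    "all" policy therefore count per location, consistent with the spectra.
    """
    ctr: Counter = Counter()
    for p in placements:
        ctr[p.read_sequence] += p.weight
    if not ctr:
        raise ValueError("no placements")
    total = sum(ctr.values())
    top, top_count = max(ctr.items(), key=lambda kv: kv[1])
    return DominantReadStats(
        top_sequence=top,
        share=top_count / total,
        n_unique=len(ctr),
        n_seen_more_than_once=sum(1 for c in ctr.values() if c > 1),
    )
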