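"""siRNA-signature classification of contigs, EVE exclusion, taxonomy walk.

A replicating virus recognised by the fly's antiviral RNAi pathway carries
many 21-23 nt small RNAs relative to both its RNAseq abundance and its
25-29 nt (piRNA-like) reads.  Plotting contigs by log(siRNA:RNAseq) against
log(siRNA:piRNA), the well-characterised viruses delimit a sector toward
the top right; contigs lacking protein-level similarity to anything known
("blast_hit False") that fall inside that sector are proposed as
siRNA-candidate viruses.

Two supporting tests live here as well: the endogenous-viral-element (EVE)
coverage test, which compares genomic read coverage of a putative virus
against a single-copy host region (a real EVE is covered like any other
locus; an infection leaves the genome bare), and the lowest-75%-majority
taxonomy walk used to summarise sets of database-hit lineages.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

MIN_CONTIG_LENGTH = 200

#: Count profiles representative of the four well-characterised Drosophila
#: viruses (DAV, DCV, Nora Virus, DMelSV) used as positive controls when no
#: measured control profiles are supplied.  Synthetic stand-ins: the shapes
#: (siRNA-rich, piRNA-poor, moderate RNAseq) match the published pattern but
#: the counts are illustrative, not measured.
DEFAULT_CONTROL_PROFILES = pd.DataFrame(
    [
        {"contig_id": "DAV", "length": 4800, "sirna": 5000, "pirna": 100,
         "rnaseq": 500, "blast_hit": True},
        {"contig_id": "DCV", "length": 9300, "sirna": 1000, "pirna": 25,
         "rnaseq": 800, "blast_hit": True},
        {"contig_id": "NoraVirus", "length": 12300, "sirna": 3000, "pirna": 60,
         "rnaseq": 300, "blast_hit": True},
        {"contig_id": "DMelSV", "length": 12600, "sirna": 8000, "pirna": 30,
         "rnaseq": 80, "blast_hit": True},
    ]
)


def build_profiles(placements, rnaseq_counts: dict, contig_lengths: dict,
                   sirna_window=(21, 23), pirna_window=(25, 29)) -> pd.DataFrame:
    """Tally per-contig siRNA-window, piRNA-window and RNAseq counts.

    Contigs shorter than 200 nt are excluded (too short for a meaningful
    small-RNA profile).  Raises if a placement's contig has no length entry.
    """
    sirna: Counter = Counter()
    pirna: Counter = Counter()
    for p in placements:
        if p.contig_id not in contig_lengths:
            raise ValueError(f"no length for contig {p.contig_id!r}")
        if sirna_window[0] <= p.length <= sirna_window[1]:
            sirna[p.contig_id] += p.weight
        elif pirna_window[0] <= p.length <= pirna_window[1]:
            pirna[p.contig_id] += p.weight
    rows = []
    for contig, length in contig_lengths.items():
        if length < MIN_CONTIG_LENGTH:
            continue
        rows.append({
            "contig_id": contig, "length": length,
            "sirna": sirna.get(contig, 0), "pirna": pirna.get(contig, 0),
            "rnaseq": rnaseq_counts.get(contig, 0), "blast_hit": False,
        })
    return pd.DataFrame(
        rows, columns=["contig_id", "length", "sirna", "pirna", "rnaseq", "blast_hit"])


def score_axes(profiles: pd.DataFrame, alpha: float = 1.0) -> pd.DataFrame:
    """Sector-plot coordinates: x = log10((s+a)/(r+a)), y = log10((s+a)/(pi+a)).

    The pseudocount a keeps zero counts finite; length normalisation cancels
    between numerator and denominator and is omitted.
    """
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be > 0")
    out = profiles.copy()
    s = out["sirna"].astype(float) + alpha
    out["x"] = (s / (out["rnaseq"].astype(float) + alpha)).map(math.log10)
    out["y"] = (s / (out["pirna"].astype(float) + alpha)).map(math.log10)
    return out


@dataclass
class SectorCalibration:
    """Lower-left corner of the sector delimited by positive controls."""

    x_min: float
    y_min: float
    alpha: float = 1.0
    min_sirna_reads: int = 1
    calibration_contigs: list = field(default_factory=list)


def calibrate_sector(control_profiles: pd.DataFrame | None = None, alpha: float = 1.0,
                     min_sirna_reads: int = 1) -> SectorCalibration:
    """Calibrate the candidate sector from known-virus control profiles.

    Thresholds are the minimum x and minimum y over eligible controls, so
    every control self-classifies in-sector (comparisons are inclusive).
    """
    if control_profiles is None:
        control_profiles = DEFAULT_CONTROL_PROFILES
    eligible = control_profiles[control_profiles["sirna"] >= min_sirna_reads]
    if eligible.empty:
        raise ValueError("no control profile with enough siRNA reads")
    scored = score_axes(eligible, alpha)
    return SectorCalibration(
        x_min=float(scored["x"].min()), y_min=float(scored["y"].min()),
        alpha=alpha, min_sirna_reads=min_sirna_reads,
        calibration_contigs=list(eligible["contig_id"]))


def classify(profiles: pd.DataFrame, calibration: SectorCalibration) -> pd.DataFrame:
    """Label contigs by the siRNA-signature sector test.

    A contig is a ``sirna_candidate`` when it has at least
    ``min_sirna_reads`` 21-23 nt reads, lies in the calibrated sector
    (x >= x_min and y >= y_min, inclusive) and has no database hit.
    In-sector contigs that do have a hit are reported as
    ``blast_candidate_region``; everything else is ``not_candidate``.
    """
    scored = score_axes(profiles, calibration.alpha)
    in_sector = (
        (scored["sirna"] >= calibration.min_sirna_reads)
        & (scored["x"] >= calibration.x_min)
        & (scored["y"] >= calibration.y_min)
    )
    labels = pd.Series("not_candidate", index=scored.index)
    labels[in_sector & ~scored["blast_hit"]] = "sirna_candidate"
    labels[in_sector & scored["blast_hit"]] = "blast_candidate_region"
    scored["label"] = labels
    return scored


@dataclass
class EveVerdict:
    genome_id: str
    target_id: str
    normalised_coverage: float | None
    eve_consistent: bool | None  # None = indeterminate (no single-copy reads)
    threshold: float


def eve_test(target_read_count: float, target_length: int,
             singlecopy_read_count: float, singlecopy_length: int = 7000,
             threshold: float = 0.1, genome_id: str = "", target_id: str = "") -> EveVerdict:
    """Coverage test for an endogenous viral element.

    Genomic reads per kb on the target are normalised to reads per kb on a
    single-copy host region (7 kbp by default).  A segregating EVE is
    covered at a rate approaching 1.0x the single-copy rate; coverage below
    ``threshold`` is inconsistent with a genomic copy and indicates the
    reads come from contamination or an active infection instead.
    """
    if target_read_count < 0 or singlecopy_read_count < 0:
        raise ValueError("read counts must be >= 0")
    if target_length <= 0 or singlecopy_length <= 0:
        raise ValueError("lengths must be > 0")
    if singlecopy_read_count == 0:
        return EveVerdict(genome_id, target_id, None, None, threshold)
    coverage = (target_read_count / target_length) / (singlecopy_read_count / singlecopy_length)
    return EveVerdict(genome_id, target_id, coverage, coverage >= threshold, threshold)


def majority_taxonomy(hit_lineages, majority: float = 0.75):
    """Deepest taxon shared by at least a ``majority`` of hit lineages.

    Each lineage is a root-to-leaf list of taxon names.  Ranks are walked
    from the deepest represented level upward; the first rank at which a
    single taxon reaches the majority is returned ("root" if none does).
    """
    lineages = [tuple(lin) for lin in hit_lineages]
    if not lineages:
        raise ValueError("no hit lineages supplied")
    if not (0.5 < majority <= 1.0):
        raise ValueError("majority must be in (0.5, 1]")
    n = len(lineages)
    for depth in range(max(len(lin) for lin in lineages), 0, -1):
        counts = Counter(lin[depth - 1] for lin in lineages if len(lin) >= depth)
        if counts:
            taxon, count = counts.most_common(1)[0]
            if count / n >= majority:
                return taxon
    return "root"
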