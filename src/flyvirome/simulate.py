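"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure the downstream analysis
assumes, with known ground truth returned alongside the data:

* ``gen_virus_reads`` — virus-derived small RNA populations: 21 nt-peaked
  length spectra, configurable strand bias, 5'-base composition,
  non-templated 3'-uridylation, and an optional dominant miRNA-like read
  (as seen for the abundant mature miRNA of a DNA nudivirus).
* ``gen_contig_scenario`` — per-contig count profiles for virus-like
  (siRNA-rich), transposon-like (piRNA-heavy) and mRNA-like
  (degradation-only) contigs.
* ``gen_survey`` — single-fly and pooled RT-PCR assay outcomes at known
  true prevalences, with per-fly Wolbachia co-infection status at a
  configurable odds ratio.
* ``gen_run_table`` — per-sequencing-run virus count tables with planted
  infections at known reads-per-million.

All randomness flows from an explicit seed through one ``numpy`` Generator
per call; identical seeds give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import normalise, revcomp

BASES = ("A", "C", "G", "T")


def _check_prob(x, name):
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {x}")


# ---------------------------------------------------------------------------
# small RNA reads


@dataclass
class VirusReadSpec:
    """Parameters of a simulated virus-derived small RNA population."""

    reference_id: str
    n_reads: int
    length_distribution: dict = field(
        default_factory=lambda: {20: 0.05, 21: 0.7, 22: 0.15, 23: 0.1})
    positive_strand_fraction: float = 0.6
    five_prime_bias: dict = field(
        default_factory=lambda: {"A": 0.3, "C": 0.25, "G": 0.15, "T": 0.3})
    nontemplated_3U_rate: float = 0.0
    dominant_miRNA: tuple | None = None  # (sequence 22 nt, share)
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_distribution sums to {total}, not 1")
        for length, p in self.length_distribution.items():
            if not (17 <= length <= 29):
                raise ValueError(f"read length {length} outside 17-29 nt")
            _check_prob(p, f"length_distribution[{length}]")
        _check_prob(self.positive_strand_fraction, "positive_strand_fraction")
        _check_prob(self.nontemplated_3U_rate, "nontemplated_3U_rate")
        self.five_prime_bias = {normalise(b): p for b, p in self.five_prime_bias.items()}
        total5 = sum(self.five_prime_bias.values())
        if abs(total5 - 1.0) > 1e-9:
            raise ValueError(f"five_prime_bias sums to {total5}, not 1")
        if self.dominant_miRNA is not None:
            seq, share = self.dominant_miRNA
            _check_prob(share, "dominant share")
            if share >= 1:
                raise ValueError("dominant share must be < 1")
            self.dominant_miRNA = (normalise(seq), share)


def gen_virus_reads(spec: VirusReadSpec, reference: str):
    """Simulate small RNA reads from a virus reference.

    Every read is a templated substring of the reference (or its reverse
    complement), apart from the optional non-templated 3' U and the optional
    dominant miRNA sequence.  Returns ``(reads, truth)`` where truth records
    the realised counts for every spec parameter.
    """
    reference = normalise(reference)
    lengths = sorted(spec.length_distribution)
    max_len = max(lengths) if lengths else 0
    if len(reference) < 29 + max_len:
        raise ValueError(
            f"reference too short ({len(reference)} nt) for reads up to {max_len} nt")
    rng = np.random.default_rng(spec.seed)

    # Start positions per (strand, 5' base): on + the 5' base is the
    # reference base at the start; on - it is the complement of the base at
    # the window's far end.
    rc = revcomp(reference)
    positions = {}
    for base in spec.five_prime_bias:
        if spec.five_prime_bias[base] > 0:
            fwd = np.array([i for i in range(len(reference) - max_len + 1)
                            if reference[i] == base], dtype=np.int64)
            rev = np.array([i for i in range(len(rc) - max_len + 1)
                            if rc[i] == base], dtype=np.int64)
            if fwd.size == 0 or rev.size == 0:
                raise ValueError(
                    f"5' bias base {base!r} absent from valid start positions")
            positions[base] = {"+": fwd, "-": rev}

    n = spec.n_reads
    reads = []
    truth = {
        "n_reads": n, "n_dominant": 0, "n_positive_strand": 0,
        "n_nontemplated_3U": 0,
        "length_counts": {length: 0 for length in lengths},
        "five_prime_counts": {b: 0 for b in BASES},
    }
    if n == 0:
        return reads, truth

    probs = np.array([spec.length_distribution[k] for k in lengths])
    bias_bases = sorted(b for b in spec.five_prime_bias if spec.five_prime_bias[b] > 0)
    bias_probs = np.array([spec.five_prime_bias[b] for b in bias_bases])

    dom_seq, dom_share = (None, 0.0)
    if spec.dominant_miRNA is not None:
        dom_seq, dom_share = spec.dominant_miRNA

    is_dom = rng.random(n) < dom_share
    len_draw = rng.choice(len(lengths), size=n, p=probs)
    strand_draw = np.where(rng.random(n) < spec.positive_strand_fraction, "+", "-")
    base_draw = rng.choice(len(bias_bases), size=n, p=bias_probs)
    u_draw = rng.random(n) < spec.nontemplated_3U_rate

    for i in range(n):
        if is_dom[i]:
            seq = dom_seq
            truth["n_dominant"] += 1
        else:
            length = lengths[len_draw[i]]
            strand = strand_draw[i]
            base = bias_bases[base_draw[i]]
            pool = positions[base][strand]
            start = pool[rng.integers(pool.size)]
            src = reference if strand == "+" else rc
            seq = src[start:start + length]
            if strand == "+":
                truth["n_positive_strand"] += 1
            if u_draw[i]:
                seq = seq[:-1] + "T"
                truth["n_nontemplated_3U"] += 1
        truth["length_counts"].setdefault(len(seq), 0)
        truth["length_counts"][len(seq)] += 1
        truth["five_prime_counts"].setdefault(seq[0], 0)
        truth["five_prime_counts"][seq[0]] += 1
        reads.append(seq)
    return reads, truth


# ---------------------------------------------------------------------------
# contig count profiles


@dataclass
class ContigScenarioDefaults:
    """Parameter ranges for the three contig classes.

    Virus-like contigs carry 10-100x more 21-23 nt reads than RNAseq reads
    and almost no 25-29 nt reads; transposon-like contigs are piRNA-heavy;
    mRNA-like contigs carry RNAseq reads only.  The default ranges are wide
    enough that the three classes occupy disjoint regions of the
    log(siRNA:RNAseq) x log(siRNA:piRNA) plane.
    """

    length_range: tuple = (1000, 10000)
    virus_rnaseq_range: tuple = (100, 1000)       # log-uniform
    virus_sirna_ratio_log10: tuple = (1.0, 2.0)    # s = r * 10^U
    virus_pirna_mean: float = 0.5                  # Poisson
    te_pirna_range: tuple = (500, 5000)            # log-uniform
    te_sirna_ratio_log10: tuple = (-1.5, -0.5)     # s = pi * 10^U
    te_rnaseq_range: tuple = (50, 500)
    mrna_rnaseq_range: tuple = (1000, 10000)
    mrna_sirna_mean: float = 1.0
    mrna_pirna_mean: float = 1.0


def _log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def gen_contig_scenario(n_virus: int, n_transposon: int, n_mrna: int, seed: int = 0,
                        params: ContigScenarioDefaults | None = None):
    """Simulate a table of per-contig small-RNA/RNAseq count profiles.

    Returns ``(DataFrame, labels)`` with columns contig_id, length, sirna
    (21-23 nt count), pirna (25-29 nt count), rnaseq, blast_hit, and the
    ground-truth label per row.
    """
    for name, v in (("n_virus", n_virus), ("n_transposon", n_transposon),
                    ("n_mrna", n_mrna)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    p = params or ContigScenarioDefaults()
    rng = np.random.default_rng(seed)
    rows, labels = [], []

    def add(kind, i, s, pi, r):
        rows.append({
            "contig_id": f"{kind}_{i:03d}",
            "length": int(rng.integers(*p.length_range)),
            "sirna": int(s), "pirna": int(pi), "rnaseq": int(r),
            "blast_hit": False,
        })
        labels.append(kind)

    for i in range(n_virus):
        r = _log_uniform(rng, *p.virus_rnaseq_range)
        s = r * 10 ** rng.uniform(*p.virus_sirna_ratio_log10)
        add("virus", i, round(s), rng.poisson(p.virus_pirna_mean), round(r))
    for i in range(n_transposon):
        pi = _log_uniform(rng, *p.te_pirna_range)
        s = pi * 10 ** rng.uniform(*p.te_sirna_ratio_log10)
        add("transposon", i, round(s), round(pi),
            round(_log_uniform(rng, *p.te_rnaseq_range)))
    for i in range(n_mrna):
        add("mrna", i, rng.poisson(p.mrna_sirna_mean), rng.poisson(p.mrna_pirna_mean),
            round(_log_uniform(rng, *p.mrna_rnaseq_range)))

    columns = ["contig_id", "length", "sirna", "pirna", "rnaseq", "blast_hit"]
    return pd.DataFrame(rows, columns=columns), labels


# ---------------------------------------------------------------------------
# field survey assays


@dataclass
class SurveySpec:
    """Design of a simulated field survey.

    ``locations`` lists ``(location_id, species, n_singles, bulk_sizes)``.
    ``true_prevalence`` maps ``(location, species, virus)`` to the underlying
    per-fly carriage probability; ``wolbachia_prevalence`` maps
    ``(location, species)``; ``wolbachia_virus_odds_ratio`` controls the
    per-fly association between virus and Wolbachia carriage (1 =
    independence).
    """

    locations: list
    true_prevalence: dict
    wolbachia_prevalence: dict = field(default_factory=dict)
    wolbachia_virus_odds_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for loc in self.locations:
            _, _, n_singles, bulks = loc
            if n_singles < 0:
                raise ValueError("n_singles must be >= 0")
            if any(k < 1 for k in bulks):
                raise ValueError("bulk sizes must be >= 1")
        for key, pr in self.true_prevalence.items():
            _check_prob(pr, f"true_prevalence[{key}]")
        for key, pr in self.wolbachia_prevalence.items():
            _check_prob(pr, f"wolbachia_prevalence[{key}]")
        if self.wolbachia_virus_odds_ratio <= 0:
            raise ValueError("odds ratio must be > 0")


def joint_cell_probabilities(p_virus: float, p_wolbachia: float, odds_ratio: float):
    """2x2 cell probabilities with the given margins and odds ratio.

    Solves for P(virus+, wolbachia+) analytically: with margins pv, pw and
    odds ratio t, p11 is the root in [max(0, pv+pw-1), min(pv, pw)] of the
    quadratic (t-1) p11^2 - (1 + (pv+pw)(t-1)) p11 + t pv pw = 0.
    """
    pv, pw, t = p_virus, p_wolbachia, odds_ratio
    if t == 1.0:
        p11 = pv * pw
    else:
        a = t - 1.0
        b = -(1.0 + (pv + pw) * a)
        c = t * pv * pw
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("odds ratio incompatible with the margins")
        p11 = (-b - math.sqrt(disc)) / (2 * a)
    lo, hi = max(0.0, pv + pw - 1.0), min(pv, pw)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError("odds ratio incompatible with the margins")
    p11 = min(max(p11, lo), hi)
    p10 = pv - p11
    p01 = pw - p11
    p00 = 1.0 - p11 - p10 - p01
    return p11, p10, p01, p00


def gen_survey(spec: SurveySpec):
    """Simulate single-fly and pooled assay outcomes.

    Every fly's carriage status is drawn individually (jointly with
    Wolbachia when a Wolbachia prevalence is given), so a bulk of k flies is
    positive with probability 1-(1-p)^k by construction.  Returns
    ``(DataFrame of assay records, truth)``; the truth carries the realised
    per-fly 2x2 virus-by-Wolbachia tables for single flies.
    """
    rng = np.random.default_rng(spec.seed)
    viruses = sorted({v for (_, _, v) in spec.true_prevalence})
    rows = []
    truth = {"tables": {}, "n_flies": 0}

    def sample_flies(loc, species, virus, k):
        """Per-fly (virus, wolbachia) status for one assay unit of k flies."""
        pv = spec.true_prevalence.get((loc, species, virus), 0.0)
        pw = spec.wolbachia_prevalence.get((loc, species))
        if pw is None:
            return rng.random(k) < pv, None
        p11, p10, p01, p00 = joint_cell_probabilities(
            pv, pw, spec.wolbachia_virus_odds_ratio)
        cells = rng.choice(4, size=k, p=[p11, p10, p01, p00])
        return np.isin(cells, (0, 1)), np.isin(cells, (0, 2))

    for loc, species, n_singles, bulks in spec.locations:
        for virus in viruses:
            for _ in range(n_singles):
                vstat, wstat = sample_flies(loc, species, virus, 1)
                rows.append((loc, species, virus, 1,
                             "positive" if vstat[0] else "negative"))
                if wstat is not None:
                    tab = truth["tables"].setdefault(
                        (loc, species, virus), np.zeros((2, 2), dtype=int))
                    tab[int(vstat[0]), int(wstat[0])] += 1
                truth["n_flies"] += 1
            for k in bulks:
                vstat, wstat = sample_flies(loc, species, virus, int(k))
                rows.append((loc, species, virus, int(k),
                             "positive" if vstat.any() else "negative"))
                truth["n_flies"] += int(k)

    df = pd.DataFrame(rows, columns=["location", "species", "virus", "k", "outcome"])
    return df, truth


# ---------------------------------------------------------------------------
# sequencing-run count tables


@dataclass
class RunTableSpec:
    """Design of a simulated per-run virus read-count table."""

    n_projects: int = 10
    samples_per_project: int = 3
    runs_per_sample: int = 2
    total_reads_range: tuple = (500_000, 2_000_000)
    infection_rate: float = 0.1
    rpm_when_infected: tuple = (100.0, 10_000.0)  # log-uniform bounds
    viruses: tuple = ("DAV", "DCV", "NoraVirus", "NewfieldVirus")
    noise_mean: float = 0.0  # Poisson mean of mismapped counts
    seed: int = 0

    def __post_init__(self):
        for name in ("n_projects", "samples_per_project", "runs_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        _check_prob(self.infection_rate, "infection_rate")
        if min(self.rpm_when_infected) <= 0:
            raise ValueError("rpm bounds must be positive")


def gen_run_table(spec: RunTableSpec):
    """Simulate a run-count table with planted infections.

    Each (run, virus) pair is infected with probability ``infection_rate``;
    infected pairs get ``round(rpm * total / 1e6)`` reads at a log-uniform
    rpm, others a Poisson(noise_mean) mismapping count.  Returns
    ``(DataFrame, truth)`` with truth listing infected pairs and their rpm.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth = {"infected": {}}
    for p in range(spec.n_projects):
        for s in range(spec.samples_per_project):
            for r in range(spec.runs_per_sample):
                run_id = f"P{p:02d}S{s:02d}R{r:02d}"
                total = int(rng.integers(*spec.total_reads_range))
                row = {"run_id": run_id, "sample_id": f"P{p:02d}S{s:02d}",
                       "project_id": f"P{p:02d}", "total_reads": total}
                for virus in spec.viruses:
                    if rng.random() < spec.infection_rate:
                        rpm = _log_uniform(rng, *spec.rpm_when_infected)
                        count = int(round(rpm * total / 1e6))
                        truth["infected"][(run_id, virus)] = rpm
                    else:
                        count = int(rng.poisson(spec.noise_mean)) if spec.noise_mean > 0 else 0
                    row[virus] = count
                rows.append(row)
    cols = ["run_id", "sample_id", "project_id", "total_reads", *spec.viruses]
    return pd.DataFrame(rows, columns=cols), truth
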