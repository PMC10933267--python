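"""Seeded generators for every input the interactomics pipeline consumes.

The generators emulate the statistical structure of a MAC-tag BioID / AP-MS
screen of nuclear transcription factors:

* GFP control purifications carrying different localization tags
  (untagged ``none``, membrane ``MYR``, nuclear-export ``NES``, nuclear
  ``NLS``), each detecting a background repertoire of contaminant preys
  with prey-specific frequency and low spectral counts;
* bait purifications in a 2 biological x 2 technical replicate design,
  with planted true interactors at elevated PSM counts on top of the same
  background;
* protein sequences with planted nine-amino-acid transactivation-domain
  (9aaTAD) motifs;
* stage-resolved embryonic expression tables with 8-cell-stage peaks;
* genomic fixtures (TSS table, enhancer BED, peak BED) with known
  annotation categories;
* localization-marker reference profiles with compartment-specific prey
  blocks, and bait profiles generated from a planted compartment.

All generators are deterministic under a fixed seed, and every generator
returns a ground-truth table sufficient to score the downstream pipeline
(sensitivity, FDR, recovered positions) without reaching back into
generator internals.

PSM counts follow a negative binomial (gamma-Poisson) law with mean
``lam`` and dispersion ``alpha`` such that ``var = lam + alpha * lam**2``;
``alpha = 0`` degenerates to Poisson. Technical replicates share their
biological replicate's latent abundance and add independent Poisson noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TAG_CLASSES = ("none", "MYR", "NES", "NLS")

#: long-format run table columns (the on-disk TSV layout)
RUN_COLUMNS = [
    "run_id", "bait_id", "is_control", "tag_class",
    "biological_rep", "technical_rep", "prey_id", "psm_count",
]

#: developmental stages covered by the expression generator, in order
STAGES = ("oocyte", "zygote", "2cell", "4cell", "8cell", "morula")

# Approximate human proteome amino-acid frequencies used as sequence
# background (rounded, renormalized at use).
AA_FREQUENCIES = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic BioID/AP-MS screen.

    Defaults mirror the study design being emulated: 21 baits, a GFP
    control compendium of 64 untagged + 24 MYR + 4 NES + 26 NLS runs, and
    two biological x two technical replicates per bait. Planted
    interactors carry a mean of 20 PSMs against a background mean of 1.
    """

    seed: int = 0
    n_baits: int = 21
    n_preys: int = 2000
    n_control_runs: Mapping[str, int] = field(
        default_factory=lambda: {"none": 64, "MYR": 24, "NES": 4, "NLS": 26}
    )
    n_biological: int = 2
    n_technical: int = 2
    true_interactors_per_bait: int = 50
    lambda_true: float = 20.0
    lambda_bg: float = 1.0
    dispersion: float = 0.25
    #: fraction of the prey universe that behaves as background contaminant
    contaminant_fraction: float = 0.3
    #: Beta(a, b) law for per-prey control detection probability
    detection_prob_alpha: float = 0.6
    detection_prob_beta: float = 3.0
    #: fraction of contaminants detectable in a single tag class only
    tag_specific_fraction: float = 0.2
    #: probability that a planted pair's count is zeroed in a replicate
    dropout_rate: float = 0.0
    #: spike the bait protein itself into its own runs (excluded downstream)
    include_bait_self: bool = True

    def __post_init__(self) -> None:
        if self.n_baits <= 0 or self.n_preys <= 0:
            raise ConfigurationError("bait and prey counts must be positive")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if self.true_interactors_per_bait < 0:
            raise ConfigurationError("true-interactor count must be >= 0")
        if self.true_interactors_per_bait > self.n_preys:
            raise ConfigurationError("cannot plant more interactors than preys")
        for key in self.n_control_runs:
            if key not in TAG_CLASSES:
                raise ConfigurationError(f"unknown tag class {key!r}")
            if self.n_control_runs[key] < 0:
                raise ConfigurationError("control run counts must be >= 0")
        for p in (self.contaminant_fraction, self.tag_specific_fraction,
                  self.dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if (self.true_interactors_per_bait > 0
                and self.lambda_true <= self.lambda_bg):
            raise ConfigurationError(
                "lambda_true must exceed lambda_bg when interactors are planted")


def _nb_sample(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial draw with mean/dispersion parameterization."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


def _positive_counts(rng: np.random.Generator, n: int, mean: float,
                     dispersion: float) -> np.ndarray:
    """Zero-truncated NB counts for preys conditioned on being detected."""
    counts = _nb_sample(rng, np.full(n, mean), dispersion)
    return np.maximum(counts, 1)


def generate_runs(config: SimulationConfig, return_background: bool = False):
    """Simulate control and bait purification runs.

    Returns
    -------
    runs : DataFrame
        Long-format table with :data:`RUN_COLUMNS`; only nonzero PSM rows
        are materialized.
    truth : DataFrame
        Every planted (bait_id, prey_id) pair.
    background : DataFrame, only when ``return_background`` is true
        Per-contaminant ground truth (prey_id, detection_prob, tag_class
        with "any" for class-independent contaminants).
    """
    rng = np.random.default_rng(config.seed)
    preys = np.array([f"PREY{i:05d}" for i in range(config.n_preys)])
    baits = [f"BAIT{i:03d}" for i in range(config.n_baits)]

    n_contam = int(round(config.contaminant_fraction * config.n_preys))
    contam_idx = np.arange(n_contam)
    det_prob = rng.beta(config.detection_prob_alpha,
                        config.detection_prob_beta, size=n_contam)
    n_tag_specific = int(round(config.tag_specific_fraction * n_contam))
    tag_of_contam = np.array(["any"] * n_contam, dtype=object)
    if n_tag_specific:
        tag_of_contam[:n_tag_specific] = rng.choice(
            TAG_CLASSES, size=n_tag_specific)

    rows: list[pd.DataFrame] = []

    def emit(run_id, bait_id, is_control, tag_class, bio, tech,
             prey_ids, counts):
        mask = np.asarray(counts) > 0
        if not mask.any():
            return
        rows.append(pd.DataFrame({
            "run_id": run_id, "bait_id": bait_id, "is_control": is_control,
            "tag_class": tag_class, "biological_rep": bio,
            "technical_rep": tech,
            "prey_id": np.asarray(prey_ids)[mask],
            "psm_count": np.asarray(counts)[mask].astype(int),
        }))

    # --- GFP control runs -------------------------------------------------
    for tag in TAG_CLASSES:
        for i in range(config.n_control_runs.get(tag, 0)):
            eligible = (tag_of_contam == "any") | (tag_of_contam == tag)
            detected = eligible & (rng.random(n_contam) < det_prob)
            idx = contam_idx[detected]
            counts = _positive_counts(rng, idx.size, config.lambda_bg,
                                      config.dispersion)
            emit(f"GFP_{tag}_{i:03d}", f"GFP_{tag}", True, tag, 1, 1,
                 preys[idx], counts)

    # --- bait runs ---------------------------------------------------------
    truth_rows = []
    # nuclear baits also see NLS-specific background in their own runs
    bait_eligible = (tag_of_contam == "any") | (tag_of_contam == "NLS")
    for b, bait in enumerate(baits):
        planted = rng.choice(config.n_preys,
                             size=config.true_interactors_per_bait,
                             replace=False)
        planted.sort()
        for p in planted:
            truth_rows.append((bait, preys[p]))
        for bio in range(1, config.n_biological + 1):
            # latent abundance shared by technical replicates
            if config.dispersion > 0:
                latent = rng.gamma(1.0 / config.dispersion,
                                   config.lambda_true * config.dispersion,
                                   size=planted.size)
            else:
                latent = np.full(planted.size, config.lambda_true)
            for tech in range(1, config.n_technical + 1):
                run_id = f"{bait}_b{bio}t{tech}"
                signal = rng.poisson(latent)
                if config.dropout_rate > 0:
                    signal = np.where(
                        rng.random(planted.size) < config.dropout_rate,
                        0, signal)
                detected = bait_eligible & (rng.random(n_contam) < det_prob)
                idx = contam_idx[detected]
                bg = _positive_counts(rng, idx.size, config.lambda_bg,
                                      config.dispersion)
                prey_ids = np.concatenate([preys[planted], preys[idx]])
                counts = np.concatenate([signal, bg])
                if config.include_bait_self:
                    prey_ids = np.concatenate([prey_ids, [bait]])
                    counts = np.concatenate(
                        [counts, [rng.poisson(5 * config.lambda_true) + 1]])
                frame = pd.DataFrame({"prey_id": prey_ids, "psm_count": counts})
                # background may coincide with a planted prey: sum the counts
                frame = frame.groupby("prey_id", as_index=False).sum()
                emit(run_id, bait, False, "bait", bio, tech,
                     frame["prey_id"].to_numpy(),
                     frame["psm_count"].to_numpy())

    if rows:
        runs = pd.concat(rows, ignore_index=True)
    else:
        runs = pd.DataFrame(columns=RUN_COLUMNS)
    runs = runs[RUN_COLUMNS].sort_values(
        ["run_id", "prey_id"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["bait_id", "prey_id"])
    if return_background:
        background = pd.DataFrame({
            "prey_id": preys[contam_idx],
            "detection_prob": det_prob,
            "tag_class": tag_of_contam,
        })
        return runs, truth, background
    return runs, truth


# ---------------------------------------------------------------------------
# sequences with planted 9aaTAD-like motifs
# ---------------------------------------------------------------------------

def generate_sequences(n: int,
                       planted_motifs: Sequence[tuple[int, int, str]] = (),
                       seed: int = 0,
                       length: int = 200):
    """Random protein sequences with motifs planted at known positions.

    Parameters
    ----------
    n : number of sequences.
    planted_motifs : iterable of ``(seq_index, position, motif)`` with
        1-based, inclusive start positions.
    length : length of every sequence.

    Returns
    -------
    records : list of Bio.SeqRecord
    planted : DataFrame with columns seq_id, position, motif
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_FREQUENCIES))
    freqs = np.array(list(AA_FREQUENCIES.values()))
    freqs = freqs / freqs.sum()

    seqs = [rng.choice(letters, size=length, p=freqs) for _ in range(n)]
    planted_rows = []
    for seq_index, position, motif in planted_motifs:
        if not 0 <= seq_index < n:
            raise ValueError(f"sequence index {seq_index} out of range")
        if position < 1 or position - 1 + len(motif) > length:
            raise ValueError(
                f"motif {motif!r} does not fit at position {position} "
                f"in a {length}-mer")
        seqs[seq_index][position - 1: position - 1 + len(motif)] = list(motif)
        planted_rows.append((f"SEQ{seq_index:04d}", position, motif))

    records = [
        SeqRecord(Seq("".join(s)), id=f"SEQ{i:04d}", description="synthetic")
        for i, s in enumerate(seqs)
    ]
    planted = pd.DataFrame(planted_rows,
                           columns=["seq_id", "position", "motif"])
    return records, planted


# ---------------------------------------------------------------------------
# genomic fixtures
# ---------------------------------------------------------------------------

@dataclass
class GenomeFixtureConfig:
    """Layout of the synthetic genome used for peak-annotation fixtures."""

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 3_000_000})
    n_genes: int = 60
    gene_spacing: int = 50_000  # keeps planted categories unambiguous
    peak_width: int = 200
    n_proximal: int = 20       # |TSS distance| <= 1 kb
    n_distal_promoter: int = 15  # 1 kb < |d| <= 3 kb
    n_intergenic: int = 25
    n_enhancers: int = 30
    n_enhancer_peaks: int = 10  # intergenic peaks planted inside enhancers

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ConfigurationError("chromosome lengths must be positive")


def generate_genome_fixtures(config: GenomeFixtureConfig):
    """TSS table, enhancer BED and peak BED with known categories.

    Returns ``(tss, enhancers, peaks, truth)`` DataFrames. ``truth``
    records each peak's intended category and enhancer-overlap flag.
    Peaks are placed on a widely spaced gene grid so the intended
    category is provably the annotated one.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_lengths)

    # genes on a regular grid, alternating strand
    tss_rows = []
    g = 0
    while g < config.n_genes:
        chrom = chroms[g % len(chroms)]
        slot = g // len(chroms)
        pos = config.gene_spacing * (slot + 1)
        if pos >= config.chrom_lengths[chrom] - config.gene_spacing:
            raise ConfigurationError("genome too small for requested genes")
        tss_rows.append((f"GENE{g:04d}", chrom, pos,
                         "+" if g % 2 == 0 else "-"))
        g += 1
    tss = pd.DataFrame(tss_rows,
                       columns=["gene_id", "chrom", "tss_position", "strand"])

    half = config.peak_width // 2

    def peak_at(chrom, midpoint, name):
        start = int(midpoint - half)
        end = int(midpoint + half)
        if start < 0 or end > config.chrom_lengths[chrom]:
            raise ConfigurationError("peak outside chromosome bounds")
        return (chrom, start, end, name)

    peaks, truth = [], []

    def plant(n, category, offset_sampler):
        for i in range(n):
            row = tss.iloc[int(rng.integers(len(tss)))]
            mid = row.tss_position + offset_sampler()
            name = f"{category}_{i:03d}"
            peaks.append(peak_at(row.chrom, mid, name))
            truth.append((name, category, False))

    # |d| <= 1000 (margins keep the midpoint strictly inside the window)
    plant(config.n_proximal, "proximal",
          lambda: int(rng.integers(-900, 901)))
    plant(config.n_distal_promoter, "distal_promoter",
          lambda: int(rng.integers(1200, 2800)) * int(rng.choice([-1, 1])))
    plant(config.n_intergenic, "intergenic",
          lambda: int(rng.integers(10_000, 20_000))
          * int(rng.choice([-1, 1])))

    # enhancers live midway between gene slots, far from every TSS
    enh_rows = []
    for i in range(config.n_enhancers):
        chrom = chroms[i % len(chroms)]
        slot = i % max(1, config.n_genes // len(chroms) - 1)
        center = config.gene_spacing * (slot + 1) + config.gene_spacing // 2
        enh_rows.append((chrom, center - 500, center + 500, f"ENH{i:03d}"))
    enhancers = pd.DataFrame(enh_rows,
                             columns=["chrom", "start", "end", "name"])

    for i in range(min(config.n_enhancer_peaks, len(enh_rows))):
        chrom, start, end, _ = enh_rows[i]
        name = f"enhancer_peak_{i:03d}"
        peaks.append(peak_at(chrom, (start + end) // 2, name))
        truth.append((name, "intergenic", True))

    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end", "name"])
    truth_df = pd.DataFrame(truth,
                            columns=["name", "category", "enhancer_overlap"])
    return tss, enhancers, peaks_df, truth_df


# ---------------------------------------------------------------------------
# stage-resolved expression
# ---------------------------------------------------------------------------

def generate_expression(gene_ids: Sequence[str], seed: int = 0,
                        peak_fraction: float = 0.4,
                        expressed_fraction: float = 0.8) -> pd.DataFrame:
    """Gene x stage RPKM table with 8-cell-stage expression peaks.

    ``expressed_fraction`` of genes are expressed somewhere in the window;
    ``peak_fraction`` of those peak at the 8-cell stage (mimicking
    embryonic genome activation), the rest are flat maternal transcripts.
    Remaining genes are silent (RPKM below 1 everywhere).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in gene_ids:
        expressed = rng.random() < expressed_fraction
        peaks_8c = expressed and rng.random() < peak_fraction
        base = rng.uniform(2, 50) if expressed else rng.uniform(0, 0.5)
        for stage in STAGES:
            if not expressed:
                rpkm = base * rng.uniform(0.5, 1.0)
            elif peaks_8c:
                rpkm = base * (3.0 if stage == "8cell"
                               else rng.uniform(0.05, 0.6))
            else:
                rpkm = base * rng.uniform(0.5, 1.5)
            rows.append((gene, stage, round(float(rpkm), 4)))
    return pd.DataFrame(rows, columns=["gene_id", "stage", "rpkm"])


# ---------------------------------------------------------------------------
# localization-marker reference + bait profiles
# ---------------------------------------------------------------------------

def generate_marker_profiles(
    compartments: Sequence[str] = ("chromatin", "nucleolus", "cytosol",
                                   "plasma_membrane"),
    preys_per_compartment: int = 40,
    n_baits: int = 20,
    seed: int = 0,
    signal: float = 30.0,
    noise_sd: float = 0.3,
):
    """Reference marker profiles plus bait profiles with a planted home.

    Each compartment owns a disjoint block of signature preys with
    log-normal abundance around ``signal``. A bait profile is its planted
    compartment's marker profile perturbed by multiplicative log-normal
    noise, plus a sparse sprinkle of off-compartment preys.

    Returns ``(markers, baits, truth)``: markers as a DataFrame
    (compartment, prey_id, avg_spec), baits as (bait_id, prey_id,
    avg_spec), truth as (bait_id, compartment).
    """
    rng = np.random.default_rng(seed)
    marker_rows = []
    block = {}
    for c, comp in enumerate(compartments):
        prey_ids = [f"MARKERPREY_{comp}_{i:03d}"
                    for i in range(preys_per_compartment)]
        abundance = signal * rng.lognormal(0.0, 0.5, size=len(prey_ids))
        block[comp] = (prey_ids, abundance)
        for pid, a in zip(prey_ids, abundance):
            marker_rows.append((comp, pid, round(float(a), 3)))
    markers = pd.DataFrame(marker_rows,
                           columns=["compartment", "prey_id", "avg_spec"])

    bait_rows, truth_rows = [], []
    for b in range(n_baits):
        home = compartments[b % len(compartments)]
        bait = f"BAIT{b:03d}"
        truth_rows.append((bait, home))
        prey_ids, abundance = block[home]
        noisy = abundance * rng.lognormal(0.0, noise_sd, size=len(prey_ids))
        for pid, a in zip(prey_ids, noisy):
            bait_rows.append((bait, pid, round(float(a), 3)))
        # sparse off-target preys from other compartments
        others = [c for c in compartments if c != home]
        for comp in others:
            pids, _ = block[comp]
            picks = rng.choice(len(pids), size=3, replace=False)
            for k in picks:
                bait_rows.append(
                    (bait, pids[k], round(float(rng.uniform(0.5, 3.0)), 3)))
    baits = pd.DataFrame(bait_rows,
                         columns=["bait_id", "prey_id", "avg_spec"])
    truth = pd.DataFrame(truth_rows, columns=["bait_id", "compartment"])
    return markers, baits, truth
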