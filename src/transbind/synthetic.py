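"""Synthetic genomes, peak sets with planted motifs, and TF embeddings.

Real training data for this problem is a reference genome, one BED file of
ChIP-seq peaks per TF-cell-type experiment, and one protein-language-model
embedding vector per TF. This module fabricates all three with known ground
truth: a random genome of controllable GC content, peaks that carry motif
instances sampled from per-experiment PWMs (written into the genome so
sequence and label agree), and family-structured embedding vectors
(centroid + Gaussian noise) standing in for mean-pooled protein embeddings,
where experiments sharing a motif family share an embedding family.

Everything is a pure function of the :class:`SyntheticSpec`, including its
seed, so tests and examples are reproducible byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .pwm import ALPHABET, PositionWeightMatrix

__all__ = [
    "SyntheticSpec",
    "MotifPlacement",
    "generate_genome",
    "plant_peaks",
    "synth_tf_embeddings",
    "default_motifs",
    "write_fasta",
    "write_bed",
    "write_embeddings_tsv",
    "write_ground_truth_tsv",
    "simulate_to_dir",
]


def default_motifs(n: int, width: int = 8, sharpness: float = 0.9,
                   seed: int = 0) -> list[PositionWeightMatrix]:
    """n distinct near-deterministic motifs: consensus prob `sharpness`,
    remainder split evenly over the other three bases."""
    rng = np.random.default_rng(seed)
    motifs = []
    for m in range(n):
        cons = rng.integers(0, 4, size=width)
        probs = np.full((width, 4), (1.0 - sharpness) / 3.0)
        probs[np.arange(width), cons] = sharpness
        motifs.append(PositionWeightMatrix(f"motif_{m}", probs))
    return motifs


@dataclass
class SyntheticSpec:
    """Study design for one synthetic dataset.

    Defaults mirror the real problem's geometry where it matters downstream:
    200 bp peaks (the bin width used for labeling) and 1280-dimensional TF
    embeddings (the consumed protein-embedding dimension).
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000, "chr2": 60_000}
    )
    n_experiments: int = 2
    motif_pwms: list[PositionWeightMatrix] | None = None
    peaks_per_experiment: int = 100
    peak_width: int = 200
    motif_insert_prob: float = 0.9
    gc_content: float = 0.41  # human genome-wide GC fraction
    embedding_dim: int = 1280
    n_families: int = 2
    within_family_noise: float = 0.1
    # fraction of each experiment's peaks drawn from a family-shared
    # reference set — paralogous TFs bind overlapping site repertoires
    family_peak_share: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if not 0.0 <= self.motif_insert_prob <= 1.0:
            raise ValueError("motif_insert_prob must lie in [0, 1]")
        if not 0.0 <= self.family_peak_share <= 1.0:
            raise ValueError("family_peak_share must lie in [0, 1]")
        if self.n_families < 1:
            raise ValueError("need at least one TF family")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.motif_pwms is None:
            self.motif_pwms = default_motifs(self.n_families, seed=self.seed)
        for pwm in self.motif_pwms:
            if not np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"motif {pwm.name} rows must sum to 1")

    def family_of_experiment(self, e: int) -> int:
        """Experiments are assigned to motif/TF families round-robin."""
        return e % self.n_families

    def experiment_names(self) -> list[str]:
        return [f"exp{e}" for e in range(self.n_experiments)]


@dataclass
class MotifPlacement:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    experiment: str


def generate_genome(spec: SyntheticSpec) -> dict[str, str]:
    """Random genome with the requested GC fraction per chromosome."""
    rng = np.random.default_rng([spec.seed, 1])
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.frombuffer(ALPHABET.encode(), dtype="S1")
    genome = {}
    for chrom, length in spec.chrom_lengths.items():
        idx = rng.choice(4, size=length, p=p)
        genome[chrom] = bases[idx].tobytes().decode()
    return genome


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def plant_peaks(
    genome: dict[str, str], spec: SyntheticSpec
) -> tuple[dict[str, str], dict[str, list[tuple[str, int, int]]], list[MotifPlacement]]:
    """Place peaks and write motif instances into a copy of the genome.

    Returns (mutated genome, {experiment: [(chrom, start, end), ...]},
    ground-truth motif placements). Peaks of one experiment never overlap
    each other (rejection sampling); peaks of different experiments may,
    mirroring multi-TF co-binding. With ``family_peak_share`` > 0 that
    fraction of each experiment's peaks is drawn from a family-shared
    reference set (each reference peak carrying one planted instance), so
    paralogous TFs bind overlapping site repertoires as real TF families
    do; the remaining peaks are placed independently per experiment.
    """
    min_len = min(len(s) for s in genome.values())
    if spec.peak_width > min_len:
        raise ValueError(
            f"peak_width {spec.peak_width} exceeds shortest chromosome {min_len}"
        )
    rng = np.random.default_rng([spec.seed, 2])
    chroms = sorted(genome)
    seqs = {c: list(genome[c]) for c in chroms}
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    def place_one(taken):
        for _attempt in range(1000):
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            max_start = len(genome[chrom]) - spec.peak_width
            start = int(rng.integers(0, max_start + 1))
            end = start + spec.peak_width
            if any(c == chrom and s < end and start < t
                   for c, s, t in taken):
                continue
            taken.append((chrom, start, end))
            return chrom, start, end
        raise RuntimeError(
            "could not place a non-overlapping peak in 1000 attempts; "
            "reduce peaks_per_experiment or enlarge the genome"
        )

    def plant(pwm, peak, exp):
        if rng.random() >= spec.motif_insert_prob:
            return
        chrom, start, end = peak
        site = pwm.sample_site(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = site if strand == "+" else _revcomp(site)
        pos = int(rng.integers(start, end - pwm.width + 1))
        seqs[chrom][pos : pos + pwm.width] = written
        placements.append(
            MotifPlacement(chrom, pos, pos + pwm.width, strand, exp)
        )

    peaks: dict[str, list[tuple[str, int, int]]] = {}
    placements: list[MotifPlacement] = []
    n_shared = int(round(spec.family_peak_share * spec.peaks_per_experiment))
    family_refs: dict[int, list[tuple[str, int, int]]] = {}
    if n_shared > 0:
        for fam in range(spec.n_families):
            taken: list[tuple[str, int, int]] = []
            ref = [place_one(taken) for _ in range(spec.peaks_per_experiment)]
            exps = [x for i, x in enumerate(spec.experiment_names())
                    if spec.family_of_experiment(i) == fam]
            for peak in ref:
                plant(spec.motif_pwms[fam], peak, exps[0] if exps else f"fam{fam}")
            family_refs[fam] = ref
    for e, exp in enumerate(spec.experiment_names()):
        fam = spec.family_of_experiment(e)
        pwm = spec.motif_pwms[fam]
        exp_peaks: list[tuple[str, int, int]] = []
        taken = []
        if n_shared > 0:
            ref = family_refs[fam]
            pick = rng.choice(len(ref), size=min(n_shared, len(ref)),
                              replace=False)
            exp_peaks.extend(ref[i] for i in sorted(pick))
            taken.extend(exp_peaks)
        for _ in range(spec.peaks_per_experiment - len(exp_peaks)):
            peak = place_one(taken)
            exp_peaks.append(peak)
            plant(pwm, peak, exp)
        exp_peaks.sort()
        peaks[exp] = exp_peaks
    mutated = {c: "".join(seqs[c]) for c in chroms}
    return mutated, peaks, placements


def synth_tf_embeddings(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """One embedding per experiment: unit-norm family centroid + noise.

    Experiments carrying the same motif family share a centroid, emulating
    paralogous TFs whose protein embeddings cluster by family.
    """
    rng = np.random.default_rng([spec.seed, 3])
    centroids = rng.normal(size=(spec.n_families, spec.embedding_dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    table = {}
    for e, exp in enumerate(spec.experiment_names()):
        fam = spec.family_of_experiment(e)
        noise = rng.normal(scale=spec.within_family_noise,
                           size=spec.embedding_dim) if spec.within_family_noise > 0 \
            else np.zeros(spec.embedding_dim)
        table[exp] = centroids[fam] + noise
    return table


# ---------------------------------------------------------------------- I/O


def write_fasta(genome: dict[str, str], path: str, width: int = 70):
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: list[tuple[str, int, int]], path: str):
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_embeddings_tsv(table: dict[str, np.ndarray], path: str):
    with open(path, "w") as fh:
        for name, vec in table.items():
            fh.write(name + "\t" + "\t".join(f"{v:.8g}" for v in vec) + "\n")


def write_ground_truth_tsv(placements: list[MotifPlacement], path: str):
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\texperiment\n")
        for p in placements:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.strand}\t{p.experiment}\n")


def simulate_to_dir(spec: SyntheticSpec, out_dir: str) -> dict[str, str]:
    """Run the full generator and write FASTA/BED/TSV artifacts to a directory."""
    os.makedirs(out_dir, exist_ok=True)
    genome = generate_genome(spec)
    genome, peaks, placements = plant_peaks(genome, spec)
    emb = synth_tf_embeddings(spec)
    paths = {"genome": os.path.join(out_dir, "genome.fa")}
    write_fasta(genome, paths["genome"])
    for exp, ivals in peaks.items():
        p = os.path.join(out_dir, f"{exp}.bed")
        write_bed(ivals, p)
        paths[exp] = p
    paths["embeddings"] = os.path.join(out_dir, "tf_embeddings.tsv")
    write_embeddings_tsv(emb, paths["embeddings"])
    paths["ground_truth"] = os.path.join(out_dir, "ground_truth.tsv")
    write_ground_truth_tsv(placements, paths["ground_truth"])
    return paths
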