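"""Genome binning, peak-overlap labeling, windowing, encoding and splitting.

The preparation recipe: tile each chromosome into non-overlapping 200 bp
bins; call a bin positive for an experiment when at least half of it is
covered by that experiment's peaks (union coverage, inclusive threshold);
de-duplicate identical bins by OR-merging their label vectors; extend each
bin by 400 bp of flank to a 1000 bp window, rejecting windows that leave
the chromosome or contain non-ACGT characters; one-hot encode; add the
reverse complement of every window with unchanged labels (binding is
double-stranded); and split by chromosome so that bins from held-out
chromosomes never reach training. An 8-mer Jaccard audit quantifies
residual sequence sharing between splits.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "LabeledBin",
    "SplitSpec",
    "REJECTED",
    "make_bins",
    "read_bed",
    "label_bins",
    "dedup_merge",
    "extend_and_extract",
    "one_hot",
    "reverse_complement",
    "split_by_chromosome",
    "kmer_jaccard_audit",
    "build_dataset",
    "save_dataset",
    "load_dataset",
    "prepare",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

REJECTED = "REJECTED"  # sentinel returned for windows that cannot be used


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LabeledBin:
    interval: GenomicInterval  # the core bin
    labels: np.ndarray  # binary vector over experiments
    window: GenomicInterval | None = None  # the flank-extended context


@dataclass
class SplitSpec:
    """Chromosome-level partition; train is every chromosome not listed."""

    test_chroms: set[str] = field(default_factory=lambda: {"chr8", "chr9"})
    val_chroms: set[str] = field(default_factory=lambda: {"chr7"})
    excluded_chroms: set[str] = field(default_factory=lambda: {"chrY"})

    def __post_init__(self):
        sets = [self.test_chroms, self.val_chroms, self.excluded_chroms]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError(f"split sets overlap: {sets[i] & sets[j]}")

    def assign(self, chrom: str) -> str | None:
        if chrom in self.excluded_chroms:
            return None
        if chrom in self.test_chroms:
            return "test"
        if chrom in self.val_chroms:
            return "val"
        return "train"


def make_bins(chrom_lengths: dict[str, int], bin_size: int) -> list[GenomicInterval]:
    """Tile each chromosome from 0 in steps of bin_size; the trailing
    partial bin is dropped."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = []
    for chrom in chrom_lengths:
        n = chrom_lengths[chrom] // bin_size
        for i in range(n):
            bins.append(GenomicInterval(chrom, i * bin_size, (i + 1) * bin_size))
    return bins


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/abutting intervals; returns (starts, ends) sorted."""
    if not ivals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivals = sorted(ivals)
    starts, ends = [ivals[0][0]], [ivals[0][1]]
    for s, e in ivals[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _coverage_in(starts: np.ndarray, ends: np.ndarray,
                 qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
    """bp of [qs, qe) covered by the merged intervals, vectorized over queries."""
    if len(starts) == 0:
        return np.zeros(len(qs), dtype=np.int64)
    lengths = ends - starts
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def cov_up_to(x):
        # total covered bp in (-inf, x)
        i = np.searchsorted(starts, x, side="right")
        full = cum[np.maximum(i - 1, 0)]
        partial = np.clip(x - starts[np.maximum(i - 1, 0)], 0,
                          lengths[np.maximum(i - 1, 0)])
        return np.where(i > 0, full + partial, 0)

    return cov_up_to(qe) - cov_up_to(qs)


def label_bins(
    bins: list[GenomicInterval],
    peaks_by_experiment: dict[str, list[tuple[str, int, int]]],
    min_overlap_frac: float = 0.5,
) -> np.ndarray:
    """(n_bins, n_experiments) binary matrix; bin positive when union peak
    coverage >= min_overlap_frac of the bin (inclusive)."""
    if not 0.0 < min_overlap_frac <= 1.0:
        raise ValueError("min_overlap_frac must lie in (0, 1]")
    chroms = {b.chrom for b in bins}
    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        by_chrom.setdefault(b.chrom, []).append(i)
    labels = np.zeros((len(bins), len(peaks_by_experiment)), dtype=np.uint8)
    for e, (exp, peaks) in enumerate(peaks_by_experiment.items()):
        peaks_per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, t in peaks:
            if chrom not in chroms:
                logger.warning("experiment %s: peak on unknown chromosome %s skipped",
                               exp, chrom)
                continue
            peaks_per_chrom.setdefault(chrom, []).append((s, t))
        for chrom, ivals in peaks_per_chrom.items():
            starts, ends = _merge_intervals(ivals)
            idx = np.asarray(by_chrom[chrom])
            qs = np.array([bins[i].start for i in idx])
            qe = np.array([bins[i].end for i in idx])
            cov = _coverage_in(starts, ends, qs, qe)
            need = min_overlap_frac * (qe - qs)
            labels[idx[cov >= need], e] = 1
    return labels


def dedup_merge(labeled: list[LabeledBin]) -> list[LabeledBin]:
    """Collapse records with identical intervals, OR-merging label vectors.

    The first instance is retained; later duplicates only contribute labels.
    """
    seen: dict[tuple[str, int, int], LabeledBin] = {}
    out: list[LabeledBin] = []
    for rec in labeled:
        key = (rec.interval.chrom, rec.interval.start, rec.interval.end)
        if key in seen:
            seen[key].labels = np.maximum(seen[key].labels, rec.labels)
        else:
            kept = LabeledBin(rec.interval, rec.labels.copy(), rec.window)
            seen[key] = kept
            out.append(kept)
    return out


def extend_and_extract(bin_: GenomicInterval, genome, flank: int) -> str:
    """Extract genome[start-flank, end+flank); REJECTED when the window
    leaves the chromosome or contains a non-ACGT character.

    `genome` may be a dict of strings or any mapping whose values slice to
    sequence (e.g. a pyfaidx.Fasta).
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    record = genome[bin_.chrom]
    chrom_len = len(record)
    lo, hi = bin_.start - flank, bin_.end + flank
    if lo < 0 or hi > chrom_len:
        return REJECTED
    seq = str(record[lo:hi]).upper()
    if any(c not in _BASE_INDEX for c in seq):
        return REJECTED
    return seq


def one_hot(seq: str) -> np.ndarray:
    """(L, 4) indicator matrix over A, C, G, T."""
    idx = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        if c not in _BASE_INDEX:
            raise ValueError(f"non-ACGT character {c!r} at position {i}")
        idx[i] = _BASE_INDEX[c]
    out = np.zeros((len(seq), 4), dtype=np.uint8)
    out[np.arange(len(seq)), idx] = 1
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def split_by_chromosome(
    labeled: list[LabeledBin], split: SplitSpec
) -> dict[str, list[LabeledBin]]:
    """Assign every bin to train/val/test by chromosome; excluded dropped."""
    out: dict[str, list[LabeledBin]] = {"train": [], "val": [], "test": []}
    for rec in labeled:
        part = split.assign(rec.interval.chrom)
        if part is not None:
            out[part].append(rec)
    return out


def _kmer_presence(seqs: list[str], k: int) -> np.ndarray:
    """(n, 4**k) uint8 presence matrix; k-mers containing N are skipped."""
    n_codes = 4 ** k
    mat = np.zeros((len(seqs), n_codes), dtype=np.uint8)
    for i, seq in enumerate(seqs):
        s = seq.upper()
        idx = np.array([_BASE_INDEX.get(c, -1) for c in s], dtype=np.int64)
        if len(idx) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, k)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        codes = windows[valid] @ (4 ** np.arange(k - 1, -1, -1))
        mat[i, np.unique(codes)] = 1
    return mat


def kmer_jaccard_audit(
    seqs_a: list[str],
    seqs_b: list[str],
    k: int = 8,
    n_samples: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Mean/sd/median pairwise Jaccard similarity of k-mer presence sets.

    Samples `n_samples` sequences without replacement from each side (all of
    them if fewer) and evaluates every cross pair, quantifying how much raw
    sequence content two dataset splits share.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not seqs_a or not seqs_b:
        raise ValueError("empty sequence set")
    rng = np.random.default_rng(seed)

    def sample(seqs):
        if len(seqs) <= n_samples:
            return list(seqs)
        pick = rng.choice(len(seqs), size=n_samples, replace=False)
        return [seqs[i] for i in pick]

    sa, sb = sample(seqs_a), sample(seqs_b)
    A = _kmer_presence(sa, k)
    B = _kmer_presence(sb, k)
    sizes_a = A.sum(axis=1).astype(np.int64)
    sizes_b = B.sum(axis=1).astype(np.int64)
    inter = A.astype(np.float32) @ B.astype(np.float32).T
    union = sizes_a[:, None] + sizes_b[None, :] - inter
    with np.errstate(invalid="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    flat = jac.ravel()
    return {
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        "median": float(np.median(flat)),
        "n_pairs": int(flat.size),
    }


# ----------------------------------------------------------------- datasets


def build_dataset(
    genome,
    peaks_by_experiment: dict[str, list[tuple[str, int, int]]],
    chrom_lengths: dict[str, int],
    bin_size: int = 200,
    flank: int = 400,
    min_overlap_frac: float = 0.5,
    split: SplitSpec | None = None,
    augment: bool = True,
) -> dict:
    """Run the full preparation pipeline on in-memory inputs.

    Returns a dict with per-partition arrays ``X`` (N, window, 4) uint8 and
    ``Y`` (N, E) uint8, the experiment names, and rejection counts. With
    ``augment`` each partition also contains the reverse complement of each
    window carrying the same labels, doubling its size.
    """
    split = split or SplitSpec()
    bins = make_bins(chrom_lengths, bin_size)
    label_mat = label_bins(bins, peaks_by_experiment, min_overlap_frac)
    labeled = [LabeledBin(b, label_mat[i]) for i, b in enumerate(bins)]
    labeled = dedup_merge(labeled)
    parts = split_by_chromosome(labeled, split)
    out = {
        "experiments": list(peaks_by_experiment),
        "bin_size": bin_size,
        "flank": flank,
        "rejected": {},
        "sequences": {},
    }
    for part, recs in parts.items():
        xs, ys, seqs = [], [], []
        rejected = 0
        for rec in recs:
            seq = extend_and_extract(rec.interval, genome, flank)
            if seq == REJECTED:
                rejected += 1
                continue
            seqs.append(seq)
            xs.append(one_hot(seq))
            ys.append(rec.labels)
            if augment:
                rc = reverse_complement(seq)
                seqs.append(rc)
                xs.append(one_hot(rc))
                ys.append(rec.labels)
        out[part] = {
            "X": np.stack(xs) if xs else np.zeros((0, bin_size + 2 * flank, 4), np.uint8),
            "Y": np.stack(ys).astype(np.uint8) if ys else
                 np.zeros((0, len(peaks_by_experiment)), np.uint8),
        }
        out["rejected"][part] = rejected
        out["sequences"][part] = seqs
        if rejected:
            logger.info("%s: rejected %d windows (out of bounds or ambiguous)",
                        part, rejected)
    return out


def save_dataset(dataset: dict, path: str):
    """Persist as HDF5 with per-split X/Y datasets and a JSON provenance attr."""
    import h5py

    with h5py.File(path, "w") as fh:
        for part in ("train", "val", "test"):
            grp = fh.create_group(part)
            grp.create_dataset("X", data=dataset[part]["X"], dtype="uint8",
                               chunks=True, compression="gzip")
            grp.create_dataset("Y", data=dataset[part]["Y"], dtype="uint8",
                               chunks=True, compression="gzip")
        fh.attrs["meta"] = json.dumps(
            {
                "experiments": dataset["experiments"],
                "bin_size": dataset["bin_size"],
                "flank": dataset["flank"],
                "rejected": dataset["rejected"],
            }
        )


def load_dataset(path: str) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta"])
        out.update(meta)
        for part in ("train", "val", "test"):
            out[part] = {"X": fh[part]["X"][...], "Y": fh[part]["Y"][...]}
    return out


def prepare(genome_fasta: str, peaks_dir: str, out_path: str,
            bin_size: int = 200, flank: int = 400,
            min_overlap_frac: float = 0.5, split: SplitSpec | None = None):
    """File-level entry point: FASTA + directory of <experiment>.bed -> HDF5."""
    from pyfaidx import Fasta

    genome = Fasta(genome_fasta)
    chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
    peaks = {}
    for fn in sorted(os.listdir(peaks_dir)):
        if fn.endswith(".bed"):
            peaks[fn[:-4]] = read_bed(os.path.join(peaks_dir, fn))
    if not peaks:
        raise FileNotFoundError(f"no .bed files in {peaks_dir}")
    ds = build_dataset(genome, peaks, chrom_lengths, bin_size, flank,
                       min_overlap_frac, split)
    save_dataset(ds, out_path)
    return ds
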