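"""Per-TF protein features: embedding ingestion, mean pooling, and a
pairwise-identity diversity report.

Embeddings arrive pre-computed (one fixed-length vector per TF, e.g. the
mean-pooled output of a protein language model adapted to DNA-binding
proteins); this package never runs a language model itself. The diversity
report quantifies how much amino-acid sequence redundancy a TF panel
carries, via global (Needleman–Wunsch) alignment of every unordered pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TFRecord",
    "IdentityReport",
    "mean_pool",
    "load_embeddings",
    "save_embeddings",
    "pairwise_identity",
    "read_protein_fasta",
]

# Alignment scheme (EMBOSS-needle-style defaults); pinned here and echoed in
# the report so the identity numbers are reproducible.
ALIGNMENT_SCHEME = {
    "matrix": "BLOSUM62",
    "gap_open": 10.0,
    "gap_extend": 0.5,
    "denominator": "alignment_length",
}


@dataclass
class TFRecord:
    name: str
    embedding: np.ndarray  # length d2
    aa_sequence: str | None = None

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.ndim != 1:
            raise ValueError("embedding must be a vector")
        if not np.isfinite(self.embedding).all():
            raise ValueError(f"non-finite embedding for {self.name}")


@dataclass
class IdentityReport:
    names: list[str]
    matrix: np.ndarray  # percent identity, symmetric, diagonal 100
    scheme: dict

    @property
    def pairs(self) -> np.ndarray:
        iu = np.triu_indices(len(self.names), k=1)
        return self.matrix[iu]

    def summary(self) -> dict[str, float]:
        p = self.pairs
        return {
            "mean": float(p.mean()),
            "median": float(np.median(p)),
            "min": float(p.min()),
            "max": float(p.max()),
            "n_pairs": int(p.size),
        }

    def to_json(self) -> str:
        return json.dumps({"scheme": self.scheme, **self.summary()}, indent=2)


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Collapse an (L, d2) per-residue embedding to one d2 vector by
    averaging over sequence positions."""
    per_residue = np.asarray(per_residue, dtype=float)
    if per_residue.ndim != 2 or per_residue.shape[0] < 1:
        raise ValueError("need an L x d2 matrix with L >= 1")
    return per_residue.mean(axis=0)


def load_embeddings(path: str) -> dict[str, TFRecord]:
    """TSV of `name<TAB>v1..v_d2` -> {name: TFRecord}; ragged rows or
    duplicate names are errors."""
    records: dict[str, TFRecord] = {}
    d2 = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, vals = fields[0], fields[1:]
            if not vals:
                raise ValueError(f"line {ln}: no embedding values")
            if d2 is None:
                d2 = len(vals)
            elif len(vals) != d2:
                raise ValueError(
                    f"line {ln}: expected {d2} values, got {len(vals)}"
                )
            if name in records:
                raise ValueError(f"line {ln}: duplicate TF name {name!r}")
            records[name] = TFRecord(name, np.array([float(v) for v in vals]))
    if not records:
        raise ValueError(f"{path}: no embedding rows")
    return records


def save_embeddings(records: dict[str, TFRecord], path: str):
    with open(path, "w") as fh:
        for name, rec in records.items():
            fh.write(name + "\t" + "\t".join(f"{v:.8g}" for v in rec.embedding) + "\n")


def read_protein_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _global_identity(a: str, b: str, aligner) -> float:
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    identical = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return 100.0 * identical / len(s1)


def pairwise_identity(sequences: dict[str, str]) -> IdentityReport:
    """Percent identity under global alignment for every unordered pair.

    Identity = identical aligned residue pairs / alignment length (gaps
    included in the denominator). BLOSUM62, gap open 10, extend 0.5.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    for n, s in sequences.items():
        if not s:
            raise ValueError(f"empty sequence for {n}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        ALIGNMENT_SCHEME["matrix"]
    )
    aligner.open_gap_score = -ALIGNMENT_SCHEME["gap_open"]
    aligner.extend_gap_score = -ALIGNMENT_SCHEME["gap_extend"]
    n = len(names)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = _global_identity(sequences[names[i]], sequences[names[j]],
                                     aligner)
            mat[i, j] = mat[j, i] = ident
    return IdentityReport(names, mat, dict(ALIGNMENT_SCHEME))
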