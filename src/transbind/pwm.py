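"""Position weight matrices and MEME minimal-format serialization.

A :class:`PositionWeightMatrix` stores a width x 4 probability matrix over
the alphabet A, C, G, T, optionally backed by the integer count matrix it
was estimated from. MEME minimal format is the interchange text format read
by TOMTOM and friends, so learned motifs can be compared against databases
such as JASPAR downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"

__all__ = ["PositionWeightMatrix", "write_meme", "read_meme", "ALPHABET"]


@dataclass
class PositionWeightMatrix:
    name: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    counts: np.ndarray | None = None  # (width, 4) nonnegative, optional
    nsites: int = 20

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM must be width x 4, got {self.probs.shape}")
        if self.probs.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        if np.any(self.probs < 0):
            raise ValueError("PWM probabilities must be nonnegative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.probs.shape:
                raise ValueError("count matrix shape must match probability matrix")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray,
                    pseudocount: float = 0.0) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        smoothed = counts + pseudocount
        totals = smoothed.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("a PWM column has zero total count")
        nsites = int(round(counts.sum(axis=1).max()))
        return cls(name=name, probs=smoothed / totals, counts=counts,
                   nsites=max(nsites, 1))

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def column_total_variation(self, other: "PositionWeightMatrix") -> np.ndarray:
        """Per-column total-variation distance 0.5 * sum |p - q| to another PWM."""
        if other.width != self.width:
            raise ValueError("widths differ")
        return 0.5 * np.abs(self.probs - other.probs).sum(axis=1)

    def reverse_complement(self) -> "PositionWeightMatrix":
        rc = self.probs[::-1, ::-1].copy()
        cc = None if self.counts is None else self.counts[::-1, ::-1].copy()
        return PositionWeightMatrix(self.name + "_rc", rc, cc, self.nsites)

    def sample_site(self, rng: np.random.Generator) -> str:
        idx = [rng.choice(4, p=row) for row in self.probs]
        return "".join(ALPHABET[i] for i in idx)


def _quantize_row(row: np.ndarray, decimals: int = 6) -> np.ndarray:
    """Round to the decimal grid while keeping the row sum exactly 1
    (largest-remainder apportionment), so serialized matrices re-parse as
    valid PWMs without renormalization."""
    scale = 10 ** decimals
    scaled = row * scale
    floor = np.floor(scaled)
    deficit = int(round(scale - floor.sum()))
    if deficit > 0:
        order = np.argsort(-(scaled - floor))
        floor[order[:deficit]] += 1
    return floor / scale


def write_meme(pwms: list[PositionWeightMatrix],
               background: np.ndarray | None = None) -> str:
    """Render PWMs as MEME minimal-format text (version 4)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
        raise ValueError("background must be a length-4 probability vector")
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)),
        "",
    ]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {pwm.nsites} E= 0"
        )
        for row in pwm.probs:
            lines.append(" ".join(f"{v:.6f}" for v in _quantize_row(row)))
        lines.append("")
    return "\n".join(lines)


def read_meme(text: str) -> list[PositionWeightMatrix]:
    """Parse MEME minimal-format text produced by :func:`write_meme`."""
    pwms: list[PositionWeightMatrix] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split(None, 2)[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: missing probability matrix")
            header = lines[i].strip()
            toks = header.split(":", 1)[1].split()  # alength= 4 w= ...
            fields = dict(zip(toks[0::2], toks[1::2]))
            width = int(fields.get("w=", 0))
            nsites = int(float(fields.get("nsites=", 20)))
            rows = []
            i += 1
            while len(rows) < width:
                vals = lines[i].split()
                if vals:
                    rows.append([float(v) for v in vals])
                i += 1
            pwms.append(PositionWeightMatrix(name, np.array(rows),
                                             nsites=nsites))
        else:
            i += 1
    return pwms
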