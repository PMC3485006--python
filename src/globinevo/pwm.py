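"""Position weight matrices: JASPAR PFM parsing, pseudocounts, log-odds.

Counts are smoothed with background-proportional pseudocounts totalling 1.0
per column before normalisation, so all-zero columns become the background
distribution and log-odds stay finite.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM = np.full(4, 0.25)

PSEUDOCOUNT_TOTAL = 1.0


@dataclass
class PWM:
    """A position frequency/weight matrix with background distribution.

    ``probs`` is a 4×w array (rows A, C, G, T) whose columns sum to 1;
    ``log_odds`` is log2(probs / background).
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError(f"PWM {self.name}: expected 4 rows, got {self.probs.shape[0]}")
        if not np.allclose(self.probs.sum(axis=0), 1.0):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError(f"PWM {self.name}: background must be positive")

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount_total: float = PSEUDOCOUNT_TOTAL,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError(f"PWM {name}: expected 4 count rows")
        bg = UNIFORM.copy() if background is None else np.asarray(background, float)
        smoothed = counts + pseudocount_total * bg[:, None]
        probs = smoothed / smoothed.sum(axis=0, keepdims=True)
        return cls(name, probs, bg)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1].copy(), self.background.copy())


def _normalise_jaspar_text(text: str) -> str:
    """Rewrite letter-prefixed rows without brackets into the bracketed dialect."""
    out = []
    for line in text.splitlines():
        stripped = line.strip()
        m = re.match(r"^([ACGTacgt])\s+([\d.\s]+)$", stripped)
        if m and "[" not in stripped:
            out.append(f"{m.group(1).upper()} [ {m.group(2)} ]")
        else:
            out.append(line)
    return "\n".join(out) + "\n"


def read_jaspar_pfm(path, background: np.ndarray | None = None) -> list[PWM]:
    """Read one or more JASPAR-format PFMs (4 rows A/C/G/T per matrix).

    Headers (``>ID name``) are optional for a single bare matrix; counts are
    converted to probabilities with background-proportional pseudocounts.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.lstrip().startswith(">"):
        text = ">matrix1\n" + text
    text = _normalise_jaspar_text(text)
    parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    pwms = []
    for mot in parsed:
        counts = np.array([list(mot.counts[b]) for b in BASES], dtype=float)
        widths = {len(mot.counts[b]) for b in BASES}
        if len(widths) != 1:
            raise ValueError(f"PFM {mot.name}: rows of unequal length")
        name = mot.name or mot.matrix_id or "matrix"
        pwms.append(PWM.from_counts(name, counts, background))
    return pwms


def write_jaspar_pfm(pwms: list[PWM], path, scale: int = 100) -> None:
    """Write PWMs as JASPAR-format count matrices (probabilities × scale)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            counts = np.round(p.probs * scale).astype(int)
            for i, base in enumerate(BASES):
                fh.write(f"{base} [ " + " ".join(str(c) for c in counts[i]) + " ]\n")
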