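"""Residue conservation scoring from multi-species protein alignments.

Per-column conservation is the Jensen-Shannon divergence (log base 2)
between the column's weighted amino-acid distribution and a background
distribution of amino-acid frequencies derived from BLOSUM62, multiplied by
a gap penalty ``(1 - gap_fraction)``. Scores lie in [0, 1]; higher means
more conserved. Optional window smoothing averages neighbouring columns so
that sites embedded in conserved stretches score higher than isolated ones.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "BLOSUM62_BACKGROUND",
    "Alignment",
    "ConservationProfile",
    "AlignmentValidationError",
    "read_alignment",
    "write_alignment",
    "henikoff_weights",
    "column_distribution",
    "jsd_column_score",
    "window_smooth",
    "conservation_profile",
    "score_variant_sites",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = frozenset("-X")  # unknown residues carry no conservation signal

# Amino-acid frequencies from the BLOSUM62 marginals, in AMINO_ACIDS order.
_BG = np.array(
    [0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
     0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072]
)
BLOSUM62_BACKGROUND = _BG / _BG.sum()


class AlignmentValidationError(ValueError):
    pass


@dataclasses.dataclass
class Alignment:
    """Equal-length protein sequences over the 20 amino acids, '-' and 'X'."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentValidationError("ids and rows differ in count")
        if len(self.rows) < 2:
            raise AlignmentValidationError("an alignment needs at least 2 sequences")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise AlignmentValidationError(f"ragged alignment; offending ids: {bad}")
        if self.reference_id not in self.ids:
            raise AlignmentValidationError(
                f"reference {self.reference_id!r} not among sequence ids"
            )
        alphabet = set(AMINO_ACIDS) | GAP_CHARS
        for sid, row in zip(self.ids, self.rows):
            extra = set(row) - alphabet
            if extra:
                raise AlignmentValidationError(f"{sid}: invalid characters {sorted(extra)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def reference_residue_map(self) -> dict[int, int]:
        """Map 1-based reference residue numbers to 0-based column indices."""
        mapping: dict[int, int] = {}
        residue = 0
        for j, ch in enumerate(self.reference_row):
            if ch not in GAP_CHARS:
                residue += 1
                mapping[residue] = j
        return mapping


def read_alignment(path: str | Path, reference_id: str) -> Alignment:
    """Read an aligned FASTA file (ragged inputs raise a validation error)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentValidationError(f"{path}: no FASTA records")
    return Alignment(
        ids=[r.id for r in records],
        rows=[str(r.seq) for r in records],
        reference_id=reference_id,
    )


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(alignment.ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def henikoff_weights(alignment: Alignment) -> np.ndarray:
    """Position-based sequence weights (normalised to sum to 1).

    Each column contributes 1/(r * s) to every sequence carrying symbol s
    there, where r is the number of distinct symbols in the column; gaps
    count as a symbol class so heavily gapped sequences are down-weighted.
    """
    n = alignment.n_sequences
    weights = np.zeros(n)
    for j in range(alignment.length):
        col = alignment.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            weights[i] += 1.0 / (r * counts[ch])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def uniform_weights(alignment: Alignment) -> np.ndarray:
    return np.full(alignment.n_sequences, 1.0 / alignment.n_sequences)


def column_distribution(
    column: str | Sequence[str],
    weights: Sequence[float] | np.ndarray,
    pseudocount: float = 1e-7,
) -> tuple[np.ndarray | None, float]:
    """Weighted amino-acid distribution of one alignment column.

    Returns ``(probabilities over the 20 amino acids, gap_fraction)``.
    Gaps (and 'X') are excluded from the distribution but counted in
    ``gap_fraction``. An all-gap column has no distribution: ``(None, 1.0)``.
    """
    column = "".join(column).upper()
    weights = np.asarray(weights, dtype=float)
    if len(column) != len(weights):
        raise ValueError("column length and weight count differ")
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to 1")
    counts = np.full(len(AMINO_ACIDS), pseudocount, dtype=float)
    gap_weight = 0.0
    for ch, w in zip(column, weights):
        if ch in GAP_CHARS:
            gap_weight += w
        else:
            counts[_AA_INDEX[ch]] += w
    gap_fraction = sum(ch in GAP_CHARS for ch in column) / len(column)
    if gap_fraction == 1.0:
        return None, 1.0
    return counts / counts.sum(), gap_fraction


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_column_score(
    p: np.ndarray | None,
    q: np.ndarray | None = None,
    gap_fraction: float = 0.0,
) -> float:
    """Gap-penalised Jensen-Shannon divergence between column and background.

    With m = (p + q)/2 and base-2 entropies, JSD(p, q) = H(m) - (H(p)+H(q))/2,
    which lies in [0, 1]; the score is JSD * (1 - gap_fraction).
    """
    if p is None or gap_fraction >= 1.0:
        return 0.0
    q = BLOSUM62_BACKGROUND if q is None else np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    for name, dist in (("p", p), ("q", q)):
        if abs(dist.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not normalised (sum={dist.sum()})")
    m = 0.5 * (p + q)
    jsd = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    jsd = min(max(jsd, 0.0), 1.0)  # clip fp noise at the boundaries
    return jsd * (1.0 - gap_fraction)


def window_smooth(
    raw_scores: Sequence[float] | np.ndarray, window: int = 3, lambda_w: float = 0.5
) -> np.ndarray:
    """Blend each column's score with the mean of its neighbours.

    smoothed(i) = (1 - lambda_w) * raw(i) + lambda_w * mean(raw(j), 0 < |j-i| <= window).
    ``window=0`` or ``lambda_w=0`` is the identity; boundary columns average
    over the truncated window.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if window < 0:
        raise ValueError("window must be non-negative")
    if not (0.0 <= lambda_w <= 1.0):
        raise ValueError("lambda_w must lie in [0, 1]")
    if window == 0 or lambda_w == 0.0 or len(raw) < 2:
        return raw.copy()
    smoothed = np.empty_like(raw)
    for i in range(len(raw)):
        lo, hi = max(0, i - window), min(len(raw), i + window + 1)
        neighbours = np.concatenate([raw[lo:i], raw[i + 1 : hi]])
        smoothed[i] = (1 - lambda_w) * raw[i] + lambda_w * neighbours.mean()
    return smoothed


@dataclasses.dataclass
class ConservationProfile:
    """Per-column conservation scores plus the reference residue mapping."""

    alignment: Alignment
    jsd: np.ndarray          # smoothed, reported score per column
    raw_jsd: np.ndarray
    gap_fraction: np.ndarray
    flags: list[list[str]]   # per-column flags: "all-gap", "low-coverage"
    residue_to_column: dict[int, int]

    def to_frame(self):
        """Per-column table (1-based report coordinates)."""
        import pandas as pd

        col_to_res = {c: r for r, c in self.residue_to_column.items()}
        return pd.DataFrame(
            {
                "column": np.arange(1, len(self.jsd) + 1),
                "human_residue": [col_to_res.get(j) for j in range(len(self.jsd))],
                "jsd": self.jsd,
                "raw_jsd": self.raw_jsd,
                "gap_fraction": self.gap_fraction,
                "flags": [";".join(f) for f in self.flags],
            }
        )


GAP_FLAG_THRESHOLD = 0.3  # columns gappier than this are flagged, not dropped


def conservation_profile(
    alignment: Alignment,
    *,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-7,
    weighting: str = "henikoff",
    window: int = 3,
    lambda_w: float = 0.5,
) -> ConservationProfile:
    """Score every column of the alignment."""
    if weighting == "henikoff":
        weights = henikoff_weights(alignment)
    elif weighting == "uniform":
        weights = uniform_weights(alignment)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    n_cols = alignment.length
    raw = np.zeros(n_cols)
    gaps = np.zeros(n_cols)
    flags: list[list[str]] = []
    for j in range(n_cols):
        p, gf = column_distribution(alignment.column(j), weights, pseudocount)
        raw[j] = jsd_column_score(p, background, gf)
        gaps[j] = gf
        f: list[str] = []
        if gf >= 1.0:
            f.append("all-gap")
        elif gf > GAP_FLAG_THRESHOLD:
            f.append("low-coverage")
        flags.append(f)
    smoothed = window_smooth(raw, window=window, lambda_w=lambda_w)
    return ConservationProfile(
        alignment=alignment,
        jsd=smoothed,
        raw_jsd=raw,
        gap_fraction=gaps,
        flags=flags,
        residue_to_column=alignment.reference_residue_map(),
    )


def score_variant_sites(
    profile: ConservationProfile, sites: Iterable[int]
) -> list[dict]:
    """Report conservation at 1-based reference residue positions.

    ``conserved`` is True iff every sequence shows the reference amino acid
    at that column and no sequence is gapped there. Unmappable sites yield
    an ``error`` entry instead of raising.
    """
    aln = profile.alignment
    ref_row = aln.reference_row
    reports: list[dict] = []
    for site in sites:
        col = profile.residue_to_column.get(int(site))
        if col is None:
            reports.append(
                {"residue": int(site), "error": "residue not alignable in reference"}
            )
            continue
        column = aln.column(col)
        ref_aa = ref_row[col]
        conserved = all(ch == ref_aa for ch in column)
        reports.append(
            {
                "residue": int(site),
                "column": col + 1,
                "reference_aa": ref_aa,
                "jsd": float(profile.jsd[col]),
                "gap_fraction": float(profile.gap_fraction[col]),
                "conserved": bool(conserved),
                "flags": list(profile.flags[col]),
            }
        )
    return reports
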