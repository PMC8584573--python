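"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* a three-latent-class predictor-score table whose per-class means and SDs
  default to the published cluster statistics of the real cohort, so that
  cluster-recovery tests run at realistic separations; and
* multi-species protein alignments whose per-column conservation level is
  dialled from uniform-random to fully conserved, with controllable gap
  fraction, for validating the JSD conservation scorer.

Both are deterministic under a seed. Latent class labels are returned (and
written) separately from the score table so pipeline code cannot see them.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .conservation import AMINO_ACIDS, Alignment, BLOSUM62_BACKGROUND
from .variant_table import CohortRow, CohortTable, Consequence, ScorePanel, VariantRecord

__all__ = [
    "ScorePanelSimulationConfig",
    "AlignmentSimulationConfig",
    "DEFAULT_CLASS_PARAMS",
    "SPECIES",
    "simulate_score_table",
    "simulate_alignment",
]

CLASSES = ("pathogenic", "uncertain", "benign")

#: Per-class (mean, SD) per score. Condel, CADD and REVEL use the published
#: per-cluster statistics of the real cohort; MetaLR/MetaSVM group statistics
#: are not published, so their defaults are round values consistent with the
#: packaged table's per-cluster means. JSD defaults reflect that pathogenic
#: clusters sit at more conserved residues.
DEFAULT_CLASS_PARAMS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "metalr": {"pathogenic": (0.75, 0.13), "uncertain": (0.32, 0.15), "benign": (0.21, 0.18)},
    "metasvm": {"pathogenic": (0.77, 0.12), "uncertain": (0.27, 0.17), "benign": (0.31, 0.12)},
    "cadd_phred": {"pathogenic": (25.5, 3.2), "uncertain": (22.8, 3.0), "benign": (13.7, 5.8)},
    "revel": {"pathogenic": (0.809, 0.143), "uncertain": (0.433, 0.154), "benign": (0.086, 0.136)},
    "condel": {"pathogenic": (0.790, 0.186), "uncertain": (0.500, 0.225), "benign": (0.070, 0.117)},
    "jsd": {"pathogenic": (0.77, 0.06), "uncertain": (0.75, 0.06), "benign": (0.66, 0.13)},
}

SCORE_BOUNDS: Mapping[str, tuple[float, float]] = {
    "metalr": (0.0, 1.0),
    "metasvm": (0.0, 1.0),
    "cadd_phred": (0.0, 60.0),
    "revel": (0.0, 1.0),
    "condel": (0.0, 1.0),
    "jsd": (0.0, 1.0),
}

#: The ten species whose orthologues the conservation analysis aligns.
SPECIES = (
    "Homo_sapiens",
    "Pan_troglodytes",
    "Mus_musculus",
    "Rattus_norvegicus",
    "Canis_lupus_familiaris",
    "Equus_caballus",
    "Bos_taurus",
    "Xenopus_tropicalis",
    "Gallus_gallus",
    "Danio_rerio",
)


@dataclasses.dataclass
class ScorePanelSimulationConfig:
    """Three-class truncated-normal score-table generator settings.

    ``class_sizes`` are the (pathogenic, uncertain, benign) counts; the
    defaults are the published five-score-view cluster sizes (24, 27, 32).
    ``noncoding_rows`` adds splice-site rows whose score panels are missing,
    mirroring the real table where only missense rows carry complete panels.
    """

    class_sizes: tuple[int, int, int] = (24, 27, 32)
    class_params: Mapping[str, Mapping[str, tuple[float, float]]] = dataclasses.field(
        default_factory=lambda: DEFAULT_CLASS_PARAMS
    )
    bounds: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: SCORE_BOUNDS
    )
    noncoding_rows: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.class_sizes):
            raise ValueError("class sizes must be >= 1")
        for score, per_class in self.class_params.items():
            for cls, (mean, sd) in per_class.items():
                if sd < 0:
                    raise ValueError(f"{score}/{cls}: SD must be non-negative")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; keeps moments interpretable near bounds."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError(f"degenerate mean {mean} outside [{lo}, {hi}]")
        return np.full(size, mean)
    mass = norm.cdf(hi, mean, sd) - norm.cdf(lo, mean, sd)
    if mass < 1e-3:
        raise ValueError(
            f"infeasible truncation: N({mean}, {sd}^2) has mass {mass:.2e} in [{lo}, {hi}]"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_score_table(
    config: ScorePanelSimulationConfig,
) -> tuple[CohortTable, np.ndarray]:
    """Generate a cohort table of complete panels plus latent class labels.

    Returns ``(table, labels)`` where ``labels`` gives the generating class
    per row ('pathogenic'/'uncertain'/'benign', or '' for the score-free
    non-coding rows). The labels are never stored inside the table.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[CohortRow] = []
    labels: list[str] = []
    idx = 0
    for cls, n in zip(CLASSES, config.class_sizes):
        draws = {
            score: _truncated_normal(
                rng, *config.class_params[score][cls], *config.bounds[score], n
            )
            for score in config.class_params
        }
        for i in range(n):
            idx += 1
            record = VariantRecord(
                gene=f"SIM{idx:03d}",
                transcript=f"NM_{900000 + idx}.1",
                cdna_change=f"c.{100 + 3 * idx}A>G",
                protein_change=f"p.Ala{idx}Val",
                consequence=Consequence.MISSENSE,
                dbsnp_id=f"rs9{idx:06d}",
                novel=False,
            )
            panel = ScorePanel(
                **{score: float(np.clip(draws[score][i], *config.bounds[score]))
                   for score in draws}
            )
            rows.append(CohortRow(record=record, panel=panel))
            labels.append(cls)
    for j in range(config.noncoding_rows):
        idx += 1
        record = VariantRecord(
            gene=f"SIM{idx:03d}",
            transcript=f"NM_{900000 + idx}.1",
            cdna_change=f"c.{100 + 3 * idx}+1G>A",
            protein_change="",
            consequence=Consequence.SPLICE_DONOR,
            dbsnp_id=f"rs9{idx:06d}",
            novel=False,
        )
        rows.append(CohortRow(record=record, panel=ScorePanel()))
        labels.append("")
    return CohortTable(rows), np.asarray(labels)


@dataclasses.dataclass
class AlignmentSimulationConfig:
    """Synthetic aligned-protein generator settings.

    ``conservation`` is the probability that a non-reference sequence carries
    the reference residue at a column (scalar, or one value per column);
    residues not copied from the reference are drawn from the BLOSUM62
    background, as are the reference residues themselves. The reference row
    is never gapped; other rows gap i.i.d. at ``gap_rate``.
    """

    n_species: int = 10
    length: int = 100
    conservation: float | Sequence[float] = 1.0
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        cons = np.atleast_1d(np.asarray(self.conservation, dtype=float))
        if ((cons < 0) | (cons > 1)).any():
            raise ValueError("conservation levels must lie in [0, 1]")
        if not (0.0 <= self.gap_rate <= 1.0):
            raise ValueError("gap rate must lie in [0, 1]")


def simulate_alignment(
    config: AlignmentSimulationConfig,
) -> tuple[Alignment, np.ndarray]:
    """Generate an alignment plus the true per-column conservation levels."""
    rng = np.random.default_rng(config.seed)
    cons = np.broadcast_to(
        np.atleast_1d(np.asarray(config.conservation, dtype=float)), (config.length,)
    ).copy()
    aa = np.array(list(AMINO_ACIDS))
    ref = rng.choice(aa, size=config.length, p=BLOSUM62_BACKGROUND)
    rows = ["".join(ref)]
    for _ in range(config.n_species - 1):
        copy_ref = rng.random(config.length) < cons
        residues = np.where(
            copy_ref, ref, rng.choice(aa, size=config.length, p=BLOSUM62_BACKGROUND)
        )
        gaps = rng.random(config.length) < config.gap_rate
        residues = np.where(gaps, "-", residues)
        rows.append("".join(residues))
    if config.n_species == len(SPECIES):
        ids = list(SPECIES)
    else:
        ids = [SPECIES[0]] + [f"species_{i}" for i in range(1, config.n_species)]
    return Alignment(ids=ids, rows=rows, reference_id=ids[0]), cons
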