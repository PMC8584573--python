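"""Annotated PCD variant cohort table.

One row per variant: gene, HGVS cDNA/protein change, consequence class,
dbSNP id, gnomAD allele frequency, and a panel of in-silico pathogenicity
predictor scores (ranked MetaLR, ranked MetaSVM, PHRED-scaled CADD, ranked
REVEL, Condel) plus a Jensen-Shannon-Divergence residue conservation score
where available. Rows may additionally carry published k-means cluster
colors for the two clustering views (five-score "MDS" view, REVEL-vs-Condel
"Scatter" view).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
import re
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "VariantRecord",
    "ScorePanel",
    "CohortRow",
    "CohortTable",
    "TableDialect",
    "CohortValidationError",
    "HgvsParseError",
    "classify_consequence",
    "read_cohort_table",
    "write_cohort_table",
    "load_packaged_cohort",
    "tally_by_gene",
    "tally_by_consequence",
    "tally_novel",
]


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


class HgvsParseError(ValueError):
    """Raised when an HGVS change string cannot be interpreted."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    INFRAME_DELETION = "inframe_deletion"
    DUPLICATION = "duplication"


CLUSTER_COLORS = ("red", "blue", "green")  # pathogenic / uncertain / benign


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    gene: str
    transcript: str
    cdna_change: str
    protein_change: str
    consequence: Consequence
    dbsnp_id: str = ""
    novel: bool = False
    allele_frequency: float | None = None
    homozygote_reported: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        if self.novel != (self.dbsnp_id == ""):
            raise CohortValidationError(
                f"{self.gene} {self.cdna_change}: novel flag must mirror an "
                f"empty dbSNP id (novel={self.novel}, dbsnp={self.dbsnp_id!r})"
            )
        af = self.allele_frequency
        if af is not None and not (0.0 <= af <= 1.0):
            raise CohortValidationError(
                f"{self.gene} {self.cdna_change}: allele frequency {af} outside [0, 1]"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.cdna_change)


#: valid (inclusive) range per score; CADD is PHRED-scaled, the rest ranked [0, 1]
SCORE_RANGES: Mapping[str, tuple[float, float]] = {
    "jsd": (0.0, 1.0),
    "metalr": (0.0, 1.0),
    "metasvm": (0.0, 1.0),
    "cadd_phred": (0.0, 99.0),
    "revel": (0.0, 1.0),
    "condel": (0.0, 1.0),
}

PREDICTOR_FIELDS = ("metalr", "metasvm", "cadd_phred", "revel", "condel")


@dataclasses.dataclass(frozen=True)
class ScorePanel:
    """Predictor scores for one variant; any field may be missing (None)."""

    jsd: float | None = None
    metalr: float | None = None
    metasvm: float | None = None
    cadd_phred: float | None = None
    revel: float | None = None
    condel: float | None = None
    conserved: bool | None = None  # full cross-species conservation at the site

    def __post_init__(self) -> None:
        for name, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise CohortValidationError(f"{name}={v} outside [{lo}, {hi}]")

    @property
    def is_complete(self) -> bool:
        """True iff all five pathogenicity predictors are present."""
        return all(getattr(self, f) is not None for f in PREDICTOR_FIELDS)


@dataclasses.dataclass(frozen=True)
class CohortRow:
    record: VariantRecord
    panel: ScorePanel
    scatter_label: str | None = None
    mds_label: str | None = None

    def __post_init__(self) -> None:
        for lab in (self.scatter_label, self.mds_label):
            if lab is not None and lab not in CLUSTER_COLORS:
                raise CohortValidationError(f"unknown cluster color {lab!r}")


@dataclasses.dataclass
class CohortTable:
    rows: list[CohortRow]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            key = row.record.key
            if key in seen:
                raise CohortValidationError(f"duplicate variant {key}")
            seen.add(key)
            if (row.scatter_label or row.mds_label) and not row.panel.is_complete:
                raise CohortValidationError(
                    f"{key}: published cluster label on an incomplete score panel"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[CohortRow]:
        return iter(self.rows)

    def complete_rows(self) -> list[CohortRow]:
        return [r for r in self.rows if r.panel.is_complete]


# --- HGVS consequence classification -------------------------------------

_P_SUBST = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|\*|=)$")
_P_FS = re.compile(r"^p\..*fs", re.IGNORECASE)
_P_DEL = re.compile(r"^p\.[A-Z][a-z]{2}\d+(_[A-Z][a-z]{2}\d+)?del$")
_C_INTRON = re.compile(r"^c\.\d+([+-])\d+")
_C_DELDUP = re.compile(r"^c\.(\d+)(?:_(\d+))?(del|dup)([ACGT]*)$")
_C_EXON_DUP = re.compile(r"dup.*exon|exon.*dup", re.IGNORECASE)


def classify_consequence(cdna_change: str, protein_change: str) -> Consequence:
    """Infer the consequence class from HGVS c. / p. strings.

    Protein-level evidence wins when present: stop gains, frameshifts,
    synonymous changes, in-frame deletions, then single-residue
    substitutions. cDNA-only changes are classified by intron offset sign
    (``+`` = donor side, ``-`` = acceptor side), by deletion/duplication
    length modulo 3, or as whole-exon duplications.
    """
    cdna = (cdna_change or "").strip()
    protein = (protein_change or "").strip()
    if not cdna and not protein:
        raise HgvsParseError("both cDNA and protein change are empty")

    if protein:
        if _P_FS.match(protein):
            return Consequence.FRAMESHIFT
        m = _P_SUBST.match(protein)
        if m:
            alt = m.group(3)
            if alt in ("Ter", "*"):
                return Consequence.NONSENSE
            if alt == "=":
                return Consequence.SYNONYMOUS
            return Consequence.MISSENSE
        if _P_DEL.match(protein):
            return Consequence.INFRAME_DELETION
        raise HgvsParseError(f"unrecognised protein change {protein!r}")

    m = _C_INTRON.match(cdna)
    if m:
        return (
            Consequence.SPLICE_DONOR if m.group(1) == "+" else Consequence.SPLICE_ACCEPTOR
        )
    if _C_EXON_DUP.search(cdna):
        return Consequence.DUPLICATION
    m = _C_DELDUP.match(cdna)
    if m:
        start, end, op, seq = m.groups()
        length = len(seq) if seq else (int(end) - int(start) + 1 if end else 1)
        if length % 3 == 0 and op == "del":
            return Consequence.INFRAME_DELETION
        return Consequence.FRAMESHIFT
    raise HgvsParseError(f"unrecognised cDNA change {cdna!r}")


# --- table I/O -------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TableDialect:
    """Header-name mapping and token conventions for the delimited table."""

    sep: str = "\t"
    missing: str = "-"
    true_token: str = "yes"
    columns: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: {
            "gene": "Gene",
            "transcript": "Transcript",
            "cdna_change": "cDNA",
            "protein_change": "Protein",
            "consequence": "Consequence",
            "dbsnp_id": "dbSNP",
            "novel": "Novel",
            "allele_frequency": "Frequency",
            "homozygote_reported": "Homozygote",
            "jsd": "JSD",
            "conserved": "Conserved",
            "metalr": "MetaLR",
            "metasvm": "MetaSVM",
            "cadd_phred": "CADD",
            "revel": "REVEL",
            "condel": "Condel",
            "scatter_label": "Scatter",
            "mds_label": "MDS",
        }
    )
    consequence_labels: Mapping[str, Consequence] = dataclasses.field(
        default_factory=lambda: {
            "Missense": Consequence.MISSENSE,
            "Nonsense": Consequence.NONSENSE,
            "Frameshift": Consequence.FRAMESHIFT,
            "Synonymous": Consequence.SYNONYMOUS,
            "Splice donor": Consequence.SPLICE_DONOR,
            "Splice acceptor": Consequence.SPLICE_ACCEPTOR,
            "Inframe deletion": Consequence.INFRAME_DELETION,
            "Duplication": Consequence.DUPLICATION,
        }
    )


DEFAULT_DIALECT = TableDialect()


def _parse_score(raw: str, name: str, dialect: TableDialect, context: str) -> float | None:
    if raw == "" or raw == dialect.missing:
        return None
    try:
        value = float(raw)
    except ValueError:
        log.warning("%s: malformed %s cell %r treated as missing", context, name, raw)
        return None
    lo, hi = SCORE_RANGES.get(name, (-math.inf, math.inf))
    if not (lo <= value <= hi):
        log.warning(
            "%s: %s=%s outside [%s, %s], treated as missing", context, name, value, lo, hi
        )
        return None
    return value


def read_cohort_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> CohortTable:
    """Read a delimited cohort table into a validated :class:`CohortTable`.

    Malformed score cells are logged and treated as missing; structural
    problems (duplicate variants, labels on incomplete panels) raise
    :class:`CohortValidationError`.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    cols = dialect.columns
    for field in ("gene", "cdna_change", "consequence"):
        if cols[field] not in df.columns:
            raise CohortValidationError(
                f"{path}: required column {cols[field]!r} not found in header"
            )

    def cell(row: pd.Series, field: str) -> str:
        name = cols.get(field)
        if name is None or name not in df.columns:
            return ""
        raw = str(row[name]).strip()
        return "" if raw == dialect.missing else raw

    rows: list[CohortRow] = []
    for _, r in df.iterrows():
        gene, cdna = cell(r, "gene"), cell(r, "cdna_change")
        context = f"{gene} {cdna}"
        cons_raw = cell(r, "consequence")
        if cons_raw in dialect.consequence_labels:
            consequence = dialect.consequence_labels[cons_raw]
        else:
            # fall back to HGVS inference when the printed label is absent
            consequence = classify_consequence(cdna, cell(r, "protein_change"))
        freq_raw = cell(r, "allele_frequency")
        freq = _parse_score(freq_raw, "allele_frequency", dialect, context) if freq_raw else None
        if freq is not None and not (0.0 <= freq <= 1.0):
            log.warning("%s: allele frequency %s outside [0,1], dropped", context, freq)
            freq = None
        record = VariantRecord(
            gene=gene,
            transcript=cell(r, "transcript"),
            cdna_change=cdna,
            protein_change=cell(r, "protein_change"),
            consequence=consequence,
            dbsnp_id=cell(r, "dbsnp_id"),
            novel=cell(r, "novel") == dialect.true_token,
            allele_frequency=freq,
            homozygote_reported=cell(r, "homozygote_reported") == dialect.true_token,
        )
        conserved_raw = cell(r, "conserved")
        panel = ScorePanel(
            jsd=_parse_score(cell(r, "jsd"), "jsd", dialect, context),
            metalr=_parse_score(cell(r, "metalr"), "metalr", dialect, context),
            metasvm=_parse_score(cell(r, "metasvm"), "metasvm", dialect, context),
            cadd_phred=_parse_score(cell(r, "cadd_phred"), "cadd_phred", dialect, context),
            revel=_parse_score(cell(r, "revel"), "revel", dialect, context),
            condel=_parse_score(cell(r, "condel"), "condel", dialect, context),
            conserved=(conserved_raw == dialect.true_token) if conserved_raw else None,
        )
        rows.append(
            CohortRow(
                record=record,
                panel=panel,
                scatter_label=cell(r, "scatter_label").lower() or None,
                mds_label=cell(r, "mds_label").lower() or None,
            )
        )
    return CohortTable(rows)


def write_cohort_table(
    table: CohortTable, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Serialize a cohort table; inverse of :func:`read_cohort_table`."""
    cols = dialect.columns
    inv_cons = {v: k for k, v in dialect.consequence_labels.items()}
    out: list[dict[str, str]] = []
    for row in table:
        rec, panel = row.record, row.panel

        def fmt(v: object) -> str:
            if v is None:
                return dialect.missing
            if isinstance(v, bool):
                return dialect.true_token if v else dialect.missing
            if isinstance(v, float):
                return repr(v)
            return str(v) if str(v) else dialect.missing

        out.append(
            {
                cols["gene"]: rec.gene,
                cols["transcript"]: fmt(rec.transcript),
                cols["cdna_change"]: rec.cdna_change,
                cols["protein_change"]: fmt(rec.protein_change),
                cols["consequence"]: inv_cons[rec.consequence],
                cols["dbsnp_id"]: fmt(rec.dbsnp_id),
                cols["novel"]: fmt(rec.novel),
                cols["allele_frequency"]: fmt(rec.allele_frequency),
                cols["homozygote_reported"]: fmt(rec.homozygote_reported),
                cols["jsd"]: fmt(panel.jsd),
                cols["conserved"]: fmt(panel.conserved),
                cols["metalr"]: fmt(panel.metalr),
                cols["metasvm"]: fmt(panel.metasvm),
                cols["cadd_phred"]: fmt(panel.cadd_phred),
                cols["revel"]: fmt(panel.revel),
                cols["condel"]: fmt(panel.condel),
                cols["scatter_label"]: (row.scatter_label or dialect.missing).capitalize()
                if row.scatter_label
                else dialect.missing,
                cols["mds_label"]: (row.mds_label or dialect.missing).capitalize()
                if row.mds_label
                else dialect.missing,
            }
        )
    pd.DataFrame(out).to_csv(path, sep=dialect.sep, index=False)


def load_packaged_cohort() -> CohortTable:
    """Load the packaged 112-variant PCD cohort fixture."""
    with resources.as_file(
        resources.files("pcd_triage").joinpath("data/pcd_variants.tsv")
    ) as p:
        return read_cohort_table(p)


# --- tallies ----------------------------------------------------------------


def tally_by_gene(table: CohortTable) -> dict[str, int]:
    if not len(table):
        raise CohortValidationError("empty table")
    return dict(Counter(row.record.gene for row in table))


def tally_by_consequence(table: CohortTable) -> dict[Consequence, int]:
    if not len(table):
        raise CohortValidationError("empty table")
    return dict(Counter(row.record.consequence for row in table))


def tally_novel(table: CohortTable) -> int:
    return sum(row.record.novel for row in table)
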