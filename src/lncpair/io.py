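"""Readers, writers and validated containers for the pipeline's standard inputs.

Four inputs drive the analysis: a genes x samples expression matrix of
non-negative normalized values (FPKM-like), a gene catalog separating lncRNAs
from protein-coding genes (GTF or 3-column TSV), a plain-text list of
immune-related gene symbols, and a clinical table with overall-survival
follow-up. Cohort hygiene applied here: patients with missing follow-up or a
survival time below 30 days are excluded before any modelling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ensembl folded several historical lncRNA biotypes into "lncRNA"; accept the
#: older labels too since the GTF vintage in use varies between archives.
LNCRNA_BIOTYPE_ALIASES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)

MIN_FOLLOWUP_DAYS = 30

CLINICAL_COLUMNS = ["patient_id", "os_time_days", "event", "age", "sex", "stage", "t", "n", "m"]


class ParseError(ValueError):
    """Malformed input file (bad cell, missing column, invalid value)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with group labels.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    sample. ``sample_group`` maps every sample to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    sample_group: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParseError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ParseError("duplicate sample identifiers in expression matrix")
        missing = set(self.values.columns) - set(self.sample_group)
        if missing:
            raise ParseError(f"samples without a tumor/normal label: {sorted(missing)[:5]}")
        bad = set(self.sample_group.values()) - {"tumor", "normal"}
        if bad:
            raise ParseError(f"invalid group labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            gi, si = np.argwhere(np.isnan(arr))[0]
            raise ParseError(
                f"non-numeric or missing value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative expression value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_group[s] == group]

    def log2p1(self) -> pd.DataFrame:
        """Expression on the log2(x + 1) scale used for correlation and DE."""
        return np.log2(self.values + 1.0)


@dataclass
class GeneCatalog:
    """gene_id -> (symbol, biotype) with biotype in {lncRNA, protein_coding, other}."""

    records: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ParseError("empty gene catalog")
        for gid, (symbol, biotype) in self.records.items():
            if not symbol:
                raise ParseError(f"empty symbol for gene {gid!r}")
            if biotype not in {"lncRNA", "protein_coding", "other"}:
                raise ParseError(f"invalid biotype {biotype!r} for gene {gid!r}")

    def genes_of_biotype(self, biotype: str) -> set[str]:
        return {g for g, (_, b) in self.records.items() if b == biotype}

    def ids_for_symbols(self, symbols: Iterable[str]) -> set[str]:
        wanted = set(symbols)
        return {g for g, (sym, _) in self.records.items() if sym in wanted}


@dataclass
class ClinicalRecord:
    patient_id: str
    os_time_days: float
    event: int
    age: float
    sex: str
    stage: str
    t_cat: str
    n_cat: str
    m_cat: str


@dataclass
class GeneList:
    """Deduplicated, non-empty set of gene symbols (immune-related genes)."""

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ParseError("empty gene list")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path, group_map: str | Path | Mapping[str, str]
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV; first column gene IDs, header sample IDs.

    ``group_map`` is either a mapping sample_id -> group or a path to a
    two-column TSV (sample_id, group). Duplicate gene rows are collapsed by
    their linear-scale mean with a logged warning; duplicate sample columns
    are an error.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):  # pandas would silently mangle these
        dup = next(h for h in header if header.count(h) > 1)
        raise ParseError(f"duplicate sample identifier {dup!r} in {path.name}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell at gene {df.index[gi]!r}, sample {df.columns[si]!r} "
            f"in {path.name}: {df.iloc[gi, si]!r}"
        )
    if body.index.has_duplicates:
        n_dup = int(body.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean in %s", n_dup, path.name)
        body = body.groupby(level=0, sort=False).mean()
    if not isinstance(group_map, Mapping):
        gm = pd.read_csv(group_map, sep="\t", header=None, names=["sample_id", "group"])
        group_map = dict(zip(gm["sample_id"].astype(str), gm["group"].astype(str)))
    groups = {s: group_map[s] for s in body.columns if s in group_map}
    return ExpressionMatrix(values=body, sample_group=groups)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    expr.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def write_group_map(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.sample_group[s]}\n")


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _classify_biotype(raw: str, lncrna_aliases: frozenset[str]) -> str:
    if raw in lncrna_aliases:
        return "lncRNA"
    if raw == "protein_coding":
        return "protein_coding"
    return "other"


def parse_gene_catalog(
    path: str | Path, lncrna_aliases: frozenset[str] = LNCRNA_BIOTYPE_ALIASES
) -> GeneCatalog:
    """Parse a GTF (feature-type ``gene`` rows only) or a 3-column TSV catalog.

    TSV columns: gene_id, symbol, biotype. GTF rows lacking a gene_id
    attribute are skipped with a warning; an empty result is an error.
    """
    path = Path(path)
    records: dict[str, tuple[str, str]] = {}
    if path.suffix.lower() in {".gtf", ".gff"}:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9 or fields[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                gid = attrs.get("gene_id")
                if not gid:
                    logger.warning("%s:%d gene row without gene_id attribute, skipped", path.name, lineno)
                    continue
                symbol = attrs.get("gene_name", gid)
                biotype = _classify_biotype(attrs.get("gene_biotype", ""), lncrna_aliases)
                records[gid] = (symbol, biotype)
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "symbol", "biotype"], comment="#")
        for row in df.itertuples(index=False):
            records[str(row.gene_id)] = (str(row.symbol), _classify_biotype(str(row.biotype), lncrna_aliases))
    if not records:
        raise ParseError(f"no gene records parsed from {path.name}")
    return GeneCatalog(records=records)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, (symbol, biotype) in catalog.records.items():
            fh.write(f"{gid}\t{symbol}\t{biotype}\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


def read_clinical_table(
    path: str | Path, min_followup_days: int = MIN_FOLLOWUP_DAYS
) -> list[ClinicalRecord]:
    """Read the clinical TSV and apply the short-follow-up exclusion.

    Patients with missing survival time or event, or with os_time_days
    strictly below ``min_followup_days``, are removed (counts logged).
    A time of exactly ``min_followup_days`` is retained.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"clinical table missing required columns: {missing_cols}")
    df["os_time_days"] = pd.to_numeric(df["os_time_days"], errors="coerce")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    valid_event = df["event"].isin([0, 1]) | df["event"].isna()
    if not valid_event.all():
        bad = df.loc[~valid_event, "event"].iloc[0]
        raise ParseError(f"event indicator must be 0 or 1, got {bad!r}")
    n_in = len(df)
    df = df[df["os_time_days"].notna() & df["event"].notna()]
    df = df[df["os_time_days"] >= min_followup_days]
    n_removed = n_in - len(df)
    if n_removed:
        logger.info(
            "clinical filter: removed %d of %d patients (missing follow-up or "
            "os_time < %d days)", n_removed, n_in, min_followup_days,
        )
    records = [
        ClinicalRecord(
            patient_id=str(r.patient_id),
            os_time_days=float(r.os_time_days),
            event=int(r.event),
            age=float(r.age) if pd.notna(r.age) else float("nan"),
            sex=str(r.sex),
            stage=str(r.stage),
            t_cat=str(r.t),
            n_cat=str(r.n),
            m_cat=str(r.m),
        )
        for r in df.itertuples(index=False)
    ]
    return records


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by patient_id (columns as on disk)."""
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "os_time_days": [r.os_time_days for r in records],
            "event": [r.event for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "stage": [r.stage for r in records],
            "t": [r.t_cat for r in records],
            "n": [r.n_cat for r in records],
            "m": [r.m_cat for r in records],
        }
    )
    return df.set_index("patient_id", drop=False)


def write_clinical_table(records: list[ClinicalRecord], path: str | Path) -> None:
    clinical_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene list
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> GeneList:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.add(s)
    return GeneList(symbols=frozenset(symbols))


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(genes.symbols):
            fh.write(s + "\n")
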