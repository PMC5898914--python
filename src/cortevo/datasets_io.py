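"""Readers, writers and ID harmonization for the tabular inputs of the pipeline.

All tables are UTF-8 tab-delimited text with a header row.  Gene sets are
plain one-ID-per-line files.  The 50 primate-specific genes with
progenitor-enriched expression (symbol, occurrence clade, gene-set
membership, origin mechanism, zinc-finger annotation) ship as a packaged
fixture under ``cortevo/data/table1.tsv``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CLADE_LABELS = (
    "Homo",
    "Hominini",
    "Homininae",
    "Hominidae",
    "Hominoidae",
    "Catarrhini",
    "Simiiformes",
    "Haplorrhini",
)

DATASET_NAMES = ("Florio", "Fietz", "Pollen", "Miller", "Johnson")

MECHANISMS = (
    "whole_duplication",
    "partial_duplication",
    "exon_replacement",
    "stop_codon_loss",
    "retroposition",
    "unknown",
)

#: sha256 of the packaged Table 1 fixture; guards against silent edits.
TABLE1_SHA256 = "a1bfe52f21295639973b13fe8bcb8f58bed8b5799ef0f2f6a9eda9c4a2809cb4"


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class RangeError(ValueError):
    """A value violates its declared range; the message names the row."""


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


class UnmappedIDError(KeyError):
    """IDs without a translation under the strict harmonization policy."""


@dataclass(frozen=True)
class GeneRecord:
    """One primate-specific gene as catalogued by the study.

    ``occurrence`` is the primate clade in whose ancestor the gene arose
    (the most recent common ancestor of the species with an intact reading
    frame).  ``homo_sub`` refines human-specific genes by whether they
    predate or postdate the Neandertal–Denisovan split and is only valid
    for ``occurrence == "Homo"``.
    """

    symbol: str
    gene_id: str
    occurrence: str
    homo_sub: str | None = None
    mechanism: str = "unknown"
    dataset_membership: frozenset[str] = field(default_factory=frozenset)
    is_znf: bool = False

    def __post_init__(self) -> None:
        if self.occurrence not in CLADE_LABELS:
            raise ValueError(f"unknown occurrence clade {self.occurrence!r}")
        if (self.occurrence == "Homo") != (self.homo_sub is not None):
            raise ValueError(
                f"{self.symbol}: homo_sub must be set iff occurrence is Homo"
            )
        if self.homo_sub is not None and self.homo_sub not in (
            "before_split",
            "after_split",
        ):
            raise ValueError(f"invalid homo_sub {self.homo_sub!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"invalid mechanism {self.mechanism!r}")
        unknown = self.dataset_membership - set(DATASET_NAMES)
        if unknown:
            raise ValueError(f"unknown dataset names {sorted(unknown)}")


@dataclass(frozen=True)
class GeneSet:
    """A named set of harmonized gene IDs (one screened dataset's output)."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

#: recognised column kinds and their validation ranges
_COLUMN_KINDS = {
    "gene_id": None,
    "label": None,
    "p_value": (0.0, 1.0),
    "abundance": (0.0, None),
    "correlation": (-1.0, 1.0),
    "count": (0, None),
    "number": None,
}


def read_summary_table(path: str | Path, schema: Mapping[str, str]) -> pd.DataFrame:
    """Read a per-dataset gene-level summary table.

    Parameters
    ----------
    path
        TSV file with a header row.
    schema
        Mapping of required column name -> kind, where kind is one of
        ``gene_id``, ``label``, ``p_value``, ``abundance``, ``correlation``,
        ``count`` or ``number``.  Numeric kinds are range-validated and
        violations are reported with the offending row number (1-based,
        counting the header as row 1).
    """
    path = Path(path)
    for kind in schema.values():
        if kind not in _COLUMN_KINDS:
            raise SchemaError(f"unknown column kind {kind!r}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(schema) - set(table.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    out = {}
    for col, kind in schema.items():
        series = table[col]
        if kind in ("gene_id", "label"):
            out[col] = series.astype(str)
            continue
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise RangeError(
                f"{path.name} row {row}: non-numeric value {series[bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        lo_hi = _COLUMN_KINDS[kind]
        if lo_hi is not None:
            lo, hi = lo_hi
            viol = pd.Series(False, index=numeric.index)
            if lo is not None:
                viol |= numeric < lo
            if hi is not None:
                viol |= numeric > hi
            if viol.any():
                row = int(viol.idxmax()) + 2
                raise RangeError(
                    f"{path.name} row {row}: value {numeric[viol.idxmax()]} out of "
                    f"range for {kind} column {col!r}"
                )
        if kind == "count":
            if not (numeric.dropna() == numeric.dropna().round()).all():
                bad2 = numeric != numeric.round()
                row = int(bad2.idxmax()) + 2
                raise RangeError(f"{path.name} row {row}: non-integer count in {col!r}")
            out[col] = numeric.astype("Int64")
        else:
            out[col] = numeric
    return pd.DataFrame(out)


def write_summary_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a summary table as TSV (inverse of :func:`read_summary_table`)."""
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    path = Path(path)
    members = frozenset(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    return GeneSet(name=name or path.stem, members=members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")


def harmonize_gene_ids(
    sets: Iterable[GeneSet],
    id_map: Mapping[str, str],
    policy: str = "drop",
) -> list[GeneSet]:
    """Translate every member ID through ``id_map``.

    Mirrors the conversion of all dataset gene IDs to a single annotation
    release before intersection.  Many-to-one collisions collapse within a
    set (sets cannot hold duplicates).  Unmapped IDs are dropped with a
    warning under ``policy="drop"`` (default) or raise under
    ``policy="strict"``.
    """
    if policy not in ("drop", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    out = []
    for gs in sets:
        unmapped = sorted(m for m in gs.members if m not in id_map)
        if unmapped:
            if policy == "strict":
                raise UnmappedIDError(
                    f"gene set {gs.name!r}: unmapped IDs {unmapped}"
                )
            warnings.warn(
                f"gene set {gs.name!r}: dropping {len(unmapped)} unmapped IDs",
                stacklevel=2,
            )
        out.append(
            GeneSet(
                name=gs.name,
                members=frozenset(id_map[m] for m in gs.members if m in id_map),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Table 1 fixture
# ---------------------------------------------------------------------------


def _fixture_bytes() -> bytes:
    return (resources.files("cortevo") / "data" / "table1.tsv").read_bytes()


def load_table1_fixture(verify: bool = True) -> list[GeneRecord]:
    """Load the packaged catalogue of the 50 primate-specific genes.

    Every record carries at least two dataset memberships (the catalogue is
    defined as genes enriched in at least two of the five screens).
    """
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE1_SHA256:
            raise FixtureIntegrityError(
                f"table1.tsv checksum mismatch: {digest} != {TABLE1_SHA256}"
            )
    records = []
    lines = raw.decode("utf-8").splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        rec = GeneRecord(
            symbol=row["symbol"],
            gene_id=row["gene_id"],
            occurrence=row["occurrence"],
            homo_sub=row["homo_sub"] or None,
            mechanism=row["mechanism"],
            dataset_membership=frozenset(row["datasets"].split(",")),
            is_znf=row["is_znf"] == "1",
        )
        if len(rec.dataset_membership) < 2:
            raise FixtureIntegrityError(
                f"{rec.symbol}: fixture records must belong to >=2 gene sets"
            )
        records.append(rec)
    return records


def fixture_gene_sets(records: Iterable[GeneRecord] | None = None) -> list[GeneSet]:
    """The five dataset membership sets restricted to the catalogued genes."""
    if records is None:
        records = load_table1_fixture()
    records = list(records)
    return [
        GeneSet(
            name=ds,
            members=frozenset(
                r.gene_id for r in records if ds in r.dataset_membership
            ),
        )
        for ds in DATASET_NAMES
    ]


def packaged_tree_path() -> Path:
    """Path to the bundled example primate tree (illustrative branch lengths)."""
    return Path(str(resources.files("cortevo") / "data" / "primate_tree.nwk"))
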