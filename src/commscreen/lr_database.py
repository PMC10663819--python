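"""Ligand-receptor interaction database: records, I/O, merging, family gene sets.

The database is the dictionary the communication scores sum over: each record
is a directed interaction from a ligand complex (1-2 subunit genes) to a
receptor complex (1-3 subunit genes), annotated with a molecule family
(cytokine, chemokine, immune checkpoint, growth factor, cell adhesion, or
other).  Heterodimeric complexes are unordered sets of subunits; the
deduplication key therefore ignores subunit order within a side, while the
ligand->receptor direction is preserved (A->B and B->A are distinct).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = (
    "cytokine",
    "chemokine",
    "immune_checkpoint",
    "growth_factor",
    "cell_adhesion",
    "other",
)

MAX_LIGAND_SUBUNITS = 2
MAX_RECEPTOR_SUBUNITS = 3

#: Case-insensitive aliases seen in curated tables.
_FAMILY_ALIASES = {
    "cytokine": "cytokine",
    "cytokines": "cytokine",
    "chemokine": "chemokine",
    "chemokines": "chemokine",
    "immune checkpoint": "immune_checkpoint",
    "immune checkpoints": "immune_checkpoint",
    "immune_checkpoint": "immune_checkpoint",
    "checkpoint": "immune_checkpoint",
    "growth factor": "growth_factor",
    "growth factors": "growth_factor",
    "growth_factor": "growth_factor",
    "cell adhesion": "cell_adhesion",
    "cell adhesion molecule": "cell_adhesion",
    "cell_adhesion": "cell_adhesion",
    "adhesion": "cell_adhesion",
    "other": "other",
    "unclassified": "other",
    "other/unclassified": "other",
    "notclassified": "other",
}

#: Default column mapping for delimited interaction tables.
DEFAULT_DIALECT = {
    "ligand": ["Ligand 1", "Ligand 2"],
    "receptor": ["Receptor 1", "Receptor 2", "Receptor 3"],
    "family": "Family",
    "subfamily": "Subfamily",
    "id": "Interaction id",
}


class SchemaError(ValueError):
    """Mandatory columns missing from an interaction table."""


class RecordValidationError(ValueError):
    """One or more rows could not be turned into valid interaction records."""


def normalize_family(raw: str | None) -> str:
    """Map a free-text family label onto the controlled vocabulary.

    Unknown labels map to ``other`` with a logged warning.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return "other"
    key = str(raw).strip().lower().replace("-", " ")
    if key in _FAMILY_ALIASES:
        return _FAMILY_ALIASES[key]
    logger.warning("unknown family label %r mapped to 'other'", raw)
    return "other"


def _clean_symbols(symbols: Iterable[str]) -> list[str]:
    """Upper-case, strip, drop blanks, and deduplicate preserving order."""
    out: list[str] = []
    for s in symbols:
        if s is None or (isinstance(s, float) and pd.isna(s)):
            continue
        s = str(s).strip().upper()
        if s and s not in out:
            out.append(s)
    return out


@dataclass(frozen=True)
class InteractionRecord:
    """A directed ligand-complex -> receptor-complex interaction."""

    interaction_id: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    family: str = "other"
    subfamily: str | None = None
    provenance: str = "original"  # or "curated_addition"

    def __post_init__(self) -> None:
        lig = tuple(_clean_symbols(self.ligand_subunits))
        rec = tuple(_clean_symbols(self.receptor_subunits))
        object.__setattr__(self, "ligand_subunits", lig)
        object.__setattr__(self, "receptor_subunits", rec)
        if not lig:
            raise RecordValidationError(f"{self.interaction_id}: no ligand subunit")
        if not rec:
            raise RecordValidationError(f"{self.interaction_id}: no receptor subunit")
        if self.family not in FAMILIES:
            raise RecordValidationError(
                f"{self.interaction_id}: family {self.family!r} not in {FAMILIES}"
            )

    @property
    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        """Dedup key: unordered subunit sets, direction preserved."""
        return (frozenset(self.ligand_subunits), frozenset(self.receptor_subunits))

    @property
    def genes(self) -> set[str]:
        return set(self.ligand_subunits) | set(self.receptor_subunits)

    def label(self) -> str:
        return "+".join(self.ligand_subunits) + " / " + "+".join(self.receptor_subunits)


@dataclass
class InteractionDB:
    """A validated collection of interaction records (the N of the pair score)."""

    records: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple, str] = {}
        for r in self.records:
            if r.key in seen:
                raise RecordValidationError(
                    f"duplicate interaction key: {r.interaction_id} vs {seen[r.key]}"
                )
            seen[r.key] = r.interaction_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.genes
        return out

    def by_id(self, interaction_id: str) -> InteractionRecord:
        for r in self.records:
            if r.interaction_id == interaction_id:
                return r
        raise KeyError(interaction_id)

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form with a fixed column order."""
        rows = []
        for r in self.records:
            lig = list(r.ligand_subunits) + [""] * (MAX_LIGAND_SUBUNITS - len(r.ligand_subunits))
            rec = list(r.receptor_subunits) + [""] * (
                MAX_RECEPTOR_SUBUNITS - len(r.receptor_subunits)
            )
            rows.append(
                {
                    "Interaction id": r.interaction_id,
                    "Ligand 1": lig[0],
                    "Ligand 2": lig[1],
                    "Receptor 1": rec[0],
                    "Receptor 2": rec[1],
                    "Receptor 3": rec[2],
                    "Family": r.family,
                    "Subfamily": r.subfamily or "",
                    "Provenance": r.provenance,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "Interaction id",
                "Ligand 1",
                "Ligand 2",
                "Receptor 1",
                "Receptor 2",
                "Receptor 3",
                "Family",
                "Subfamily",
                "Provenance",
            ],
        )


def read_interaction_table(
    path: str | Path,
    dialect: Mapping | None = None,
    sep: str | None = None,
) -> InteractionDB:
    """Read a delimited ligand-receptor table into a validated database.

    Parameters
    ----------
    path
        CSV or TSV file.  The separator is sniffed from the extension unless
        given explicitly.
    dialect
        Column mapping with keys ``ligand`` (list of subunit columns),
        ``receptor`` (list of subunit columns), ``family`` and optionally
        ``subfamily`` and ``id``.  Defaults to the canonical
        ``Ligand 1/2, Receptor 1/2/3, Family, Subfamily`` layout.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [c for c in d["ligand"] + d["receptor"] if c not in df.columns]
    # At least one subunit column per side and the family column are mandatory.
    if d["ligand"][0] not in df.columns or d["receptor"][0] not in df.columns:
        raise SchemaError(f"missing mandatory columns in {path}: {missing}")
    if d["family"] not in df.columns:
        raise SchemaError(f"missing mandatory column {d['family']!r} in {path}")

    lig_cols = [c for c in d["ligand"] if c in df.columns]
    rec_cols = [c for c in d["receptor"] if c in df.columns]
    id_col = d.get("id")
    sub_col = d.get("subfamily")

    records: list[InteractionRecord] = []
    bad_rows: list[int] = []
    for idx, row in df.iterrows():
        lig = _clean_symbols(row[c] for c in lig_cols)
        rec = _clean_symbols(row[c] for c in rec_cols)
        if not lig or not rec:
            bad_rows.append(int(idx))
            continue
        iid = (
            str(row[id_col]).strip()
            if id_col and id_col in df.columns and str(row[id_col]).strip()
            else "+".join(lig) + "_" + "+".join(rec)
        )
        subfam = None
        if sub_col and sub_col in df.columns and str(row[sub_col]).strip():
            subfam = str(row[sub_col]).strip()
        records.append(
            InteractionRecord(
                interaction_id=iid,
                ligand_subunits=tuple(lig),
                receptor_subunits=tuple(rec),
                family=normalize_family(row[d["family"]]),
                subfamily=subfam,
            )
        )
    if bad_rows:
        raise RecordValidationError(
            f"{path}: rows with no ligand or no receptor symbol: {bad_rows}"
        )
    return InteractionDB(records)


def write_interaction_table(db: InteractionDB, path: str | Path, sep: str = "\t") -> None:
    """Write the canonical table; column order is fixed for reproducible diffs."""
    db.to_frame().to_csv(path, sep=sep, index=False)


def merge_databases(base: InteractionDB, additions: InteractionDB) -> InteractionDB:
    """Union of two databases keyed on unordered subunit sets per side.

    Duplicate keys keep the base record (and are logged); surviving additions
    are stamped ``curated_addition``.
    """
    keys = {r.key for r in base.records}
    merged = list(base.records)
    for r in additions.records:
        if r.key in keys:
            logger.info("merge collision, keeping base record for %s", r.label())
            continue
        keys.add(r.key)
        merged.append(replace(r, provenance="curated_addition"))
    return InteractionDB(merged)


def family_gene_sets(db: InteractionDB) -> dict[str, set[str]]:
    """Per family, the set of genes occurring as any subunit in that family.

    A gene annotated to records of two families appears in both sets.
    """
    sets: dict[str, set[str]] = {}
    for r in db.records:
        sets.setdefault(r.family, set()).update(r.genes)
    return sets


def validate_db(db_or_records: InteractionDB | Iterable[InteractionRecord]) -> list[dict]:
    """Report-only validation: duplicate keys, arity and symbol problems.

    Accepts a raw record iterable so that findings an ``InteractionDB``
    constructor would reject can still be reported.
    """
    records = list(db_or_records.records if isinstance(db_or_records, InteractionDB) else db_or_records)
    findings: list[dict] = []
    seen: dict[tuple, str] = {}
    for r in records:
        if r.key in seen:
            findings.append(
                {
                    "kind": "duplicate_key",
                    "interaction_id": r.interaction_id,
                    "detail": f"same subunit sets as {seen[r.key]}",
                }
            )
        else:
            seen[r.key] = r.interaction_id
        if len(r.ligand_subunits) > MAX_LIGAND_SUBUNITS:
            findings.append(
                {
                    "kind": "ligand_arity",
                    "interaction_id": r.interaction_id,
                    "detail": f"{len(r.ligand_subunits)} ligand subunits (max {MAX_LIGAND_SUBUNITS})",
                }
            )
        if len(r.receptor_subunits) > MAX_RECEPTOR_SUBUNITS:
            findings.append(
                {
                    "kind": "receptor_arity",
                    "interaction_id": r.interaction_id,
                    "detail": f"{len(r.receptor_subunits)} receptor subunits (max {MAX_RECEPTOR_SUBUNITS})",
                }
            )
        for g in r.genes:
            if not g.replace("-", "").replace("_", "").isalnum():
                findings.append(
                    {
                        "kind": "malformed_symbol",
                        "interaction_id": r.interaction_id,
                        "detail": g,
                    }
                )
        if r.family not in FAMILIES:
            findings.append(
                {
                    "kind": "family_vocabulary",
                    "interaction_id": r.interaction_id,
                    "detail": r.family,
                }
            )
    return findings
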