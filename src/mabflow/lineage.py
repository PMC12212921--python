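"""Relational sample-lineage store with UUID provenance.

Every sample state in the antibody-production workflow (a sorted B-cell, a
PCR product, a picked bacterial colony, a transfected HEK well ...) is one
record in one of 19 interrelated tables.  Each record gets a 16-byte unique
identifier on entry, and each downstream table inherits its parents' IDs in
``FK_``-prefixed columns, so any terminal record (e.g. a harvested antibody)
can be traced back to the originating cell sort without duplicating payload
data along the way.

The store is backed by an embedded sqlite database (in-memory by default,
single-file when given a path).  Import/export files are plain UTF-8 CSV
with a header row and ID columns first.
"""

from __future__ import annotations

import logging
import random
import sqlite3
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .errors import (
    HeaderValidationError,
    ReferentialIntegrityError,
    RowValidationError,
    SchemaError,
    UnknownRecordError,
    UnknownTableError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecordID",
    "TableDef",
    "Schema",
    "LineageRecord",
    "default_schema",
    "LineageStore",
]

ID_BYTE_LENGTH = 16


class RecordID:
    """A 16-byte unique record identifier, rendered as a canonical UUID string."""

    __slots__ = ("_uuid",)

    def __init__(self, value: "uuid.UUID | str | bytes | RecordID"):
        if isinstance(value, RecordID):
            self._uuid = value._uuid
        elif isinstance(value, uuid.UUID):
            self._uuid = value
        elif isinstance(value, bytes):
            if len(value) != ID_BYTE_LENGTH:
                raise ValueError(f"record ID must be {ID_BYTE_LENGTH} bytes, got {len(value)}")
            self._uuid = uuid.UUID(bytes=value)
        elif isinstance(value, str):
            self._uuid = uuid.UUID(value)
        else:
            raise TypeError(f"cannot build RecordID from {type(value).__name__}")

    @classmethod
    def new(cls, rng: random.Random | None = None) -> "RecordID":
        """Mint a fresh random 128-bit ID (seedable via ``rng`` for reproducible runs)."""
        if rng is None:
            return cls(uuid.uuid4())
        return cls(rng.getrandbits(128).to_bytes(ID_BYTE_LENGTH, "big"))

    @property
    def bytes(self) -> bytes:
        return self._uuid.bytes

    def __str__(self) -> str:
        return str(self._uuid)

    def __repr__(self) -> str:
        return f"RecordID({str(self._uuid)!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, RecordID):
            return self._uuid == other._uuid
        if isinstance(other, (uuid.UUID, str)):
            try:
                return self._uuid == RecordID(other)._uuid
            except ValueError:
                return False
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._uuid)


@dataclass(frozen=True)
class TableDef:
    """Definition of one lineage table.

    ``fk_fields`` maps each ``FK_``-prefixed column to the parent table it
    references.  ``natural_key`` optionally names payload columns whose value
    combination must be unique — re-registering the same natural key returns
    the existing record instead of creating a twin (e.g. the same bacteria
    plate entered twice).
    """

    name: str
    id_field: str
    fk_fields: Mapping[str, str] = field(default_factory=dict)
    payload_fields: tuple[str, ...] = ()
    natural_key: tuple[str, ...] = ()

    def __post_init__(self):
        for fk in self.fk_fields:
            if not fk.startswith("FK_"):
                raise SchemaError(f"foreign-key column {fk!r} in {self.name} must start with 'FK_'")
        for key_col in self.natural_key:
            if key_col not in self.payload_fields:
                raise SchemaError(
                    f"natural-key column {key_col!r} of {self.name} is not a payload field"
                )

    @property
    def columns(self) -> list[str]:
        """CSV/database column order: own ID, parent IDs, timestamp, payload."""
        return [self.id_field, *self.fk_fields, "created_at", *self.payload_fields]


@dataclass(frozen=True)
class Schema:
    """An ordered set of table definitions forming an acyclic lineage graph."""

    tables: tuple[TableDef, ...]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [t.name for t in self.tables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate table names in schema")
        by_name = {t.name: t for t in self.tables}
        id_fields = [t.id_field for t in self.tables]
        if len(set(id_fields)) != len(id_fields):
            raise SchemaError("table ID field names must be unique across the schema")
        for t in self.tables:
            for fk, parent in t.fk_fields.items():
                if parent not in by_name:
                    raise SchemaError(
                        f"table {t.name!r}: foreign key {fk!r} references unknown table {parent!r}"
                    )
        # cycle check over the table graph (parent -> child)
        visiting: set[str] = set()
        done: set[str] = set()

        def visit(name: str) -> None:
            if name in done:
                return
            if name in visiting:
                raise SchemaError(f"cycle in schema involving table {name!r}")
            visiting.add(name)
            for parent in by_name[name].fk_fields.values():
                visit(parent)
            visiting.discard(name)
            done.add(name)

        for t in self.tables:
            visit(t.name)

    def __getitem__(self, name: str) -> TableDef:
        for t in self.tables:
            if t.name == name:
                return t
        raise UnknownTableError(f"no table named {name!r} in schema")

    def __contains__(self, name: str) -> bool:
        return any(t.name == name for t in self.tables)

    def __len__(self) -> int:
        return len(self.tables)

    @property
    def roots(self) -> list[str]:
        return [t.name for t in self.tables if not t.fk_fields]

    def extend(self, new_table: TableDef) -> "Schema":
        """Return a new schema with ``new_table`` appended (FKs must resolve)."""
        return Schema(tables=(*self.tables, new_table))


@dataclass(frozen=True)
class LineageRecord:
    """One stored record: its table, ID, parent links, payload and timestamp."""

    table: str
    id: RecordID
    fk_values: dict[str, RecordID]
    payload: dict[str, object]
    created_at: str


def default_schema() -> Schema:
    """The packaged 19-table antibody-production schema.

    Six tables carry the documented key fields of the plating/picking,
    plasmid working-stock/safe-stock and transfection/harvested-antibody
    excerpts; the remaining tables are named after the wet-lab workflow
    steps (FACS sorting through antibody quantification).  The root is the
    FACS table, which carries the donor identity in its payload.
    """
    t = [
        TableDef("FACS", "FACS_ID", {},
                 ("donor_id", "plate_barcode", "well"), ()),
        TableDef("cDNA", "cDNA_ID", {"FK_FACS_ID": "FACS"},
                 ("plate_barcode", "well")),
        TableDef("PCR1", "PCR1_ID", {"FK_cDNA_ID": "cDNA"},
                 ("chain", "plate_barcode", "well")),
        TableDef("PCR2", "PCR2_ID", {"FK_PCR1_ID": "PCR1"},
                 ("plate_barcode", "well")),
        TableDef("cELE1", "cELE1_ID", {"FK_PCR2_ID": "PCR2"},
                 ("band_size_bp", "status")),
        TableDef("SEQ1", "SEQ1_ID", {"FK_cELE1_ID": "cELE1"},
                 ("v_allele", "j_allele", "evaluation")),
        TableDef("PCR3", "PCR3_ID", {"FK_SEQ1_ID": "SEQ1"},
                 ("plate_barcode", "well", "forward_primer", "reverse_primer")),
        TableDef("cELE2", "cELE2_ID", {"FK_PCR3_ID": "PCR3"},
                 ("band_size_bp", "status")),
        TableDef("GiAs", "GiAs_ID", {"FK_cELE2_ID": "cELE2"},
                 ("plate_barcode", "well")),
        TableDef("TRFO", "TRFO_ID", {"FK_GiAs_ID": "GiAs"},
                 ("plate_barcode", "well")),
        TableDef("Plating", "Plating_ID", {"FK_TRFO_ID": "TRFO"},
                 ("plate_barcode",), natural_key=("plate_barcode",)),
        TableDef("Picking", "Picking_ID", {"FK_Plating_ID": "Plating"},
                 ("colony_number",)),
        TableDef("Glyc", "Glyc_ID", {"FK_Picking_ID": "Picking"},
                 ("location",)),
        TableDef("Working_Stock", "Working_Stock_ID", {"FK_Picking_ID": "Picking"},
                 ("chain", "concentration_ng_ul", "seq2_status")),
        TableDef("Safe_Stock", "Safe_Stock_ID", {"FK_Working_Stock_ID": "Working_Stock"},
                 ("location",)),
        TableDef("ConcAdj", "ConcAdj_ID", {"FK_Working_Stock_ID": "Working_Stock"},
                 ("stock_volume_ul", "diluent_volume_ul", "final_ng_ul")),
        TableDef("Transfection", "Transfection_ID",
                 {"FK_Heavy_Working_Stock_ID": "Working_Stock",
                  "FK_Light_Working_Stock_ID": "Working_Stock"},
                 ("plate_barcode", "well")),
        TableDef("AB", "AB_ID", {"FK_Transfection_ID": "Transfection"},
                 ("harvest_date",)),
        TableDef("quant", "Quant_ID", {"FK_AB_ID": "AB"},
                 ("concentration_ug_ml",)),
    ]
    return Schema(tables=tuple(t))


def _default_clock() -> str:
    return datetime.now(timezone.utc).isoformat()


class LineageStore:
    """Embedded relational store over a :class:`Schema`.

    Parameters
    ----------
    schema : Schema, optional
        Defaults to the packaged 19-table schema.
    path : str or Path
        sqlite location; ``":memory:"`` (default) keeps the store in RAM.
    id_rng : random.Random, optional
        Seedable source for record IDs; fresh random UUIDs when omitted.
    clock : callable, optional
        Returns the ``created_at`` ISO-8601 string; injectable so generated
        datasets are byte-reproducible.
    """

    def __init__(
        self,
        schema: Schema | None = None,
        path: str | Path = ":memory:",
        id_rng: random.Random | None = None,
        clock: Callable[[], str] | None = None,
    ):
        self.schema = schema if schema is not None else default_schema()
        self._conn = sqlite3.connect(str(path))
        self._id_rng = id_rng
        self._clock = clock or _default_clock
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS _registry (id TEXT PRIMARY KEY, table_name TEXT NOT NULL)"
        )
        for t in self.schema.tables:
            self._create_table(t)

    # -- schema plumbing ---------------------------------------------------

    def _create_table(self, t: TableDef) -> None:
        cols = [f'"{t.id_field}" TEXT PRIMARY KEY']
        cols += [f'"{fk}" TEXT NOT NULL' for fk in t.fk_fields]
        cols.append('"created_at" TEXT NOT NULL')
        cols += [f'"{p}" TEXT' for p in t.payload_fields]
        self._conn.execute(f'CREATE TABLE IF NOT EXISTS "{t.name}" ({", ".join(cols)})')

    def extend_schema(self, new_table: TableDef) -> Schema:
        """Add a table (e.g. a functional-assay readout keyed on AB_ID).

        Existing data is untouched; the new table's foreign keys must
        reference tables already in the schema.
        """
        self.schema = self.schema.extend(new_table)
        self._create_table(new_table)
        return self.schema

    # -- registration ------------------------------------------------------

    def register(
        self,
        table: str,
        payload: Mapping[str, object] | None = None,
        parents: Mapping[str, "RecordID | str"] | None = None,
    ) -> RecordID:
        """Create one record; returns its fresh 16-byte ID.

        All of the table's declared FK columns must be supplied in
        ``parents`` and resolve to existing records of the right table.
        If the table declares a natural key and a record with the same key
        already exists, that record's ID is returned with a warning instead
        of creating a duplicate row.
        """
        tdef = self.schema[table]
        payload = dict(payload or {})
        parents = {k: RecordID(v) for k, v in (parents or {}).items()}

        unknown = set(payload) - set(tdef.payload_fields)
        if unknown:
            raise SchemaError(f"unknown payload fields for {table}: {sorted(unknown)}")
        missing_fk = set(tdef.fk_fields) - set(parents)
        if missing_fk:
            raise ReferentialIntegrityError(
                f"{table} requires parent IDs for: {sorted(missing_fk)}"
            )
        extra_fk = set(parents) - set(tdef.fk_fields)
        if extra_fk:
            raise ReferentialIntegrityError(
                f"{table} does not declare foreign keys: {sorted(extra_fk)}"
            )
        for fk, parent_id in parents.items():
            parent_table = tdef.fk_fields[fk]
            if not self._exists(parent_table, parent_id):
                raise ReferentialIntegrityError(
                    f"{table}.{fk}: no record {parent_id} in table {parent_table!r}"
                )

        if tdef.natural_key:
            existing = self._find_by_natural_key(tdef, payload)
            if existing is not None:
                logger.warning(
                    "%s with natural key %s already registered; returning existing ID %s",
                    table,
                    {k: payload.get(k) for k in tdef.natural_key},
                    existing,
                )
                return existing

        rid = self._fresh_id()
        row = {tdef.id_field: str(rid)}
        row.update({fk: str(v) for fk, v in parents.items()})
        row["created_at"] = self._clock()
        row.update({p: payload.get(p) for p in tdef.payload_fields})
        self._insert(tdef, row)
        return rid

    def _fresh_id(self) -> RecordID:
        while True:
            rid = RecordID.new(self._id_rng)
            if self._conn.execute(
                "SELECT 1 FROM _registry WHERE id = ?", (str(rid),)
            ).fetchone() is None:
                return rid

    def _insert(self, tdef: TableDef, row: Mapping[str, object]) -> None:
        cols = tdef.columns
        self._conn.execute(
            f'INSERT INTO "{tdef.name}" ({", ".join(f_quote(c) for c in cols)}) '
            f'VALUES ({", ".join("?" for _ in cols)})',
            [_to_db(row.get(c)) for c in cols],
        )
        self._conn.execute(
            "INSERT INTO _registry (id, table_name) VALUES (?, ?)",
            (str(row[tdef.id_field]), tdef.name),
        )

    def _exists(self, table: str, rid: RecordID) -> bool:
        tdef = self.schema[table]
        return self._conn.execute(
            f'SELECT 1 FROM "{tdef.name}" WHERE "{tdef.id_field}" = ?', (str(rid),)
        ).fetchone() is not None

    def _find_by_natural_key(self, tdef: TableDef, payload: Mapping) -> RecordID | None:
        conds = " AND ".join(f'"{k}" IS ?' for k in tdef.natural_key)
        row = self._conn.execute(
            f'SELECT "{tdef.id_field}" FROM "{tdef.name}" WHERE {conds}',
            [_to_db(payload.get(k)) for k in tdef.natural_key],
        ).fetchone()
        return RecordID(row[0]) if row else None

    # -- retrieval ---------------------------------------------------------

    def table_of(self, rid: "RecordID | str") -> str:
        row = self._conn.execute(
            "SELECT table_name FROM _registry WHERE id = ?", (str(RecordID(rid)),)
        ).fetchone()
        if row is None:
            raise UnknownRecordError(f"no record with ID {rid}")
        return row[0]

    def get(self, rid: "RecordID | str") -> LineageRecord:
        rid = RecordID(rid)
        tdef = self.schema[self.table_of(rid)]
        cur = self._conn.execute(
            f'SELECT {", ".join(f_quote(c) for c in tdef.columns)} '
            f'FROM "{tdef.name}" WHERE "{tdef.id_field}" = ?',
            (str(rid),),
        )
        row = dict(zip(tdef.columns, cur.fetchone()))
        return LineageRecord(
            table=tdef.name,
            id=rid,
            fk_values={fk: RecordID(row[fk]) for fk in tdef.fk_fields},
            payload={p: row[p] for p in tdef.payload_fields},
            created_at=row["created_at"],
        )

    def count(self, table: str) -> int:
        tdef = self.schema[table]
        return self._conn.execute(f'SELECT COUNT(*) FROM "{tdef.name}"').fetchone()[0]

    def children_of(self, rid: "RecordID | str", child_table: str) -> list[RecordID]:
        """IDs of records in ``child_table`` whose FKs point at ``rid``."""
        rid = RecordID(rid)
        parent_table = self.table_of(rid)
        tdef = self.schema[child_table]
        fks = [fk for fk, pt in tdef.fk_fields.items() if pt == parent_table]
        out: list[RecordID] = []
        for fk in fks:
            for (val,) in self._conn.execute(
                f'SELECT "{tdef.id_field}" FROM "{tdef.name}" WHERE "{fk}" = ?', (str(rid),)
            ):
                out.append(RecordID(val))
        return out

    # -- lineage -----------------------------------------------------------

    def trace_lineage(self, rid: "RecordID | str") -> list[LineageRecord]:
        """Full ancestor chain of a record, root-first, the record itself last.

        Walks every FK edge upward, deduplicates shared ancestors, and
        returns a topological order (every parent precedes its children).
        A transfection record therefore yields exactly two plasmid
        working-stock ancestors, one heavy and one light.
        """
        start = RecordID(rid)
        records: dict[RecordID, LineageRecord] = {}
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur in records:
                continue
            rec = self.get(cur)
            records[cur] = rec
            stack.extend(rec.fk_values.values())

        # Kahn's algorithm on the ancestor subgraph, ties broken by
        # (created_at, id) for a stable order.
        children: dict[RecordID, list[RecordID]] = {r: [] for r in records}
        indeg = {r: 0 for r in records}
        for rec in records.values():
            for parent in rec.fk_values.values():
                children[parent].append(rec.id)
                indeg[rec.id] += 1
        ready = sorted(
            (r for r, d in indeg.items() if d == 0),
            key=lambda r: (records[r].created_at, str(r)),
        )
        out: list[LineageRecord] = []
        while ready:
            cur = ready.pop(0)
            out.append(records[cur])
            for ch in children[cur]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    ready.append(ch)
            ready.sort(key=lambda r: (records[r].created_at, str(r)))
        return out

    def ancestors_in(self, rid: "RecordID | str", table: str) -> list[LineageRecord]:
        """Ancestors of ``rid`` (including itself) that live in ``table``."""
        return [r for r in self.trace_lineage(rid) if r.table == table]

    # -- import / export ---------------------------------------------------

    def export_table(self, table: str, path: str | Path, where: Callable[[LineageRecord], bool] | None = None) -> int:
        """Write a table to a CSV database-export file; returns the row count."""
        tdef = self.schema[table]
        df = pd.read_sql_query(
            f'SELECT {", ".join(f_quote(c) for c in tdef.columns)} FROM "{tdef.name}"',
            self._conn,
        )
        if where is not None:
            keep = [where(self.get(v)) for v in df[tdef.id_field]]
            df = df[keep]
        df.to_csv(path, index=False)
        return len(df)

    def import_file(self, path: str | Path) -> list[RecordID]:
        """Import a database export file, auto-detecting its table.

        The header must match the table's configured columns exactly.  The
        import is transactional: rows with an empty ID, a dangling FK, or an
        ID that already exists with a different payload reject the whole
        file with a per-row report.  Rows identical to already-stored
        records are skipped (idempotent re-import).
        """
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        header = list(df.columns)
        tdef = self._detect_table(header, path)
        expected = tdef.columns
        if header != expected:
            missing = [c for c in expected if c not in header]
            extra = [c for c in header if c not in expected]
            raise HeaderValidationError(
                f"{Path(path).name}: header does not match table {tdef.name!r}: "
                f"missing {missing}, unexpected {extra}",
                missing=missing,
                extra=extra,
            )

        row_errors: list[str] = []
        to_insert: list[dict] = []
        seen_ids: set[str] = set()
        for i, raw in df.iterrows():
            row = {c: (raw[c] if raw[c] != "" else None) for c in expected}
            rid = raw[tdef.id_field]
            line = i + 2  # 1-based, after header
            if not rid:
                row_errors.append(f"line {line}: empty {tdef.id_field}")
                continue
            try:
                RecordID(rid)
            except ValueError:
                row_errors.append(f"line {line}: malformed ID {rid!r}")
                continue
            if rid in seen_ids:
                row_errors.append(f"line {line}: duplicate ID {rid} within file")
                continue
            seen_ids.add(rid)
            for fk, parent_table in tdef.fk_fields.items():
                if not row.get(fk):
                    row_errors.append(f"line {line}: empty foreign key {fk}")
                elif not self._exists(parent_table, RecordID(row[fk])):
                    row_errors.append(
                        f"line {line}: {fk}={row[fk]} does not resolve in {parent_table!r}"
                    )
            existing = self._conn.execute(
                "SELECT table_name FROM _registry WHERE id = ?", (rid,)
            ).fetchone()
            if existing is not None:
                if existing[0] != tdef.name:
                    row_errors.append(
                        f"line {line}: ID {rid} already exists in table {existing[0]!r}"
                    )
                    continue
                stored = self.get(rid)
                same = (
                    {k: str(v) for k, v in stored.fk_values.items()}
                    == {fk: row.get(fk) for fk in tdef.fk_fields}
                    and {k: (None if v is None else str(v)) for k, v in stored.payload.items()}
                    == {p: row.get(p) for p in tdef.payload_fields}
                )
                if same:
                    continue  # idempotent re-import
                row_errors.append(
                    f"line {line}: ID {rid} already exists with a different payload "
                    "(stored records are unmodifiable)"
                )
                continue
            to_insert.append(row)

        if row_errors:
            raise RowValidationError(
                f"{Path(path).name}: import rejected ({len(row_errors)} problem rows)",
                row_errors=row_errors,
            )
        out = []
        for row in to_insert:
            self._insert(tdef, row)
            out.append(RecordID(row[tdef.id_field]))
        return out

    def _detect_table(self, header: list[str], path) -> TableDef:
        for t in self.schema.tables:
            if t.id_field in header:
                return t
        raise HeaderValidationError(
            f"{Path(path).name}: no schema table matches header {header}"
        )

    def close(self) -> None:
        self._conn.close()


def f_quote(col: str) -> str:
    return f'"{col}"'


def _to_db(value) -> object:
    if value is None:
        return None
    if isinstance(value, (RecordID, uuid.UUID)):
        return str(value)
    if isinstance(value, (int, float)):
        return str(value)
    return value


def register_chain(
    store: LineageStore,
    stages: Iterable[tuple[str, Mapping[str, object]]],
    extra_parents: Mapping[str, Mapping[str, RecordID]] | None = None,
) -> dict[str, RecordID]:
    """Register a linear chain of records, wiring each stage to the previous.

    Convenience used by the synthetic generator and tests: ``stages`` is an
    ordered (table, payload) sequence where each table's single FK (if any)
    points to the stage registered just before it; ``extra_parents`` supplies
    additional FKs (e.g. the second plasmid of a transfection).
    """
    extra_parents = extra_parents or {}
    ids: dict[str, RecordID] = {}
    prev_table: str | None = None
    for table, payload in stages:
        tdef = store.schema[table]
        parents: dict[str, RecordID] = dict(extra_parents.get(table, {}))
        for fk, parent_table in tdef.fk_fields.items():
            if fk in parents:
                continue
            if prev_table == parent_table:
                parents[fk] = ids[parent_table]
        ids[table] = store.register(table, payload, parents)
        prev_table = table
    return ids
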