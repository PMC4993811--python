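"""The shared cohort database.

One embedded SQLite file holds everything non-spatial that analyses create or
import: typed variables with per-subject values, named samples (with the
definition that produced them, so membership can be re-derived), sphere ROIs,
named bundle expressions, saved scenarios with annotations, and an
append-only session log.  Every analysis stage reads and writes the same
file, which is what lets a value captured from geometry be used as a
regressor five minutes later.

Missing values are a first-class state (SQL NULL), never a sentinel number.
Variables are either numeric or nominal; nominal variables store integer
level codes plus a level -> label table.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NotFoundError, ValidationError
from .roi import SphereROI

_SCHEMA = """
CREATE TABLE IF NOT EXISTS subjects (subject_id TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS variables (
    var_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE COLLATE NOCASE,
    var_type TEXT NOT NULL CHECK (var_type IN ('numeric', 'nominal')),
    description TEXT DEFAULT '',
    provenance TEXT DEFAULT 'imported');
CREATE TABLE IF NOT EXISTS var_levels (
    var_id INTEGER NOT NULL REFERENCES variables(var_id),
    level INTEGER NOT NULL,
    label TEXT NOT NULL,
    PRIMARY KEY (var_id, level));
CREATE TABLE IF NOT EXISTS var_values (
    subject_id TEXT NOT NULL,
    var_id INTEGER NOT NULL REFERENCES variables(var_id),
    value REAL,
    PRIMARY KEY (subject_id, var_id));
CREATE TABLE IF NOT EXISTS samples (
    sample_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    definition TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS sample_members (
    sample_id INTEGER NOT NULL REFERENCES samples(sample_id),
    subject_id TEXT NOT NULL,
    PRIMARY KEY (sample_id, subject_id));
CREATE TABLE IF NOT EXISTS rois (
    roi_id TEXT PRIMARY KEY,
    subject_id TEXT, space TEXT,
    cx REAL, cy REAL, cz REAL, r REAL,
    auto_propagated INTEGER DEFAULT 0);
CREATE TABLE IF NOT EXISTS bundle_defs (
    name TEXT PRIMARY KEY,
    expression TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS scenarios (
    scenario_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL,
    description TEXT DEFAULT '',
    application TEXT DEFAULT '',
    state TEXT NOT NULL,
    created TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS annotations (
    annotation_id INTEGER PRIMARY KEY,
    target_kind TEXT NOT NULL,
    target_id TEXT NOT NULL,
    text TEXT NOT NULL,
    created TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS session_log (
    entry_id INTEGER PRIMARY KEY,
    created TEXT NOT NULL,
    module TEXT NOT NULL,
    subject_id TEXT,
    scenario_id INTEGER,
    event TEXT NOT NULL);
"""


@dataclass(frozen=True)
class Variable:
    var_id: int
    name: str
    var_type: str  # 'numeric' | 'nominal'
    description: str = ""
    provenance: str = "imported"
    levels: dict[int, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Sample:
    sample_id: int
    name: str
    subjects: tuple[str, ...]
    definition: dict


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat()


class CohortDB:
    """Single-file transactional store shared by every analysis stage."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self):
        self._conn.close()

    # -- variables ---------------------------------------------------------

    def add_variable(self, name: str, var_type: str = "numeric",
                     description: str = "", provenance: str = "imported",
                     levels: dict[int, str] | None = None) -> Variable:
        """Create or update a variable definition; the name is the key.

        Re-registering an existing name with the same type updates its
        metadata in place; a conflicting type is an error.
        """
        if var_type not in ("numeric", "nominal"):
            raise ValidationError(f"var_type must be numeric|nominal, got {var_type!r}")
        cur = self._conn.execute(
            "SELECT var_id, var_type FROM variables WHERE name = ? COLLATE NOCASE",
            (name,))
        row = cur.fetchone()
        if row is not None:
            var_id, existing = row
            if existing != var_type:
                raise ValidationError(
                    f"variable {name!r} already exists as {existing}, "
                    f"cannot re-declare as {var_type}")
            self._conn.execute(
                "UPDATE variables SET description = ?, provenance = ? WHERE var_id = ?",
                (description, provenance, var_id))
        else:
            cur = self._conn.execute(
                "INSERT INTO variables (name, var_type, description, provenance) "
                "VALUES (?, ?, ?, ?)", (name, var_type, description, provenance))
            var_id = cur.lastrowid
        if levels:
            self._conn.execute("DELETE FROM var_levels WHERE var_id = ?", (var_id,))
            self._conn.executemany(
                "INSERT INTO var_levels (var_id, level, label) VALUES (?, ?, ?)",
                [(var_id, int(k), str(v)) for k, v in levels.items()])
        self._conn.commit()
        return self.get_variable(name)

    def get_variable(self, name: str) -> Variable:
        cur = self._conn.execute(
            "SELECT var_id, name, var_type, description, provenance "
            "FROM variables WHERE name = ? COLLATE NOCASE", (name,))
        row = cur.fetchone()
        if row is None:
            raise NotFoundError(f"no variable named {name!r}")
        levels = dict(self._conn.execute(
            "SELECT level, label FROM var_levels WHERE var_id = ?", (row[0],)))
        return Variable(row[0], row[1], row[2], row[3], row[4],
                        {int(k): v for k, v in levels.items()})

    def list_variables(self) -> list[Variable]:
        names = [r[0] for r in self._conn.execute(
            "SELECT name FROM variables ORDER BY name")]
        return [self.get_variable(n) for n in names]

    def set_values(self, name: str, values: dict):
        """Upsert per-subject values; None / NaN stores an explicit missing."""
        var = self.get_variable(name)
        rows = []
        for sid, val in values.items():
            if val is None or (isinstance(val, float) and np.isnan(val)):
                stored = None
            else:
                stored = float(val)
                if var.var_type == "nominal" and var.levels \
                        and int(stored) not in var.levels:
                    raise ValidationError(
                        f"{name!r}: value {val} is not a declared level")
            rows.append((str(sid), var.var_id, stored))
        self._conn.executemany(
            "INSERT OR IGNORE INTO subjects (subject_id) VALUES (?)",
            [(r[0],) for r in rows])
        self._conn.executemany(
            "INSERT INTO var_values (subject_id, var_id, value) VALUES (?, ?, ?) "
            "ON CONFLICT (subject_id, var_id) DO UPDATE SET value = excluded.value",
            rows)
        self._conn.commit()

    def get_values(self, names, subjects=None) -> pd.DataFrame:
        """DataFrame of variables (columns) by subject (index); NaN = missing."""
        if isinstance(names, str):
            names = [names]
        variables = [self.get_variable(n) for n in names]
        if subjects is None:
            subjects = self.list_subjects()
        subjects = [str(s) for s in subjects]
        frame = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
        for var in variables:
            rows = dict(self._conn.execute(
                "SELECT subject_id, value FROM var_values WHERE var_id = ?",
                (var.var_id,)))
            frame[var.name] = [rows.get(s, np.nan) if rows.get(s) is not None
                               else np.nan for s in subjects]
        return frame

    def list_subjects(self) -> list[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT subject_id FROM subjects ORDER BY subject_id")]

    # -- tabular import / export ------------------------------------------

    def import_table(self, csv_path: str,
                     type_hints: dict[str, dict] | None = None) -> list[Variable]:
        """Import a clinical CSV: first column = subject id, header row = names.

        Column types are inferred (numeric dtype -> numeric, anything else ->
        nominal) unless hinted via ``type_hints[name] = {"type": ...,
        "labels": {level: label}}``.  Re-importing updates values in place;
        a type conflict with an existing variable aborts with a message
        listing every conflicting column.
        """
        type_hints = type_hints or {}
        table = pd.read_csv(csv_path)
        if table.shape[1] < 2:
            raise ValidationError("CSV needs a subject-id column plus variables")
        id_col = table.columns[0]
        table[id_col] = table[id_col].astype(str)

        conflicts = []
        plans = []  # (name, var_type, levels, values dict)
        for col in table.columns[1:]:
            hint = type_hints.get(col, {})
            numeric = pd.api.types.is_numeric_dtype(table[col])
            var_type = hint.get("type", "numeric" if numeric else "nominal")
            levels = {int(k): str(v) for k, v in (hint.get("labels") or {}).items()}
            if var_type == "nominal" and not levels:
                observed = sorted(str(v) for v in table[col].dropna().unique())
                levels = {i + 1: lab for i, lab in enumerate(observed)}
            values = {}
            for sid, raw in zip(table[id_col], table[col]):
                if pd.isna(raw):
                    values[sid] = None
                elif var_type == "nominal":
                    if numeric:
                        values[sid] = int(raw)
                    else:
                        code = {lab: lev for lev, lab in levels.items()}.get(str(raw))
                        if code is None:
                            raise ValidationError(
                                f"column {col!r}: value {raw!r} not in label table")
                        values[sid] = code
                else:
                    values[sid] = float(raw)
            try:
                existing = self.get_variable(col)
                if existing.var_type != var_type:
                    conflicts.append(
                        f"{col!r}: stored as {existing.var_type}, import says {var_type}")
                    continue
            except NotFoundError:
                pass
            plans.append((col, var_type, levels, values))
        if conflicts:
            raise ValidationError(
                "type conflicts on re-import: " + "; ".join(conflicts))
        out = []
        for name, var_type, levels, values in plans:
            var = self.add_variable(name, var_type, levels=levels or None)
            self.set_values(name, values)
            out.append(self.get_variable(name))
        return out

    def export_table(self, csv_path: str, names=None, subjects=None):
        names = names or [v.name for v in self.list_variables()]
        frame = self.get_values(names, subjects)
        frame.to_csv(csv_path)

    # -- samples -----------------------------------------------------------

    def _store_sample(self, name: str, subjects, definition: dict) -> Sample:
        members = tuple(sorted(set(str(s) for s in subjects)))
        known = set(self.list_subjects())
        unknown = [s for s in members if s not in known]
        if unknown:
            raise ValidationError(f"sample references unknown subjects: {unknown}")
        self._conn.execute("DELETE FROM sample_members WHERE sample_id IN "
                           "(SELECT sample_id FROM samples WHERE name = ?)", (name,))
        self._conn.execute("DELETE FROM samples WHERE name = ?", (name,))
        cur = self._conn.execute(
            "INSERT INTO samples (name, definition) VALUES (?, ?)",
            (name, json.dumps(definition, sort_keys=True)))
        sid = cur.lastrowid
        self._conn.executemany(
            "INSERT INTO sample_members (sample_id, subject_id) VALUES (?, ?)",
            [(sid, m) for m in members])
        self._conn.commit()
        return Sample(sid, name, members, definition)

    def create_sample(self, name: str, subjects) -> Sample:
        """Explicit-list sample."""
        subjects = sorted(set(str(s) for s in subjects))
        return self._store_sample(name, subjects,
                                  {"kind": "explicit", "subjects": subjects})

    def get_sample(self, name: str) -> Sample:
        row = self._conn.execute(
            "SELECT sample_id, definition FROM samples WHERE name = ?",
            (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"no sample named {name!r}")
        members = tuple(r[0] for r in self._conn.execute(
            "SELECT subject_id FROM sample_members WHERE sample_id = ? "
            "ORDER BY subject_id", (row[0],)))
        return Sample(row[0], name, members, json.loads(row[1]))

    def list_samples(self) -> list[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT name FROM samples ORDER BY name")]

    def _filter_membership(self, conditions, missing_policy: str) -> list[str]:
        subjects = self.list_subjects()
        names = [c[0] for c in conditions]
        frame = self.get_values(names, subjects) if names else pd.DataFrame(
            index=pd.Index(subjects))
        members = []
        for sid in subjects:
            ok = True
            for var_name, relation, bound in conditions:
                var = self.get_variable(var_name)
                val = frame.loc[sid, var_name] if names else np.nan
                if pd.isna(val):
                    if missing_policy == "exclude":
                        ok = False
                        break
                    continue  # include: missing does not veto
                ok = _apply_relation(var, float(val), relation, bound)
                if not ok:
                    break
            if ok:
                members.append(sid)
        return members

    def create_sample_filter(self, name: str, conditions,
                             missing_policy: str = "exclude") -> Sample:
        """Sample = subjects satisfying the conjunction of conditions.

        Each condition is (variable, relation, bound) with relations
        ``<= >= < > == != between in``; ordering relations require a numeric
        variable, ``in`` takes a set of nominal level codes.  Subjects with a
        missing value for a filtered variable are kept or dropped according
        to ``missing_policy`` (include | exclude).
        """
        if missing_policy not in ("include", "exclude"):
            raise ValidationError("missing_policy must be include|exclude")
        for var_name, relation, _ in conditions:
            var = self.get_variable(var_name)  # raises NotFoundError
            if relation in ("<=", ">=", "<", ">", "between") \
                    and var.var_type != "numeric":
                raise ValidationError(
                    f"relation {relation!r} needs a numeric variable, "
                    f"{var_name!r} is {var.var_type}")
            if relation not in ("<=", ">=", "<", ">", "==", "!=", "between", "in"):
                raise ValidationError(f"unknown relation {relation!r}")
        members = self._filter_membership(conditions, missing_policy)
        definition = {"kind": "filter", "missing_policy": missing_policy,
                      "conditions": [[c[0], c[1], _jsonable(c[2])] for c in conditions]}
        return self._store_sample(name, members, definition)

    def sample_setop(self, name: str, a: str | Sample, b: str | Sample,
                     op: str) -> Sample:
        """union | intersection | difference of two existing samples."""
        sa = a if isinstance(a, Sample) else self.get_sample(a)
        sb = b if isinstance(b, Sample) else self.get_sample(b)
        A, B = set(sa.subjects), set(sb.subjects)
        if op == "union":
            members = A | B
        elif op == "intersection":
            members = A & B
        elif op == "difference":
            members = A - B
        else:
            raise ValidationError(f"unknown set operation {op!r}")
        return self._store_sample(
            name, members, {"kind": "setop", "op": op, "a": sa.name, "b": sb.name})

    def random_subsample(self, name: str, parent: str | Sample, n: int,
                         seed: int) -> Sample:
        """Uniform subsample without replacement, reproducible from the seed."""
        sp = parent if isinstance(parent, Sample) else self.get_sample(parent)
        if not (0 < n <= len(sp.subjects)):
            raise ValidationError(
                f"subsample size {n} not in 1..{len(sp.subjects)}")
        rng = np.random.default_rng(int(seed))
        chosen = rng.choice(np.array(sp.subjects), size=n, replace=False)
        return self._store_sample(
            name, chosen.tolist(),
            {"kind": "random", "parent": sp.name, "n": int(n), "seed": int(seed)})

    def reevaluate_sample(self, name: str) -> tuple[str, ...]:
        """Recompute membership from the stored definition (unchanged data
        must reproduce it exactly)."""
        sample = self.get_sample(name)
        d = sample.definition
        kind = d["kind"]
        if kind == "explicit":
            return tuple(sorted(d["subjects"]))
        if kind == "filter":
            conditions = [(c[0], c[1], _unjsonable(c[2])) for c in d["conditions"]]
            return tuple(sorted(self._filter_membership(
                conditions, d["missing_policy"])))
        if kind == "setop":
            A = set(self.reevaluate_sample(d["a"]))
            B = set(self.reevaluate_sample(d["b"]))
            out = {"union": A | B, "intersection": A & B,
                   "difference": A - B}[d["op"]]
            return tuple(sorted(out))
        if kind == "random":
            rng = np.random.default_rng(d["seed"])
            parent = self.reevaluate_sample(d["parent"])
            return tuple(sorted(
                rng.choice(np.array(sorted(parent)), size=d["n"], replace=False)))
        raise ValidationError(f"unknown sample definition kind {kind!r}")

    # -- ROIs and bundle expressions --------------------------------------

    def save_roi(self, roi: SphereROI):
        self._conn.execute(
            "INSERT OR REPLACE INTO rois VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
            (roi.roi_id, roi.subject_id, roi.space.name,
             *map(float, roi.center), float(roi.radius),
             int(roi.auto_propagated)))
        self._conn.commit()

    def get_roi(self, roi_id: str) -> SphereROI:
        row = self._conn.execute(
            "SELECT * FROM rois WHERE roi_id = ?", (roi_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"no ROI with id {roi_id!r}")
        return SphereROI(row[0], row[1], row[2], row[3:6], row[6], bool(row[7]))

    def list_rois(self) -> list[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT roi_id FROM rois ORDER BY roi_id")]

    def save_bundle(self, name: str, expression: str):
        from .bundles import parse_bundle_expr

        parse_bundle_expr(expression)  # reject malformed text at save time
        self._conn.execute(
            "INSERT OR REPLACE INTO bundle_defs VALUES (?, ?)", (name, expression))
        self._conn.commit()

    def get_bundle(self, name: str) -> str:
        row = self._conn.execute(
            "SELECT expression FROM bundle_defs WHERE name = ?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"no bundle named {name!r}")
        return row[0]

    # -- scenarios, annotations, log --------------------------------------

    def save_scenario(self, name: str, state: dict, application: str = "",
                      description: str = "") -> int:
        cur = self._conn.execute(
            "INSERT INTO scenarios (name, description, application, state, created) "
            "VALUES (?, ?, ?, ?, ?)",
            (name, description, application,
             json.dumps(state, sort_keys=True), _now()))
        self._conn.commit()
        return cur.lastrowid

    def load_scenario(self, scenario_id: int) -> dict:
        row = self._conn.execute(
            "SELECT name, description, application, state, created "
            "FROM scenarios WHERE scenario_id = ?", (scenario_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"no scenario with id {scenario_id}")
        return {"scenario_id": scenario_id, "name": row[0], "description": row[1],
                "application": row[2], "state": json.loads(row[3]),
                "created": row[4]}

    def annotate(self, target_kind: str, target_id: str, text: str):
        self._conn.execute(
            "INSERT INTO annotations (target_kind, target_id, text, created) "
            "VALUES (?, ?, ?, ?)", (target_kind, target_id, text, _now()))
        self._conn.commit()

    def get_annotations(self, target_kind: str, target_id: str) -> list[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT text FROM annotations WHERE target_kind = ? AND target_id = ? "
            "ORDER BY annotation_id", (target_kind, target_id))]

    def log_event(self, module: str, event: dict, subject_id: str | None = None,
                  scenario_id: int | None = None) -> int:
        cur = self._conn.execute(
            "INSERT INTO session_log (created, module, subject_id, scenario_id, event) "
            "VALUES (?, ?, ?, ?, ?)",
            (_now(), module, subject_id, scenario_id,
             json.dumps(event, sort_keys=True)))
        self._conn.commit()
        return cur.lastrowid

    def query_log(self, module: str | None = None,
                  subject_id: str | None = None) -> list[dict]:
        sql = ("SELECT entry_id, created, module, subject_id, scenario_id, event "
               "FROM session_log WHERE 1=1")
        args = []
        if module is not None:
            sql += " AND module = ?"
            args.append(module)
        if subject_id is not None:
            sql += " AND subject_id = ?"
            args.append(subject_id)
        sql += " ORDER BY entry_id"
        return [_log_row_to_dict(r) for r in self._conn.execute(sql, args)]

    def export_log(self) -> str:
        """JSON-lines dump of the session log (one entry per line)."""
        return "\n".join(json.dumps(e, sort_keys=True) for e in self.query_log())


def _log_row_to_dict(row) -> dict:
    return {"entry_id": row[0], "created": row[1], "module": row[2],
            "subject_id": row[3], "scenario_id": row[4],
            "event": json.loads(row[5])}


def parse_log(text: str) -> list[dict]:
    """Parse an export_log dump back into entries."""
    return [json.loads(line) for line in text.splitlines() if line.strip()]


def _apply_relation(var: Variable, val: float, relation: str, bound) -> bool:
    if relation == "<=":
        return val <= bound
    if relation == ">=":
        return val >= bound
    if relation == "<":
        return val < bound
    if relation == ">":
        return val > bound
    if relation == "==":
        return val == bound
    if relation == "!=":
        return val != bound
    if relation == "between":
        lo, hi = bound
        return lo <= val <= hi
    if relation == "in":
        return val in {float(b) for b in bound}
    raise ValidationError(f"unknown relation {relation!r}")


def _jsonable(bound):
    if isinstance(bound, (set, frozenset, tuple)):
        return sorted(bound) if isinstance(bound, (set, frozenset)) else list(bound)
    return bound


def _unjsonable(bound):
    return tuple(bound) if isinstance(bound, list) else bound
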