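"""Annotation data model and I/O.

The unit of analysis is the *annotation record*: one rater's response to one
question on one item (an advertisement, say).  Single-option questions carry a
single label drawn from the question's codebook; multi-option questions carry
a set of labels.  An explicit absence category (``"None"``, ``"Non-applicable"``)
is an ordinary codebook label — responses are never empty sets.

Tables are stored long-format (one row per record) as CSV or JSON-lines;
codebooks as JSON.  Multi-label responses are serialized with ``"|"`` between
labels, since commas and slashes occur inside label names (``"Chocolate/Sugar"``).
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

MULTI_DELIMITER = "|"

Label = str
LabelSet = frozenset  # of Label
Response = "Label | LabelSet"


class SchemaError(ValueError):
    """A codebook or record violates the annotation data model."""


@dataclass(frozen=True)
class QuestionSchema:
    """One question's identity, kind, and codebook.

    Parameters
    ----------
    question_id : str
        Unique question name.
    kind : {"single", "multi"}
        Whether raters pick exactly one label or a label set.
    codebook : tuple of str
        Ordered list of permissible labels; its length ``k`` enters the
        chance-agreement formulas.
    ai_excluded : frozenset of str
        Labels excluded from model bias analysis (e.g. an ``"Other"`` option
        that was only offered to human coders).
    none_label : str or None
        The explicit absence category for multi-option questions.
    """

    question_id: str
    kind: str
    codebook: tuple[Label, ...]
    ai_excluded: frozenset = frozenset()
    none_label: Label | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "multi"):
            raise SchemaError(
                f"{self.question_id}: kind must be 'single' or 'multi', got {self.kind!r}"
            )
        labels = [str(c).strip() for c in self.codebook]
        if any(not c for c in labels):
            raise SchemaError(f"{self.question_id}: empty label in codebook")
        if len(set(labels)) != len(labels):
            dupes = sorted({c for c in labels if labels.count(c) > 1})
            raise SchemaError(f"{self.question_id}: duplicate label(s) in codebook: {dupes}")
        object.__setattr__(self, "codebook", tuple(labels))
        object.__setattr__(self, "ai_excluded", frozenset(str(c).strip() for c in self.ai_excluded))
        if self.kind == "single" and self.k < 2:
            raise SchemaError(f"{self.question_id}: single-option question needs k >= 2")
        unknown = self.ai_excluded - set(self.codebook)
        if unknown:
            raise SchemaError(f"{self.question_id}: ai_excluded labels not in codebook: {sorted(unknown)}")
        if self.none_label is not None and self.none_label not in self.codebook:
            raise SchemaError(f"{self.question_id}: none_label {self.none_label!r} not in codebook")

    @property
    def k(self) -> int:
        """Number of choices (codebook size)."""
        return len(self.codebook)

    def validate_response(self, response) -> Response:
        """Normalize and validate one response against this schema."""
        if self.kind == "single":
            if not isinstance(response, str):
                raise SchemaError(
                    f"{self.question_id}: single-option response must be one label, got {response!r}"
                )
            token = response.strip()
            if token not in self.codebook:
                raise SchemaError(f"{self.question_id}: unknown label {token!r}")
            return token
        if isinstance(response, str):
            raise SchemaError(
                f"{self.question_id}: multi-option response must be a label set, got {response!r}"
            )
        labels = frozenset(str(t).strip() for t in response)
        if not labels:
            raise SchemaError(f"{self.question_id}: empty label set (use the explicit none label)")
        unknown = labels - set(self.codebook)
        if unknown:
            raise SchemaError(f"{self.question_id}: unknown label(s) {sorted(unknown)}")
        return labels


@dataclass(frozen=True)
class AnnotationRecord:
    """One rater's response to one question on one item."""

    item_id: str
    rater_id: str
    role: str  # crowd | expert | model | consensus
    question_id: str
    response: object  # Label or LabelSet, validated against the schema
    stratum: str | None = None


@dataclass(frozen=True)
class ResponseSeries:
    """Item-aligned responses of one rater on one question.

    This is the unit all pairwise agreement metrics operate on.
    """

    question_id: str
    rater_id: str
    items: tuple
    responses: tuple

    def __post_init__(self) -> None:
        if len(self.items) != len(self.responses):
            raise SchemaError("items and responses must be aligned")
        if len(set(self.items)) != len(self.items):
            raise SchemaError("duplicate item ids in series")

    def __len__(self) -> int:
        return len(self.items)


class AnnotationTable:
    """Validated collection of annotation records plus their question schemas.

    Construction validates every record: unknown questions or labels and
    duplicate (item, rater, question) keys raise :class:`SchemaError` before
    any metric can see the data.
    """

    def __init__(self, records: Iterable[AnnotationRecord], schemas: Iterable[QuestionSchema]):
        self.schemas: dict[str, QuestionSchema] = {}
        for s in schemas:
            if s.question_id in self.schemas:
                raise SchemaError(f"duplicate question_id {s.question_id!r}")
            self.schemas[s.question_id] = s
        self.records: list[AnnotationRecord] = []
        self._index: dict[tuple, AnnotationRecord] = {}
        for rec in records:
            schema = self.schemas.get(rec.question_id)
            if schema is None:
                raise SchemaError(f"record references unknown question {rec.question_id!r}")
            response = schema.validate_response(rec.response)
            rec = AnnotationRecord(
                item_id=str(rec.item_id),
                rater_id=str(rec.rater_id),
                role=rec.role,
                question_id=rec.question_id,
                response=response,
                stratum=rec.stratum,
            )
            key = (rec.item_id, rec.rater_id, rec.question_id)
            if key in self._index:
                raise SchemaError(f"duplicate record for (item={key[0]}, rater={key[1]}, question={key[2]})")
            self._index[key] = rec
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.records == other.records and self.schemas == other.schemas

    # ------------------------------------------------------------------ views

    def raters(self, role: str | None = None) -> list[str]:
        """Rater ids in first-appearance order, optionally filtered by role."""
        seen: dict[str, None] = {}
        for rec in self.records:
            if role is None or rec.role == role:
                seen.setdefault(rec.rater_id, None)
        return list(seen)

    def items(self) -> list[str]:
        """Item ids in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.item_id, None)
        return list(seen)

    def role_of(self, rater_id: str) -> str:
        for rec in self.records:
            if rec.rater_id == rater_id:
                return rec.role
        raise KeyError(rater_id)

    def strata(self) -> dict[str, str | None]:
        """Per-item stratum attribute (first record wins)."""
        out: dict[str, str | None] = {}
        for rec in self.records:
            out.setdefault(rec.item_id, rec.stratum)
        return out

    def get(self, item_id: str, rater_id: str, question_id: str) -> AnnotationRecord | None:
        return self._index.get((str(item_id), str(rater_id), question_id))

    def rater_items(self, rater_id: str, question_id: str) -> list[str]:
        """Items the rater coded on the question, in table order."""
        return [
            rec.item_id
            for rec in self.records
            if rec.rater_id == rater_id and rec.question_id == question_id
        ]

    def extract_series(
        self,
        rater_id: str,
        question_id: str,
        items: Sequence[str] | None = None,
    ) -> ResponseSeries:
        """Item-aligned response series for one rater on one question.

        When ``items`` is given, responses follow that order and every item
        must have been coded by the rater; otherwise the rater's full item
        set in table order is used.
        """
        if question_id not in self.schemas:
            raise SchemaError(f"unknown question {question_id!r}")
        if items is None:
            items = self.rater_items(rater_id, question_id)
            if not items:
                raise SchemaError(f"rater {rater_id!r} has no records for question {question_id!r}")
        items = [str(i) for i in items]
        missing = [i for i in items if (i, rater_id, question_id) not in self._index]
        if missing:
            raise SchemaError(
                f"rater {rater_id!r} missing {len(missing)} item(s) on {question_id!r}: "
                f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
            )
        responses = tuple(self._index[(i, rater_id, question_id)].response for i in items)
        return ResponseSeries(question_id, rater_id, tuple(items), responses)

    # ------------------------------------------------------------------- I/O

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            resp = rec.response
            if isinstance(resp, frozenset):
                schema = self.schemas[rec.question_id]
                ordered = [c for c in schema.codebook if c in resp]
                resp = MULTI_DELIMITER.join(ordered)
            rows.append(
                {
                    "item_id": rec.item_id,
                    "rater_id": rec.rater_id,
                    "role": rec.role,
                    "question_id": rec.question_id,
                    "response": resp,
                    "stratum": rec.stratum if rec.stratum is not None else "",
                }
            )
        return pd.DataFrame(
            rows, columns=["item_id", "rater_id", "role", "question_id", "response", "stratum"]
        )


# ---------------------------------------------------------------------- files


def load_schema(path) -> list[QuestionSchema]:
    """Read a question codebook from JSON.

    The file holds a list of objects with keys ``question_id``, ``kind``,
    ``codebook`` and optional ``ai_excluded``, ``none_label``.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise SchemaError(f"{path}: empty codebook file")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    if isinstance(payload, dict) and "questions" in payload:
        payload = payload["questions"]
    schemas = []
    seen = set()
    for entry in payload:
        for req in ("question_id", "kind", "codebook"):
            if req not in entry:
                raise SchemaError(f"{path}: question entry missing field {req!r}: {entry}")
        if entry["question_id"] in seen:
            raise SchemaError(f"{path}: duplicate question_id {entry['question_id']!r}")
        seen.add(entry["question_id"])
        schemas.append(
            QuestionSchema(
                question_id=entry["question_id"],
                kind=entry["kind"],
                codebook=tuple(entry["codebook"]),
                ai_excluded=frozenset(entry.get("ai_excluded", ())),
                none_label=entry.get("none_label"),
            )
        )
    return schemas


def write_schema(schemas: Iterable[QuestionSchema], path) -> None:
    payload = [
        {
            "question_id": s.question_id,
            "kind": s.kind,
            "codebook": list(s.codebook),
            "ai_excluded": sorted(s.ai_excluded),
            "none_label": s.none_label,
        }
        for s in schemas
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _parse_response(schema: QuestionSchema, raw: str, where: str):
    raw = str(raw)
    if schema.kind == "single":
        if MULTI_DELIMITER in raw:
            raise SchemaError(f"{where}: single-option question {schema.question_id!r} got a label set {raw!r}")
        return raw.strip()
    return frozenset(t.strip() for t in raw.split(MULTI_DELIMITER) if t.strip())


def load_annotations(path, schemas: Iterable[QuestionSchema]) -> AnnotationTable:
    """Read an annotation table from long-format CSV or JSON-lines.

    Dialect is inferred from the extension (``.csv`` vs ``.jsonl``/``.json``).
    Unknown labels are rejected with the offending row number, never dropped.
    """
    path = Path(path)
    schemas = list(schemas)
    by_id = {s.question_id: s for s in schemas}
    if path.suffix.lower() in (".jsonl", ".json"):
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rows.append((lineno, json.loads(line)))
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON line ({exc})") from exc
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"item_id", "rater_id", "role", "question_id", "response"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        rows = [(i + 2, row) for i, row in enumerate(df.to_dict("records"))]  # +2: header line
    records = []
    for lineno, row in rows:
        qid = row["question_id"]
        schema = by_id.get(qid)
        if schema is None:
            raise SchemaError(f"{path}:{lineno}: unknown question {qid!r}")
        try:
            response = _parse_response(schema, row["response"], f"{path}:{lineno}")
            response = schema.validate_response(response)
            stratum = row.get("stratum") or None
            records.append(
                AnnotationRecord(
                    item_id=row["item_id"],
                    rater_id=row["rater_id"],
                    role=row["role"],
                    question_id=qid,
                    response=response,
                    stratum=stratum,
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    try:
        return AnnotationTable(records, schemas)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_annotations(table: AnnotationTable, path) -> None:
    """Write a table in the long-format CSV or JSON-lines dialect."""
    path = Path(path)
    df = table.to_dataframe()
    if path.suffix.lower() in (".jsonl", ".json"):
        with open(path, "w") as fh:
            for row in df.to_dict("records"):
                fh.write(json.dumps(row) + "\n")
    else:
        df.to_csv(path, index=False)
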