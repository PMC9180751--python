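"""Label sets for ICF coding of functional status information.

Two fixed label sets are shipped:

* ``MOBILITY`` — 13 labels: twelve second-level categories of ICF Chapter 4
  (Mobility) observed in disability-claim documents, plus a catch-all
  ``OTHER``.  d465 (*Moving around using equipment*) is deliberately absent:
  equipment use is represented by Assistance components of activity mentions,
  so the action itself reduces to d455.  d480 is absent because it does not
  occur in this document genre.
* ``SELFCARE_DOMESTIC`` — 16 labels: thirteen second-level categories of ICF
  Chapters 5 (Self-Care) and 6 (Domestic Life), two SNOMED CT-derived
  extension labels (*Manage medication*, 285033005; *Therapy*, 709007004)
  that split patient engagement in treatment out of the overly broad d570,
  and ``OTHER``.

"Other specified" / "unspecified" ICF codes (d498, d598, d599, ...) are never
used; the catch-all is the non-ICF token ``OTHER``.

Every category carries a ``definition_text`` — the string whose averaged word
embedding represents the category in candidate selection.  For the d-codes
these are WHO-style short definitions shipped as package data (editions vary
in wording; supply a custom JSON label set to override them).  The OTHER and
SNOMED labels use fixed strings required by the coding procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

MOBILITY = "MOBILITY"
SELFCARE_DOMESTIC = "SELFCARE_DOMESTIC"
DOMAIN_IDS = (MOBILITY, SELFCARE_DOMESTIC)

VALID_CHAPTERS = ("mobility", "self-care", "domestic-life", "extension", "other")
VALID_SOURCES = ("ICF", "SNOMED", "OTHER")
_SNOMED_CODES = ("285033005", "709007004")


class SchemaError(ValueError):
    """Invalid label set or unknown code/domain."""


@dataclass(frozen=True)
class ICFCategory:
    """One coding target: an ICF second-level category or an added label."""

    code: str
    name: str
    chapter: str
    definition_text: str
    source: str = "ICF"
    snomed_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise SchemaError("category code must be non-empty")
        if not self.definition_text:
            raise SchemaError(f"category {self.code!r} has empty definition_text")
        if self.chapter not in VALID_CHAPTERS:
            raise SchemaError(f"category {self.code!r}: unknown chapter {self.chapter!r}")
        if self.source not in VALID_SOURCES:
            raise SchemaError(f"category {self.code!r}: unknown source {self.source!r}")
        if (self.source == "SNOMED") != (self.snomed_code in _SNOMED_CODES):
            raise SchemaError(
                f"category {self.code!r}: SNOMED-sourced categories carry exactly "
                f"the concept codes {_SNOMED_CODES}"
            )


@dataclass(frozen=True)
class LabelSet:
    """Ordered, fixed inventory of categories for one annotation domain."""

    domain_id: str
    categories: tuple[ICFCategory, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        codes = [c.code for c in self.categories]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise SchemaError(f"duplicate codes in label set: {dupes}")
        for banned in ("d465", "d498", "d598", "d599"):
            if banned in codes:
                raise SchemaError(f"excluded code {banned} may not appear in a label set")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.categories)

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self) -> Iterator[ICFCategory]:
        return iter(self.categories)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def get(self, code: str) -> ICFCategory:
        for c in self.categories:
            if c.code == code:
                return c
        raise SchemaError(
            f"code {code!r} is not in label set {self.domain_id} "
            f"(valid codes: {', '.join(self.codes)})"
        )

    def definition_text(self, code: str) -> str:
        return self.get(code).definition_text

    # --- JSON serialization (custom label sets) -------------------------
    def to_json(self) -> str:
        payload = {
            "domain_id": self.domain_id,
            "categories": [
                {
                    "code": c.code,
                    "name": c.name,
                    "chapter": c.chapter,
                    "definition_text": c.definition_text,
                    "source": c.source,
                    "snomed_code": c.snomed_code,
                }
                for c in self.categories
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LabelSet":
        payload = json.loads(text)
        cats = tuple(ICFCategory(**entry) for entry in payload["categories"])
        return cls(domain_id=payload["domain_id"], categories=cats)


def _load_packaged() -> dict[str, LabelSet]:
    raw = resources.files("icfcoder.data").joinpath("label_sets.json").read_text("utf-8")
    data = json.loads(raw)
    out = {}
    for domain_id, entries in data.items():
        cats = tuple(ICFCategory(**e) for e in entries)
        out[domain_id] = LabelSet(domain_id=domain_id, categories=cats)
    return out


_PACKAGED: dict[str, LabelSet] | None = None


def load_label_set(domain_id: str) -> LabelSet:
    """Return the fixed label set for ``MOBILITY`` or ``SELFCARE_DOMESTIC``.

    Repeated calls return identical inventories.  Raises :class:`SchemaError`
    for any other domain id, naming the valid ones.
    """
    global _PACKAGED
    if _PACKAGED is None:
        _PACKAGED = _load_packaged()
        assert len(_PACKAGED[MOBILITY]) == 13
        assert len(_PACKAGED[SELFCARE_DOMESTIC]) == 16
    if domain_id not in _PACKAGED:
        raise SchemaError(
            f"unknown domain id {domain_id!r}; valid domains: {', '.join(DOMAIN_IDS)}"
        )
    return _PACKAGED[domain_id]


def definition_text(code: str, domain_id: str) -> str:
    """The definition string embedded for candidate selection.

    d-codes return the packaged short definition; ``OTHER`` returns
    "Mobility other or unspecified" / "Self-care or domestic life other or
    unspecified"; the SNOMED labels return their concept names.
    """
    return load_label_set(domain_id).definition_text(code)
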