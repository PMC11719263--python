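"""Survey ingestion: codebooks, ordinal response matrices, exclusion screening.

Items are 5-point Likert responses (1 = substantially reduced ... 5 =
substantially increased) belonging to one of two declared communities,
``lifestyle`` or ``outcome``.  Items whose wording carries a "less" prefix are
reverse coded at load time so that, downstream, higher always means
healthier/better.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

COMMUNITIES = ("lifestyle", "outcome")

#: exclusion rules in screening order; a record is charged to the first
#: rule it violates, so the per-rule counts partition the excluded set.
EXCLUSION_RULES = (
    "blank_incomplete",
    "duplicate",
    "inconsistent_validation",
    "nonparticipating_country",
    "missing_age_gender",
)


@dataclass(frozen=True)
class ItemSpec:
    """One survey item: identity, community membership and coding direction."""

    id: str
    community: str
    description: str = ""
    reverse_coded: bool = False
    levels: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.community not in COMMUNITIES:
            raise ValueError(
                f"item {self.id!r}: community must be one of {COMMUNITIES}, "
                f"got {self.community!r}"
            )
        lv = tuple(int(x) for x in self.levels)
        if len(lv) < 2 or any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(
                f"item {self.id!r}: levels must be strictly increasing with >=2 values"
            )
        object.__setattr__(self, "levels", lv)


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of :class:`ItemSpec` with unique ids."""

    items: tuple[ItemSpec, ...]

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids in codebook: {dupes}")

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def communities(self) -> dict[str, str]:
        return {it.id: it.community for it in self.items}

    def __getitem__(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.id == item_id for it in self.items)

    def subset(self, item_ids: Sequence[str]) -> "Codebook":
        return Codebook(tuple(self[i] for i in item_ids))

    def ids_in_community(self, community: str) -> list[str]:
        return [it.id for it in self.items if it.community == community]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "Codebook":
        return cls(tuple(ItemSpec(**dict(r)) for r in records))

    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if isinstance(data, Mapping) and "items" in data:
            data = data["items"]
        recs = []
        for r in data:
            r = dict(r)
            if "levels" in r:
                r["levels"] = tuple(r["levels"])
            recs.append(r)
        return cls.from_records(recs)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "items": [
                {
                    "id": it.id,
                    "community": it.community,
                    "description": it.description,
                    "reverse_coded": it.reverse_coded,
                    "levels": list(it.levels),
                }
                for it in self.items
            ]
        }
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class SurveyMatrix:
    """n x p ordinal response table; missing cells are NaN.

    ``data`` is a float DataFrame whose columns follow the codebook order.
    """

    data: pd.DataFrame
    country: str = ""

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return self.data.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the response is missing."""
        return self.data.isna()

    def copy(self) -> "SurveyMatrix":
        return SurveyMatrix(self.data.copy(), self.country)

    def select(self, item_ids: Sequence[str]) -> "SurveyMatrix":
        return SurveyMatrix(self.data[list(item_ids)].copy(), self.country)

    def complete_cases(self) -> "SurveyMatrix":
        return SurveyMatrix(self.data.dropna(axis=0), self.country)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        # integers with empty cells for missing
        out.to_csv(path, index=False, float_format="%.0f")


@dataclass
class ExclusionLedger:
    """Accounting of the screening funnel: screened = eligible + excluded."""

    screened: int
    per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def excluded(self) -> int:
        return sum(self.per_rule.values())

    @property
    def eligible(self) -> int:
        return self.screened - self.excluded

    def validate(self) -> None:
        if self.screened < 0 or any(v < 0 for v in self.per_rule.values()):
            raise ValueError("ledger counts must be non-negative")
        if self.eligible < 0:
            raise ValueError(
                f"exclusions ({self.excluded}) exceed screened ({self.screened})"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "screened": self.screened,
                "per_rule": self.per_rule,
                "excluded": self.excluded,
                "eligible": self.eligible,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class ExclusionRules:
    """Configuration for :func:`apply_exclusions`.

    ``validation_answers`` maps a validation-question column to the set of
    accepted answers; matching is exact after lowercasing and trimming.
    """

    item_ids: Sequence[str]
    duplicate_key: Sequence[str] = ()
    validation_answers: Mapping[str, Sequence[str]] = field(default_factory=dict)
    participating_countries: Sequence[str] | None = None
    country_col: str = "country"
    age_col: str = "age"
    gender_col: str = "gender"


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def load_survey(
    table_file: str | Path,
    codebook: Codebook | str | Path,
    country: str = "",
    apply_reverse: bool = True,
) -> SurveyMatrix:
    """Read a respondent-by-item CSV and return a validated ordinal matrix.

    Every codebook item must be present as a column; extra columns are
    ignored (and logged).  Cells must parse as integers within the item's
    declared levels; empty cells become missing.  Reverse-coded items are
    flipped at load time unless ``apply_reverse`` is False.
    """
    if not isinstance(codebook, Codebook):
        codebook = Codebook.from_file(codebook)
    raw = pd.read_csv(table_file, dtype=str, keep_default_na=False)
    missing_cols = [i for i in codebook.item_ids if i not in raw.columns]
    if missing_cols:
        raise ValueError(f"survey table is missing codebook item column(s): {missing_cols}")
    extra = [c for c in raw.columns if c not in codebook.item_ids]
    if extra:
        logger.info("ignoring %d non-codebook column(s): %s", len(extra), extra)

    cols = {}
    for spec in codebook.items:
        col = raw[spec.id].str.strip()
        blank = col == ""
        numeric = pd.to_numeric(col.where(~blank, None), errors="coerce")
        bad = (~blank) & (numeric.isna() | (numeric != numeric.round()))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-integer value {col.iloc[row]!r} at row {row}, item {spec.id!r}"
            )
        out_of_range = numeric.notna() & ~numeric.isin(spec.levels)
        if out_of_range.any():
            row = int(np.flatnonzero(out_of_range.to_numpy())[0])
            raise ValueError(
                f"value {int(numeric.iloc[row])} outside levels {spec.levels} "
                f"at row {row}, item {spec.id!r}"
            )
        cols[spec.id] = numeric.astype(float)
    matrix = SurveyMatrix(pd.DataFrame(cols), country=country)
    if apply_reverse:
        matrix = reverse_code(matrix, codebook)
    return matrix


def reverse_code(matrix: SurveyMatrix, codebook: Codebook) -> SurveyMatrix:
    """Flip flagged items ``x -> (min+max) - x``; an involution on the levels.

    Requires each flagged item's level set to be symmetric under that map
    (true for any contiguous range such as 1..5).  Missing cells stay missing.
    """
    data = matrix.data.copy()
    for spec in codebook.items:
        if not spec.reverse_coded or spec.id not in data.columns:
            continue
        lo, hi = spec.levels[0], spec.levels[-1]
        if {lo + hi - x for x in spec.levels} != set(spec.levels):
            raise ValueError(
                f"item {spec.id!r}: level set {spec.levels} is not symmetric; "
                "cannot reverse code"
            )
        data[spec.id] = (lo + hi) - data[spec.id]
    return SurveyMatrix(data, matrix.country)


def required_sample_size(p_nodes: int, per_parameter: int = 3) -> int:
    """Minimum n under the three-respondents-per-parameter planning rule.

    A saturated p-node partial-correlation network has p(p-1)/2 free edge
    parameters; the rule asks for ``per_parameter`` respondents per edge.
    """
    if p_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {p_nodes}")
    return per_parameter * (p_nodes * (p_nodes - 1) // 2)


def apply_exclusions(
    raw_records: pd.DataFrame | Sequence[Mapping],
    rules: ExclusionRules,
    codebook: Codebook | None = None,
    country: str = "",
) -> tuple[SurveyMatrix, ExclusionLedger]:
    """Screen raw records and charge each exclusion to its first failing rule.

    Rule order: blank/incomplete items, duplicate of an earlier record,
    failed validation question, non-participating country, missing age or
    gender.  Eligible records form the returned matrix (item columns only).
    """
    if not isinstance(raw_records, pd.DataFrame):
        raw_records = pd.DataFrame(list(raw_records))
    ledger = ExclusionLedger(screened=len(raw_records), per_rule={r: 0 for r in EXCLUSION_RULES})
    if len(raw_records) == 0:
        empty = pd.DataFrame({i: pd.Series(dtype=float) for i in rules.item_ids})
        return SurveyMatrix(empty, country), ledger

    item_ids = list(rules.item_ids)
    keep = []
    seen_keys: set[tuple] = set()
    for _, rec in raw_records.iterrows():
        rule = None
        if any(c not in rec or _is_blank(rec[c]) for c in item_ids):
            rule = "blank_incomplete"
        if rule is None and rules.duplicate_key:
            key = tuple(str(rec.get(c)) for c in rules.duplicate_key)
            if key in seen_keys:
                rule = "duplicate"
            else:
                seen_keys.add(key)
        if rule is None:
            for q, accepted in rules.validation_answers.items():
                acc = {str(a).strip().lower() for a in accepted}
                if str(rec.get(q, "")).strip().lower() not in acc:
                    rule = "inconsistent_validation"
                    break
        if rule is None and rules.participating_countries is not None:
            if str(rec.get(rules.country_col, "")).strip() not in set(
                rules.participating_countries
            ):
                rule = "nonparticipating_country"
        if rule is None and (
            _is_blank(rec.get(rules.age_col)) or _is_blank(rec.get(rules.gender_col))
        ):
            rule = "missing_age_gender"

        if rule is None:
            keep.append(rec)
        else:
            ledger.per_rule[rule] += 1

    if keep:
        kept = pd.DataFrame(keep)[item_ids].apply(pd.to_numeric).astype(float)
        kept = kept.reset_index(drop=True)
    else:
        kept = pd.DataFrame({i: pd.Series(dtype=float) for i in item_ids})
    matrix = SurveyMatrix(kept, country)
    if codebook is not None:
        matrix = reverse_code(matrix, codebook)
    ledger.validate()
    assert ledger.screened == ledger.eligible + ledger.excluded
    return matrix, ledger
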