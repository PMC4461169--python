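"""Phoneme inventories, articulatory feature tables and substitution costs.

Production scoring rests on a weighted Levenshtein distance whose
substitution costs come from articulatory feature vectors: each vowel is a
point in (Height, Forwardness) space and each consonant a point in an
8-dimensional space (Aspiration, Place, Constrictor, Stop, Nasal, Lateral,
Sulcal, Double), all coordinates in [0, 1].  The distance between two
phonemes of the same category is the L1 distance between their vectors;
substituting one for the other costs that distance scaled into [0, 0.8] by
the category's maximum pairwise distance, while any vowel-for-consonant
substitution (or vice versa) costs 1.

The shipped tables give the feature values for the transcription set used
to code learner productions (plus /u/ and the /i/ extension noted in the
fixture), and reproduce the published category maxima of 1.5 for vowels and
4.25 for consonants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping

__all__ = [
    "Phoneme",
    "FeatureTable",
    "CostScheme",
    "FeatureTableError",
    "PhonemeError",
    "load_feature_table",
    "load_aliases",
    "default_feature_table",
    "default_cost_scheme",
    "phoneme_distance",
    "substitution_cost",
    "max_category_distance",
    "tokenize",
]

VOWEL_FEATURES = ("Height", "Forwardness")
CONSONANT_FEATURES = (
    "Aspiration",
    "Place",
    "Constrictor",
    "Stop",
    "Nasal",
    "Lateral",
    "Sulcal",
    "Double",
)

#: printed category normalizers the shipped tables must reproduce
EXPECTED_VOWEL_NORMALIZER = 1.5
EXPECTED_CONSONANT_NORMALIZER = 4.25

# marks of a length distinction; the transcription scheme deliberately has none
_LENGTH_MARKS = ("ː", ":")


class FeatureTableError(ValueError):
    """A feature-table fixture failed validation on load."""


class PhonemeError(KeyError):
    """A symbol does not resolve against the active inventory."""


@dataclass(frozen=True)
class Phoneme:
    """A phoneme symbol with its fixed major category."""

    symbol: str
    category: str  # "vowel" | "consonant"

    def __post_init__(self) -> None:
        if self.category not in ("vowel", "consonant"):
            raise FeatureTableError(
                f"unknown category {self.category!r} for {self.symbol!r}"
            )


class FeatureTable:
    """Per-category articulatory feature vectors for a phoneme inventory.

    Parameters
    ----------
    vowel_features, consonant_features
        Maps from phoneme symbol to a feature vector (tuple of reals in
        [0, 1]); all vowels share one dimensionality and all consonants
        another.
    aliases
        Optional map from input alias (e.g. ASCII ``tS``) to canonical
        symbol, applied by :meth:`resolve` and :func:`tokenize`.
    """

    def __init__(
        self,
        vowel_features: Mapping[str, tuple[float, ...]],
        consonant_features: Mapping[str, tuple[float, ...]],
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self.vowel_features = dict(vowel_features)
        self.consonant_features = dict(consonant_features)
        self.aliases = dict(aliases or {})
        self._validate()
        # longest-first symbol list for greedy tokenization
        self._match_symbols = sorted(
            set(self.symbols()) | set(self.aliases), key=len, reverse=True
        )

    def _validate(self) -> None:
        overlap = set(self.vowel_features) & set(self.consonant_features)
        if overlap:
            raise FeatureTableError(f"symbols in both categories: {sorted(overlap)}")
        for name, mapping in (
            ("vowel", self.vowel_features),
            ("consonant", self.consonant_features),
        ):
            dims = {len(v) for v in mapping.values()}
            if len(dims) > 1:
                raise FeatureTableError(
                    f"inconsistent {name} feature dimensionality: {dims}"
                )
            for sym, vec in mapping.items():
                for value in vec:
                    if not (0.0 <= value <= 1.0):
                        raise FeatureTableError(
                            f"feature value {value} outside [0,1] for {name} {sym!r}"
                        )
        for alias, target in self.aliases.items():
            if (
                target not in self.vowel_features
                and target not in self.consonant_features
            ):
                raise FeatureTableError(
                    f"alias {alias!r} points at unknown symbol {target!r}"
                )

    # -- inventory -------------------------------------------------------

    def symbols(self) -> list[str]:
        return list(self.vowel_features) + list(self.consonant_features)

    def category(self, symbol: str) -> str:
        symbol = self.resolve(symbol)
        if symbol in self.vowel_features:
            return "vowel"
        return "consonant"

    def resolve(self, symbol: str) -> str:
        """Map an input symbol through the alias table to its canonical form."""
        for mark in _LENGTH_MARKS:
            if mark in symbol:
                raise PhonemeError(
                    f"{symbol!r} carries a length mark; length is not transcribed"
                )
        symbol = self.aliases.get(symbol, symbol)
        if symbol not in self.vowel_features and symbol not in self.consonant_features:
            raise PhonemeError(f"unknown phoneme {symbol!r}")
        return symbol

    def vector(self, symbol: str) -> tuple[float, ...]:
        symbol = self.resolve(symbol)
        if symbol in self.vowel_features:
            return self.vowel_features[symbol]
        return self.consonant_features[symbol]

    def phoneme(self, symbol: str) -> Phoneme:
        symbol = self.resolve(symbol)
        return Phoneme(symbol, self.category(symbol))


def _read_rows(path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(line for line in fh if not line.startswith("#")))
    return rows


def load_aliases(path) -> dict[str, str]:
    """Read an ``ascii,ipa`` alias CSV into a mapping."""
    return {row["ascii"]: row["ipa"] for row in _read_rows(path)}


def load_feature_table(vowels_path, consonants_path, aliases_path=None) -> FeatureTable:
    """Load and validate a feature table from the two category CSV fixtures.

    Each CSV has columns ``symbol,category,<feature...>``; values must parse
    as reals in [0, 1], symbols must be unique, and every row's category must
    match its file.  Offending rows are named in the raised error.
    """
    tables: dict[str, dict[str, tuple[float, ...]]] = {"vowel": {}, "consonant": {}}
    for path, category, feature_names in (
        (vowels_path, "vowel", VOWEL_FEATURES),
        (consonants_path, "consonant", CONSONANT_FEATURES),
    ):
        for i, row in enumerate(_read_rows(path), start=2):
            sym = (row.get("symbol") or "").strip()
            if not sym:
                raise FeatureTableError(f"{path}: row {i}: missing symbol")
            if row.get("category") != category:
                raise FeatureTableError(
                    f"{path}: row {i} ({sym!r}): category {row.get('category')!r}, "
                    f"expected {category!r}"
                )
            if sym in tables[category]:
                raise FeatureTableError(f"{path}: row {i}: duplicate symbol {sym!r}")
            vec = []
            for feat in feature_names:
                cell = row.get(feat)
                if cell is None or cell.strip() == "":
                    raise FeatureTableError(f"{path}: row {i} ({sym!r}): missing {feat}")
                try:
                    value = float(cell)
                except ValueError as exc:
                    raise FeatureTableError(
                        f"{path}: row {i} ({sym!r}): bad value {cell!r} for {feat}"
                    ) from exc
                if not (0.0 <= value <= 1.0):
                    raise FeatureTableError(
                        f"{path}: row {i} ({sym!r}): {feat}={value} outside [0,1]"
                    )
                vec.append(value)
            tables[category][sym] = tuple(vec)
    aliases = load_aliases(aliases_path) if aliases_path is not None else None
    return FeatureTable(tables["vowel"], tables["consonant"], aliases)


def default_feature_table() -> FeatureTable:
    """The shipped feature table (published values plus the /i/ extension)."""
    data = resources.files("speakvar.data")
    return load_feature_table(
        data / "vowels.csv", data / "consonants.csv", data / "aliases.csv"
    )


# -- distances and costs ------------------------------------------------


def phoneme_distance(a: str, b: str, table: FeatureTable) -> float:
    """L1 distance between same-category phonemes in feature space.

    Cross-category pairs have no feature distance; they are costed only by
    :class:`CostScheme`'s flat cross-category cost.
    """
    pa, pb = table.phoneme(a), table.phoneme(b)
    if pa.category != pb.category:
        raise PhonemeError(
            f"cross-category pair ({pa.symbol!r}, {pb.symbol!r}) has no feature distance"
        )
    va, vb = table.vector(pa.symbol), table.vector(pb.symbol)
    return sum(abs(x - y) for x, y in zip(va, vb))


def max_category_distance(table: FeatureTable, category: str) -> float:
    """Maximum pairwise feature distance within a category (brute force)."""
    if category not in ("vowel", "consonant"):
        raise FeatureTableError(f"unknown category {category!r}")
    mapping = table.vowel_features if category == "vowel" else table.consonant_features
    if not mapping:
        raise FeatureTableError(f"empty category {category!r}")
    syms = list(mapping)
    if len(syms) == 1:
        return 0.0
    return max(phoneme_distance(a, b, table) for a, b in combinations(syms, 2))


@dataclass(frozen=True)
class CostScheme:
    """Edit-cost parameters for the weighted Levenshtein distance.

    Within-category substitutions are scaled by the category's maximum
    pairwise distance and the 0.8 ceiling, so every per-edit cost lies in
    [0, 1] and length-normalized string distances stay in [0, 1].
    """

    indel_cost: float = 1.0
    within_category_scale: float = 0.8
    cross_category_cost: float = 1.0
    vowel_normalizer: float = EXPECTED_VOWEL_NORMALIZER
    consonant_normalizer: float = EXPECTED_CONSONANT_NORMALIZER

    def __post_init__(self) -> None:
        if self.vowel_normalizer <= 0 or self.consonant_normalizer <= 0:
            raise ValueError("category normalizers must be strictly positive")

    @classmethod
    def from_table(
        cls,
        table: FeatureTable,
        *,
        expected_vowel: float | None = None,
        expected_consonant: float | None = None,
        **kwargs,
    ) -> "CostScheme":
        """Compute the normalizers from ``table``.

        If expected constants are given, a mismatch with the recomputed
        maxima is an error: it means the fixture was edited.
        """
        v = max_category_distance(table, "vowel")
        c = max_category_distance(table, "consonant")
        if expected_vowel is not None and abs(v - expected_vowel) > 1e-12:
            raise FeatureTableError(
                f"vowel normalizer {v} != expected {expected_vowel}; "
                "feature table drifted"
            )
        if expected_consonant is not None and abs(c - expected_consonant) > 1e-12:
            raise FeatureTableError(
                f"consonant normalizer {c} != expected {expected_consonant}; "
                "feature table drifted"
            )
        return cls(vowel_normalizer=v, consonant_normalizer=c, **kwargs)


def default_cost_scheme(table: FeatureTable | None = None) -> CostScheme:
    """The published cost scheme, with normalizers recomputed and checked."""
    table = table if table is not None else default_feature_table()
    return CostScheme.from_table(
        table,
        expected_vowel=EXPECTED_VOWEL_NORMALIZER,
        expected_consonant=EXPECTED_CONSONANT_NORMALIZER,
    )


def substitution_cost(a: str, b: str, table: FeatureTable, scheme: CostScheme) -> float:
    """Cost of replacing phoneme ``a`` with ``b`` under ``scheme``."""
    pa, pb = table.phoneme(a), table.phoneme(b)
    if pa.symbol == pb.symbol:
        return 0.0
    if pa.category != pb.category:
        return scheme.cross_category_cost
    norm = (
        scheme.vowel_normalizer
        if pa.category == "vowel"
        else scheme.consonant_normalizer
    )
    return (
        phoneme_distance(pa.symbol, pb.symbol, table)
        / norm
        * scheme.within_category_scale
    )


# -- transcription parsing ----------------------------------------------


def tokenize(transcription: str | Iterable[str], table: FeatureTable) -> tuple[str, ...]:
    """Split a transcription into canonical phoneme symbols.

    Accepts either an iterable of symbols or a string, in which case greedy
    longest-match against the inventory (and alias table) is used, so
    two-character symbols like ``tʃ`` or ASCII ``tS`` parse correctly.
    Leading hyphens (suffix notation) and whitespace are ignored.
    """
    if not isinstance(transcription, str):
        return tuple(table.resolve(s) for s in transcription)
    out: list[str] = []
    i = 0
    s = transcription
    while i < len(s):
        if s[i] in "- \t":
            i += 1
            continue
        for cand in table._match_symbols:
            if s.startswith(cand, i):
                out.append(table.resolve(cand))
                i += len(cand)
                break
        else:
            raise PhonemeError(f"unparseable symbol at position {i} in {transcription!r}")
    return tuple(out)
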