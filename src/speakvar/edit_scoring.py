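"""Weighted Levenshtein scoring of transcribed productions against targets.

A production is scored by the minimum-cost sequence of edits turning it
into its target: insertions and deletions cost 1, same-category
substitutions cost the feature distance scaled into [0, 0.8], and
cross-category substitutions cost 1.  The raw distance is normalized by the
length of the longer string (so it lies in [0, 1]) and accuracy is one
minus that value.

Example: production /kam/ against target /fi/ aligns as the substitutions
k->f ((1.3/4.25)*0.8) and a->i ((1.5/1.5)*0.8) plus one deletion of /m/
(cost 1); the normalized distance is 2.0447/3 = 0.682 and the accuracy
1 - 0.682 = 0.318.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .phone_features import (
    CostScheme,
    FeatureTable,
    PhonemeError,
    substitution_cost,
    tokenize,
)

__all__ = [
    "AlignmentResult",
    "weighted_edit_distance",
    "normalized_distance",
    "production_accuracy",
    "score_stem_table",
]


@dataclass
class AlignmentResult:
    """Distance, accuracy and one optimal edit script for a scored pair."""

    raw_distance: float
    normalized_distance: float
    accuracy: float
    edit_script: list[tuple[str, int, str]] = field(default_factory=list)


def _as_symbols(s, table: FeatureTable) -> tuple[str, ...]:
    return tokenize(s, table)


def _dp_matrix(
    source: tuple[str, ...],
    target: tuple[str, ...],
    table: FeatureTable,
    scheme: CostScheme,
) -> list[list[float]]:
    m, n = len(source), len(target)
    d = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        d[i][0] = i * scheme.indel_cost
    for j in range(1, n + 1):
        d[0][j] = j * scheme.indel_cost
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = d[i - 1][j - 1] + substitution_cost(
                source[i - 1], target[j - 1], table, scheme
            )
            delete = d[i - 1][j] + scheme.indel_cost
            insert = d[i][j - 1] + scheme.indel_cost
            d[i][j] = min(sub, delete, insert)
    return d


def weighted_edit_distance(source, target, table: FeatureTable, scheme: CostScheme) -> float:
    """Minimum total edit cost between two phoneme strings (either may be empty)."""
    s, t = _as_symbols(source, table), _as_symbols(target, table)
    return _dp_matrix(s, t, table, scheme)[len(s)][len(t)]


def normalized_distance(source, target, table: FeatureTable, scheme: CostScheme) -> float:
    """Edit distance divided by the length of the longer string.

    The both-empty case is defined as 0 (identity); with every per-position
    cost at most 1 the result lies in [0, 1].
    """
    s, t = _as_symbols(source, table), _as_symbols(target, table)
    longest = max(len(s), len(t))
    if longest == 0:
        return 0.0
    return _dp_matrix(s, t, table, scheme)[len(s)][len(t)] / longest


def production_accuracy(
    source, target, table: FeatureTable, scheme: CostScheme
) -> AlignmentResult:
    """Score a production against a (nonempty) target string.

    Returns the raw and normalized distances, the accuracy (1 minus the
    normalized distance) and one optimal edit script.  Ties among
    equal-cost alignments are broken substitution > deletion > insertion so
    the script is reproducible; the distance itself is tie-free.
    """
    s, t = _as_symbols(source, table), _as_symbols(target, table)
    if len(t) == 0:
        raise PhonemeError("empty target: no target string in the language is empty")
    d = _dp_matrix(s, t, table, scheme)
    raw = d[len(s)][len(t)]
    norm = raw / max(len(s), len(t))

    script: list[tuple[str, int, str]] = []
    i, j = len(s), len(t)
    eps = 1e-12
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = substitution_cost(s[i - 1], t[j - 1], table, scheme)
            if abs(d[i][j] - (d[i - 1][j - 1] + cost)) < eps:
                if cost > 0:
                    script.append(("substitute", i - 1, f"{s[i - 1]}->{t[j - 1]}"))
                else:
                    script.append(("match", i - 1, s[i - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(d[i][j] - (d[i - 1][j] + scheme.indel_cost)) < eps:
            script.append(("delete", i - 1, s[i - 1]))
            i -= 1
            continue
        script.append(("insert", i, t[j - 1]))
        j -= 1
    script.reverse()
    return AlignmentResult(raw, norm, 1.0 - norm, script)


def score_stem_table(
    productions: pd.DataFrame,
    table: FeatureTable,
    scheme: CostScheme,
    *,
    production_col: str = "stem_transcription",
    target_col: str = "stem_target",
) -> pd.DataFrame:
    """Append stem distance/accuracy columns to a production table.

    The input carries one row per trial with pre-segmented stem
    transcriptions (alias-ASCII or IPA); segmentation itself happens
    upstream, by hand in the lab workflow or by construction in simulation.
    """
    out = productions.copy()
    raws, norms, accs = [], [], []
    for _, row in out.iterrows():
        res = production_accuracy(row[production_col], row[target_col], table, scheme)
        raws.append(res.raw_distance)
        norms.append(res.normalized_distance)
        accs.append(res.accuracy)
    out["stem_raw_distance"] = raws
    out["stem_normalized_distance"] = norms
    out["stem_accuracy"] = accs
    return out
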