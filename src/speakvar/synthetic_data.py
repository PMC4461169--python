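"""Synthetic participants with the statistical structure the analyses assume.

No human data ships with this project, so every downstream stage is
exercised on simulated learners:

* segmentation trials are Bernoulli draws from a logistic model whose
  fixed-effect structure (condition, speaker identity, test order, their
  interaction; Normal participant intercepts) is exactly the model the
  analysis fits — a correctly specified generative check whose default
  coefficients are the published fitted values;
* production trials emit phoneme-string stems corrupted toward a target
  expected accuracy that rises over rounds and drops for novel items, and
  affixes drawn from a mixture over qualitatively distinct production types
  (exact alternation, wrong-harmony alternation, near miss, unrelated
  string, silence) whose exact-production probability follows the same
  round/novelty logic.

The stem corruption rate is calibrated per target by a small Monte-Carlo
grid (noise rate -> mean scored accuracy, fixed internal seed) inverted by
interpolation, so the scorer sees strings whose mean accuracy tracks the
requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .affix_coding import TargetLanguage, sample_training_set
from .edit_scoring import production_accuracy
from .phone_features import CostScheme, FeatureTable, phoneme_distance, tokenize

__all__ = [
    "SegmentationSimParams",
    "ProductionSimParams",
    "SimulationError",
    "simulate_segmentation_experiment",
    "simulate_production_experiment",
    "corrupt_string",
]


class SimulationError(ValueError):
    """Simulation parameters are inconsistent with the design."""


@dataclass(frozen=True)
class SegmentationSimParams:
    """Logit-scale generating coefficients for the forced-choice experiment.

    Defaults are the published fitted values under centred +/-0.5 coding
    (multiple condition, novel speaker and familiar-test-second at +0.5).
    The participant intercept sd has no published estimate; 0.5 logits is a
    deliberately arbitrary documented default.
    """

    beta_intercept: float = 0.343
    beta_condition: float = 0.097
    beta_speaker_identity: float = -0.439
    beta_order: float = -0.258
    beta_interaction: float = -0.093
    participant_sd: float = 0.5
    trials_per_block: int = 36


def simulate_segmentation_experiment(
    design: pd.DataFrame,
    params: SegmentationSimParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate per-trial correctness for every participant in ``design``.

    ``design`` is the speaker-assignment table (one row per participant
    with ``condition`` and ``familiar_first``); each participant completes
    two 36-trial blocks (familiar- and novel-voice).  Centred codes are
    computed from the realized design so they are exactly mean-zero.
    """
    required = {"participant", "condition", "familiar_first"}
    if not required.issubset(design.columns):
        raise SimulationError(f"design table needs columns {sorted(required)}")
    if params.participant_sd < 0:
        raise SimulationError("participant_sd must be >= 0")

    rows = []
    for _, d in design.iterrows():
        for kind in ("familiar", "novel"):
            for trial in range(params.trials_per_block):
                rows.append(
                    {
                        "participant": d["participant"],
                        "condition": d["condition"],
                        "block_kind": kind,
                        "trial": trial,
                        "condition_code": 1.0 if d["condition"] == "multiple" else 0.0,
                        "novel_speaker": 1.0 if kind == "novel" else 0.0,
                        "familiar_second": 0.0 if d["familiar_first"] else 1.0,
                    }
                )
    table = pd.DataFrame(rows)
    for col in ("condition_code", "novel_speaker", "familiar_second"):
        table[col] = table[col] - table[col].mean()

    intercepts = rng.normal(0.0, params.participant_sd, size=design["participant"].nunique())
    pid_index = {p: i for i, p in enumerate(design["participant"])}
    eta = (
        params.beta_intercept
        + params.beta_condition * table["condition_code"]
        + params.beta_speaker_identity * table["novel_speaker"]
        + params.beta_order * table["familiar_second"]
        + params.beta_interaction * table["condition_code"] * table["novel_speaker"]
        + np.array([intercepts[pid_index[p]] for p in table["participant"]])
    )
    table["correct"] = (rng.random(len(table)) < expit(eta.to_numpy())).astype(int)
    return table


# -- production experiment ----------------------------------------------

_PROFILE_KEYS = ("exact", "wrong_harmony", "near_miss", "unrelated", "silent")


@dataclass(frozen=True)
class ProductionSimParams:
    """Generating parameters for the morphology-learning experiment.

    Stem expected accuracy is ``base + round_slope*(round-1) -
    novelty_penalty*novel + participant effect`` on the accuracy scale; the
    round and novelty defaults are the published linear-model estimates.
    The affix production-type mixture starts at ``affix_profile`` and its
    exact-production probability moves on the logit scale by
    ``affix_round_slope`` per round (centred) and down by
    ``affix_novelty_penalty`` for novel items.
    """

    base_accuracy: float = 0.55
    round_slope: float = 0.059
    novelty_penalty: float = 0.020
    participant_sd: float = 0.05
    affix_profile: dict = field(
        default_factory=lambda: {
            "exact": 0.50,
            "wrong_harmony": 0.20,
            "near_miss": 0.15,
            "unrelated": 0.10,
            "silent": 0.05,
        }
    )
    affix_round_slope: float = 0.30
    affix_novelty_penalty: float = 1.10

    def __post_init__(self) -> None:
        if set(self.affix_profile) != set(_PROFILE_KEYS):
            raise SimulationError(f"affix_profile must have keys {_PROFILE_KEYS}")
        if abs(sum(self.affix_profile.values()) - 1.0) > 1e-9:
            raise SimulationError("affix_profile must sum to 1")
        if not (0.0 < self.base_accuracy < 1.0):
            raise SimulationError("base_accuracy must be in (0,1)")


# -- stem corruption -----------------------------------------------------

_CALIBRATION_CACHE: dict = {}
_GRID = np.linspace(0.0, 1.0, 11)
_CAL_DRAWS = 200
_CAL_SEED = 202306


def _apply_noise(
    target: tuple[str, ...],
    rate: float,
    table: FeatureTable,
    rng: np.random.Generator,
    ops_weights: tuple[float, float, float],
) -> tuple[str, ...]:
    """One corrupted draw: per position substitute / delete / insert."""
    w_sub, w_del, w_ins = ops_weights
    out: list[str] = []
    for sym in target:
        u = rng.random()
        if u < rate * w_del:
            continue
        if u < rate * (w_del + w_sub):
            out.append(_neighbour(sym, table, rng))
        else:
            out.append(sym)
        if rng.random() < rate * w_ins:
            pool = table.symbols()
            out.append(pool[int(rng.integers(len(pool)))])
    return tuple(out)


def _neighbour(sym: str, table: FeatureTable, rng: np.random.Generator) -> str:
    """A same-category replacement, weighted toward nearby feature vectors."""
    category = table.category(sym)
    pool = [
        s
        for s in (table.vowel_features if category == "vowel" else table.consonant_features)
        if s != table.resolve(sym)
    ]
    dists = np.array([phoneme_distance(sym, s, table) for s in pool])
    weights = np.exp(-dists)
    weights /= weights.sum()
    return pool[int(rng.choice(len(pool), p=weights))]


def _calibration_curve(
    target: tuple[str, ...],
    table: FeatureTable,
    scheme: CostScheme,
    ops_weights: tuple[float, float, float],
) -> np.ndarray:
    """Mean scored accuracy at each grid noise rate (fixed internal seed)."""
    key = (target, ops_weights, scheme.within_category_scale, scheme.indel_cost)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    cal_rng = np.random.default_rng(_CAL_SEED + len(target))
    means = np.empty_like(_GRID)
    for i, r in enumerate(_GRID):
        if r == 0.0:
            means[i] = 1.0
            continue
        accs = [
            production_accuracy(
                _apply_noise(target, r, table, cal_rng, ops_weights), target, table, scheme
            ).accuracy
            for _ in range(_CAL_DRAWS)
        ]
        means[i] = float(np.mean(accs))
    _CALIBRATION_CACHE[key] = means
    return means


def corrupt_string(
    target,
    expected_accuracy: float,
    table: FeatureTable,
    scheme: CostScheme,
    rng: np.random.Generator,
    *,
    ops_weights: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> tuple[str, ...]:
    """Corrupt ``target`` so the mean scored accuracy tracks the request.

    Per-position edits (feature-weighted same-category substitution,
    deletion, insertion in proportions ``ops_weights``) are applied at a
    rate read off the target's Monte-Carlo calibration curve.  Requested
    accuracies below the curve's floor are met by mixing in fully deleted
    (empty) productions.  1 returns the target unchanged; 0 the empty
    string.
    """
    if not (0.0 <= expected_accuracy <= 1.0):
        raise SimulationError(f"expected_accuracy {expected_accuracy} outside [0,1]")
    target = tokenize(target, table)
    if len(target) == 0:
        raise SimulationError("cannot corrupt an empty target")
    if expected_accuracy >= 1.0:
        return target
    if expected_accuracy <= 0.0:
        return ()
    curve = _calibration_curve(target, table, scheme, ops_weights)
    floor = float(curve.min())
    if expected_accuracy < floor:
        # mixture with the empty production hits the expectation exactly
        p_keep = expected_accuracy / floor
        if rng.random() >= p_keep:
            return ()
        rate = float(_GRID[int(curve.argmin())])
    else:
        # curve decreases in rate; invert by interpolation on the reversed axis
        rate = float(np.interp(-expected_accuracy, -curve, _GRID))
    return _apply_noise(target, rate, table, rng, ops_weights)


def simulate_production_experiment(
    language: TargetLanguage,
    design: pd.DataFrame,
    params: ProductionSimParams,
    table: FeatureTable,
    scheme: CostScheme,
    rng: np.random.Generator,
    *,
    n_rounds: int = 6,
) -> pd.DataFrame:
    """Simulate stem and affix productions for every designed participant.

    Each participant gets a constraint-satisfying 8-sentence training set;
    all 12 sentences are tested every round, the 4 untrained ones flagged
    novel.  Returns one row per (participant, round, sentence) with target
    and produced transcriptions.
    """
    if not {"participant", "condition"}.issubset(design.columns):
        raise SimulationError("design table needs participant and condition columns")

    base_logit_exact = params.affix_profile["exact"]
    other_keys = [k for k in _PROFILE_KEYS if k != "exact"]
    other_base = np.array([params.affix_profile[k] for k in other_keys])

    rows = []
    for _, d in design.iterrows():
        training = sample_training_set(language, rng)
        trained_ids = {(s.noun.gloss, s.case.name) for s in training}
        u_i = rng.normal(0.0, params.participant_sd)
        for rnd in range(1, n_rounds + 1):
            order = rng.permutation(len(language.sentences))
            for idx in order:
                s = language.sentences[idx]
                novel = (s.noun.gloss, s.case.name) not in trained_ids
                exp_acc = float(
                    np.clip(
                        params.base_accuracy
                        + params.round_slope * (rnd - 1)
                        - params.novelty_penalty * novel
                        + u_i,
                        0.02,
                        0.98,
                    )
                )
                stem_prod = corrupt_string(s.noun.stem, exp_acc, table, scheme, rng)

                if base_logit_exact in (0.0, 1.0):
                    p_exact = base_logit_exact
                else:
                    p_exact = float(
                        expit(
                            logit(base_logit_exact)
                            + params.affix_round_slope * (rnd - (n_rounds + 1) / 2)
                            - params.affix_novelty_penalty * novel
                        )
                    )
                if other_base.sum() > 0:
                    others = (1.0 - p_exact) * other_base / other_base.sum()
                else:
                    others = np.zeros_like(other_base)
                probs = np.concatenate([[p_exact], others])
                kind = (_PROFILE_KEYS[0], *other_keys)[int(rng.choice(len(probs), p=probs))]
                affix_prod = _realize_affix(kind, s, language, table, rng)

                rows.append(
                    {
                        "participant": d["participant"],
                        "condition": d["condition"],
                        "round": rnd,
                        "gloss": s.noun.gloss,
                        "case": s.case.name,
                        "item_id": s.image_id,
                        "novel": int(novel),
                        "stem_target": "".join(s.noun.stem),
                        "stem_transcription": "".join(stem_prod),
                        "affix_target": "".join(s.target_suffix),
                        "affix_transcription": "".join(affix_prod),
                        "production_kind": kind,
                    }
                )
    return pd.DataFrame(rows)


def _realize_affix(
    kind: str,
    sentence,
    language: TargetLanguage,
    table: FeatureTable,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    target = sentence.target_suffix
    suffixes = {suf for _, suf, _ in language.all_suffixes()}
    if kind == "exact":
        return target
    if kind == "wrong_harmony":
        other = "back" if sentence.noun.harmony == "front" else "front"
        return sentence.case.suffix(other)
    if kind == "silent":
        return ()
    if kind == "near_miss":
        for _ in range(20):
            pos = int(rng.integers(len(target)))
            mutated = list(target)
            mutated[pos] = _neighbour(target[pos], table, rng)
            cand = tuple(mutated)
            if cand not in suffixes:
                return cand
        kind = "unrelated"  # pathological suffix inventory; fall through
    # unrelated: a random CVC over the language's own phonemes
    vowels = sorted({p for s in suffixes for p in s if table.category(p) == "vowel"})
    consonants = sorted({p for s in suffixes for p in s if table.category(p) == "consonant"})
    for _ in range(50):
        cand = (
            consonants[int(rng.integers(len(consonants)))],
            vowels[int(rng.integers(len(vowels)))],
            consonants[int(rng.integers(len(consonants)))],
        )
        if cand not in suffixes:
            return cand
    raise SimulationError("could not draw an unrelated affix distinct from the suffixes")
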