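"""Dominance scoring and classification.

Implements the two rating systems used for cage hierarchies — an Elo
system that accepts ties and temporal order, and David's score built from
dyadic win proportions — plus the directional consistency index (DCI),
assay-specific match-outcome rules (urine-spot tie rule, majority rule for
reward-competition trials), simplification of scores to a 1–4 cage rank,
and the per-dyad stability classification used for cross-assay rank
comparisons.

Elo: each contest updates both opponents by ``R' = R + K (S − E)`` with
``E_A = 1 / (1 + 10^{(R_B − R_A)/scale})`` and score ``S ∈ {1, 0, 0.5}``
(0.5 for a tie). With K = 20, scale = 400 and a 1,000 baseline, a cage
that never fights keeps everyone at baseline, and every update is exactly
zero-sum.

David's score: from the win matrix α (α_ij = wins of i over j) the dyadic
proportions are ``P_ij = α_ij / (α_ij + α_ji)`` for dyads that interacted,
then ``DS_i = w_i + w2_i − l_i − l2_i`` with ``w_i = Σ_j P_ij``,
``w2_i = Σ_j P_ij w_j``, ``l_i = Σ_j P_ji``, ``l2_i = Σ_j P_ji l_j``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from domsuite.errors import UnmeasurableError, ValidationError
from domsuite.records_io import Assay, MatchRecord, Outcome


@dataclass(frozen=True)
class EloConfig:
    """Constants controlling rating sensitivity.

    ``k_factor`` is the maximum points transferred per match, ``scale``
    sets how a rating gap maps to win expectancy (a gap of one scale unit
    is 10:1 odds), and ``baseline`` is every animal's starting rating.
    """

    k_factor: float = 20.0
    scale: float = 400.0
    baseline: float = 1000.0

    def __post_init__(self) -> None:
        if self.k_factor <= 0 or self.scale <= 0:
            raise ValidationError("k_factor and scale must be positive")


@dataclass
class RatingHistory:
    """Per-animal Elo trajectories for one assay × cage.

    ``trajectory[animal]`` lists (order, post-match rating) for matches the
    animal took part in; ``final`` maps animal → final rating; ``rank``
    maps animal → dense 1..n rank (1 = highest final rating).
    """

    baseline: float
    trajectory: dict[str, list[tuple[int, float]]]
    final: dict[str, float]
    rank: dict[str, int]


@dataclass
class DavidTable:
    """Win matrix, dyadic proportions and David's-score components."""

    animals: list[str]
    alpha: np.ndarray
    p: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray

    def score_of(self, animal: str) -> float:
        return float(self.ds[self.animals.index(animal)])


class Stability(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    UNMEASURABLE = "unmeasurable"


@dataclass(frozen=True)
class DyadStatus:
    """Stability classification of one dyad in one assay."""

    id_a: str
    id_b: str
    assay: Assay
    n_interactions: int
    same_winner_fraction: float | None
    status: Stability
    dominant_id: str | None


@dataclass(frozen=True)
class GroupDCI:
    cage: str
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValidationError(f"DCI {self.value} outside [0, 1]")


def elo_expected(r_a: float, r_b: float, cfg: EloConfig = EloConfig()) -> float:
    """Expected probability that the first opponent wins."""
    return 1.0 / (1.0 + 10.0 ** ((r_b - r_a) / cfg.scale))


_SCORE = {Outcome.A_WINS: 1.0, Outcome.B_WINS: 0.0, Outcome.TIE: 0.5}


def elo_update(
    r_a: float, r_b: float, outcome: Outcome, cfg: EloConfig = EloConfig()
) -> tuple[float, float]:
    """One match update; returns (r_a', r_b').

    Constructed to be exactly zero-sum: the same point delta is added to
    one side and subtracted from the other.
    """
    s_a = _SCORE[outcome]
    delta = cfg.k_factor * (s_a - elo_expected(r_a, r_b, cfg))
    return r_a + delta, r_b - delta


def elo_ratings(
    matches: Sequence[MatchRecord],
    cfg: EloConfig = EloConfig(),
    animals: Iterable[str] = (),
) -> RatingHistory:
    """Fold the Elo update over a chronologically ordered match list.

    All matches must come from one assay × cage, sorted by ``order``.
    Animals listed in ``animals`` but never matched stay at baseline (the
    rating of a cage that did not fight). Ties update via S = 0.5.
    """
    if len({(m.assay, m.cage) for m in matches}) > 1:
        raise ValidationError("matches span multiple assay/cage groups")
    orders = [m.order for m in matches]
    if orders != sorted(orders):
        raise ValidationError("matches are not sorted by chronological order")

    ratings: dict[str, float] = {a: cfg.baseline for a in animals}
    trajectory: dict[str, list[tuple[int, float]]] = {a: [] for a in ratings}
    for m in matches:
        for animal in (m.id_a, m.id_b):
            ratings.setdefault(animal, cfg.baseline)
            trajectory.setdefault(animal, [])
        ra, rb = elo_update(ratings[m.id_a], ratings[m.id_b], m.outcome, cfg)
        ratings[m.id_a], ratings[m.id_b] = ra, rb
        trajectory[m.id_a].append((m.order, ra))
        trajectory[m.id_b].append((m.order, rb))

    final = dict(ratings)
    return RatingHistory(
        baseline=cfg.baseline,
        trajectory=trajectory,
        final=final,
        rank=simplify_ranks(final),
    )


def win_matrix(matches: Sequence[MatchRecord]) -> tuple[list[str], np.ndarray]:
    """Animal list (sorted) and integer win-count matrix α; ties excluded."""
    animals = sorted({a for m in matches for a in (m.id_a, m.id_b)})
    index = {a: i for i, a in enumerate(animals)}
    alpha = np.zeros((len(animals), len(animals)), dtype=int)
    for m in matches:
        if m.outcome is Outcome.A_WINS:
            alpha[index[m.id_a], index[m.id_b]] += 1
        elif m.outcome is Outcome.B_WINS:
            alpha[index[m.id_b], index[m.id_a]] += 1
    return animals, alpha


def david_scores_from_alpha(animals: Sequence[str], alpha: np.ndarray) -> DavidTable:
    """David's score from a win matrix. Non-interacting dyads contribute 0."""
    n = len(animals)
    if n < 2:
        raise ValidationError("David's score needs at least two animals")
    if alpha.sum() == 0:
        raise UnmeasurableError(
            "no decisive interactions: David's score cannot be calculated "
            "for a group that did not fight"
        )
    totals = alpha + alpha.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, alpha / np.where(totals > 0, totals, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    w = p.sum(axis=1)
    w2 = p @ w
    l = p.sum(axis=0)
    l2 = p.T @ l
    ds = w + w2 - l - l2
    return DavidTable(list(animals), alpha.copy(), p, w, w2, l, l2, ds)


def david_scores(matches: Sequence[MatchRecord]) -> DavidTable:
    """David's score table for one assay × cage; ties are excluded from α."""
    if len({(m.assay, m.cage) for m in matches}) > 1:
        raise ValidationError("matches span multiple assay/cage groups")
    animals, alpha = win_matrix(matches)
    return david_scores_from_alpha(animals, alpha)


def dci(matches: Sequence[MatchRecord], cage: str | None = None) -> GroupDCI:
    """Directional consistency index for one cage's matches.

    With H = decisive interactions in each dyad's more frequent direction
    and L = the complementary total, DCI = (H − L)/(H + L): 1 when every
    dyad is unidirectional, 0 when every dyad is evenly split. Suited to
    small groups because it needs no hierarchy fit.
    """
    animals, alpha = win_matrix(matches)
    if alpha.sum() == 0:
        raise UnmeasurableError("no decisive interactions: DCI is unmeasurable")
    h = 0
    low = 0
    n = len(animals)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = int(alpha[i, j]), int(alpha[j, i])
            h += max(a, b)
            low += min(a, b)
    if cage is None:
        cages = {m.cage for m in matches}
        cage = cages.pop() if len(cages) == 1 else "mixed"
    return GroupDCI(cage=cage, value=(h - low) / (h + low))


def simplify_ranks(final_scores: Mapping[str, float]) -> dict[str, int]:
    """Dense 1..n ranks from scores; 1 = highest.

    Equal scores are broken deterministically by animal identifier so the
    rank vector is always a permutation of 1..n.
    """
    if not final_scores:
        raise ValidationError("no scores to rank")
    ordered = sorted(final_scores, key=lambda a: (-final_scores[a], a))
    return {animal: i + 1 for i, animal in enumerate(ordered)}


def urine_outcome(spots_a: int, spots_b: int) -> Outcome:
    """Outcome of a urine-marking match from per-animal spot counts.

    A tie is declared when the counts differ by fewer than 5 spots or by
    less than 20% of the larger count; otherwise the animal with more
    spots wins. The 20% comparison uses exact rational arithmetic so the
    boundary is not subject to floating-point jitter.
    """
    if spots_a < 0 or spots_b < 0:
        raise ValidationError("spot counts must be non-negative")
    diff = abs(spots_a - spots_b)
    larger = max(spots_a, spots_b)
    if larger == 0 or diff < 5 or Fraction(diff, larger) < Fraction(1, 5):
        return Outcome.TIE
    return Outcome.A_WINS if spots_a > spots_b else Outcome.B_WINS


def reward_match_outcome(
    trial_winners: Sequence[str | None], id_a: str, id_b: str
) -> Outcome:
    """Match outcome from per-trial winner labels (None = tied trial).

    Tied trials are excluded from the denominator; the animal winning more
    than 50% of decisive trials wins the match. An exact split is broken
    deterministically: the lexicographically lower identifier is assigned
    the win. All-tied → TIE.
    """
    if not trial_winners:
        raise ValidationError("no trials")
    wins_a = sum(1 for t in trial_winners if t == id_a)
    wins_b = sum(1 for t in trial_winners if t == id_b)
    unknown = [t for t in trial_winners if t not in (id_a, id_b, None)]
    if unknown:
        raise ValidationError(f"winner labels {unknown} match neither animal")
    if wins_a + wins_b == 0:
        return Outcome.TIE
    if wins_a == wins_b:
        return Outcome.A_WINS if min(id_a, id_b) == id_a else Outcome.B_WINS
    return Outcome.A_WINS if wins_a > wins_b else Outcome.B_WINS


# Inclusive same-winner thresholds per assay; agonistic additionally
# requires a minimum interaction count to be measurable at all.
STABILITY_THRESHOLDS: dict[Assay, Fraction] = {
    Assay.AGONISTIC: Fraction(3, 4),
    Assay.TUBE: Fraction(3, 4),
    Assay.REWARD: Fraction(3, 5),
}
AGONISTIC_MIN_INTERACTIONS = 3


def classify_dyad_stability(matches: Sequence[MatchRecord], assay: Assay) -> DyadStatus:
    """Classify one dyad's hierarchy stability in one assay.

    Criteria (thresholds inclusive):

    - agonistic: ≥3 interactions, ≥75% initiated (won) by the same mouse;
      fewer than 3 interactions → unmeasurable;
    - urine: all trials decisive with the same winner;
    - tube: ≥75% of matches won by the same mouse;
    - reward: ≥60% of decisive trials won by the same mouse (tied trials
      excluded from the denominator).

    A dyad with no interactions at all is unmeasurable in every assay.
    """
    assays = {m.assay for m in matches}
    if assays - {assay}:
        raise ValidationError(f"matches from assays {assays} passed for {assay}")
    pairs = {frozenset((m.id_a, m.id_b)) for m in matches}
    if len(pairs) > 1:
        raise ValidationError("matches span more than one dyad")
    if matches:
        id_a, id_b = sorted(pairs.pop())
    else:
        id_a = id_b = ""

    n = len(matches)
    wins = {id_a: 0, id_b: 0}
    for m in matches:
        if m.outcome is Outcome.A_WINS:
            wins[m.id_a] += 1
        elif m.outcome is Outcome.B_WINS:
            wins[m.id_b] += 1
    decisive = wins[id_a] + wins[id_b] if matches else 0

    def result(status: Stability, frac: Fraction | None, dom: str | None) -> DyadStatus:
        return DyadStatus(
            id_a=id_a,
            id_b=id_b,
            assay=assay,
            n_interactions=n,
            same_winner_fraction=None if frac is None else float(frac),
            status=status,
            dominant_id=dom if status is Stability.STABLE else None,
        )

    if n == 0:
        return result(Stability.UNMEASURABLE, None, None)

    if assay is Assay.URINE:
        # stable iff every trial is decisive with the same winner
        frac = Fraction(max(wins.values()), n) if n else None
        if decisive == n and min(wins.values()) == 0:
            return result(Stability.STABLE, Fraction(1), max(wins, key=wins.get))
        return result(Stability.UNSTABLE, frac, None)

    if assay is Assay.AGONISTIC and n < AGONISTIC_MIN_INTERACTIONS:
        return result(Stability.UNMEASURABLE, None, None)

    if assay in (Assay.AGONISTIC, Assay.TUBE):
        denom = n  # all matches count, ties (if any) dilute consistency
    else:  # reward: tied trials excluded
        denom = decisive
    if denom == 0:
        return result(Stability.UNMEASURABLE, None, None)
    top = max(wins, key=lambda a: (wins[a], a))
    frac = Fraction(wins[top], denom)
    if frac >= STABILITY_THRESHOLDS[assay]:
        return result(Stability.STABLE, frac, top)
    return result(Stability.UNSTABLE, frac, None)


def group_matches(
    matches: Sequence[MatchRecord],
) -> dict[tuple[Assay, str], list[MatchRecord]]:
    """Split a mixed match list into per-(assay, cage) chronological lists."""
    groups: dict[tuple[Assay, str], list[MatchRecord]] = {}
    for m in sorted(matches, key=lambda r: (r.assay.value, r.cage, r.order)):
        groups.setdefault((m.assay, m.cage), []).append(m)
    return groups


def dyads(matches: Sequence[MatchRecord]) -> dict[frozenset, list[MatchRecord]]:
    """Split one group's matches by unordered animal pair."""
    out: dict[frozenset, list[MatchRecord]] = {}
    for m in matches:
        out.setdefault(frozenset((m.id_a, m.id_b)), []).append(m)
    return out


def all_dyads(animals: Sequence[str]) -> list[tuple[str, str]]:
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(animals), 2)]
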