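"""Set analysis and set completion: which barcodes can be added to a pool.

The completion workflow answers the everyday pooling question: given the
samples already on a lane (with their shares) and k new libraries at
given shares, which k barcodes from a candidate pool keep the combined
set color balanced?  Small problems are solved exhaustively; large ones
fall back to a deterministic greedy beam search, flagged as
non-exhaustive in the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

from .balance import (
    BalanceVerdict,
    CriterionSpec,
    FractionMatrix,
    compute_fraction_matrix,
    default_criteria,
    evaluate_criterion,
)
from .decoder import DEFAULT_MISMATCH
from .distance import DecodabilityReport, decodability_check, hamming_matrix
from .panel import BarcodePanel, PanelError, WeightedBarcodeSet

EXHAUSTIVE_CAP = 100_000
BEAM_WIDTH = 64
_PERM_CAP = 5  # up to k! weight assignments tried exactly


Score = tuple[int, float, float]


def score_set(fm: FractionMatrix,
              criterion: CriterionSpec | None = None) -> Score:
    """Lexicographic balance score; lower is better.

    ``(n_outside, max |f - 0.25|, RMS deviation from 0.25)`` — a perfectly
    balanced matrix scores (0, 0, 0).  ``criterion`` defaults to the
    strong corridor.
    """
    if criterion is None:
        criterion, _ = default_criteria()
    verdict = evaluate_criterion(fm, criterion)
    dev = fm.values - 0.25
    rms = float(np.sqrt((dev ** 2).mean()))
    return (verdict.n_outside, fm.max_deviation, rms)


@dataclass
class SelectionProblem:
    """A set-completion request.

    ``current`` may be ``None`` for a from-scratch selection.  ``pool``
    must be disjoint from the current members; ``new_weights`` are the
    shares of the k new libraries relative to the current weights' scale.
    """

    current: WeightedBarcodeSet | None
    k: int
    new_weights: list[float]
    pool: list[str]
    criterion: CriterionSpec
    max_results: int = 10

    def __post_init__(self) -> None:
        self.pool = list(self.pool)
        if self.k < 0:
            raise PanelError("k must be >= 0")
        if self.k > len(self.pool):
            raise PanelError(
                f"k={self.k} exceeds pool size {len(self.pool)}"
            )
        if not self.new_weights:
            self.new_weights = [1.0] * self.k
        self.new_weights = [float(w) for w in self.new_weights]
        if len(self.new_weights) != self.k:
            raise PanelError(
                f"k={self.k} but {len(self.new_weights)} new weights"
            )
        if any(w <= 0 for w in self.new_weights):
            raise PanelError("new weights must be positive")
        if len(set(self.pool)) != len(self.pool):
            raise PanelError("pool ids must be distinct")
        if self.current is not None:
            overlap = set(self.pool) & set(self.current.members)
            if overlap:
                raise PanelError(
                    f"pool overlaps current members: {sorted(overlap)}"
                )
        if self.max_results < 1:
            raise PanelError("max_results must be >= 1")


@dataclass(frozen=True)
class SelectionCandidate:
    added: tuple[str, ...]
    added_weights: tuple[float, ...]
    verdict: BalanceVerdict
    score: Score


@dataclass
class SelectionResult:
    """Ranked passing completions (best first).

    ``exhaustive`` says whether every combination was evaluated; when the
    search fails, ``best_failing`` carries the closest near-miss so the
    user can relax to the lite corridor or raise ``max_outside``.
    """

    candidates: list[SelectionCandidate]
    exhaustive: bool
    n_evaluated: int
    best_failing: SelectionCandidate | None = None

    def to_dict(self) -> dict:
        d = {
            "exhaustive": self.exhaustive,
            "n_evaluated": self.n_evaluated,
            "candidates": [
                {
                    "added": list(c.added),
                    "added_weights": list(c.added_weights),
                    "score": list(c.score),
                    "verdict": c.verdict.to_dict(),
                }
                for c in self.candidates
            ],
        }
        if self.best_failing is not None:
            d["best_failing"] = {
                "added": list(self.best_failing.added),
                "score": list(self.best_failing.score),
                "offending": [
                    {"position": p, "base": b, "fraction": f}
                    for p, b, f in self.best_failing.verdict.offending
                ],
            }
        return d


def _combined_set(current: WeightedBarcodeSet | None,
                  added: Sequence[str],
                  added_weights: Sequence[float]) -> WeightedBarcodeSet:
    if current is None:
        return WeightedBarcodeSet(list(added), list(added_weights))
    return WeightedBarcodeSet(
        list(current.members) + list(added),
        list(current.weights) + list(added_weights),
    )


def _best_weight_assignment(problem: SelectionProblem, panel: BarcodePanel,
                            combo: tuple[str, ...]) -> tuple[
                                tuple[float, ...], FractionMatrix, Score]:
    """Match the k new weights to the k chosen barcodes.

    The pairing changes the fraction matrix when weights differ, so all
    k! assignments are scored exactly for small k; larger k uses a greedy
    one-at-a-time pairing.  Ties break on the weight ordering itself so
    results are deterministic.
    """
    weights = problem.new_weights
    if len(set(weights)) == 1 or problem.k <= 1:
        wset = _combined_set(problem.current, combo, weights)
        fm = compute_fraction_matrix(wset, panel)
        return tuple(weights), fm, score_set(fm, problem.criterion)
    best: tuple[Score, tuple[float, ...], FractionMatrix] | None = None
    if problem.k <= _PERM_CAP:
        seen: set[tuple[float, ...]] = set()
        for perm in itertools.permutations(weights):
            if perm in seen:
                continue
            seen.add(perm)
            wset = _combined_set(problem.current, combo, perm)
            fm = compute_fraction_matrix(wset, panel)
            sc = score_set(fm, problem.criterion)
            if best is None or (sc, perm) < (best[0], best[1]):
                best = (sc, perm, fm)
        assert best is not None
        return best[1], best[2], best[0]
    # Greedy pairing: place the largest weights first where they hurt least.
    remaining = sorted(weights, reverse=True)
    assignment: dict[str, float] = {}
    free = list(combo)
    for w in remaining:
        best_id, best_sc = None, None
        for bid in free:
            trial = dict(assignment)
            trial[bid] = w
            ids = list(trial)
            wset = _combined_set(problem.current, ids,
                                 [trial[i] for i in ids])
            fm = compute_fraction_matrix(wset, panel)
            sc = score_set(fm, problem.criterion)
            if best_sc is None or sc < best_sc:
                best_sc, best_id = sc, bid
        assignment[best_id] = w
        free.remove(best_id)
    final_weights = tuple(assignment[bid] for bid in combo)
    wset = _combined_set(problem.current, combo, final_weights)
    fm = compute_fraction_matrix(wset, panel)
    return final_weights, fm, score_set(fm, problem.criterion)


def _evaluate_combo(problem: SelectionProblem, panel: BarcodePanel,
                    combo: tuple[str, ...]) -> SelectionCandidate:
    w, fm, sc = _best_weight_assignment(problem, panel, combo)
    verdict = evaluate_criterion(fm, problem.criterion)
    return SelectionCandidate(added=combo, added_weights=w,
                              verdict=verdict, score=sc)


def _rank_key(c: SelectionCandidate) -> tuple:
    return (c.score, c.added)


def complete_set(problem: SelectionProblem, panel: BarcodePanel,
                 exhaustive_cap: int = EXHAUSTIVE_CAP,
                 beam_width: int = BEAM_WIDTH) -> SelectionResult:
    """Find k-barcode additions that keep the combined pool balanced.

    All C(|pool|, k) combinations are enumerated when that count is at
    most ``exhaustive_cap``; otherwise a deterministic greedy beam search
    explores the pool and the result is flagged ``exhaustive=False``.
    Passing candidates are ranked by score then lexicographic ids; an
    empty candidate list carries the best failing combination as a
    diagnostic.
    """
    if problem.k == 0:
        combo: tuple[str, ...] = ()
        cand = _evaluate_combo(problem, panel, combo)
        passing = [cand] if cand.verdict.passed else []
        return SelectionResult(
            candidates=passing, exhaustive=True, n_evaluated=1,
            best_failing=None if passing else cand,
        )

    n_combos = comb(len(problem.pool), problem.k)
    exhaustive = n_combos <= exhaustive_cap
    if exhaustive:
        combos = itertools.combinations(problem.pool, problem.k)
    else:
        combos = _beam_search_combos(problem, panel, beam_width)

    passing: list[SelectionCandidate] = []
    best_fail: SelectionCandidate | None = None
    n_evaluated = 0
    for combo in combos:
        n_evaluated += 1
        cand = _evaluate_combo(problem, panel, tuple(combo))
        if cand.verdict.passed:
            passing.append(cand)
        elif best_fail is None or _rank_key(cand) < _rank_key(best_fail):
            best_fail = cand
    passing.sort(key=_rank_key)
    return SelectionResult(
        candidates=passing[:problem.max_results],
        exhaustive=exhaustive,
        n_evaluated=n_evaluated,
        best_failing=None if passing else best_fail,
    )


def _beam_search_combos(problem: SelectionProblem, panel: BarcodePanel,
                        beam_width: int) -> list[tuple[str, ...]]:
    """Deterministic greedy beam search over k-subsets of the pool.

    Partial selections are scored with the first ``len(partial)`` new
    weights; the ``beam_width`` best partials survive each round.  Pool
    order (= panel/file order) breaks ties.
    """
    pool = problem.pool
    beams: list[tuple[str, ...]] = [()]
    for step in range(problem.k):
        step_weights = problem.new_weights[: step + 1]
        scored: list[tuple[Score, tuple[str, ...]]] = []
        seen: set[tuple[str, ...]] = set()
        for partial in beams:
            last_idx = pool.index(partial[-1]) if partial else -1
            for bid in pool[last_idx + 1:]:
                ext = partial + (bid,)
                if ext in seen:
                    continue
                seen.add(ext)
                wset = _combined_set(problem.current, ext, step_weights)
                fm = compute_fraction_matrix(wset, panel)
                scored.append((score_set(fm, problem.criterion), ext))
        scored.sort(key=lambda t: (t[0], t[1]))
        beams = [ext for _, ext in scored[:beam_width]]
        if not beams:
            break
    return beams


@dataclass(frozen=True)
class AnalysisReport:
    """Full single-set report: fractions, verdicts, distances, decodability."""

    wset: WeightedBarcodeSet
    fraction_matrix: FractionMatrix
    verdicts: tuple[BalanceVerdict, ...]
    d_min: int | None
    decodability: DecodabilityReport

    @property
    def passed_all(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def to_dict(self) -> dict:
        return {
            "members": list(self.wset.members),
            "weights": list(self.wset.weights),
            "fractions": self.fraction_matrix.to_dict(),
            "verdicts": [v.to_dict() for v in self.verdicts],
            "d_min": self.d_min,
            "decodability": self.decodability.to_dict(),
        }


def analyze_set(wset: WeightedBarcodeSet, panel: BarcodePanel,
                criteria: Sequence[CriterionSpec] | None = None,
                m: int = DEFAULT_MISMATCH) -> AnalysisReport:
    """Analyze one pooled set: balance under each criterion plus the
    pool's minimum pairwise distance and mismatch-tolerance safety."""
    if criteria is None:
        criteria = list(default_criteria())
    fm = compute_fraction_matrix(wset, panel)
    verdicts = tuple(evaluate_criterion(fm, c) for c in criteria)
    sub = panel.subset(wset.members)
    dm = hamming_matrix(sub)
    report = decodability_check(sub, m)
    return AnalysisReport(
        wset=wset,
        fraction_matrix=fm,
        verdicts=verdicts,
        d_min=dm.d_min,
        decodability=report,
    )
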