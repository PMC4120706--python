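"""Intelligibility scoring: tight keyword scoring and phonemic alignment.

Two complementary measures are provided.  Tight keyword scoring counts a
keyword correct only when its exact orthographic form (or an accepted
homonym) appears in the response; it is the stricter, primary measure.
The phonemic score aligns the response phoneme sequence against the
reference by minimum-cost insert/delete/substitute editing and reports
100 x correctly-aligned / reference-length; it is the more lenient upper
bound.  Pooled condition means weight every keyword equally rather than
averaging per-sentence percentages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "TranscriptPair",
    "ScoreReport",
    "AlignmentCosts",
    "normalize_text",
    "tight_keyword_score",
    "align_phonemes",
    "phoneme_score",
    "pooled_condition_score",
    "competitor_efficacy",
]

_PUNCT_RE = re.compile(r"[^\w']+", flags=re.UNICODE)


@dataclass(frozen=True)
class TranscriptPair:
    """Reference material and listener response for one sentence."""

    ref_keywords: tuple[str, ...]
    ref_phonemes: tuple[str, ...] = ()
    response_text: str = ""
    response_phonemes: tuple[str, ...] = ()


@dataclass(frozen=True)
class AlignmentCosts:
    """Edit costs for phoneme alignment.

    The defaults (substitution 10, insertion 7, deletion 7) make a single
    substitution cheaper than a deletion plus an insertion, following the
    convention of standard speech-recognition scoring tools.
    """

    substitution: float = 10.0
    insertion: float = 7.0
    deletion: float = 7.0


@dataclass(frozen=True)
class ScoreReport:
    """Keyword and phoneme scores with alignment counts."""

    keyword_pct: float
    phoneme_pct: float
    hits: int = 0
    subs: int = 0
    dels: int = 0
    ins: int = 0


def normalize_text(text: str) -> list[str]:
    """Lowercase, strip punctuation, and tokenize on whitespace."""
    return [tok for tok in _PUNCT_RE.split(text.lower()) if tok]


def tight_keyword_score(
    pair: TranscriptPair, homonyms: Mapping[str, set[str]] | None = None
) -> float:
    """Percentage of keywords reported exactly (homonyms accepted).

    Response tokens are consumed one-to-one, so a single response word
    cannot satisfy two keywords.  No stemming or fuzzy matching is applied.
    """
    if not pair.ref_keywords:
        raise ValueError("keyword list must be non-empty")
    homonyms = homonyms or {}
    available = list(normalize_text(pair.response_text))
    correct = 0
    for kw in pair.ref_keywords:
        kw_norm = kw.lower()
        accepted = {kw_norm} | {h.lower() for h in homonyms.get(kw_norm, set())}
        for i, tok in enumerate(available):
            if tok in accepted:
                correct += 1
                del available[i]
                break
    return 100.0 * correct / len(pair.ref_keywords)


def align_phonemes(
    ref: Sequence[str], hyp: Sequence[str], costs: AlignmentCosts | None = None
) -> tuple[int, int, int, int]:
    """Minimum-cost global alignment of phoneme sequences.

    Dynamic programming over insert/delete/substitute edits; ties are
    broken preferring substitution, then deletion, then insertion.  Returns
    ``(hits, subs, dels, ins)`` with ``hits + subs + dels == len(ref)``.
    """
    costs = costs or AlignmentCosts()
    n, m = len(ref), len(hyp)
    # D[i][j]: min cost aligning ref[:i] with hyp[:j]
    D = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i * costs.deletion
    for j in range(1, m + 1):
        D[0][j] = j * costs.insertion
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1][j - 1] + (0.0 if ref[i - 1] == hyp[j - 1] else costs.substitution)
            dele = D[i - 1][j] + costs.deletion
            ins = D[i][j - 1] + costs.insertion
            D[i][j] = min(sub, dele, ins)
    hits = subs = dels = ins = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            match = ref[i - 1] == hyp[j - 1]
            sub_cost = D[i - 1][j - 1] + (0.0 if match else costs.substitution)
            if D[i][j] == sub_cost:
                if match:
                    hits += 1
                else:
                    subs += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and D[i][j] == D[i - 1][j] + costs.deletion:
            dels += 1
            i -= 1
            continue
        ins += 1
        j -= 1
    return hits, subs, dels, ins


def phoneme_score(alignment: tuple[int, int, int, int], ref_len: int) -> float:
    """100 x correctly aligned phonemes / reference length.

    Insertions do not reduce the score; the measure is an accuracy on the
    reference sequence only.
    """
    if ref_len < 1:
        raise ValueError("reference length must be >= 1")
    hits = alignment[0]
    return 100.0 * hits / ref_len


def pooled_condition_score(outcomes: Sequence[tuple[int, int]]) -> float:
    """Condition mean giving equal weight to every keyword.

    ``outcomes`` is a list of per-sentence ``(n_keywords, n_correct)``.
    The pooled score is 100 x total correct / total keywords — not a mean
    of per-sentence percentages, so sentences with more keywords weigh
    more.
    """
    if not outcomes:
        raise ValueError("outcomes list must be non-empty")
    total_kw = sum(n for n, _ in outcomes)
    total_ok = sum(c for _, c in outcomes)
    for n, c in outcomes:
        if n < 1:
            raise ValueError("every sentence must have >= 1 keyword")
        if c > n or c < 0:
            raise ValueError("n_correct must lie in [0, n_keywords]")
    return 100.0 * total_ok / total_kw


def competitor_efficacy(cond_pct: float, ref_pct: float, control_pct: float) -> float:
    """Impact of adding a competitor, as a percentage of the available range.

    0% efficacy corresponds to performance at the no-competitor dichotic
    reference; 100% corresponds to the control in which the competitor
    replaces the target F2 entirely:
    ``100 (ref - cond) / (ref - control)``.
    """
    if ref_pct <= control_pct:
        raise ValueError(
            "efficacy undefined: reference score must exceed control score"
        )
    return 100.0 * (ref_pct - cond_pct) / (ref_pct - control_pct)
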