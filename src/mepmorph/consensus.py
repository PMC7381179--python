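"""Consensus ground-truth construction from multi-rater morphology labels.

There is no objective ground truth for MEP morphology, so reference
labels are built by pooling annotators:

* **bad-data discard** — any trace flagged ``bad`` by at least one rater
  (primary session) is removed from all analyses;
* **5-vote** — the majority of all five raters; with five votes there is
  always a consensus;
* **3-vote** — to evaluate rater ``R`` without letting ``R``'s own vote
  skew the reference, four sets are built, each the majority of the
  three raters remaining after leaving out ``R`` and one other rater in
  turn.  Any metric "on the 3-vote" is the unweighted mean over the
  four sets.  (Using all four others at once would allow 2-2 ties.)
* **1-vote** — a single rater's own labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ConsensusSet", "discard_bad", "majority_vote", "build_consensus"]

LABEL_TO_INT = {"normal": 0, "abnormal": 1}


@dataclass(frozen=True)
class ConsensusSet:
    """Binary reference labels per trace for one voting scheme.

    ``labels`` maps trace_id -> {0 normal, 1 abnormal}; ``discarded``
    holds the bad-data trace ids removed before voting.  For three-vote
    sets, ``target_rater`` is the rater being evaluated (whose vote is
    never included) and ``left_out`` the additionally excluded rater.
    """

    scheme: str  # "five_vote", "three_vote" or "one_vote"
    labels: pd.Series = field(repr=False)
    discarded: frozenset = frozenset()
    target_rater: Optional[str] = None
    left_out: Optional[str] = None
    rater: Optional[str] = None

    def __post_init__(self) -> None:
        overlap = set(self.labels.index) & set(self.discarded)
        if overlap:
            raise ValueError(f"traces both labeled and discarded: {sorted(overlap)[:5]}")

    @property
    def name(self) -> str:
        if self.scheme == "three_vote":
            return f"three_vote({self.target_rater} minus {self.left_out})"
        if self.scheme == "one_vote":
            return f"one_vote({self.rater})"
        return self.scheme


def _primary(table: pd.DataFrame) -> pd.DataFrame:
    if "session" not in table.columns:
        return table
    return table[table["session"] == "primary"]


def discard_bad(table: pd.DataFrame) -> tuple[pd.DataFrame, frozenset]:
    """Remove every trace flagged ``bad`` by at least one rater.

    Only primary-session flags trigger the discard, but a discarded
    trace is dropped from all raters and sessions.  Returns the filtered
    table and the discarded trace ids; the discard fraction is logged.
    """
    primary = _primary(table)
    bad_ids = frozenset(primary.loc[primary["label"] == "bad", "trace_id"])
    filtered = table[~table["trace_id"].isin(bad_ids)].reset_index(drop=True)
    n_total = table["trace_id"].nunique()
    if n_total:
        logger.info(
            "discarded %d/%d traces (%.1f%%) with at least one bad-data flag",
            len(bad_ids),
            n_total,
            100.0 * len(bad_ids) / n_total,
        )
    return filtered, bad_ids


def majority_vote(votes: Sequence[int]) -> int:
    """Majority of an odd number of binary votes.

    An even panel is rejected outright: with four votes a 2-2 split has
    no consensus, which is exactly why the leave-two-out 3-vote scheme
    exists.
    """
    votes = list(votes)
    if len(votes) % 2 == 0:
        raise ValueError(
            f"majority_vote needs an odd number of votes; {len(votes)} votes can tie "
            "(e.g. two against two) and have no consensus"
        )
    if any(v not in (0, 1) for v in votes):
        raise ValueError("votes must be binary (0=normal, 1=abnormal)")
    return int(sum(votes) > len(votes) / 2)


def _vote_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """traces x raters matrix of 0/1 votes (NaN where a vote is missing)."""
    primary = _primary(table)
    primary = primary[primary["label"].isin(LABEL_TO_INT)]
    coded = primary.assign(vote=primary["label"].map(LABEL_TO_INT))
    dup = coded.duplicated(subset=["trace_id", "rater_id"], keep=False)
    if dup.any():
        raise ValueError("multiple primary labels for the same (trace, rater)")
    return coded.pivot(index="trace_id", columns="rater_id", values="vote")


def _majority_set(
    votes: pd.DataFrame,
    raters: Sequence[str],
    scheme: str,
    discarded: frozenset,
    **meta,
) -> ConsensusSet:
    sub = votes[list(raters)]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.warning(
            "%s: %d traces lack a vote from %s and are excluded", scheme, n_dropped, list(raters)
        )
    labels = complete.apply(lambda row: majority_vote([int(v) for v in row]), axis=1)
    if len(complete) == 0:
        labels = pd.Series(dtype=int)
    return ConsensusSet(scheme=scheme, labels=labels.astype(int), discarded=discarded, **meta)


def build_consensus(
    table: pd.DataFrame,
    scheme: str,
    target_rater: Optional[str] = None,
    rater: Optional[str] = None,
) -> Union[ConsensusSet, list[ConsensusSet]]:
    """Build reference label sets after the bad-data discard.

    Parameters
    ----------
    scheme
        ``"five_vote"`` (majority of all five raters), ``"three_vote"``
        (four leave-one-more-out majorities excluding ``target_rater``),
        or ``"one_vote"`` (the labels of ``rater``).  Shorthand strings
        ``"three:N5"`` / ``"one:N2"`` are accepted.
    """
    if ":" in scheme:
        scheme, who = scheme.split(":", 1)
        scheme = {"three": "three_vote", "one": "one_vote", "five": "five_vote"}.get(scheme, scheme)
        if scheme == "three_vote":
            target_rater = who
        elif scheme == "one_vote":
            rater = who
    filtered, discarded = discard_bad(table)
    votes = _vote_matrix(filtered)
    raters = sorted(votes.columns)

    if scheme == "five_vote":
        if len(raters) != 5:
            raise ValueError(f"five_vote needs exactly 5 raters, found {len(raters)}: {raters}")
        return _majority_set(votes, raters, "five_vote", discarded)

    if scheme == "three_vote":
        if target_rater is None:
            raise ValueError("three_vote requires target_rater")
        if target_rater not in raters:
            raise ValueError(f"unknown rater {target_rater!r}; panel is {raters}")
        others = [r for r in raters if r != target_rater]
        if len(others) < 4:
            raise ValueError(f"three_vote needs 4 raters besides {target_rater}, found {len(others)}")
        sets = []
        for left_out in others:
            trio = [r for r in others if r != left_out]
            sets.append(
                _majority_set(
                    votes, trio, "three_vote", discarded, target_rater=target_rater, left_out=left_out
                )
            )
        return sets

    if scheme == "one_vote":
        if rater is None:
            raise ValueError("one_vote requires rater")
        if rater not in raters:
            raise ValueError(f"unknown rater {rater!r}; panel is {raters}")
        labels = votes[rater].dropna().astype(int)
        return ConsensusSet(scheme="one_vote", labels=labels, discarded=discarded, rater=rater)

    raise ValueError(f"unknown scheme {scheme!r}")
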