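"""Inter- and intra-rater reliability of morphology labels.

Two complementary statistics per rater pair:

* **agreement fraction** — the share of traces labelled identically;
  easy to read but inflated by class imbalance (with ~74% of traces
  normal, two raters who always answer "normal" agree 74% of the time);
* **Cohen's kappa** — chance-corrected agreement,
  ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed
  agreement and ``p_e`` the agreement expected from the two raters'
  label marginals; 1 is perfect, 0 chance-level, negative worse than
  chance.

Inter-rater scores are evaluated pairwise (each rater against the other
four) and averaged per rater and over the panel; intra-rater scores
compare a rater's primary and repeat labels of the twice-labelled
traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .consensus import LABEL_TO_INT

logger = logging.getLogger(__name__)

__all__ = ["AgreementReport", "agreement_fraction", "cohens_kappa", "panel_report"]


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if len(a.index) != len(b.index) or set(a.index) != set(b.index):
            raise ValueError("label vectors cover different trace sets")
        b = b.reindex(a.index)
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("label vectors are empty")
    return a, b


def agreement_fraction(a, b) -> float:
    """Fraction of traces on which two label vectors agree."""
    a, b = _check_pair(a, b)
    return float(np.mean(a == b))


def cohens_kappa(a, b) -> float:
    """Chance-corrected agreement between two label vectors.

    Degenerate tables (one or both raters constant) never occur in the
    clinical panel but do in simulation edge cases; the conventions are:
    both raters constant and identical -> 1 (perfect agreement, p_e = 1);
    both constant but different -> 0 (logged).
    """
    a, b = _check_pair(a, b)
    classes = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in classes))
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        logger.warning("both raters constant but different; kappa defined as 0 by convention")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AgreementReport:
    """Per-rater and panel-average reliability, one row per rater.

    ``per_rater`` columns: inter_fraction, inter_kappa, intra_fraction,
    intra_kappa (intra columns absent when no repeat sessions exist).
    """

    per_rater: pd.DataFrame
    panel: dict = field(default_factory=dict)
    n_traces_inter: int = 0
    n_traces_intra: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "per_rater": {
                r: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for r, row in self.per_rater.iterrows()
            },
            "panel": self.panel,
            "n_traces_inter": self.n_traces_inter,
            "n_traces_intra": self.n_traces_intra,
        }

    def render_table(self) -> str:
        """Text table: rows = raters, agreement fraction and kappa, intra in parentheses."""
        lines = [f"{'':8s}  {'Agreement fraction':>20s}  {'Cohen kappa':>18s}"]

        def fmt(inter, intra) -> str:
            if intra is None or pd.isna(intra):
                return f"{inter:.2f}"
            return f"{inter:.2f} ({intra:.2f})"

        for rater, row in self.per_rater.iterrows():
            lines.append(
                f"{rater:8s}  {fmt(row['inter_fraction'], row.get('intra_fraction')):>20s}  "
                f"{fmt(row['inter_kappa'], row.get('intra_kappa')):>18s}"
            )
        p = self.panel
        lines.append(
            f"{'Average':8s}  {fmt(p['inter_fraction'], p.get('intra_fraction')):>20s}  "
            f"{fmt(p['inter_kappa'], p.get('intra_kappa')):>18s}"
        )
        return "\n".join(lines)


def _binary_votes(table: pd.DataFrame, session: str) -> pd.DataFrame:
    sub = table[(table["session"] == session) & table["label"].isin(LABEL_TO_INT)]
    if sub.empty:
        return pd.DataFrame()
    return sub.assign(vote=sub["label"].map(LABEL_TO_INT)).pivot(
        index="trace_id", columns="rater_id", values="vote"
    )


def panel_report(table: pd.DataFrame) -> AgreementReport:
    """Reliability of a full label table.

    Inter-rater scores use primary-session normal/abnormal labels; each
    pair is compared on the traces both have labelled.  Intra-rater
    scores compare primary and repeat labels per rater on the
    twice-labelled traces; traces whose repeat (or primary) label is bad
    are excluded.  When no repeat sessions exist, the intra columns are
    absent rather than zero.
    """
    primary = _binary_votes(table, "primary")
    if primary.empty or primary.shape[1] < 2:
        raise ValueError("panel_report needs primary labels from at least 2 raters")
    raters = sorted(primary.columns)
    repeat = _binary_votes(table, "repeat") if "repeat" in set(table["session"]) else pd.DataFrame()

    rows = {}
    n_pair_traces = []
    for r in raters:
        fracs, kappas = [], []
        for other in raters:
            if other == r:
                continue
            both = primary[[r, other]].dropna()
            if both.empty:
                continue
            fracs.append(agreement_fraction(both[r].to_numpy(), both[other].to_numpy()))
            kappas.append(cohens_kappa(both[r].to_numpy(), both[other].to_numpy()))
            n_pair_traces.append(len(both))
        rows[r] = {"inter_fraction": float(np.mean(fracs)), "inter_kappa": float(np.mean(kappas))}

    n_intra = None
    if not repeat.empty:
        for r in raters:
            if r not in repeat.columns:
                continue
            both = pd.concat([primary[r], repeat[r]], axis=1, keys=["primary", "repeat"]).dropna()
            if both.empty:
                continue
            rows[r]["intra_fraction"] = agreement_fraction(
                both["primary"].to_numpy(), both["repeat"].to_numpy()
            )
            rows[r]["intra_kappa"] = cohens_kappa(
                both["primary"].to_numpy(), both["repeat"].to_numpy()
            )
            n_intra = len(both) if n_intra is None else max(n_intra, len(both))

    per_rater = pd.DataFrame.from_dict(rows, orient="index").loc[raters]
    panel = {col: float(per_rater[col].mean()) for col in per_rater.columns}
    return AgreementReport(
        per_rater=per_rater,
        panel=panel,
        n_traces_inter=int(np.mean(n_pair_traces)) if n_pair_traces else 0,
        n_traces_intra=n_intra,
    )
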