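"""Reading, writing and assembling MEP trace and label tables.

Traces travel as long ("tidy") delimited text with one row per sample:

    trace_id, patient_id, visit_id, limb, side, excitation_pct,
    sampling_rate, sample_index, value [, date]

Labels:   trace_id, rater_id, session, label
Features: trace_id + one column per feature (+ patient_id)
EDSS:     patient_id, date (ISO-8601), edss

Recordings arrive at 19.2 or 20 kHz; 20 kHz traces are down-sampled to
19.2 kHz by the exact rational factor 24/25 with an anti-aliasing
polyphase filter, and the trace with the maximal peak-to-peak amplitude
is retained per limb/side as the analysis trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

TRACE_COLUMNS = [
    "trace_id",
    "patient_id",
    "visit_id",
    "limb",
    "side",
    "excitation_pct",
    "sampling_rate",
    "sample_index",
    "value",
]

VALID_LIMBS = {"APB", "AH"}
VALID_SIDES = {"L", "R"}
VALID_RATES = {19.2, 20.0}

__all__ = [
    "MepTrace",
    "Visit",
    "read_traces",
    "write_traces",
    "read_labels",
    "write_labels",
    "read_features",
    "write_features",
    "read_edss",
    "resample_to_19_2",
    "select_max_p2p",
]


@dataclass(frozen=True)
class MepTrace:
    """One sampled MEP voltage time series for one limb/side/excitation."""

    trace_id: str
    patient_id: str
    visit_id: str
    limb: str  # APB (hand) or AH (foot)
    side: str  # L or R
    excitation_pct: float  # % of maximal stimulator output
    sampling_rate: float  # kHz
    samples: np.ndarray = field(repr=False)  # uV

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float).ravel())
        if self.samples.size < 64:
            raise ValueError(f"trace {self.trace_id}: need >= 64 samples, got {self.samples.size}")
        if self.limb not in VALID_LIMBS:
            raise ValueError(f"trace {self.trace_id}: limb must be one of {sorted(VALID_LIMBS)}")
        if self.side not in VALID_SIDES:
            raise ValueError(f"trace {self.trace_id}: side must be one of {sorted(VALID_SIDES)}")
        if self.sampling_rate not in VALID_RATES:
            raise ValueError(
                f"trace {self.trace_id}: sampling_rate must be 19.2 or 20.0 kHz, got {self.sampling_rate}"
            )
        if not 0.0 <= self.excitation_pct <= 100.0:
            raise ValueError(f"trace {self.trace_id}: excitation_pct must be in [0, 100]")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Visit:
    """Traces of one hospital visit, grouped by (limb, side)."""

    visit_id: str
    patient_id: str
    traces: list[MepTrace] = field(default_factory=list)
    date: Optional[str] = None  # ISO-8601

    def group(self, limb: str, side: str) -> list[MepTrace]:
        return [t for t in self.traces if t.limb == limb and t.side == side]

    @property
    def groups(self) -> list[tuple[str, str]]:
        seen: list[tuple[str, str]] = []
        for t in self.traces:
            key = (t.limb, t.side)
            if key not in seen:
                seen.append(key)
        return seen


def read_traces(path, delimiter: str = ",") -> list[Visit]:
    """Parse a long-format trace table into a list of visits.

    Malformed traces (non-monotone ``sample_index``, invalid metadata,
    too few samples) are rejected individually with a logged warning;
    missing required columns are a hard error.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing required columns: {missing}")
    if df.empty:
        logger.warning("trace file %s contains a header but no rows", path)
        return []

    visits: dict[str, Visit] = {}
    n_read = 0
    n_skipped = 0
    for trace_id, g in df.groupby("trace_id", sort=True):
        idx = g["sample_index"].to_numpy()
        first_line = int(g.index.min()) + 2  # header + 1-based
        if np.any(np.diff(idx) <= 0):
            logger.warning(
                "trace %s (starting line %d): non-monotone sample_index; trace rejected",
                trace_id,
                first_line,
            )
            n_skipped += 1
            continue
        meta = g.iloc[0]
        try:
            trace = MepTrace(
                trace_id=str(trace_id),
                patient_id=str(meta["patient_id"]),
                visit_id=str(meta["visit_id"]),
                limb=str(meta["limb"]),
                side=str(meta["side"]),
                excitation_pct=float(meta["excitation_pct"]),
                sampling_rate=float(meta["sampling_rate"]),
                samples=g["value"].to_numpy(dtype=float),
            )
        except ValueError as exc:
            logger.warning("trace %s (starting line %d): %s; trace rejected", trace_id, first_line, exc)
            n_skipped += 1
            continue
        visit_id = str(meta["visit_id"])
        if visit_id not in visits:
            visits[visit_id] = Visit(
                visit_id=visit_id,
                patient_id=str(meta["patient_id"]),
                date=str(meta["date"]) if "date" in g.columns and pd.notna(meta.get("date")) else None,
            )
        visits[visit_id].traces.append(trace)
        n_read += 1
    logger.info("read %d traces (%d rejected) from %s", n_read, n_skipped, path)
    return [visits[k] for k in sorted(visits)]


def write_traces(visits: Iterable[Visit], path, delimiter: str = ",") -> None:
    """Write visits in the long format read by :func:`read_traces`.

    Voltages are written with 9 significant digits, enough for a
    read/write round trip to be the identity for clinically relevant
    amplitudes.
    """
    frames = []
    for visit in visits:
        for t in visit.traces:
            frames.append(
                pd.DataFrame(
                    {
                        "trace_id": t.trace_id,
                        "patient_id": t.patient_id,
                        "visit_id": t.visit_id,
                        "limb": t.limb,
                        "side": t.side,
                        "excitation_pct": t.excitation_pct,
                        "sampling_rate": t.sampling_rate,
                        "sample_index": np.arange(t.n_samples),
                        "value": t.samples,
                        "date": visit.date if visit.date is not None else "",
                    }
                )
            )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRACE_COLUMNS + ["date"])
    out.to_csv(path, sep=delimiter, index=False, float_format="%.9g")


def read_labels(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, delimiter=delimiter)
    required = ["trace_id", "rater_id", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"label file {path} is missing required columns: {missing}")
    if "session" not in df.columns:
        df["session"] = "primary"
    return df[["trace_id", "rater_id", "session", "label"]]


def write_labels(labels: pd.DataFrame, path, delimiter: str = ",") -> None:
    labels.to_csv(path, sep=delimiter, index=False)


def read_features(path, delimiter: str = ","):
    from .screening import FeatureMatrix

    df = pd.read_csv(path, delimiter=delimiter)
    if "trace_id" not in df.columns or "patient_id" not in df.columns:
        raise ValueError(f"feature file {path} needs trace_id and patient_id columns")
    df = df.set_index("trace_id")
    return FeatureMatrix(values=df.drop(columns=["patient_id"]), patients=df["patient_id"])


def write_features(matrix, path, delimiter: str = ",") -> None:
    out = matrix.values.copy()
    out.insert(0, "patient_id", matrix.patients)
    out.to_csv(path, sep=delimiter, index=True, index_label="trace_id", float_format="%.9g")


def read_edss(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, delimiter=delimiter)
    required = ["patient_id", "date", "edss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"EDSS file {path} is missing required columns: {missing}")
    return df[required]


def resample_to_19_2(trace: MepTrace) -> MepTrace:
    """Down-sample a 20 kHz trace to 19.2 kHz by the exact factor 24/25.

    Uses an anti-aliasing polyphase filter; a 19.2 kHz input is returned
    unchanged, which also makes the operation idempotent.  The output
    length is ``floor(N * 24 / 25)``.
    """
    if trace.sampling_rate == 19.2:
        return trace
    if trace.sampling_rate != 20.0:
        raise ValueError(f"unsupported sampling rate {trace.sampling_rate} kHz")
    resampled = resample_poly(trace.samples, up=24, down=25)
    n_out = (trace.n_samples * 24) // 25
    return replace(trace, sampling_rate=19.2, samples=resampled[:n_out])


def select_max_p2p(visit: Visit, limb: str, side: str) -> Optional[MepTrace]:
    """The analysis trace of a limb: maximal peak-to-peak amplitude.

    Ties are broken by higher excitation percentage, then lexicographic
    trace id, so the selection is deterministic and invariant under
    reordering.  Returns ``None`` when the (limb, side) measurement is
    absent from the visit.
    """
    group = visit.group(limb, side)
    if not group:
        return None
    return min(
        group,
        key=lambda t: (-(float(t.samples.max() - t.samples.min())), -t.excitation_pct, t.trace_id),
    )
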