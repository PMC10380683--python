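"""Phenotype read-outs on tabulated records.

Small, explicitly defined computations on force-test sessions and per-fiber
histology tables (image segmentation itself is out of scope — the inputs are
already-tabulated records):

* escape test: ~15 tail-pinch pull peaks; the top 5 are averaged and divided
  by body weight (plus the raw maximum peak);
* 2-limb grip test: mean of 3 measurements over body weight;
* fiber tables: percent dystrophin-positive fibers (relative to all fibers,
  as visualized by laminin) and percent centrally nucleated fibers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ForceSession",
    "SessionError",
    "EmptyTableError",
    "escape_force",
    "grip_force",
    "fiber_percentages",
    "cohort_summary",
    "read_force_sessions_csv",
    "read_fiber_table_csv",
    "simulate_force_session",
    "simulate_fiber_table",
]

MIN_ESCAPE_PEAKS = 15
GRIP_MEASUREMENTS = 3
ESCAPE_TOP_K = 5


class SessionError(ValueError):
    """Force session does not meet the protocol requirements."""


class EmptyTableError(ValueError):
    """Fiber table has no rows."""


@dataclass(frozen=True)
class ForceSession:
    """One force-test session: peak forces (N) and body weight (g)."""

    peaks: tuple[float, ...]
    body_weight: float
    kind: str  # "escape" | "grip"

    def __post_init__(self) -> None:
        if self.kind not in ("escape", "grip"):
            raise SessionError(f"unknown session kind {self.kind!r}")
        if self.body_weight <= 0:
            raise SessionError("body weight must be positive")
        if any(p < 0 for p in self.peaks):
            raise SessionError("negative force peak")


def _top_k_mean_over_weight(peaks, k: int, weight: float) -> float:
    top = np.sort(np.asarray(peaks, dtype=float))[-k:]
    return float(top.mean() / weight)


def escape_force(s: ForceSession) -> tuple[float, float]:
    """(max peak in N, mean of the top-5 peaks normalized to weight in N/g)."""
    if s.kind != "escape":
        raise SessionError(f"escape_force on a {s.kind!r} session")
    if len(s.peaks) < MIN_ESCAPE_PEAKS:
        raise SessionError(
            f"insufficient escape session: {len(s.peaks)} peaks, "
            f"need >= {MIN_ESCAPE_PEAKS}"
        )
    return (float(max(s.peaks)),
            _top_k_mean_over_weight(s.peaks, ESCAPE_TOP_K, s.body_weight))


def grip_force(s: ForceSession) -> float:
    """Mean of the 3 grip measurements normalized to weight (N/g)."""
    if s.kind != "grip":
        raise SessionError(f"grip_force on a {s.kind!r} session")
    if len(s.peaks) != GRIP_MEASUREMENTS:
        raise SessionError(
            f"grip session needs exactly {GRIP_MEASUREMENTS} measurements, "
            f"got {len(s.peaks)}"
        )
    return _top_k_mean_over_weight(s.peaks, GRIP_MEASUREMENTS, s.body_weight)


def fiber_percentages(table: pd.DataFrame) -> tuple[float, float]:
    """(dystrophin-positive %, centrally nucleated %) over all fibers."""
    if len(table) == 0:
        raise EmptyTableError("fiber table is empty")
    for col in ("dys_positive", "centrally_nucleated"):
        if col not in table.columns or table[col].isna().any():
            raise EmptyTableError(f"fiber table column {col!r} missing or undefined")
    dys = 100.0 * float(table["dys_positive"].astype(bool).mean())
    cn = 100.0 * float(table["centrally_nucleated"].astype(bool).mean())
    return dys, cn


def cohort_summary(df: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean ± SEM per group for every numeric column."""
    num = df.select_dtypes("number").columns
    g = df.groupby(group_col)[list(num)]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem(ddof=1).add_suffix("_sem")
    n = g.size().rename("n")
    return pd.concat([n, mean, sem], axis=1).reset_index()


# ---------------------------------------------------------------------------
# CSV readers and fixture generators
# ---------------------------------------------------------------------------

def read_force_sessions_csv(path) -> list[tuple[str, ForceSession]]:
    """Read sessions: columns ``mouse``, ``kind``, ``weight_g``, ``peaks``
    (semicolon-separated force values in N)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        peaks = tuple(float(x) for x in str(row["peaks"]).split(";") if x != "")
        out.append(
            (str(row["mouse"]),
             ForceSession(peaks=peaks, body_weight=float(row["weight_g"]),
                          kind=str(row["kind"])))
        )
    return out


def read_fiber_table_csv(path) -> pd.DataFrame:
    """Read a fiber table: ``fiber_id``, ``dys_positive``, ``centrally_nucleated``."""
    df = pd.read_csv(path)
    for col in ("dys_positive", "centrally_nucleated"):
        df[col] = df[col].astype(bool)
    return df


def simulate_force_session(
    kind: str,
    body_weight: float,
    rng: np.random.Generator,
    n_peaks: int | None = None,
    mean_force: float = 1.5,
    sd: float = 0.3,
) -> ForceSession:
    """Synthetic session fixture with truncated-normal peak forces."""
    if n_peaks is None:
        n_peaks = MIN_ESCAPE_PEAKS if kind == "escape" else GRIP_MEASUREMENTS
    peaks = np.clip(rng.normal(mean_force, sd, size=n_peaks), 0.0, None)
    return ForceSession(tuple(float(p) for p in peaks), body_weight, kind)


def simulate_fiber_table(
    n_fibers: int,
    p_dys: float,
    p_centronucleated: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthetic per-fiber table fixture."""
    return pd.DataFrame(
        {
            "fiber_id": np.arange(n_fibers),
            "dys_positive": rng.random(n_fibers) < p_dys,
            "centrally_nucleated": rng.random(n_fibers) < p_centronucleated,
        }
    )
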