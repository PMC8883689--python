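"""Left-truncated Kaplan-Meier estimation, median survival, and log-rank test.

Left truncation arises in real-world clinico-genomic cohorts: a patient is
at risk of (observable) death only after a qualifying entry event — e.g.
the later of their first sequencing report and a second clinic visit —
because earlier deaths could never have entered the cohort. The risk set
at time t is therefore {records: entry_time < t <= exit_time} (left-open
at entry: a subject becomes at risk strictly after entering). With all
entry times zero the estimator reduces exactly to the classical
product-limit KM. Ties between deaths and censorings at the same time are
resolved by processing deaths first (the standard convention), which the
risk-set definition encodes automatically: a record censored at t is still
at risk at t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: entry (left-truncation) time, exit time, event flag, group."""

    sample_id: str
    entry_time: float
    exit_time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.entry_time < 0:
            raise ValueError(f"{self.sample_id}: entry_time must be >= 0")
        if not self.exit_time > self.entry_time:
            raise ValueError(f"{self.sample_id}: require entry_time < exit_time")


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times.

    ``unstable_from`` flags the first event time whose risk set was empty
    (possible under heavy truncation); the curve is held constant from
    there and should not be interpreted beyond it.
    """

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t_i), after the update at t_i
    at_risk: np.ndarray        # n_i
    events: np.ndarray         # d_i
    n_records: int
    greenwood: np.ndarray = field(default_factory=lambda: np.array([]))
    unstable_from: Optional[float] = None

    def survival_at(self, t: float) -> float:
        """S(t) with the right-continuous step convention; S(t)=1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _risk_set_sizes(
    entries: np.ndarray, exits: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """n_i = #{entry < t_i <= exit} for each t_i, via sorted searches."""
    se = np.sort(entries)
    sx = np.sort(exits)
    started = np.searchsorted(se, times, side="left")   # entry < t
    gone = np.searchsorted(sx, times, side="left")      # exit < t
    return started - gone


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Left-truncated Kaplan-Meier fit.

    At each distinct event time t_i the survival updates by (1 - d_i/n_i)
    with n_i the truncation-aware risk-set size. Censored exits shape risk
    sets only. Also accumulates the Greenwood variance term
    sum d/(n(n-d)) used for confidence intervals.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    entries = np.array([r.entry_time for r in records], dtype=float)
    exits = np.array([r.exit_time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    ev_times = np.unique(exits[events])
    n_at_risk = _risk_set_sizes(entries, exits, ev_times)
    d = np.array(
        [int(((exits == t) & events).sum()) for t in ev_times], dtype=np.int64
    )

    surv = np.empty(len(ev_times))
    green = np.empty(len(ev_times))
    s = 1.0
    g = 0.0
    unstable: Optional[float] = None
    for i, (t, n_i, d_i) in enumerate(zip(ev_times, n_at_risk, d)):
        if n_i <= 0:
            if unstable is None:
                unstable = float(t)
        elif unstable is None:
            s *= 1.0 - d_i / n_i
            if n_i > d_i:
                g += d_i / (n_i * (n_i - d_i))
            else:
                g = math.inf
        surv[i] = s
        green[i] = g
    return KMCurve(
        times=ev_times,
        survival=surv,
        at_risk=n_at_risk.astype(np.int64),
        events=d,
        n_records=len(records),
        greenwood=green,
        unstable_from=unstable,
    )


def median_survival(curve: KMCurve) -> Optional[float]:
    """Smallest event time with S(t) <= 0.5; None if S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.times[below[0]])


def median_survival_ci(
    curve: KMCurve, alpha: float = 0.05
) -> Tuple[Optional[float], Optional[float]]:
    """Brookmeyer-Crowley-style CI for the median survival time.

    Pointwise confidence bands for S(t) are formed on the log scale,
    S(t) * exp(+-z * se_logS), with the Greenwood variance of log S; the
    median CI bounds are the first event times at which the lower
    (resp. upper) band drops to 0.5. Bounds that never cross are None.
    """
    z = stats.norm.ppf(1 - alpha / 2)
    s = curve.survival
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        se_log = np.sqrt(curve.greenwood)
        lower = np.where(s > 0, s * np.exp(-z * se_log), 0.0)
        upper = np.where(s > 0, np.minimum(1.0, s * np.exp(z * se_log)), 0.0)

    def first_crossing(band: np.ndarray) -> Optional[float]:
        idx = np.nonzero(band <= 0.5)[0]
        return None if len(idx) == 0 else float(curve.times[idx[0]])

    return first_crossing(lower), first_crossing(upper)


def logrank(
    records: Sequence[SurvivalRecord], group_a: str, group_b: str
) -> Tuple[float, float]:
    """Two-group log-rank test with left-truncated risk sets.

    U = sum over event times of (d_a - e_a), with e_a the expected group-a
    events under the hypergeometric null at fixed margins; V the summed
    hypergeometric variances; chi_square = U^2 / V, p from chi^2(1).
    Raises if there are no events at all.
    """
    recs_a = [r for r in records if r.group == group_a]
    recs_b = [r for r in records if r.group == group_b]
    if not recs_a or not recs_b:
        raise ValueError("both groups must be non-empty")

    def arrays(recs: Sequence[SurvivalRecord]):
        return (
            np.array([r.entry_time for r in recs], dtype=float),
            np.array([r.exit_time for r in recs], dtype=float),
            np.array([r.event for r in recs], dtype=bool),
        )

    en_a, ex_a, ev_a = arrays(recs_a)
    en_b, ex_b, ev_b = arrays(recs_b)
    all_event_times = np.unique(np.concatenate([ex_a[ev_a], ex_b[ev_b]]))
    if len(all_event_times) == 0:
        raise ValueError("no events in either group")

    na = _risk_set_sizes(en_a, ex_a, all_event_times)
    nb = _risk_set_sizes(en_b, ex_b, all_event_times)
    da = np.array([int(((ex_a == t) & ev_a).sum()) for t in all_event_times])
    db = np.array([int(((ex_b == t) & ev_b).sum()) for t in all_event_times])

    n = na + nb
    d = da + db
    ok = n > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        e_a = d * na / n
        v = d * (na / n) * (nb / n) * (n - d) / (n - 1)
    u = float((da[ok] - e_a[ok]).sum())
    var = float(v[ok].sum())
    if var <= 0:
        raise ValueError("log-rank variance is zero (no informative event times)")
    chi2 = u * u / var
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_survival_tsv(path) -> List[SurvivalRecord]:
    """Read a headered TSV: sample_id, entry_time, exit_time, event (0/1), group."""
    out: List[SurvivalRecord] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("sample_id", "entry_time", "exit_time", "event", "group"):
            if col not in idx:
                raise ValueError(f"survival file missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                SurvivalRecord(
                    sample_id=f[idx["sample_id"]],
                    entry_time=float(f[idx["entry_time"]]),
                    exit_time=float(f[idx["exit_time"]]),
                    event=bool(int(f[idx["event"]])),
                    group=f[idx["group"]],
                )
            )
    return out


def write_curve_tsv(curve: KMCurve, path, group: str = "") -> None:
    """Curve points with at-risk counts (mirrors a KM plot's risk table)."""
    with open(path, "w") as fh:
        fh.write("group\ttime\tsurvival\tat_risk\tevents\n")
        for t, s, n, d in zip(curve.times, curve.survival, curve.at_risk, curve.events):
            fh.write(f"{group}\t{t:.6g}\t{s:.6g}\t{n}\t{d}\n")
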