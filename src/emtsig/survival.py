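"""Survival endpoints, Kaplan–Meier estimation, log-rank tests and ΔMFS.

Two endpoints are supported.  Overall survival (OS) is the time from
surgery to death or last contact.  Metastasis-free survival (MFS) is a
composite endpoint in which metastasis and death both count as events:
the record time is min(met_time, os_time) and the event indicator is
whichever of the two processes fired first; patients with a metastasis
already present at surgery are excluded from MFS.  Fixed-horizon
("3-year" / "5-year") analyses administratively censor every record at
the horizon.

Kaplan–Meier curves use the product-limit estimator (via lifelines) with
the standard events-before-censoring convention for ties.  The two-group
log-rank statistic is computed directly from the pooled observed/
expected/variance table (1 df, two-sided p), which pins the tie handling
and the zero-event degenerate case; lifelines serves as an independent
cross-check in the test suite.  ΔMFS at a horizon is the high-minus-low
difference in survival fraction, in percentage points, so worse survival
in the high-score group is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit curve with event-time survival values and at-risk counts."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    max_time: float
    # full step function over every distinct time (events and censorings)
    _step_times: np.ndarray = field(repr=False, default=None)  # type: ignore
    _step_survival: np.ndarray = field(repr=False, default=None)  # type: ignore

    def survival_at(self, t: float) -> float:
        """Right-continuous S(t); errors beyond the observed follow-up."""
        if t > self.max_time:
            raise ValueError(f"t={t} beyond last observed time {self.max_time}")
        i = np.searchsorted(self._step_times, t, side="right") - 1
        return 1.0 if i < 0 else float(self._step_survival[i])


def build_endpoint(ann: pd.DataFrame, endpoint: str,
                   horizon_months: float | None = None) -> pd.DataFrame:
    """Per-patient (time, event) records for the OS or MFS endpoint.

    MFS excludes records flagged ``baseline_metastasis`` and combines
    the metastasis and death clocks; OS uses (os_time, os_event)
    directly.  With ``horizon_months``, records beyond the horizon are
    administratively censored there.  Returns a DataFrame with columns
    ``sample_id``, ``time``, ``event``, ``endpoint``.
    """
    if endpoint not in ("OS", "MFS"):
        raise ValueError(f"endpoint must be 'OS' or 'MFS', got {endpoint!r}")
    need = ["sample_id", "os_time", "os_event"]
    if endpoint == "MFS":
        need += ["met_time", "met_event", "baseline_metastasis"]
    missing = [c for c in need if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing fields: {missing}")
    df = ann[need].copy()
    time_cols = [c for c in need if c.endswith("_time")]
    bad = df.loc[df[time_cols].lt(0).any(axis=1) | df[need[1:]].isna().any(axis=1),
                 "sample_id"]
    if len(bad):
        raise ValueError(f"negative or missing survival fields for: {list(bad)}")

    if endpoint == "OS":
        out = pd.DataFrame({"sample_id": df["sample_id"],
                            "time": df["os_time"].astype(float),
                            "event": df["os_event"].astype(int)})
    else:
        df = df[~df["baseline_metastasis"].astype(bool)]
        t_met = df["met_time"].astype(float)
        t_os = df["os_time"].astype(float)
        time = np.minimum(t_met, t_os)
        event = (((t_met <= t_os) & df["met_event"].astype(bool))
                 | ((t_os <= t_met) & df["os_event"].astype(bool))).astype(int)
        out = pd.DataFrame({"sample_id": df["sample_id"], "time": time,
                            "event": event})
    if horizon_months is not None:
        over = out["time"] > horizon_months
        out.loc[over, "time"] = float(horizon_months)
        out.loc[over, "event"] = 0
    out["endpoint"] = endpoint
    return out.reset_index(drop=True)


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier product-limit estimate from (time, event) records."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    T = records["time"].to_numpy(dtype=float)
    E = records["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(T, E)
    tbl = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    times = tbl.index.to_numpy(dtype=float)
    is_event = tbl["observed"].to_numpy() > 0
    nonzero = times > 0 if times[0] == 0 and not is_event[0] else np.ones_like(times, bool)
    ev_mask = is_event & nonzero
    return KMCurve(
        event_times=times[ev_mask],
        survival=sf.to_numpy()[ev_mask],
        at_risk=tbl["at_risk"].to_numpy()[ev_mask],
        n_events=tbl["observed"].to_numpy()[ev_mask],
        censor_times=np.sort(T[E == 0]),
        max_time=float(T.max()),
        _step_times=times,
        _step_survival=sf.to_numpy(),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test (1 df, two-sided).

    Computes the pooled observed/expected/variance sums over distinct
    event times with the standard hypergeometric variance term.  When no
    events occur in either group (or the variance degenerates), returns
    statistic 0 and p = 1.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    Ta, Ea = group_a["time"].to_numpy(float), group_a["event"].to_numpy(int)
    Tb, Eb = group_b["time"].to_numpy(float), group_b["event"].to_numpy(int)
    event_times = np.unique(np.concatenate([Ta[Ea == 1], Tb[Eb == 1]]))
    if event_times.size == 0:
        return 0.0, 1.0
    O = E = V = 0.0
    for t in event_times:
        n1 = float(np.sum(Ta >= t))
        n2 = float(np.sum(Tb >= t))
        n = n1 + n2
        d1 = float(np.sum((Ta == t) & (Ea == 1)))
        d2 = float(np.sum((Tb == t) & (Eb == 1)))
        d = d1 + d2
        if n == 0:
            continue
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def delta_surv(curve_high: KMCurve, curve_low: KMCurve, t_months: float) -> float:
    """S_high(t) − S_low(t) in percentage points at a fixed horizon.

    Negative values mean the high-score group fares worse.  ``t_months``
    must lie within both curves' observed follow-up.
    """
    return 100.0 * (curve_high.survival_at(t_months) - curve_low.survival_at(t_months))
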