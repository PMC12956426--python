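import numpy as np
import pytest

from qpipd import AtRiskTable, DigitizedCurve, TickSet


@pytest.fixture
def tiny_exact():
    """Four-subject cohort: events at t=1,2,3, one censoring at t=1.5.

    The digitized curve, tick set and at-risk table identify the data
    uniquely (the only zero-objective integer reconstruction is the truth).
    """
    curve = DigitizedCurve(times=[1.0, 2.0, 3.0], values=[0.75, 0.375, 0.0], mode="km")
    ticks = TickSet(times=[1.5])
    at_risk = AtRiskTable(times=[0.0, 2.5], counts=[4, 1])
    truth = {"times": [1.0, 1.5, 2.0, 3.0], "statuses": [1, 0, 1, 1]}
    return curve, ticks, at_risk, truth


def exact_channels(truth_df):
    """Full-information channels for a simulated dataset, nothing rounded.

    At-risk counts at time 0 and every event time, ticks at every censoring
    time, exact KM values, total events: enough to pin the reconstruction.
    """
    from qpipd.estimators import kaplan_meier

    t = truth_df["time"].to_numpy()
    s = truth_df["status"].to_numpy().astype(int)
    km = kaplan_meier(t, s)
    curve = DigitizedCurve(times=km.times, values=km.sf.y, mode="km")
    ticks = TickSet(times=np.unique(t[s == 0])) if (s == 0).any() else None
    tau = np.concatenate(([0.0], np.unique(t[s > 0])))
    at_risk = AtRiskTable(times=tau, counts=[(t >= x - 1e-12).sum() for x in tau])
    return curve, ticks, at_risk, int((s > 0).sum())


@pytest.fixture
def grid_counts():
    """Map a pseudo-IPD back onto (d, c) counts on a problem's grid."""

    def _counts(ipd, times):
        t = ipd["time"].to_numpy()
        s = ipd["status"].to_numpy()
        d = np.array([((np.abs(t - g) < 1e-9) & (s > 0)).sum() for g in times])
        c = np.array([((np.abs(t - g) < 1e-9) & (s == 0)).sum() for g in times])
        return d, c

    return _counts
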