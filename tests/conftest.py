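import numpy as np
import pandas as pd
import pytest

from cwtburden.simulate import ScenarioConfig, generate_scenario
from cwtburden.trajectory import TrajectoryEnsembleSet


@pytest.fixture(scope="session")
def small_scenario():
    """A 3-day synthetic scenario shared by read-only tests."""
    cfg = ScenarioConfig(n_days=3, seed=11)
    return generate_scenario(cfg)


def make_point_set(traj_points, receptor=(39.98, 116.40), start="2024-01-01"):
    """Build a TrajectoryEnsembleSet from explicit endpoint coordinates.

    ``traj_points`` is a list of trajectories; each trajectory is a list of
    (lat, lon) endpoints (age 0 first).  Each trajectory gets its own
    arrival time, one hour apart, with member_id 1.
    """
    rows = []
    t0 = pd.Timestamp(start, tz="UTC")
    for k, pts in enumerate(traj_points):
        arrival = t0 + pd.Timedelta(hours=k)
        for a, (lat, lon) in enumerate(pts):
            rows.append({
                "arrival_time": arrival, "member_id": 1, "age_h": -a,
                "lat": lat, "lon": lon, "height": 250.0,
            })
    return TrajectoryEnsembleSet(pd.DataFrame(rows), receptor=receptor)


def series_for(tset, values):
    """Concentration series assigning ``values`` to the set's arrival times."""
    times = tset.arrival_times
    return pd.Series(np.asarray(values, dtype=float), index=times, name="pm25")
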