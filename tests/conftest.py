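import sys
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from movescape.tracks import ArgosRelocation, ArgosTrack


def make_track(
    xy: np.ndarray,
    dt_hours=1.0,
    animal_id: str = "w1",
    location_class: str = "1",
    ellipse=(500.0, 300.0, 45.0),
    lonlat: np.ndarray | None = None,
) -> ArgosTrack:
    """Track with given planar coordinates (km) and uniform-ish ellipses."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    dts = np.broadcast_to(np.asarray(dt_hours, dtype=float), (n - 1,))
    hours = np.concatenate([[0.0], np.cumsum(dts)])
    t0 = datetime(2019, 3, 1, tzinfo=timezone.utc)
    if lonlat is None:
        # rough degrees so lon/lat stay valid; planar xy is what models use
        lonlat = np.column_stack([-73.5 + xy[:, 0] / 80.0, -43.5 + xy[:, 1] / 111.0])
    relocs = [
        ArgosRelocation(
            timestamp=t0 + timedelta(hours=float(h)),
            lon=float(lonlat[i, 0]),
            lat=float(lonlat[i, 1]),
            location_class=location_class,
            ellipse_semi_major=ellipse[0],
            ellipse_semi_minor=ellipse[1],
            ellipse_orientation=ellipse[2],
        )
        for i, h in enumerate(hours)
    ]
    return ArgosTrack(animal_id=animal_id, relocations=relocs, projected_xy=xy)


@pytest.fixture
def rng():
    return np.random.default_rng(20190301)


@pytest.fixture
def toy_track(rng):
    """Projected 5-fix track with modest observation noise."""
    xy = np.cumsum(rng.normal(0.0, 1.5, (5, 2)), axis=0)
    return make_track(xy, dt_hours=rng.uniform(0.8, 1.4, 4))
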